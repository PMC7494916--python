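import numpy as np
import pytest

from riboreinit import (
    TranscriptModel,
    annotate_catalog,
    simulate_libraries,
    simulate_transcriptome,
)
from riboreinit.simulate import SimulationConfig, UORFDesign


@pytest.fixture(scope="session")
def stalled_sim():
    """Simulated study: GCG-stalled stops, 2-aa GCG uORFs, reinitiation failure.

    Moderate depth; shared across tests that only need realistic structure.
    """
    config = SimulationConfig(
        seed=11,
        n_transcripts=120,
        depth=300_000,
        uorf_designs=(UORFDesign(2, "GCG", 0.3),),
        stall_factors={"GCG": 8.0},
        reinit_failure=0.25,
    )
    transcriptome = simulate_transcriptome(config)
    libraries = {
        g: simulate_libraries(config, transcriptome, g) for g in ("WT", "KO1", "KO2")
    }
    catalog = annotate_catalog(transcriptome.models)
    return config, transcriptome, libraries, catalog


@pytest.fixture()
def toy_model():
    """A transcript with one contained 1-aa uORF (ATGTGA) in a 30-nt 5'UTR."""
    utr = "CCCTTTGGGCCCATGTGACCCTTTGGGCCC"
    cds = "ATG" + "GGC" * 8 + "GCG" + "TAG"
    return TranscriptModel(
        transcript_id="TOY1",
        gene_id="GTOY1",
        sequence=utr + cds + "CCCTTTGGG",
        cds_start=len(utr),
        cds_end=len(utr) + len(cds),
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
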