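"""Synthetic transcriptomes and footprint libraries with known ground truth.

The generator emulates the statistical structure the analysis stack
assumes, so every stage can be verified against planted truth:

* transcripts with a 5'UTR, a main ORF and a 3'UTR; designed uORFs are
  embedded in the 5'UTR.  Background sequence is drawn from a C/T/G
  alphabet so no unintended ATG (hence no unintended uORF) can arise;
* 80S footprint 5' ends 15 nt upstream of the ribosome's P-site codon:
  uniform elongation over translated ORFs plus initiation and termination
  peaks, and — in knockout libraries, at stop codons whose -1 codon has a
  stall factor > 1 — a queued-80S peak one ribosome length (30 nt) behind
  the termination peak, i.e. 45 nt upstream of the stop;
* 40S footprints (20-80 nt) from scanning background over the 5'UTR plus a
  recycling peak on each stop codon, scaled in knockouts by the stall
  factor of the stop's -1 codon;
* reduced main-ORF 80S density (reinitiation failure) in knockouts for
  transcripts carrying an affected uORF;
* per-transcript, per-library multiplicative lognormal abundance noise;
* exact library depths (reads are a single multinomial draw over the
  position-by-length grid), so depth conservation is exact and identical
  seeds give bit-identical output.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .annotation import SENSE_CODONS, TranscriptModel
from .footprints import FootprintLibrary, library_from_arrays

BACKGROUND_ALPHABET = np.array(list("CTG"))  # no A: background cannot form ATG
_NO_A_FILLERS = tuple(c for c in SENSE_CODONS if "A" not in c)
_UORF_STOP = "TAG"  # starts with T and ends with G: junction-safe in a no-A context


class SimulationError(ValueError):
    pass


@dataclass(frozen=True)
class UORFDesign:
    """A uORF to plant: amino-acid length, -1 codon, fraction of transcripts."""

    n_sense_codons: int
    codon_minus1: str
    fraction: float

    def __post_init__(self) -> None:
        if self.n_sense_codons < 1:
            raise SimulationError("uORF needs at least one sense codon")
        if self.n_sense_codons == 1 and self.codon_minus1 != "ATG":
            raise SimulationError("a 1-aa uORF's -1 codon is its own ATG")
        if self.codon_minus1 not in SENSE_CODONS:
            raise SimulationError(f"{self.codon_minus1!r} is not a sense codon")
        if not (0.0 <= self.fraction <= 1.0):
            raise SimulationError("fraction must be in [0, 1]")


@dataclass
class SimulationConfig:
    """Study-condition parameters for the generator.

    Geometry defaults reproduce 5'-end-assigned footprinting of HeLa-like
    data: a 15-nt offset from footprint 5' end to the P-site codon, ~30-nt
    80S footprints (so a queued ribosome sits 30 nt behind a stalled one,
    and its 5' end 45 nt upstream of the stop), 40S fragments of 20-80 nt.
    ``stall_factors`` maps a -1 codon to the fold increase of its stop's
    40S recycling peak in knockout libraries; wild type is always 1.
    """

    seed: int = 0
    n_transcripts: int = 200
    utr5_length_range: tuple[int, int] = (90, 240)
    cds_length_codons_range: tuple[int, int] = (100, 300)
    utr3_length_range: tuple[int, int] = (30, 90)
    uorf_designs: Sequence[UORFDesign] = field(default_factory=tuple)
    depth: int = 1_000_000
    lengths_80s: tuple[int, int] = (29, 31)
    lengths_40s: tuple[int, int] = (20, 80)
    offset80s: int = 15
    queue_spacing: int = 30
    stall_factors: dict[str, float] = field(default_factory=dict)
    queue_probability: float = 0.8
    reinit_failure: float = 1.0
    te_noise_sd: float = 0.2  # sd of the log2 per-transcript abundance multiplier
    init_peak_weight: float = 10.0  # relative to one elongation position
    term_peak_weight: float = 10.0
    scan_weight: float = 1.0  # 40S scanning background per 5'UTR position
    stop_peak_weight: float = 20.0  # baseline 40S recycling-peak weight
    uorf_density: float = 1.0  # uORF 80S density relative to mORF
    morf_minus1_codons: Optional[Sequence[str]] = None  # round-robin; None = random
    wt_label: str = "WT"

    def __post_init__(self) -> None:
        if sum(d.fraction for d in self.uorf_designs) > 1.0 + 1e-9:
            raise SimulationError("uORF design fractions sum above 1")
        if any(f <= 0 for f in self.stall_factors.values()):
            raise SimulationError("stall factors must be positive")
        if self.depth <= 0:
            raise SimulationError("depth must be positive")


@dataclass
class SyntheticTranscriptome:
    """Generated transcripts plus the planted ground truth."""

    models: list[TranscriptModel]
    truth: pd.DataFrame  # one row per transcript

    def write_fasta(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for m in self.models:
                fh.write(f">{m.transcript_id}\n{m.sequence}\n")

    def write_cds_table(self, path: str | Path) -> None:
        pd.DataFrame(
            {
                "transcript_id": [m.transcript_id for m in self.models],
                "gene_id": [m.gene_id for m in self.models],
                "cds_start": [m.cds_start for m in self.models],
                "cds_end": [m.cds_end for m in self.models],
            }
        ).to_csv(path, sep="\t", index=False)


def _rng(config: SimulationConfig, *labels: str) -> np.random.Generator:
    parts = [config.seed] + [zlib.crc32(s.encode()) for s in labels]
    return np.random.default_rng(parts)


def _background(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(BACKGROUND_ALPHABET, size=n))


def _uorf_sequence(rng: np.random.Generator, design: UORFDesign) -> str:
    if design.n_sense_codons == 1:
        return "ATG" + _UORF_STOP
    fillers = rng.choice(_NO_A_FILLERS, size=design.n_sense_codons - 2)
    return "ATG" + "".join(fillers) + design.codon_minus1 + _UORF_STOP


def simulate_transcriptome(config: SimulationConfig) -> SyntheticTranscriptome:
    """Generate transcript sequences with planted uORFs and a truth table.

    Each transcript carries at most one designed uORF, placed at a random
    in-UTR position such that its stop codon lies fully within the 5'UTR.
    The truth table records the planted uORF coordinates and -1 codon, the
    mORF -1 codon, and whether the transcript is "affected" (its uORF's -1
    codon has a knockout stall factor > 1, so reinitiation failure applies
    to the mORF in knockouts).
    """
    rng = _rng(config, "transcriptome")
    n = config.n_transcripts

    # assign designs to disjoint transcript blocks after a fixed shuffle
    order = rng.permutation(n)
    assignment: list[Optional[UORFDesign]] = [None] * n
    cursor = 0
    for design in config.uorf_designs:
        count = int(round(design.fraction * n))
        for idx in order[cursor : cursor + count]:
            assignment[idx] = design
        cursor += count

    if config.morf_minus1_codons is not None:
        morf_minus1 = [
            config.morf_minus1_codons[i % len(config.morf_minus1_codons)] for i in range(n)
        ]
    else:
        morf_minus1 = list(rng.choice(SENSE_CODONS, size=n))

    models: list[TranscriptModel] = []
    truth_rows = []
    lo_u, hi_u = config.utr5_length_range
    lo_c, hi_c = config.cds_length_codons_range
    lo_3, hi_3 = config.utr3_length_range
    for i in range(n):
        tid = f"TX{i:05d}"
        gid = f"G{i:05d}"
        utr_len = int(rng.integers(lo_u, hi_u + 1))
        n_codons = int(rng.integers(lo_c, hi_c + 1))
        utr3_len = int(rng.integers(lo_3, hi_3 + 1))

        utr = _background(rng, utr_len)
        design = assignment[i]
        uorf_start = uorf_stop = None
        if design is not None:
            uorf_nt = 3 * (design.n_sense_codons + 1)
            # keep the start-codon 5'-end peak window on the transcript
            min_start = config.offset80s + 4
            if uorf_nt + min_start > utr_len:
                raise SimulationError(
                    f"{tid}: designed uORF ({uorf_nt} nt) does not fit the 5'UTR "
                    f"({utr_len} nt) with a {min_start}-nt cap margin"
                )
            uorf_seq = _uorf_sequence(rng, design)
            uorf_start = int(rng.integers(min_start, utr_len - uorf_nt + 1))
            utr = utr[:uorf_start] + uorf_seq + utr[uorf_start + uorf_nt :]
            uorf_stop = uorf_start + uorf_nt - 3

        m1 = morf_minus1[i]
        n_fillers = n_codons - 2  # ATG + fillers + minus1
        if n_fillers < 0:
            raise SimulationError("CDS needs at least 2 sense codons")
        cds = "ATG" + "".join(rng.choice(_NO_A_FILLERS, size=n_fillers)) + m1 + "TAG"
        seq = utr + cds + _background(rng, utr3_len)
        model = TranscriptModel(
            transcript_id=tid,
            gene_id=gid,
            sequence=seq,
            cds_start=utr_len,
            cds_end=utr_len + len(cds),
        )
        models.append(model)

        uorf_factor = (
            config.stall_factors.get(design.codon_minus1, 1.0) if design is not None else 1.0
        )
        truth_rows.append(
            {
                "transcript_id": tid,
                "gene_id": gid,
                "utr5_length": utr_len,
                "cds_start": model.cds_start,
                "cds_end": model.cds_end,
                "morf_minus1": m1,
                "morf_stall_factor": config.stall_factors.get(m1, 1.0),
                "has_uorf": design is not None,
                "uorf_start": uorf_start,
                "uorf_stop_start": uorf_stop,
                "uorf_n_sense_codons": design.n_sense_codons if design else None,
                "uorf_minus1": design.codon_minus1 if design else None,
                "uorf_stall_factor": uorf_factor if design is not None else None,
                "affected": design is not None and uorf_factor > 1.0,
            }
        )
    return SyntheticTranscriptome(models=models, truth=pd.DataFrame(truth_rows))


def write_truth(transcriptome: SyntheticTranscriptome, path: str | Path) -> None:
    """Write the per-transcript ground-truth table as TSV."""
    transcriptome.truth.to_csv(path, sep="\t", index=False)


def read_truth(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def _position_weights(
    config: SimulationConfig,
    transcriptome: SyntheticTranscriptome,
    genotype: str,
    assay: str,
    abundance: np.ndarray,
) -> list[np.ndarray]:
    """Per-transcript expected 5'-end weight vectors for one library."""
    is_ko = genotype != config.wt_label
    off = config.offset80s
    out = []
    for m, row, a in zip(
        transcriptome.models, transcriptome.truth.to_dict("records"), abundance
    ):
        w = np.zeros(len(m.sequence))
        if assay == "RNA":
            w[:] = a
        elif assay == "RIBO80S":
            g = (
                config.reinit_failure
                if (is_ko and bool(row["affected"]))
                else 1.0
            )
            # mORF: elongation (one position per P-site codon), init and term peaks
            psites = np.arange(m.cds_start, m.cds_end - 3, 3)
            w[psites - off] += g * a
            w[m.cds_start - off] += config.init_peak_weight * g * a
            w[m.stop_start - off] += config.term_peak_weight * g * a
            morf_stalled = config.stall_factors.get(str(row["morf_minus1"]), 1.0) > 1.0
            if is_ko and morf_stalled:
                w[m.stop_start - off - config.queue_spacing] += (
                    config.queue_probability * config.term_peak_weight * g * a
                )
            if bool(row["has_uorf"]):
                us, ustop = int(row["uorf_start"]), int(row["uorf_stop_start"])
                d = config.uorf_density
                upsites = np.arange(us, ustop, 3)
                pos = upsites - off
                w[pos[pos >= 0]] += d * a
                if us - off >= 0:
                    w[us - off] += config.init_peak_weight * d * a
                if ustop - off >= 0:
                    w[ustop - off] += config.term_peak_weight * d * a
                uorf_stalled = (row["uorf_stall_factor"] or 1.0) > 1.0
                qpos = ustop - off - config.queue_spacing
                if is_ko and uorf_stalled and qpos >= 0:
                    w[qpos] += config.queue_probability * config.term_peak_weight * d * a
        elif assay == "RIBO40S":
            w[: m.cds_start] += config.scan_weight * a
            factor_m = (
                config.stall_factors.get(str(row["morf_minus1"]), 1.0) if is_ko else 1.0
            )
            w[m.stop_start - off] += config.stop_peak_weight * factor_m * a
            if bool(row["has_uorf"]):
                ustop = int(row["uorf_stop_start"])
                factor_u = (row["uorf_stall_factor"] or 1.0) if is_ko else 1.0
                if ustop - off >= 0:
                    w[ustop - off] += config.stop_peak_weight * factor_u * a
        else:
            raise SimulationError(f"unknown assay {assay!r}")
        out.append(w)
    return out


def simulate_library(
    config: SimulationConfig,
    transcriptome: SyntheticTranscriptome,
    genotype: str,
    assay: str,
) -> FootprintLibrary:
    """Draw one library of exactly ``config.depth`` reads.

    Reads are a single multinomial draw over the (position x length)
    grid of expected weights, so total read count equals the configured
    depth exactly and identical seeds give identical libraries.
    """
    rng = _rng(config, "library", genotype, assay)
    n = config.n_transcripts
    abundance = 2.0 ** rng.normal(0.0, config.te_noise_sd, size=n)
    weights = _position_weights(config, transcriptome, genotype, assay, abundance)

    lengths = {
        "RNA": np.arange(config.lengths_80s[0], config.lengths_80s[1] + 1),
        "RIBO80S": np.arange(config.lengths_80s[0], config.lengths_80s[1] + 1),
        "RIBO40S": np.arange(config.lengths_40s[0], config.lengths_40s[1] + 1),
    }[assay]
    n_len = len(lengths)

    flat = np.concatenate(weights)
    total = flat.sum()
    if total <= 0:
        raise SimulationError("all-zero expected weights")
    # positions first, then lengths per position (multinomial splitting:
    # jointly equivalent to one draw over the position x length grid)
    counts_pos = rng.multinomial(config.depth, flat / total)
    nzp = np.flatnonzero(counts_pos)
    len_counts = rng.multinomial(counts_pos[nzp], np.full(n_len, 1.0 / n_len))

    pos_rep = np.repeat(nzp, n_len)
    len_rep = np.tile(lengths, len(nzp))
    cnt = len_counts.ravel()
    keep = cnt > 0
    pos_idx = pos_rep[keep]

    bounds = np.cumsum([0] + [len(w) for w in weights])
    tx_idx = np.searchsorted(bounds, pos_idx, side="right") - 1
    five_prime = pos_idx - bounds[tx_idx]
    all_tids = np.array([m.transcript_id for m in transcriptome.models], dtype=object)
    return library_from_arrays(
        library_id=f"{genotype}_{assay}",
        condition=genotype,
        assay=assay,
        transcript_ids=all_tids[tx_idx],
        five_prime=five_prime,
        read_length=len_rep[keep],
        weight=cnt[keep].astype(float),
        total_alignments=float(config.depth),
    )


def simulate_libraries(
    config: SimulationConfig,
    transcriptome: SyntheticTranscriptome,
    genotype: str,
    assays: Sequence[str] = ("RNA", "RIBO80S", "RIBO40S"),
) -> dict[str, FootprintLibrary]:
    """Simulate the RNA / 80S / 40S libraries of one genotype."""
    return {
        assay: simulate_library(config, transcriptome, genotype, assay) for assay in assays
    }
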