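"""TE computation, Z-vs-Z outlier scan, gene collapse, uORF-length groups."""

import numpy as np
import pandas as pd
import pytest

from riboreinit import (
    TranscriptModel,
    collapse_to_gene,
    compute_te,
    te_log2fc,
    uorf_length_group_test,
    zz_outlier_scan,
)
from riboreinit.footprints import library_from_arrays
from riboreinit.te import TEError


def lib_from_positions(tid_pos, depth, assay="RIBO80S"):
    tids = [t for t, _ in tid_pos]
    pos = np.array([p for _, p in tid_pos])
    return library_from_arrays(
        "l", "WT", assay, tids, pos, np.full(len(pos), 30), np.ones(len(pos)),
        total_alignments=depth, length_range=(1, 100),
    )


def toy_models():
    seq = "C" * 50 + "ATG" + "GGC" * 30 + "TAA" + "C" * 20
    return [TranscriptModel(f"T{i}", f"G{i}", seq, 50, 50 + 96) for i in range(2)]


def test_te_is_cds80s_over_transcript_rna():
    models = toy_models()
    lib80 = lib_from_positions([("T0", 60)] * 50, depth=1e6)
    librna = lib_from_positions([("T0", 10)] * 100, depth=1e6, assay="RNA")
    te = compute_te(lib80, librna, models, min_rna=1, min_80s=1)
    assert te["T0"].te == pytest.approx(0.5)
    assert te["T1"].te is None and not te["T1"].detected


def test_te_invariant_to_depth_rescaling():
    models = toy_models()
    lib80 = lib_from_positions([("T0", 60)] * 40, depth=2e5)
    librna = lib_from_positions([("T0", 10)] * 80, depth=8e5, assay="RNA")
    te1 = compute_te(lib80, librna, models, min_rna=1, min_80s=1)["T0"].te
    lib80c = lib_from_positions([("T0", 60)] * 400, depth=2e6)
    librnac = lib_from_positions([("T0", 10)] * 800, depth=8e6, assay="RNA")
    te3 = compute_te(lib80c, librnac, models, min_rna=1, min_80s=1)["T0"].te
    assert te3 == pytest.approx(te1, rel=1e-9)  # x10 reads at x10 depth: identical TE


@pytest.mark.parametrize("ko, wt, expected", [(1.0, 1.0, 0.0), (0.25, 1.0, -2.0), (8.0, 2.0, 2.0)])
def test_te_log2fc_values(ko, wt, expected):
    assert te_log2fc(ko, wt) == pytest.approx(expected)


def test_te_log2fc_antisymmetric(rng):
    for _ in range(100):
        a, b = rng.uniform(0.01, 10, 2)
        assert te_log2fc(a, b) == pytest.approx(-te_log2fc(b, a))
    with pytest.raises(TEError):
        te_log2fc(0.0, 1.0)


def test_zz_scan_location_and_scale_invariance(rng):
    x = rng.normal(0, 1, 2000)
    x[:40] -= 5.0
    base = zz_outlier_scan(x)
    shifted = zz_outlier_scan(x + 17.3)
    scaled = zz_outlier_scan(x * 4.2 + 1.0)
    assert list(base["flag"]) == list(shifted["flag"]) == list(scaled["flag"])


def test_zz_scan_symmetric_null_balance(rng):
    x = rng.standard_t(df=3, size=8000)  # heavy-tailed, symmetric
    scan = zz_outlier_scan(x)
    n_up = (scan["flag"] == "up").sum()
    n_down = (scan["flag"] == "down").sum()
    assert abs(n_up - n_down) <= 4 * np.sqrt(n_up + n_down + 1)


def test_zz_scan_degenerate_and_small_inputs():
    with pytest.raises(TEError, match="degenerate"):
        zz_outlier_scan(np.zeros(100) + 1.0)
    with pytest.raises(TEError, match="at least 50"):
        zz_outlier_scan(np.arange(10))


def test_collapse_to_gene_keeps_most_extreme_variant(rng):
    records = pd.DataFrame(
        {
            "transcript_id": [f"T{i}" for i in range(9)],
            "gene_id": ["A", "A", "B", "B", "B", "C", "D", "D", "E"],
            "mean_log2fc_te": [-1.2, -0.3, 0.5, -2.0, 1.9, 0.0, 0.7, -0.7, 3.0],
        }
    )
    out = collapse_to_gene(records).set_index("gene_id")
    assert out.loc["A", "mean_log2fc_te"] == -1.2
    assert out.loc["B", "mean_log2fc_te"] == -2.0
    assert out.loc["D", "transcript_id"] == "T6"  # |0.7| tie: lexicographic transcript
    # random multisets vs max-by-|x| oracle
    for _ in range(20):
        n = int(rng.integers(2, 30))
        frame = pd.DataFrame(
            {
                "transcript_id": [f"T{i:02d}" for i in range(n)],
                "gene_id": rng.choice(["G1", "G2", "G3"], n),
                "mean_log2fc_te": rng.normal(0, 2, n),
            }
        )
        got = collapse_to_gene(frame)
        for gene, grp in frame.groupby("gene_id"):
            expect = grp["mean_log2fc_te"].abs().max()
            assert abs(got.set_index("gene_id").loc[gene, "mean_log2fc_te"]) == pytest.approx(expect)


def make_group_inputs(rng, shift_1aa=0.0, n_per=300):
    """TE records plus a catalog with 1-aa, 5-aa and 20-aa uORF transcripts."""
    rows, cat = [], []
    for i in range(4 * n_per):
        tid = f"T{i:05d}"
        kind = i % 4
        x = rng.normal(0, 1)
        if kind == 1:
            cat.append((tid, 0, 1))
            x += shift_1aa
        elif kind == 2:
            cat.append((tid, 0, 5))
        elif kind == 3:
            cat.append((tid, 0, 20))
        rows.append((tid, x))
    records = pd.DataFrame(rows, columns=["transcript_id", "mean_log2fc_te"])
    catalog = pd.DataFrame(cat, columns=["transcript_id", "uorf_start", "n_sense_codons"])
    return records, catalog


def test_group_test_type_one_and_power(rng):
    records, catalog = make_group_inputs(rng)
    _, p_null, _ = uorf_length_group_test(records, catalog, bins=((1, 1), (2, 10), (11, 50)))
    assert p_null > 1e-4  # all groups from one distribution
    records, catalog = make_group_inputs(rng, shift_1aa=-1.0)
    summary, p_alt, pairwise = uorf_length_group_test(
        records, catalog, bins=((1, 1), (2, 10), (11, 50))
    )
    assert p_alt < 1e-6
    assert pairwise.set_index("group").loc["1", "p_adjusted"] < 1e-6
    assert summary.set_index("group").loc["1", "median"] < summary.set_index("group").loc["no uORF", "median"]


def test_one_aa_transcripts_excluded_from_other_groups(rng):
    records = pd.DataFrame(
        {"transcript_id": [f"T{i}" for i in range(120)], "mean_log2fc_te": rng.normal(0, 1, 120)}
    )
    cat_rows = []
    for i in range(40):  # transcripts carrying BOTH a 1-aa and a 20-aa uORF
        cat_rows += [(f"T{i}", 0, 1), (f"T{i}", 30, 20)]
    for i in range(40, 80):
        cat_rows.append((f"T{i}", 0, 20))
    catalog = pd.DataFrame(cat_rows, columns=["transcript_id", "uorf_start", "n_sense_codons"])
    summary, _, _ = uorf_length_group_test(records, catalog, bins=((1, 1), (11, 50)))
    counts = summary.set_index("group")["n"]
    assert counts["1"] == 40  # dual carriers counted once, only here
    assert counts["11-50"] == 40  # and not in the longer-uORF group
    assert counts["no uORF"] == 40
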