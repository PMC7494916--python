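"""40S stall scoring at stop codons and translated-uORF detection."""

import math

import numpy as np
import pandas as pd
import pytest

from riboreinit import (
    StopSite,
    annotate_catalog,
    classify_stalled,
    detect_translated_uorfs,
    morf_stop_sites,
    stall_scores,
)
from riboreinit.footprints import library_from_arrays
from riboreinit.recycling import RecyclingError, peak_window


def lib40(tid_pos_weight, depth, library_id="l", condition="WT"):
    tids = [t for t, _, _ in tid_pos_weight]
    pos = np.array([p for _, p, _ in tid_pos_weight])
    wts = np.array([w for _, _, w in tid_pos_weight], dtype=float)
    return library_from_arrays(
        library_id, condition, "RIBO40S", tids, pos, np.full(len(pos), 40), wts,
        total_alignments=depth,
    )


def sites_at(positions, kind="mORF", codon="GCG"):
    return [
        StopSite(f"s{i}", f"T{i}", p, kind, codon) for i, p in enumerate(positions)
    ]


def test_peak_window_is_ten_nt_centered_on_peak():
    a, b = peak_window(100)
    assert (a, b) == (96, 106) and b - a == 10


def test_stall_score_zero_when_ko_equals_wt():
    # many sites so the robust Z denominator is defined; one site perturbed
    positions = [100] * 30
    rows = [(f"T{i}", 100 - 15, 50.0) for i in range(30)]
    wt = lib40(rows, depth=1e6)
    ko_rows = [(f"T{i}", 100 - 15, 50.0 if i else 200.0) for i in range(30)]
    ko = lib40(ko_rows, depth=1e6, condition="KO")
    scores = stall_scores(wt, {"KO1": ko, "KO2": ko}, sites_at(positions), offset40s=15)
    assert scores["mean_log2fc"].iloc[1:].abs().max() == pytest.approx(0.0, abs=1e-12)
    assert scores["mean_log2fc"].iloc[0] == pytest.approx(2.0, abs=1e-2)  # 4x, tiny pseudocount


def test_stall_score_fourfold_is_two_log_units():
    rows_wt = [(f"T{i}", 85, 100.0) for i in range(25)]
    rows_ko = [(f"T{i}", 85, 400.0) for i in range(25)] + [("T0", 85, 0.0001)]
    wt = lib40(rows_wt, depth=1e6)
    ko = lib40(rows_ko[:-1], depth=1e6, condition="KO")
    scores = stall_scores(
        wt, {"KO1": ko, "KO2": ko}, sites_at([100] * 25), offset40s=15, pseudocount=0.0
    )
    np.testing.assert_allclose(scores["mean_log2fc"], 2.0)


def test_stall_scores_match_hand_computed_oracle(rng):
    depth_wt, depth_k1, depth_k2 = 3e5, 4e5, 5e5
    pc = 0.05
    n = 40
    w_wt = rng.integers(1, 200, n).astype(float)
    w_k1 = rng.integers(1, 200, n).astype(float)
    w_k2 = rng.integers(1, 200, n).astype(float)
    mk = lambda w, d, c: lib40([(f"T{i}", 85, w[i]) for i in range(n)], d, condition=c)
    scores = stall_scores(
        mk(w_wt, depth_wt, "WT"),
        {"KO1": mk(w_k1, depth_k1, "KO1"), "KO2": mk(w_k2, depth_k2, "KO2")},
        sites_at([100] * n),
        offset40s=15,
        pseudocount=pc,
    )
    for i in range(n):
        cpm = lambda w, d: w * 1e6 / d
        fc1 = math.log2((cpm(w_k1[i], depth_k1) + pc) / (cpm(w_wt[i], depth_wt) + pc))
        fc2 = math.log2((cpm(w_k2[i], depth_k2) + pc) / (cpm(w_wt[i], depth_wt) + pc))
        assert scores["mean_log2fc"].iloc[i] == pytest.approx((fc1 + fc2) / 2, rel=1e-9)
    # robust Z recomputed independently
    x = scores["mean_log2fc"].to_numpy()
    med = np.median(x)
    mad = np.median(np.abs(x - med))
    np.testing.assert_allclose(scores["z"], (x - med) / (1.4826 * mad), rtol=1e-9)


def test_stall_scores_invariant_to_ko_label_swap(rng):
    n = 30
    w = lambda: rng.integers(1, 100, n).astype(float)
    mk = lambda wts, c: lib40([(f"T{i}", 85, wts[i]) for i in range(n)], 1e5, condition=c)
    wt, k1, k2 = w(), w(), w()
    a = stall_scores(mk(wt, "WT"), {"KO1": mk(k1, "K1"), "KO2": mk(k2, "K2")},
                     sites_at([100] * n), offset40s=15)
    b = stall_scores(mk(wt, "WT"), {"KO1": mk(k2, "K2"), "KO2": mk(k1, "K1")},
                     sites_at([100] * n), offset40s=15)
    np.testing.assert_allclose(a["mean_log2fc"], b["mean_log2fc"], rtol=1e-12)
    np.testing.assert_allclose(a["z"], b["z"], rtol=1e-12)


def test_pseudocount_shrinks_scores_toward_zero(rng):
    n = 30
    wt_w = rng.integers(1, 50, n).astype(float)
    ko_w = rng.integers(1, 50, n).astype(float)
    mk = lambda wts, c: lib40([(f"T{i}", 85, wts[i]) for i in range(n)], 1e6, condition=c)
    small = stall_scores(mk(wt_w, "WT"), {"KO1": mk(ko_w, "K"), "KO2": mk(ko_w, "K")},
                         sites_at([100] * n), offset40s=15, pseudocount=0.01)
    big = stall_scores(mk(wt_w, "WT"), {"KO1": mk(ko_w, "K"), "KO2": mk(ko_w, "K")},
                       sites_at([100] * n), offset40s=15, pseudocount=5.0)
    assert (big["mean_log2fc"].abs() <= small["mean_log2fc"].abs() + 1e-12).all()


def test_stall_scan_requires_two_ko_libraries():
    lib = lib40([("T0", 85, 5.0)], 1e4)
    with pytest.raises(RecyclingError, match="two knockout"):
        stall_scores(lib, {"KO1": lib}, sites_at([100]), offset40s=15)


@pytest.mark.parametrize(
    "z, fold, expected", [(3.0, 5.0, True), (3.0, 3.9, False), (1.0, 9.0, False)]
)
def test_classification_gates(z, fold, expected):
    scores = pd.DataFrame({"z": [z], "fold_change": [fold]})
    assert classify_stalled(scores)["classified"].iloc[0] == expected


def test_translated_uorf_window_trivials():
    catalog = pd.DataFrame(
        {
            "transcript_id": ["T0", "T1"],
            "uorf_start": [50, 50],
            "stop_start": [56, 56],
            "n_sense_codons": [2, 2],
            "uorf_class": ["contained"] * 2,
            "codon_minus1": ["GCG"] * 2,
            "codon_minus2": [None, None],
            "codon_minus3": [None, None],
        }
    )
    # T0 has a read exactly at the initiation 5'-end peak, T1 only 30 nt downstream
    lib = library_from_arrays(
        "l", "WT", "RIBO80S", ["T0", "T1"], np.array([50 - 15, 50 - 15 + 30]),
        np.array([30, 30]), np.array([1.0, 1.0]), total_alignments=100.0,
    )
    kept = detect_translated_uorfs([lib], catalog)
    assert list(kept["transcript_id"]) == ["T0"]


def test_translated_uorfs_recovered_from_simulation(stalled_sim):
    config, transcriptome, libraries, catalog = stalled_sim
    libs80 = [libraries[g]["RIBO80S"] for g in ("WT", "KO1", "KO2")]
    kept = detect_translated_uorfs(libs80, catalog)
    planted = set(transcriptome.truth.loc[transcriptome.truth.has_uorf, "transcript_id"])
    assert set(kept["transcript_id"]) == planted


def test_morf_sites_carry_consistent_context(stalled_sim):
    _, transcriptome, _, _ = stalled_sim
    sites = morf_stop_sites(transcriptome.models)
    truth = transcriptome.truth.set_index("transcript_id")
    for s in sites:
        assert s.codon_minus1 == truth.loc[s.transcript_id, "morf_minus1"]
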