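"""Footprint libraries: loading, CPM normalization, profiles, peak finding."""

import numpy as np
import pytest

from riboreinit import TranscriptModel, find_peak_offset, metagene_profile, transcript_trace
from riboreinit.footprints import (
    FootprintError,
    FootprintLibrary,
    MetageneProfile,
    library_from_arrays,
    load_alignment_library,
    smooth_profile,
    write_alignment_sam,
    write_alignment_tsv,
)


def make_library(rows, depth=None, assay="RIBO80S", length_range=None):
    tids = [r[0] for r in rows]
    return library_from_arrays(
        "lib", "WT", assay,
        tids,
        np.array([r[1] for r in rows]),
        np.array([r[2] for r in rows]),
        np.array([r[3] for r in rows], dtype=float),
        total_alignments=depth,
        length_range=length_range,
    )


def test_tsv_load_filters_lengths_but_depth_precedes_filtering(tmp_path):
    path = tmp_path / "aln.tsv"
    path.write_text(
        "transcript_id\tfive_prime\tread_length\tweight\n"
        + "\n".join(f"T1\t{i * 10}\t{ln}\t1.0" for i, ln in enumerate([30, 29, 31, 30, 18]))
        + "\n"
    )
    lib = load_alignment_library(path, assay="RIBO80S", condition="WT", length_range=(25, 35))
    assert lib.total_alignments == 5
    assert lib.raw_window_count("T1", 0, 10**6) == 4


def test_empty_alignment_file_is_an_error(tmp_path):
    path = tmp_path / "empty.tsv"
    path.write_text("transcript_id\tfive_prime\tread_length\tweight\n")
    with pytest.raises(FootprintError, match="no alignments"):
        load_alignment_library(path, assay="RNA", condition="WT")


def test_sam_and_tsv_encodings_agree(tmp_path):
    rows = [("T1", 5, 30, 1.0), ("T1", 5, 30, 1.0), ("T2", 40, 28, 1.0)]
    lib = make_library(rows)
    sam = tmp_path / "lib.sam"
    tsv = tmp_path / "lib.tsv"
    write_alignment_sam(lib, sam, {"T1": 200, "T2": 200})
    write_alignment_tsv(lib, tsv)
    from_sam = load_alignment_library(sam, assay="RIBO80S", condition="WT")
    from_tsv = load_alignment_library(tsv, assay="RIBO80S", condition="WT")
    assert from_sam.total_alignments == from_tsv.total_alignments == 3
    for tid in ("T1", "T2"):
        assert from_sam.raw_window_count(tid, 0, 200) == from_tsv.raw_window_count(tid, 0, 200)
        np.testing.assert_allclose(
            from_sam.position_weights(tid, 200), from_tsv.position_weights(tid, 200)
        )


def test_normalized_count_matches_per_read_loop(rng):
    n = 500
    rows = [
        ("T1", int(p), 30, float(w))
        for p, w in zip(rng.integers(0, 300, n), rng.uniform(0.1, 2.0, n))
    ]
    lib = make_library(rows, depth=12345.0)
    for a, b in [(0, 300), (50, 60), (120, 121), (250, 400)]:
        naive = sum(w for _, p, _, w in rows if a <= p < b) * 1e6 / 12345.0
        assert lib.normalized_count("T1", a, b) == pytest.approx(naive, rel=1e-9)


def test_window_additivity_and_depth_invariance(rng):
    rows = [("T1", int(p), 30, 1.0) for p in rng.integers(0, 200, 200)]
    lib = make_library(rows, depth=1e6)
    left = lib.normalized_count("T1", 0, 100)
    right = lib.normalized_count("T1", 100, 200)
    assert left + right == pytest.approx(lib.normalized_count("T1", 0, 200), rel=1e-12)
    scaled = make_library([(t, p, l, w * 7.5) for t, p, l, w in rows], depth=7.5e6)
    assert scaled.normalized_count("T1", 0, 200) == pytest.approx(
        lib.normalized_count("T1", 0, 200), rel=1e-9
    )


def test_counts_in_window_trivials():
    lib = make_library([("T1", 10, 30, 1.0)] * 3, depth=1e6)
    assert lib.normalized_count("T1", 10, 11) == pytest.approx(3.0)
    assert lib.normalized_count("T1", 50, 60) == 0.0
    assert lib.normalized_count("ABSENT", 0, 10) == 0.0


def simple_model(utr=30, codons=20):
    seq = "C" * utr + "ATG" + "GGC" * (codons - 1) + "TAA" + "C" * 20
    return TranscriptModel("T1", "G1", seq, utr, utr + 3 * codons + 3)


def test_metagene_single_alignment_at_anchor():
    m = simple_model()
    lib = make_library([("T1", m.cds_start, 30, 1.0)], depth=1e6)
    prof = metagene_profile([lib], [m], "start", 10, 10)
    assert prof.value_at(0) == pytest.approx(1.0)
    assert prof.values.sum() == pytest.approx(1.0)


def test_metagene_mass_conservation(rng):
    m = simple_model(utr=60, codons=40)
    rows = [("T1", int(p), 30, 1.0) for p in rng.integers(0, 150, 400)]
    lib = make_library(rows, depth=2e5)
    L = R = 80
    prof = metagene_profile([lib], [m], "stop", L, R)
    anchor = m.cds_end - 3
    windowed = lib.normalized_count("T1", max(anchor - L, 0), anchor + R + 1)
    assert prof.values.sum() == pytest.approx(windowed, rel=1e-9)


def test_smoothing_preserves_constant_and_widens_even_windows():
    const = np.full(31, 4.2)
    np.testing.assert_allclose(smooth_profile(const, 3), const)
    ramp = np.arange(21, dtype=float)
    np.testing.assert_allclose(smooth_profile(ramp, 10), smooth_profile(ramp, 11))


def test_transcript_trace_properties(rng):
    m = simple_model(utr=50, codons=30)
    rows = [("T1", int(p), 30, 1.0) for p in rng.integers(0, len(m.sequence), 300)]
    lib = make_library(rows, depth=1e6)
    trace = transcript_trace(lib, m)
    assert trace.sum() == pytest.approx(lib.normalized_count("T1", 0, len(m.sequence)), rel=1e-9)
    doubled = make_library([(t, p, l, 2.0) for t, p, l, _ in rows], depth=2e6)
    np.testing.assert_allclose(transcript_trace(doubled, m), trace, rtol=1e-9)
    empty = make_library([("OTHER", 0, 30, 1.0)], depth=1e6)
    assert not transcript_trace(empty, m).any()


def test_trace_mrna_scaling_requires_rna_library():
    m = simple_model()
    lib = make_library([("T1", 5, 30, 1.0)], depth=1e6)
    with pytest.raises(FootprintError):
        transcript_trace(lib, m, scale_mode="per_mrna_abundance")


def test_find_peak_offset_tie_breaks():
    offsets = np.arange(-20, 21)
    values = np.zeros(41)
    values[offsets == -15] = 5.0
    prof = MetageneProfile("stop", offsets, values)
    assert find_peak_offset(prof, (-20, 20)) == -15
    values = np.zeros(41)
    values[offsets == -16] = 3.0
    values[offsets == -14] = 3.0
    assert find_peak_offset(MetageneProfile("stop", offsets, values), (-20, 0)) == -14
    values = np.zeros(41)
    values[offsets == -14] = 3.0
    values[offsets == 14] = 3.0
    assert find_peak_offset(MetageneProfile("stop", offsets, values), (-20, 20)) == -14
    with pytest.raises(FootprintError, match="no peak"):
        find_peak_offset(MetageneProfile("stop", offsets, np.zeros(41)), (-5, 5))
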