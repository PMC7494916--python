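"""Footprint libraries: 5'-end assignment, depth normalization, profiles.

Every alignment is reduced to the transcript coordinate of its 5'-most
nucleotide (5'-end assignment).  For 80S footprints the 5' end sits 15 nt
upstream of the first nucleotide of the ribosome's P-site codon, so
initiation peaks appear 15 nt upstream of start codons and termination
peaks 15 nt upstream of stop codons in metagene profiles.

Depth normalization is counts per million alignments (CPM): the total
alignment count of a library is fixed *before* any footprint-length
filtering, so filtered and unfiltered views of one library share a common
scale, and fold changes between libraries are depth-free.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import pysam

from .annotation import TranscriptModel

logger = logging.getLogger(__name__)

#: Default footprint-length retention windows per assay (nt).
DEFAULT_LENGTH_RANGES: dict[str, tuple[int, int]] = {
    "RIBO80S": (25, 35),
    "RIBO40S": (20, 80),
    "RNA": (1, 10**9),
}

#: 5'-end offset of an 80S footprint to its P-site codon (nt).
OFFSET_80S = 15


class FootprintError(ValueError):
    pass


@dataclass
class FootprintLibrary:
    """One sequencing library of 5'-end-assigned alignments.

    ``data`` maps transcript_id to a record array with fields
    ``five_prime`` (int), ``read_length`` (int) and ``weight`` (float);
    identical (position, length) pairs may be aggregated with summed
    weight.  ``total_alignments`` is the library depth used for CPM
    normalization and is fixed at load time, before length filtering.
    """

    library_id: str
    condition: str
    assay: str
    total_alignments: float
    data: dict[str, np.ndarray] = field(default_factory=dict)
    _dense_cache: dict[str, np.ndarray] = field(default_factory=dict, repr=False)

    def transcripts(self) -> list[str]:
        return list(self.data)

    def raw_window_count(self, transcript_id: str, a: int, b: int) -> float:
        """Sum of alignment weights with 5' end in [a, b). Unknown transcript -> 0."""
        arr = self.data.get(transcript_id)
        if arr is None:
            return 0.0
        mask = (arr["five_prime"] >= a) & (arr["five_prime"] < b)
        return float(arr["weight"][mask].sum())

    def normalized_count(self, transcript_id: str, a: int, b: int) -> float:
        """CPM-normalized weight of 5' ends in window [a, b)."""
        if a >= b:
            raise FootprintError(f"empty window [{a}, {b})")
        return self.raw_window_count(transcript_id, a, b) * 1e6 / self.total_alignments

    def position_weights(self, transcript_id: str, length: int) -> np.ndarray:
        """Dense per-position 5'-end weight vector of the given length.

        Alignments whose 5' end falls at or beyond ``length`` are ignored.
        """
        key = transcript_id
        cached = self._dense_cache.get(key)
        if cached is not None and len(cached) >= length:
            return cached[:length]
        vec = np.zeros(length, dtype=float)
        arr = self.data.get(transcript_id)
        if arr is not None:
            pos = arr["five_prime"]
            ok = pos < length
            np.add.at(vec, pos[ok], arr["weight"][ok])
        self._dense_cache[key] = vec
        return vec


def _pack(
    tids: Sequence[str],
    five_prime: np.ndarray,
    read_length: np.ndarray,
    weight: np.ndarray,
) -> dict[str, np.ndarray]:
    dtype = [("five_prime", np.int64), ("read_length", np.int64), ("weight", np.float64)]
    out: dict[str, np.ndarray] = {}
    tids = np.asarray(tids, dtype=object)
    order = np.argsort(tids, kind="stable")
    tids, five_prime = tids[order], five_prime[order]
    read_length, weight = read_length[order], weight[order]
    boundaries = np.flatnonzero(np.r_[True, tids[1:] != tids[:-1], True])
    for i, j in zip(boundaries[:-1], boundaries[1:]):
        arr = np.empty(j - i, dtype=dtype)
        arr["five_prime"] = five_prime[i:j]
        arr["read_length"] = read_length[i:j]
        arr["weight"] = weight[i:j]
        out[str(tids[i])] = arr
    return out


def library_from_arrays(
    library_id: str,
    condition: str,
    assay: str,
    transcript_ids: Sequence[str],
    five_prime: np.ndarray,
    read_length: np.ndarray,
    weight: np.ndarray,
    total_alignments: Optional[float] = None,
    length_range: Optional[tuple[int, int]] = None,
) -> FootprintLibrary:
    """Assemble a library from parallel arrays (used by loaders and the simulator)."""
    five_prime = np.asarray(five_prime, dtype=np.int64)
    read_length = np.asarray(read_length, dtype=np.int64)
    weight = np.asarray(weight, dtype=np.float64)
    if np.any(five_prime < 0) or np.any(read_length < 1) or np.any(weight <= 0):
        raise FootprintError(f"{library_id}: invalid alignment fields")
    depth = float(weight.sum()) if total_alignments is None else float(total_alignments)
    if depth <= 0:
        raise FootprintError(f"{library_id}: no alignments")
    if length_range is None:
        length_range = DEFAULT_LENGTH_RANGES.get(assay, (1, 10**9))
    keep = (read_length >= length_range[0]) & (read_length <= length_range[1])
    return FootprintLibrary(
        library_id=library_id,
        condition=condition,
        assay=assay,
        total_alignments=depth,
        data=_pack(
            np.asarray(transcript_ids, dtype=object)[keep],
            five_prime[keep],
            read_length[keep],
            weight[keep],
        ),
    )


def load_alignment_library(
    path: str | Path,
    assay: str,
    condition: str,
    library_id: Optional[str] = None,
    length_range: Optional[tuple[int, int]] = None,
    known_transcripts: Optional[Iterable[str]] = None,
) -> FootprintLibrary:
    """Load a library from SAM/BAM or the TSV alignment dialect.

    The TSV dialect has columns ``transcript_id``, ``five_prime``,
    ``read_length``, ``weight``; rows with identical coordinates may carry
    weight > 1 (aggregated).  Depth is the total alignment weight in the
    file before length filtering; every reported alignment counts
    (multi-mapping allowed).  Alignments on transcripts not in
    ``known_transcripts`` are retained but logged.
    """
    path = Path(path)
    library_id = library_id or path.stem
    if path.suffix.lower() in {".sam", ".bam"}:
        tids, fp, rl, wt = [], [], [], []
        mode = "rb" if path.suffix.lower() == ".bam" else "r"
        with pysam.AlignmentFile(str(path), mode, check_sq=False) as fh:
            for rec in fh:
                if rec.is_unmapped:
                    continue
                tids.append(rec.reference_name)
                fp.append(rec.reference_start)
                rl.append(rec.query_length or rec.infer_read_length() or 0)
                wt.append(1.0)
        if not tids:
            raise FootprintError(f"{path}: no alignments")
        frame = pd.DataFrame(
            {"transcript_id": tids, "five_prime": fp, "read_length": rl, "weight": wt}
        )
    else:
        frame = pd.read_csv(path, sep="\t", comment="#")
        if frame.empty:
            raise FootprintError(f"{path}: no alignments")
    if known_transcripts is not None:
        unknown = set(frame["transcript_id"]) - set(known_transcripts)
        if unknown:
            logger.warning(
                "%s: %d alignments on %d unknown transcripts retained",
                path,
                int(frame["transcript_id"].isin(unknown).sum()),
                len(unknown),
            )
    return library_from_arrays(
        library_id,
        condition,
        assay,
        frame["transcript_id"].to_numpy(),
        frame["five_prime"].to_numpy(),
        frame["read_length"].to_numpy(),
        frame["weight"].to_numpy(),
        length_range=length_range,
    )


def write_alignment_tsv(library: FootprintLibrary, path: str | Path) -> None:
    """Write a library in the TSV alignment dialect (lossless for loaded data)."""
    rows = []
    for tid in sorted(library.data):
        arr = library.data[tid]
        for rec in arr:
            rows.append((tid, int(rec["five_prime"]), int(rec["read_length"]), float(rec["weight"])))
    frame = pd.DataFrame(rows, columns=["transcript_id", "five_prime", "read_length", "weight"])
    frame.to_csv(path, sep="\t", index=False)


def write_alignment_sam(
    library: FootprintLibrary, path: str | Path, reference_lengths: Mapping[str, int]
) -> None:
    """Write a library as plain SAM against the given transcript references.

    Aggregated weights are expanded to one record per unit weight (weights
    must be integral); sequences are written as runs of N since only the
    5' coordinate and length carry information downstream.
    """
    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [{"SN": tid, "LN": int(ln)} for tid, ln in reference_lengths.items()],
    }
    with pysam.AlignmentFile(str(path), "wh", header=header) as out:
        serial = 0
        for tid in sorted(library.data):
            arr = library.data[tid]
            for rec in arr:
                n = int(round(float(rec["weight"])))
                if abs(n - float(rec["weight"])) > 1e-9:
                    raise FootprintError("SAM export needs integral weights")
                for _ in range(n):
                    a = pysam.AlignedSegment()
                    a.query_name = f"{library.library_id}.{serial}"
                    serial += 1
                    a.reference_id = out.get_tid(tid)
                    a.reference_start = int(rec["five_prime"])
                    a.mapping_quality = 255
                    length = int(rec["read_length"])
                    a.query_sequence = "N" * length
                    a.cigarstring = f"{length}M"
                    a.flag = 0
                    out.write(a)


@dataclass
class MetageneProfile:
    """Depth-normalized 5'-end density around a shared anchor.

    ``offsets`` runs from -flank_upstream to +flank_downstream inclusive;
    ``values[i]`` is the pooled CPM at ``offsets[i]``.
    """

    anchor: str  # "start" or "stop"
    offsets: np.ndarray
    values: np.ndarray
    smoothing_window: Optional[int] = None

    def value_at(self, offset: int) -> float:
        idx = int(offset - self.offsets[0])
        return float(self.values[idx])


def smooth_profile(values: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average with truncated edges.

    Even windows are widened to the next odd value (centered averaging
    needs symmetry); the adjustment is logged.
    """
    if window <= 1:
        return values.astype(float)
    if window % 2 == 0:
        logger.info("smoothing window %d widened to %d (must be odd)", window, window + 1)
        window += 1
    half = window // 2
    kernel = np.ones(window)
    sums = np.convolve(values, kernel, mode="same")
    counts = np.convolve(np.ones_like(values, dtype=float), kernel, mode="same")
    out = sums / counts
    return out


def metagene_profile(
    libraries: Sequence[FootprintLibrary],
    models: Sequence[TranscriptModel],
    anchor: str,
    flank_upstream: int = 50,
    flank_downstream: int = 50,
    smoothing_window: Optional[int] = None,
) -> MetageneProfile:
    """Pool depth-normalized 5'-end counts around start or stop codons.

    The anchor coordinate is ``cds_start`` (first nt of the start codon)
    or ``cds_end - 3`` (first nt of the stop codon).  Each alignment
    contributes at offset ``five_prime - anchor``; contributions are CPM
    per library and summed over the provided libraries of one sample.
    """
    if not models:
        raise FootprintError("empty model list")
    if anchor not in {"start", "stop"}:
        raise FootprintError(f"unknown anchor {anchor!r}")
    L, R = flank_upstream, flank_downstream
    raw = np.zeros(L + R + 1)
    for lib in libraries:
        scale = 1e6 / lib.total_alignments
        for model in models:
            arr = lib.data.get(model.transcript_id)
            if arr is None:
                continue
            a = model.cds_start if anchor == "start" else model.cds_end - 3
            offs = arr["five_prime"] - a
            ok = (offs >= -L) & (offs <= R)
            np.add.at(raw, offs[ok] + L, arr["weight"][ok] * scale)
    values = smooth_profile(raw, smoothing_window) if smoothing_window else raw
    return MetageneProfile(
        anchor=anchor,
        offsets=np.arange(-L, R + 1),
        values=values,
        smoothing_window=smoothing_window,
    )


def transcript_trace(
    library: FootprintLibrary,
    model: TranscriptModel,
    smoothing_window: Optional[int] = None,
    scale_mode: str = "none",
    rna_library: Optional[FootprintLibrary] = None,
) -> np.ndarray:
    """Per-position CPM trace of 5'-end counts along one transcript.

    ``scale_mode="per_mrna_abundance"`` divides by the RNA library's CPM on
    the whole transcript (one scalar), mirroring figure traces "scaled to
    mRNA abundance".
    """
    vec = library.position_weights(model.transcript_id, len(model.sequence)).copy()
    vec *= 1e6 / library.total_alignments
    if scale_mode == "per_mrna_abundance":
        if rna_library is None:
            raise FootprintError("per_mrna_abundance scaling requires an RNA library")
        denom = rna_library.normalized_count(model.transcript_id, 0, len(model.sequence))
        if denom <= 0:
            raise FootprintError(f"{model.transcript_id}: zero RNA abundance")
        vec /= denom
    elif scale_mode != "none":
        raise FootprintError(f"unknown scale_mode {scale_mode!r}")
    if smoothing_window:
        vec = smooth_profile(vec, smoothing_window)
    return vec


def find_peak_offset(
    profile: MetageneProfile, search_range: tuple[int, int]
) -> int:
    """Offset of the profile maximum within [lo, hi] (inclusive).

    Ties break toward the offset closest to zero, then toward the smaller
    offset.  An all-zero search range is an error.
    """
    lo, hi = search_range
    if lo < profile.offsets[0] or hi > profile.offsets[-1]:
        raise FootprintError("search range outside profile offsets")
    sel = (profile.offsets >= lo) & (profile.offsets <= hi)
    offs = profile.offsets[sel]
    vals = profile.values[sel]
    if np.all(vals == 0):
        raise FootprintError("no peak: all-zero search range")
    best = vals.max()
    candidates = offs[vals == best]
    candidates = sorted(candidates, key=lambda o: (abs(o), o))
    return int(candidates[0])


def write_profile_tsv(profile: MetageneProfile, path: str | Path) -> None:
    pd.DataFrame({"offset": profile.offsets, "value": profile.values}).to_csv(
        path, sep="\t", index=False
    )
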