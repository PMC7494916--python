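"""40S recycling-defect scoring at stop codons and translated-uORF calls.

On loss of the 40S recycling machinery, post-termination small subunits
accumulate on stop codons whose last sense (-1) codon leaves a
tightly-bound deacylated tRNA in the 40S.  The score for each stop site is
the log2 fold change of depth-normalized 40S footprint counts in a 10-nt
window at the stop-codon peak, knockout over wild type, averaged over the
knockout lines, then standardized into a robust Z over all sites of the
same kind (mORF stops and uORF stops are separate populations).

A uORF counts as potentially translated when 80S footprints fall in a
10-nt window on its start-codon peak (5'-end assigned, 15-nt offset).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .annotation import TranscriptModel, stop_context_codons
from .footprints import OFFSET_80S, FootprintLibrary, find_peak_offset, metagene_profile
from .te import MAD_SCALE

WINDOW_SIZE = 10  # nt, the counting window at a peak


class RecyclingError(ValueError):
    pass


@dataclass(frozen=True)
class StopSite:
    """One stop codon to be scored (mORF or uORF)."""

    site_id: str
    transcript_id: str
    stop_start: int
    kind: str  # "mORF" or "uORF"
    codon_minus1: str
    codon_minus2: Optional[str] = None
    codon_minus3: Optional[str] = None


def peak_window(anchor: int) -> tuple[int, int]:
    """The 10-nt counting window [anchor-4, anchor+6) around a 5'-end peak."""
    return anchor - 4, anchor + 6


def detect_translated_uorfs(
    lib80s_list: Sequence[FootprintLibrary],
    uorf_catalog: pd.DataFrame,
    min_reads: float = 1.0,
    offset80s: int = OFFSET_80S,
) -> pd.DataFrame:
    """Subset of the uORF catalog with 80S footprints on the start codon.

    The window is 10 nt around the expected initiation 5'-end peak at
    ``uorf_start - offset80s``; a uORF is kept when the summed raw
    alignment weight across the provided 80S libraries reaches
    ``min_reads``.
    """
    keep = []
    for _, row in uorf_catalog.iterrows():
        a, b = peak_window(int(row["uorf_start"]) - offset80s)
        total = sum(
            lib.raw_window_count(str(row["transcript_id"]), a, b) for lib in lib80s_list
        )
        keep.append(total >= min_reads)
    return uorf_catalog[np.asarray(keep, dtype=bool)].reset_index(drop=True)


def morf_stop_sites(models: Sequence[TranscriptModel]) -> list[StopSite]:
    """One StopSite per transcript's main-ORF stop codon."""
    sites = []
    for m in models:
        m1, m2, m3 = stop_context_codons(m, m.cds_start, m.stop_start)
        sites.append(
            StopSite(
                site_id=f"{m.transcript_id}:mORF",
                transcript_id=m.transcript_id,
                stop_start=m.stop_start,
                kind="mORF",
                codon_minus1=m1,
                codon_minus2=m2,
                codon_minus3=m3,
            )
        )
    return sites


def uorf_stop_sites(uorf_catalog: pd.DataFrame) -> list[StopSite]:
    """One StopSite per cataloged uORF stop codon."""
    return [
        StopSite(
            site_id=f"{row.transcript_id}:uORF@{int(row.uorf_start)}",
            transcript_id=str(row.transcript_id),
            stop_start=int(row.stop_start),
            kind="uORF",
            codon_minus1=str(row.codon_minus1),
            codon_minus2=None if pd.isna(row.codon_minus2) else str(row.codon_minus2),
            codon_minus3=None if pd.isna(row.codon_minus3) else str(row.codon_minus3),
        )
        for row in uorf_catalog.itertuples()
    ]


def calibrate_stop_offset(
    libs40s: Sequence[FootprintLibrary],
    models: Sequence[TranscriptModel],
    search_range: tuple[int, int] = (-40, 0),
) -> int:
    """40S 5'-end peak offset at stop codons, from the pooled stop metagene.

    Returns the distance upstream (a positive number) of the first stop
    nucleotide at which pooled 40S 5'-end density peaks.
    """
    profile = metagene_profile(libs40s, models, anchor="stop", flank_upstream=50, flank_downstream=20)
    return -find_peak_offset(profile, search_range)


def stall_scores(
    lib_wt: FootprintLibrary,
    libs_ko: Mapping[str, FootprintLibrary],
    sites: Sequence[StopSite],
    offset40s: int | str = "calibrate",
    pseudocount: float = 0.05,
    models: Optional[Sequence[TranscriptModel]] = None,
    min_total_reads: float = 0.0,
) -> pd.DataFrame:
    """Score 40S accumulation at stop codons in knockout vs wild type.

    Per site, 40S 5'-end CPM is counted in the 10-nt window at the stop
    peak (window anchor ``stop_start - offset40s``); per knockout line
    log2fc = log2((KO + pc) / (WT + pc)) with a symmetric CPM pseudocount;
    the mean over knockout lines is standardized into a robust Z
    (median/MAD) over all sites of the same kind.  ``offset40s``
    "calibrate" derives the offset from the pooled stop-anchored metagene
    (requires ``models``); the fallback constant is 15 nt.

    ``min_total_reads`` optionally restricts the site universe to sites
    with at least that raw 40S weight in the window in any library.
    """
    if len(libs_ko) < 2:
        raise RecyclingError("need at least two knockout libraries")
    if offset40s == "calibrate":
        if models is None:
            raise RecyclingError("calibration requires transcript models")
        all_libs = [lib_wt, *libs_ko.values()]
        try:
            offset40s = calibrate_stop_offset(all_libs, models)
        except Exception:
            offset40s = OFFSET_80S
    offset40s = int(offset40s)

    rows = []
    ko_labels = list(libs_ko)
    for site in sites:
        a, b = peak_window(site.stop_start - offset40s)
        raw_any = max(
            lib.raw_window_count(site.transcript_id, a, b)
            for lib in (lib_wt, *libs_ko.values())
        )
        if raw_any < min_total_reads:
            continue
        wt_cpm = lib_wt.normalized_count(site.transcript_id, a, b)
        fcs = {}
        for label in ko_labels:
            ko_cpm = libs_ko[label].normalized_count(site.transcript_id, a, b)
            fcs[f"log2fc_{label}"] = math.log2((ko_cpm + pseudocount) / (wt_cpm + pseudocount))
        rows.append(
            {
                "site_id": site.site_id,
                "transcript_id": site.transcript_id,
                "stop_start": site.stop_start,
                "kind": site.kind,
                "codon_minus1": site.codon_minus1,
                "codon_minus2": site.codon_minus2,
                "codon_minus3": site.codon_minus3,
                "wt_cpm": wt_cpm,
                **{
                    f"cpm_{label}": libs_ko[label].normalized_count(site.transcript_id, a, b)
                    for label in ko_labels
                },
                **fcs,
                "mean_log2fc": float(np.mean(list(fcs.values()))),
            }
        )
    table = pd.DataFrame(rows)
    if table.empty:
        return table
    table["fold_change"] = 2.0 ** table["mean_log2fc"]
    table["z"] = np.nan
    for kind, group in table.groupby("kind"):
        x = group["mean_log2fc"].to_numpy()
        med = np.median(x)
        mad = np.median(np.abs(x - med))
        if mad > 0:
            z = (x - med) / (MAD_SCALE * mad)
        else:
            # >50% identical scores: fall back to moment standardization,
            # or all-zero Z when the distribution is a point mass
            sd = x.std()
            z = (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)
        table.loc[group.index, "z"] = z
    return table


def classify_stalled(
    scores: pd.DataFrame, z_threshold: float = 1.645, fold_threshold: float = 4.0
) -> pd.DataFrame:
    """Flag sites as recycling-dependent: z >= threshold AND fold change > threshold."""
    out = scores.copy()
    out["classified"] = (out["z"] >= z_threshold) & (out["fold_change"] > fold_threshold)
    return out
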