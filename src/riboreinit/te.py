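"""Translation efficiency (TE) and outlier detection.

TE of a transcript is the 80S footprint density on its coding sequence
divided by the RNA-seq read density on the whole transcript, both in CPM.
The knockout effect is log2(TE_KO / TE_WT), averaged over knockout lines.

Outliers are found by comparing each transcript's observed Z-score
(robust: median/MAD standardization) with the theoretical Z-score of its
rank under a standard normal (Blom plotting positions).  Transcripts whose
observed Z falls well below the identity line — i.e. whose TE change is
larger than a Gaussian of the data's own scale would produce — are flagged.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .annotation import TranscriptModel
from .footprints import FootprintLibrary

logger = logging.getLogger(__name__)

MAD_SCALE = 1.4826  # consistency factor: MAD -> sd under normality


class TEError(ValueError):
    pass


@dataclass
class TEResult:
    """Per-transcript TE in one condition plus the raw counts behind it."""

    transcript_id: str
    gene_id: str
    cds_80s_cpm: float
    rna_cpm: float
    raw_80s: float
    raw_rna: float
    te: Optional[float]
    detected: bool


def compute_te(
    lib80s: FootprintLibrary,
    libRNA: FootprintLibrary,
    models: Sequence[TranscriptModel],
    min_rna: float = 10.0,
    min_80s: float = 10.0,
    enforce_thresholds: bool = True,
) -> dict[str, TEResult]:
    """TE per transcript: CDS 80S CPM / whole-transcript RNA CPM.

    Raw-count detection thresholds (``min_rna`` RNA reads on the
    transcript, ``min_80s`` 80S reads on the CDS) are meant to be enforced
    in the reference (wild-type) condition; transcripts failing them are
    marked undetected.  Division by zero never occurs: zero RNA means
    undetected.
    """
    out: dict[str, TEResult] = {}
    for model in models:
        tid = model.transcript_id
        raw80 = lib80s.raw_window_count(tid, model.cds_start, model.cds_end)
        rawrna = libRNA.raw_window_count(tid, 0, len(model.sequence))
        cpm80 = raw80 * 1e6 / lib80s.total_alignments
        cpmrna = rawrna * 1e6 / libRNA.total_alignments
        detected = rawrna > 0 and raw80 > 0
        if enforce_thresholds:
            detected = detected and rawrna >= min_rna and raw80 >= min_80s
        te = cpm80 / cpmrna if cpmrna > 0 and raw80 > 0 else None
        out[tid] = TEResult(
            transcript_id=tid,
            gene_id=model.gene_id,
            cds_80s_cpm=cpm80,
            rna_cpm=cpmrna,
            raw_80s=raw80,
            raw_rna=rawrna,
            te=te,
            detected=detected,
        )
    return out


def te_log2fc(te_ko: float, te_wt: float) -> float:
    """log2 fold change of TE upon knockout."""
    if te_ko <= 0 or te_wt <= 0:
        raise TEError("TE values must be positive")
    return math.log2(te_ko / te_wt)


def te_table(
    wt: Mapping[str, TEResult],
    kos: Mapping[str, Mapping[str, TEResult]],
) -> pd.DataFrame:
    """Combine per-condition TE into one table with per-KO and mean log2FC.

    ``kos`` maps knockout labels to their TE results.  A transcript enters
    the table when it is detected in WT and has positive TE in WT and in
    every knockout line.
    """
    rows = []
    for tid, w in wt.items():
        if not w.detected or w.te is None:
            continue
        fcs = {}
        ok = True
        for label, res in kos.items():
            r = res.get(tid)
            if r is None or r.te is None or r.te <= 0:
                ok = False
                break
            fcs[f"log2fc_te_{label}"] = te_log2fc(r.te, w.te)
        if not ok:
            continue
        row = {
            "transcript_id": tid,
            "gene_id": w.gene_id,
            "te_wt": w.te,
            **{f"te_{label}": res[tid].te for label, res in kos.items()},
            **fcs,
        }
        row["mean_log2fc_te"] = float(np.mean(list(fcs.values())))
        rows.append(row)
    return pd.DataFrame(rows)


def zz_outlier_scan(
    values: Sequence[float] | np.ndarray,
    delta: float = 1.0,
    z_min: float = 1.5,
) -> pd.DataFrame:
    """Observed-vs-theoretical Z scan for heavier-than-Gaussian TE changes.

    observed_z = (x - median) / (1.4826 * MAD); theoretical_z is the
    standard-normal quantile of the Blom plotting position
    (rank - 0.375) / (n + 0.25).  A value is flagged ``down`` when
    observed_z - theoretical_z <= -delta and observed_z <= -z_min; ``up``
    symmetrically.  Returns a DataFrame aligned with the input order with
    columns observed_z, theoretical_z, flag.
    """
    x = np.asarray(values, dtype=float)
    n = len(x)
    if n < 50:
        raise TEError(f"need at least 50 values, got {n}")
    med = np.median(x)
    mad = np.median(np.abs(x - med))
    if mad == 0:
        raise TEError("degenerate distribution: MAD is zero")
    obs = (x - med) / (MAD_SCALE * mad)
    ranks = stats.rankdata(x, method="average")
    theo = stats.norm.ppf((ranks - 0.375) / (n + 0.25))
    diff = obs - theo
    flag = np.full(n, "none", dtype=object)
    flag[(diff <= -delta) & (obs <= -z_min)] = "down"
    flag[(diff >= delta) & (obs >= z_min)] = "up"
    return pd.DataFrame({"observed_z": obs, "theoretical_z": theo, "flag": flag})


def scan_te_table(table: pd.DataFrame, delta: float = 1.0, z_min: float = 1.5) -> pd.DataFrame:
    """Attach observed/theoretical Z and outlier flags to a TE table."""
    scan = zz_outlier_scan(table["mean_log2fc_te"].to_numpy(), delta=delta, z_min=z_min)
    out = table.reset_index(drop=True).copy()
    out[["observed_z", "theoretical_z", "flag"]] = scan
    return out


def collapse_to_gene(records: pd.DataFrame) -> pd.DataFrame:
    """Keep, per gene, the transcript with the most extreme mean_log2fc_te.

    Ties break by lexicographic transcript_id, so the collapse is
    deterministic.
    """
    if records.empty:
        return records
    ordered = records.assign(_abs_fc=records["mean_log2fc_te"].abs()).sort_values(
        ["gene_id", "_abs_fc", "transcript_id"], ascending=[True, False, True]
    )
    return (
        ordered.drop_duplicates("gene_id", keep="first")
        .drop(columns="_abs_fc")
        .reset_index(drop=True)
    )


def uorf_length_group_test(
    records: pd.DataFrame,
    uorf_catalog: pd.DataFrame,
    translated_uorf_ids: Optional[set[tuple[str, int]]] = None,
    bins: Sequence[tuple[int, int]] = ((1, 1), (2, 10), (11, 50), (51, 10**9)),
) -> tuple[pd.DataFrame, float, pd.DataFrame]:
    """Compare TE change across groups of transcripts by uORF length.

    Groups are nonexclusive across length bins, except that any transcript
    bearing a 1-aa uORF belongs only to the 1-aa group (so TE reduction in
    longer-uORF groups cannot be driven by 1-aa uORFs).  A "no uORF"
    reference group holds transcripts with no (translated) uORF at all.

    Returns (per-group summary with median/quartiles/deciles, omnibus
    Kruskal-Wallis p across all groups, pairwise table of each group vs
    the reference by rank-sum test with Holm adjustment).
    """
    catalog = uorf_catalog
    if translated_uorf_ids is not None:
        keys = list(zip(catalog["transcript_id"], catalog["uorf_start"]))
        catalog = catalog[[k in translated_uorf_ids for k in keys]]

    lengths_by_tid: dict[str, set[int]] = {}
    for tid, L in zip(catalog["transcript_id"], catalog["n_sense_codons"]):
        lengths_by_tid.setdefault(tid, set()).add(int(L))

    fc = dict(zip(records["transcript_id"], records["mean_log2fc_te"]))
    groups: dict[str, list[float]] = {"no uORF": []}
    labels = [
        f"{lo}" if lo == hi else (f"{lo}+" if hi >= 10**9 else f"{lo}-{hi}")
        for lo, hi in bins
    ]
    for lab in labels:
        groups[lab] = []

    one_aa_bin = next((i for i, (lo, hi) in enumerate(bins) if lo <= 1 <= hi), None)
    for tid, x in fc.items():
        lens = lengths_by_tid.get(tid)
        if not lens:
            groups["no uORF"].append(x)
            continue
        if one_aa_bin is not None and 1 in lens:
            groups[labels[one_aa_bin]].append(x)
            continue
        for (lo, hi), lab in zip(bins, labels):
            if any(lo <= L <= hi for L in lens):
                groups[lab].append(x)

    kept = {k: np.asarray(v) for k, v in groups.items() if len(v) > 0}
    for name in set(groups) - set(kept):
        logger.warning("empty uORF-length group %r dropped", name)
    if len(kept) < 2:
        raise TEError("need at least two nonempty groups")

    _, omnibus_p = stats.kruskal(*kept.values())

    summary = pd.DataFrame(
        [
            {
                "group": name,
                "n": len(v),
                "decile_lo": np.quantile(v, 0.1),
                "q1": np.quantile(v, 0.25),
                "median": np.quantile(v, 0.5),
                "q3": np.quantile(v, 0.75),
                "decile_hi": np.quantile(v, 0.9),
            }
            for name, v in kept.items()
        ]
    )

    ref = kept.get("no uORF")
    pair_rows = []
    if ref is not None and len(ref) > 0:
        names = [n for n in kept if n != "no uORF"]
        pvals = [
            stats.mannwhitneyu(kept[name], ref, alternative="two-sided")[1]
            for name in names
        ]
        if pvals:
            adj = multipletests(pvals, method="holm")[1]
            pair_rows = [
                {"group": name, "p_value": p, "p_adjusted": pa}
                for name, p, pa in zip(names, pvals, adj)
            ]
    pairwise = pd.DataFrame(pair_rows, columns=["group", "p_value", "p_adjusted"])
    return summary, float(omnibus_p), pairwise
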