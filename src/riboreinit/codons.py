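"""Codon-position enrichment statistics and per-codon TE effects.

The frequency of each of the 61 sense codons at a context position (-1,
-2 or -3 relative to the stop codon) in an affected (foreground) set of
stop sites is compared against all detected (background) sites — the
foreground is a subset of the background — with an exact binomial test
per codon and a multiple-testing adjustment over the 61 tests.
"""

from __future__ import annotations

import math
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import binomtest
from statsmodels.stats.multitest import multipletests

from .annotation import SENSE_CODONS

N_TESTS = len(SENSE_CODONS)  # 61: one test per amino-acid-coding codon


class CodonStatsError(ValueError):
    pass


def _codon_column(position: int) -> str:
    if position not in (-1, -2, -3):
        raise CodonStatsError(f"position must be -1, -2 or -3, got {position}")
    return f"codon_minus{-position}"


def _codon_counts(sites: pd.DataFrame, column: str) -> tuple[dict[str, int], int]:
    vals = sites[column].dropna()
    counts = vals.value_counts().to_dict()
    return counts, int(len(vals))


def codon_enrichment_test(
    fg_sites: pd.DataFrame,
    bg_sites: pd.DataFrame,
    position: int = -1,
    alpha: float = 0.05,
    adjust: str = "bonferroni",
) -> pd.DataFrame:
    """Per-codon enrichment of a foreground site set within its background.

    For each sense codon c with background frequency p0 = count_bg/n_bg,
    the foreground count out of n_fg is tested against p0 with a
    two-sided exact binomial test; p-values are adjusted over the 61
    codons (Bonferroni by default; "holm" and "bh" available).
    log2_enrichment = log2(freq_fg / freq_bg).  Codons absent from the
    background get an undefined enrichment and p = 1.

    The foreground must be a subset of the background (site_id-wise when a
    site_id column is present, count-wise otherwise).
    """
    column = _codon_column(position)
    if "site_id" in fg_sites.columns and "site_id" in bg_sites.columns:
        if not set(fg_sites["site_id"]).issubset(set(bg_sites["site_id"])):
            raise CodonStatsError("foreground sites are not a subset of the background")
    fg_counts, n_fg = _codon_counts(fg_sites, column)
    bg_counts, n_bg = _codon_counts(bg_sites, column)
    if n_fg == 0:
        raise CodonStatsError("empty foreground")
    if any(fg_counts.get(c, 0) > bg_counts.get(c, 0) for c in fg_counts):
        raise CodonStatsError("foreground codon count exceeds background")

    rows = []
    pvals = []
    for codon in SENSE_CODONS:
        k_fg = fg_counts.get(codon, 0)
        k_bg = bg_counts.get(codon, 0)
        if k_bg == 0:
            p = 1.0
            enr = math.nan
        else:
            p0 = k_bg / n_bg
            p = binomtest(k_fg, n_fg, p0, alternative="two-sided").pvalue
            f_fg = k_fg / n_fg
            enr = math.log2(f_fg / p0) if f_fg > 0 else -math.inf
        pvals.append(p)
        rows.append(
            {
                "codon": codon,
                "position": position,
                "count_fg": k_fg,
                "n_fg": n_fg,
                "count_bg": k_bg,
                "n_bg": n_bg,
                "log2_enrichment": enr,
                "p_value": p,
            }
        )
    table = pd.DataFrame(rows)
    if adjust == "bonferroni":
        table["p_adjusted"] = np.minimum(1.0, table["p_value"] * N_TESTS)
    elif adjust == "holm":
        table["p_adjusted"] = multipletests(pvals, method="holm")[1]
    elif adjust == "bh":
        table["p_adjusted"] = multipletests(pvals, method="fdr_bh")[1]
    else:
        raise CodonStatsError(f"unknown adjustment {adjust!r}")
    table["significant"] = table["p_adjusted"] < alpha
    return table


def per_codon_te_effect(
    te_records: pd.DataFrame,
    translated_uorfs: pd.DataFrame,
    position: int = -1,
    low_n: int = 20,
) -> pd.DataFrame:
    """Distribution of mORF TE change grouped by uORF context codon.

    Every potentially translated uORF inherits the mean log2FC(TE) of its
    host transcript (a transcript with several translated uORFs
    contributes once per uORF); uORFs are grouped by the codon at the
    requested position and per-codon median and interquartile range are
    reported.  Codons with fewer than ``low_n`` uORFs are flagged.
    """
    column = _codon_column(position)
    fc = dict(zip(te_records["transcript_id"], te_records["mean_log2fc_te"]))
    values: dict[str, list[float]] = {}
    for row in translated_uorfs.itertuples():
        x = fc.get(row.transcript_id)
        codon = getattr(row, column)
        if x is None or codon is None or (isinstance(codon, float) and math.isnan(codon)):
            continue
        values.setdefault(str(codon), []).append(float(x))
    rows = [
        {
            "codon": codon,
            "position": position,
            "n_uorfs": len(v),
            "median_log2fc_te": float(np.median(v)),
            "q1": float(np.quantile(v, 0.25)),
            "q3": float(np.quantile(v, 0.75)),
            "low_n": len(v) < low_n,
        }
        for codon, v in sorted(values.items())
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "codon",
            "position",
            "n_uorfs",
            "median_log2fc_te",
            "q1",
            "q3",
            "low_n",
        ],
    )
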