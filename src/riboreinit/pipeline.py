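"""End-to-end orchestration: annotate -> load -> metagene -> TE ->
translated uORFs -> stall scoring -> codon enrichment, driven by one
configuration object, with plain TSV intermediates and a run manifest.

Stages that lack their inputs (e.g. no 40S libraries) are skipped with a
logged notice rather than failing the run; stages never mutate one
another's outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Optional

import pandas as pd
import yaml

from . import __version__
from .annotation import annotate_catalog, load_transcriptome, write_catalog
from .codons import codon_enrichment_test
from .footprints import (
    FootprintLibrary,
    load_alignment_library,
    metagene_profile,
    write_profile_tsv,
)
from .recycling import (
    classify_stalled,
    detect_translated_uorfs,
    morf_stop_sites,
    stall_scores,
    uorf_stop_sites,
)
from .te import compute_te, scan_te_table, collapse_to_gene, te_table

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: str):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class LibrarySpec:
    path: str
    assay: str  # RNA | RIBO80S | RIBO40S
    condition: str  # WT or a knockout label


@dataclass
class PipelineConfig:
    transcriptome_fasta: str
    cds_table: str
    libraries: list[LibrarySpec]
    output_dir: str = "riboreinit_out"
    wt_label: str = "WT"
    include_overlapping_uorfs: bool = False
    min_rna: float = 10.0
    min_80s: float = 10.0
    zz_delta: float = 1.0
    zz_z_min: float = 1.5
    stall_z_threshold: float = 1.645
    stall_fold_threshold: float = 4.0
    stall_pseudocount: float = 0.05
    offset40s: Any = "calibrate"
    min_reads_translated: float = 1.0
    metagene_flank: int = 60
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        libs = [LibrarySpec(**d) for d in raw.pop("libraries", [])]
        return cls(libraries=libs, **raw)

    def validate(self) -> None:
        for p in (self.transcriptome_fasta, self.cds_table):
            if not Path(p).exists():
                raise PipelineError("config", f"missing input file {p}")
        for spec in self.libraries:
            if not Path(spec.path).exists():
                raise PipelineError("config", f"missing library file {spec.path}")

    def digest(self) -> str:
        payload = json.dumps(
            {k: (v if not isinstance(v, list) else [vars(s) for s in v]) for k, v in vars(self).items()},
            sort_keys=True,
            default=str,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> dict[str, Any]:
    """Run all stages; returns the manifest (also written to the output dir)."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {
        "config_hash": config.digest(),
        "version": __version__,
        "stages": {},
    }

    def record(stage: str, rows: int) -> None:
        manifest["stages"][stage] = {"rows": rows}
        logger.info("stage %s: %d rows", stage, rows)

    # 1. annotate
    models = load_transcriptome(config.transcriptome_fasta, config.cds_table)
    catalog = annotate_catalog(models, include_overlapping=config.include_overlapping_uorfs)
    write_catalog(catalog, out / "uorf_catalog.tsv")
    record("annotate", len(catalog))

    # 2. load libraries
    libs: dict[tuple[str, str], FootprintLibrary] = {}
    known = [m.transcript_id for m in models]
    for spec in config.libraries:
        lib = load_alignment_library(
            spec.path, assay=spec.assay, condition=spec.condition, known_transcripts=known
        )
        libs[(spec.condition, spec.assay)] = lib
    record("load", len(libs))

    ko_labels = sorted(
        {c for c, _ in libs if c != config.wt_label}
    )

    # 3. metagene (per 80S library, start- and stop-anchored)
    n_profiles = 0
    for (cond, assay), lib in libs.items():
        if assay not in {"RIBO80S", "RIBO40S"}:
            continue
        for anchor in ("start", "stop"):
            profile = metagene_profile(
                [lib], models, anchor=anchor,
                flank_upstream=config.metagene_flank,
                flank_downstream=config.metagene_flank,
            )
            write_profile_tsv(profile, out / f"metagene_{cond}_{assay}_{anchor}.tsv")
            n_profiles += 1
    record("metagene", n_profiles)

    # 4. TE
    te_scan = None
    have_te = (config.wt_label, "RIBO80S") in libs and (config.wt_label, "RNA") in libs
    te_kos = [
        k for k in ko_labels if (k, "RIBO80S") in libs and (k, "RNA") in libs
    ]
    if have_te and te_kos:
        wt_te = compute_te(
            libs[(config.wt_label, "RIBO80S")],
            libs[(config.wt_label, "RNA")],
            models,
            min_rna=config.min_rna,
            min_80s=config.min_80s,
        )
        ko_te = {
            k: compute_te(
                libs[(k, "RIBO80S")], libs[(k, "RNA")], models, enforce_thresholds=False
            )
            for k in te_kos
        }
        table = te_table(wt_te, ko_te)
        if len(table) >= 50:
            te_scan = scan_te_table(table, delta=config.zz_delta, z_min=config.zz_z_min)
            te_scan.to_csv(out / "te_transcripts.tsv", sep="\t", index=False)
            collapse_to_gene(te_scan).to_csv(out / "te_genes.tsv", sep="\t", index=False)
            record("te", len(te_scan))
        else:
            logger.warning("TE stage: only %d transcripts pass thresholds; scan skipped", len(table))
            table.to_csv(out / "te_transcripts.tsv", sep="\t", index=False)
            record("te", len(table))
    else:
        logger.info("TE stage skipped: missing 80S+RNA library pairs")

    # 5. translated uORFs (80S on uORF start codons, all conditions pooled)
    libs80 = [lib for (c, a), lib in libs.items() if a == "RIBO80S"]
    translated = None
    if libs80 and len(catalog):
        translated = detect_translated_uorfs(
            libs80, catalog, min_reads=config.min_reads_translated
        )
        write_catalog(translated, out / "translated_uorfs.tsv")
        record("translated_uorfs", len(translated))
    else:
        logger.info("translated-uORF stage skipped: no 80S libraries or empty catalog")

    # 6+7. stall scoring and codon enrichment
    libs40_wt = libs.get((config.wt_label, "RIBO40S"))
    libs40_ko = {k: libs[(k, "RIBO40S")] for k in ko_labels if (k, "RIBO40S") in libs}
    if libs40_wt is not None and len(libs40_ko) >= 2:
        for kind, sites in (
            ("mORF", morf_stop_sites(models)),
            ("uORF", uorf_stop_sites(translated if translated is not None else catalog)),
        ):
            if not sites:
                continue
            scores = stall_scores(
                libs40_wt,
                libs40_ko,
                sites,
                offset40s=config.offset40s,
                pseudocount=config.stall_pseudocount,
                models=models,
                min_total_reads=1.0 if kind == "uORF" else 0.0,
            )
            if scores.empty:
                continue
            classified = classify_stalled(
                scores,
                z_threshold=config.stall_z_threshold,
                fold_threshold=config.stall_fold_threshold,
            )
            classified.to_csv(out / f"stall_scores_{kind}.tsv", sep="\t", index=False)
            record(f"stall_{kind}", len(classified))
            fg = classified[classified["classified"]]
            if len(fg) > 0:
                enrich = codon_enrichment_test(fg, classified, position=-1)
                enrich.sort_values("p_adjusted").to_csv(
                    out / f"codon_enrichment_{kind}.tsv", sep="\t", index=False
                )
                record(f"enrichment_{kind}", len(enrich))
    else:
        logger.info("recycling stages skipped: need WT plus >=2 knockout 40S libraries")

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
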