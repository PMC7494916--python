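"""Transcript models and upstream-ORF (uORF) annotation.

A transcript is represented in transcript coordinates (0-based, half-open)
as a DNA sequence plus the CDS interval of its main ORF (mORF).  uORFs are
AUG-initiated reading frames whose start codon lies in the 5'UTR; the first
in-frame stop codon closes the uORF.  A uORF whose stop codon is fully
inside the 5'UTR is *contained*; one whose stop reaches into or past the
CDS is *overlapping* and is only a uORF proper when its frame differs from
the mORF frame (an in-frame upstream start is an N-terminal extension).

The three in-frame codons immediately 5' of a stop codon (-1, -2, -3; the
stop itself counts as the last codon, so -1 is the "penultimate" codon)
are recorded because the identity of the -1 codon governs whether the
post-termination 40S ribosome needs active recycling to support
reinitiation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})

#: The 61 amino-acid-coding codons (all triplets minus the three stops).
SENSE_CODONS: tuple[str, ...] = tuple(
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in STOP_CODONS
)


class AnnotationError(ValueError):
    """Raised when a transcript record violates a structural invariant."""


@dataclass(frozen=True)
class TranscriptModel:
    """One transcript: sequence plus the CDS interval of its main ORF.

    Coordinates are 0-based; ``cds_start`` is the first nucleotide of the
    start codon and ``cds_end`` is one past the last nucleotide of the stop
    codon.  The 5'UTR is ``sequence[:cds_start]``.
    """

    transcript_id: str
    gene_id: str
    sequence: str
    cds_start: int
    cds_end: int

    def __post_init__(self) -> None:
        if not (0 <= self.cds_start < self.cds_end <= len(self.sequence)):
            raise AnnotationError(
                f"{self.transcript_id}: CDS [{self.cds_start}, {self.cds_end}) "
                f"out of bounds for sequence of length {len(self.sequence)}"
            )
        if (self.cds_end - self.cds_start) % 3 != 0:
            raise AnnotationError(
                f"{self.transcript_id}: CDS length "
                f"{self.cds_end - self.cds_start} is not a multiple of 3"
            )

    @property
    def utr5(self) -> str:
        return self.sequence[: self.cds_start]

    @property
    def utr5_length(self) -> int:
        return self.cds_start

    @property
    def stop_start(self) -> int:
        """Coordinate of the first nucleotide of the mORF stop codon."""
        return self.cds_end - 3


@dataclass(frozen=True)
class UORF:
    """An ATG-initiated upstream ORF.

    ``n_sense_codons`` is the amino-acid length: number of sense codons
    including the initiator ATG and excluding the stop (so ``ATGTGA`` is a
    1-aa uORF).  ``codon_minus1`` is the last sense codon (the penultimate
    codon, with the stop counting as last); ``codon_minus2``/``minus3`` are
    ``None`` when the uORF is too short to have them.
    """

    transcript_id: str
    start: int
    stop_start: int
    n_sense_codons: int
    uorf_class: str  # "contained" or "overlapping"
    codon_minus1: str
    codon_minus2: Optional[str] = None
    codon_minus3: Optional[str] = None


def load_transcriptome(
    fasta_path: str | Path, cds_table_path: str | Path
) -> list[TranscriptModel]:
    """Read transcript sequences (FASTA) and CDS coordinates (TSV).

    The CDS table must have columns ``transcript_id``, ``gene_id``,
    ``cds_start``, ``cds_end`` with 0-based half-open coordinates.  FASTA
    records with no CDS entry are skipped with a warning; records whose
    coordinates violate the model invariants raise :class:`AnnotationError`
    naming the record.
    """
    cds = pd.read_csv(cds_table_path, sep="\t", dtype={"transcript_id": str, "gene_id": str})
    required = {"transcript_id", "gene_id", "cds_start", "cds_end"}
    if not required.issubset(cds.columns):
        raise AnnotationError(
            f"CDS table {cds_table_path} missing columns {sorted(required - set(cds.columns))}"
        )
    cds = cds.set_index("transcript_id")

    models: list[TranscriptModel] = []
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        tid = rec.id
        if tid not in cds.index:
            logger.warning("no CDS entry for %s; skipped", tid)
            continue
        row = cds.loc[tid]
        models.append(
            TranscriptModel(
                transcript_id=tid,
                gene_id=str(row["gene_id"]),
                sequence=str(rec.seq).upper().replace("U", "T"),
                cds_start=int(row["cds_start"]),
                cds_end=int(row["cds_end"]),
            )
        )
    return models


def load_genbank_transcript(path: str | Path, gene_id: str | None = None) -> TranscriptModel:
    """Build a TranscriptModel from a single GenBank flat file with a CDS feature."""
    rec = SeqIO.read(str(path), "genbank")
    cds_feats = [f for f in rec.features if f.type == "CDS"]
    if not cds_feats:
        raise AnnotationError(f"{rec.id}: no CDS feature in GenBank record")
    feat = cds_feats[0]
    return TranscriptModel(
        transcript_id=rec.id,
        gene_id=gene_id or feat.qualifiers.get("gene", [rec.id])[0],
        sequence=str(rec.seq).upper().replace("U", "T"),
        cds_start=int(feat.location.start),
        cds_end=int(feat.location.end),
    )


def _first_inframe_stop(sequence: str, start: int) -> Optional[int]:
    """Coordinate of the first in-frame stop codon at/after ``start``, or None."""
    for pos in range(start, len(sequence) - 2, 3):
        if sequence[pos : pos + 3] in STOP_CODONS:
            return pos
    return None


def stop_context_codons(
    model: TranscriptModel, orf_start: int, stop_start: int
) -> tuple[str, Optional[str], Optional[str]]:
    """The three in-frame codons immediately upstream of a stop codon.

    ``orf_start`` is the coordinate of the ORF's ATG; codons that would lie
    upstream of it are returned as ``None``.  The -1 codon always exists
    (every ORF has at least its initiator codon).
    """
    if (stop_start - orf_start) % 3 != 0:
        raise AnnotationError(
            f"{model.transcript_id}: stop at {stop_start} not in frame with ORF start {orf_start}"
        )
    if stop_start - orf_start < 3:
        raise AnnotationError(
            f"{model.transcript_id}: stop at {stop_start} leaves no sense codon after {orf_start}"
        )
    out: list[Optional[str]] = []
    for k in (1, 2, 3):
        pos = stop_start - 3 * k
        out.append(model.sequence[pos : pos + 3] if pos >= orf_start else None)
    m1, m2, m3 = out
    assert m1 is not None
    return m1, m2, m3


def annotate_uorfs(model: TranscriptModel, include_overlapping: bool = False) -> list[UORF]:
    """Annotate ATG-initiated uORFs in a transcript's 5'UTR.

    Every ATG with start < cds_start is extended in frame to its first stop
    codon.  Contained uORFs (stop fully within the 5'UTR) are always
    reported.  Overlapping uORFs are reported only when
    ``include_overlapping`` is true and the uORF frame differs from the
    mORF frame; in-frame upstream starts are N-terminal extensions, not
    uORFs.  ATGs with no downstream in-frame stop yield nothing.  Output is
    sorted by start coordinate.
    """
    seq = model.sequence
    uorfs: list[UORF] = []
    for start in range(model.cds_start):
        if seq[start : start + 3] != "ATG":
            continue
        stop = _first_inframe_stop(seq, start)
        if stop is None:
            continue
        contained = stop + 3 <= model.cds_start
        if not contained:
            if not include_overlapping:
                continue
            if (start - model.cds_start) % 3 == 0:
                continue  # N-terminal extension of the mORF
        m1, m2, m3 = stop_context_codons(model, start, stop)
        uorfs.append(
            UORF(
                transcript_id=model.transcript_id,
                start=start,
                stop_start=stop,
                n_sense_codons=(stop - start) // 3,
                uorf_class="contained" if contained else "overlapping",
                codon_minus1=m1,
                codon_minus2=m2,
                codon_minus3=m3,
            )
        )
    uorfs.sort(key=lambda u: (u.start, u.stop_start))
    return uorfs


def annotate_catalog(
    models: Iterable[TranscriptModel], include_overlapping: bool = False
) -> pd.DataFrame:
    """uORF catalog over many transcripts as a tidy DataFrame.

    Columns: transcript_id, gene_id, uorf_start, stop_start, n_sense_codons,
    uorf_class, codon_minus1..3.  Coordinates are 0-based half-open.
    """
    rows = []
    for model in models:
        for u in annotate_uorfs(model, include_overlapping=include_overlapping):
            rows.append(
                {
                    "transcript_id": u.transcript_id,
                    "gene_id": model.gene_id,
                    "uorf_start": u.start,
                    "stop_start": u.stop_start,
                    "n_sense_codons": u.n_sense_codons,
                    "uorf_class": u.uorf_class,
                    "codon_minus1": u.codon_minus1,
                    "codon_minus2": u.codon_minus2,
                    "codon_minus3": u.codon_minus3,
                }
            )
    columns = [
        "transcript_id",
        "gene_id",
        "uorf_start",
        "stop_start",
        "n_sense_codons",
        "uorf_class",
        "codon_minus1",
        "codon_minus2",
        "codon_minus3",
    ]
    return pd.DataFrame(rows, columns=columns)


def write_catalog(catalog: pd.DataFrame, path: str | Path) -> None:
    """Write a uORF catalog TSV (coordinates 0-based half-open, noted in header)."""
    with open(path, "w") as fh:
        fh.write("# coordinates: 0-based, half-open, transcript space\n")
        catalog.to_csv(fh, sep="\t", index=False)


def read_catalog(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")
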