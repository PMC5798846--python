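"""Gene interval models from UCSC Table Browser transcript exports.

Each gene is modelled as a single genomic interval covering all transcript
variants sharing its name, split into two sub-regions: the union of all
annotated exons (``exon_union``) and the remainder of the span
(``introns``).  The distinction matters because a gene-trap vector
truncates a transcript from an intron only when its splice acceptor points
in the direction of transcription, while exonic insertions disrupt in
either orientation.

Input follows the UCSC Table Browser tab-separated genePred/refFlat
dialect (0-based half-open coordinates, comma-terminated exon lists);
coordinates are converted to the package-wide 1-based inclusive
convention on load.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable

import pandas as pd

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = (
    "name", "chrom", "strand", "txStart", "txEnd", "exonStarts", "exonEnds", "name2",
)

#: 1-based inclusive (start, end) interval
Interval = tuple[int, int]


class AnnotationFormatError(ValueError):
    """Raised when the annotation table lacks a required column."""


@dataclass(frozen=True)
class TranscriptRecord:
    """One transcript row, coordinates as in the UCSC export (0-based half-open)."""

    gene_name: str
    transcript_id: str
    chrom: str
    strand: str
    tx_start: int
    tx_end: int
    exon_starts: tuple[int, ...]
    exon_ends: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.exon_starts) != len(self.exon_ends):
            raise ValueError(f"{self.transcript_id}: exon list lengths differ")
        if not self.tx_start < self.tx_end:
            raise ValueError(f"{self.transcript_id}: txStart >= txEnd")


@dataclass(frozen=True)
class GeneModel:
    """Per-gene union interval with exon-union and intron sub-regions.

    All coordinates are 1-based inclusive.  ``exon_union`` and ``introns``
    are sorted, disjoint, and partition ``span`` exactly.
    """

    gene_name: str
    chrom: str
    strand: str
    span: Interval
    exon_union: tuple[Interval, ...]
    introns: tuple[Interval, ...] = field(default=())


def _parse_coord_list(text: str) -> tuple[int, ...]:
    return tuple(int(x) for x in str(text).rstrip(",").split(",") if x != "")


def parse_annotation(path_or_handle) -> list[TranscriptRecord]:
    """Parse a UCSC Table Browser transcript export.

    Expects a tab-separated table whose header (leading '#' tolerated)
    includes name, chrom, strand, txStart, txEnd, exonStarts, exonEnds and
    name2 (the gene symbol).  Extra columns are ignored.
    """
    table = pd.read_csv(path_or_handle, sep="\t", dtype=str)
    table.columns = [c.lstrip("#") for c in table.columns]
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise AnnotationFormatError(
            f"annotation table is missing required column(s): {', '.join(missing)}"
        )
    records = [
        TranscriptRecord(
            gene_name=row.name2,
            transcript_id=row.name,
            chrom=row.chrom,
            strand=row.strand,
            tx_start=int(row.txStart),
            tx_end=int(row.txEnd),
            exon_starts=_parse_coord_list(row.exonStarts),
            exon_ends=_parse_coord_list(row.exonEnds),
        )
        for row in table.itertuples(index=False)
    ]
    logger.info("parse_annotation: %d transcript records", len(records))
    return records


def _merge_intervals(intervals: Iterable[Interval]) -> tuple[Interval, ...]:
    """Union of 1-based inclusive intervals (adjacent intervals merge)."""
    merged: list[list[int]] = []
    for start, end in sorted(intervals):
        if merged and start <= merged[-1][1] + 1:
            merged[-1][1] = max(merged[-1][1], end)
        else:
            merged.append([start, end])
    return tuple((s, e) for s, e in merged)


def _complement(span: Interval, covered: tuple[Interval, ...]) -> tuple[Interval, ...]:
    """Sub-intervals of ``span`` not covered by the sorted disjoint ``covered``."""
    gaps: list[Interval] = []
    cursor = span[0]
    for start, end in covered:
        if start > cursor:
            gaps.append((cursor, start - 1))
        cursor = max(cursor, end + 1)
    if cursor <= span[1]:
        gaps.append((cursor, span[1]))
    return tuple(gaps)


def build_gene_models(records: Iterable[TranscriptRecord]) -> list[GeneModel]:
    """Merge transcript variants into one interval model per gene locus.

    Transcripts are grouped by (gene name, chrom, strand); the span covers
    all grouped transcripts, the exon union pools all their exons, and the
    introns are the remainder of the span.  A gene name appearing at
    several loci (different chrom or strand) yields separate models
    suffixed ``_1``, ``_2``, ... in genomic order.
    """
    groups: dict[tuple[str, str, str], list[TranscriptRecord]] = {}
    for rec in records:
        groups.setdefault((rec.gene_name, rec.chrom, rec.strand), []).append(rec)

    loci_by_name: dict[str, list[tuple[str, str, list[TranscriptRecord]]]] = {}
    for (gene, chrom, strand), recs in groups.items():
        loci_by_name.setdefault(gene, []).append((chrom, strand, recs))

    models: list[GeneModel] = []
    for gene, loci in loci_by_name.items():
        loci.sort(key=lambda locus: (locus[0], min(r.tx_start for r in locus[2]), locus[1]))
        multi = len(loci) > 1
        for i, (chrom, strand, recs) in enumerate(loci, start=1):
            # UCSC 0-based half-open -> 1-based inclusive
            span = (min(r.tx_start for r in recs) + 1, max(r.tx_end for r in recs))
            exons = [
                (s + 1, e)
                for r in recs
                for s, e in zip(r.exon_starts, r.exon_ends)
            ]
            exon_union = _merge_intervals(exons)
            models.append(
                GeneModel(
                    gene_name=f"{gene}_{i}" if multi else gene,
                    chrom=chrom,
                    strand=strand,
                    span=span,
                    exon_union=exon_union,
                    introns=_complement(span, exon_union),
                )
            )
    models.sort(key=lambda m: (m.chrom, m.span, m.gene_name))
    logger.info("build_gene_models: %d gene models", len(models))
    return models
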