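"""Per-gene insertion statistics: I.I., D.I. and Bias.

Read counts are deliberately never used as a measure of selection —
amplification bias makes them unreliable — so every statistic here counts
independent insertions (I.I.).  Three parameters summarize the mutagenic
load of a gene:

* ``n_II`` — independent insertions anywhere in the gene span;
* ``n_DI`` — disruptive insertions: exonic insertions in either
  orientation plus intronic insertions whose splice acceptor is oriented
  with transcription (``n_exonic + n_intron_sense``);
* ``bias`` — the ratio of sense over antisense intronic insertions,
  ``(n_intron_sense + pc) / (n_intron_anti + pc)`` with a pseudocount
  ``pc`` (default 1) keeping the ratio finite; evidence of selection
  independent of the insertion count, because unselected intronic
  insertions land in either orientation equally.

Gene tables are pandas DataFrames indexed by gene name with columns
``n_II, n_exonic, n_intron_sense, n_intron_anti, n_DI, bias``.
"""

from __future__ import annotations

import logging
from bisect import bisect_right
from typing import Iterable, Literal, Sequence

import pandas as pd
from intervaltree import IntervalTree

from .annotation import GeneModel
from .insertion_core import InsertionSite

logger = logging.getLogger(__name__)

DEFAULT_PSEUDOCOUNT = 1.0

COUNT_COLUMNS = ["n_II", "n_exonic", "n_intron_sense", "n_intron_anti", "n_DI", "bias"]
COMPONENT_COLUMNS = ["n_exonic", "n_intron_sense", "n_intron_anti"]

OrientationMode = Literal["as_aligned", "inverted"]
AggregationMode = Literal["sum", "median"]


def compute_bias(n_intron_sense: float, n_intron_anti: float,
                 pseudocount: float = DEFAULT_PSEUDOCOUNT) -> float:
    """Sense/antisense intronic insertion ratio with a pseudocount."""
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    return (n_intron_sense + pseudocount) / (n_intron_anti + pseudocount)


class _GeneIndex:
    """Interval lookup from genomic position to overlapping gene models."""

    def __init__(self, genes: Sequence[GeneModel]):
        self.genes = list(genes)
        self._trees: dict[str, IntervalTree] = {}
        for idx, g in enumerate(self.genes):
            tree = self._trees.setdefault(g.chrom, IntervalTree())
            # IntervalTree is half-open; span is 1-based inclusive
            tree.addi(g.span[0], g.span[1] + 1, idx)

    def overlapping(self, chrom: str, position: int) -> list[int]:
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        return sorted(iv.data for iv in tree.at(position))


def _in_exon_union(gene: GeneModel, position: int) -> bool:
    starts = [s for s, _ in gene.exon_union]
    i = bisect_right(starts, position) - 1
    return i >= 0 and position <= gene.exon_union[i][1]


def derive_statistics(table: pd.DataFrame,
                      pseudocount: float = DEFAULT_PSEUDOCOUNT) -> pd.DataFrame:
    """Recompute n_II, n_DI and bias from the three component counts."""
    out = table.copy()
    out["n_II"] = out[COMPONENT_COLUMNS].sum(axis=1)
    out["n_DI"] = out["n_exonic"] + out["n_intron_sense"]
    out["bias"] = [
        compute_bias(s, a, pseudocount)
        for s, a in zip(out["n_intron_sense"], out["n_intron_anti"])
    ]
    return out[COUNT_COLUMNS]


def assign_insertions(
    sites: Iterable[InsertionSite],
    genes: Sequence[GeneModel],
    orientation_mode: OrientationMode = "as_aligned",
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> tuple[pd.DataFrame, int]:
    """Tally insertions into gene sub-regions.

    A site inside a gene's exon union counts as exonic regardless of
    orientation; an intronic site counts as sense when its effective
    strand equals the gene strand, antisense otherwise.  The effective
    strand is the alignment strand, flipped when
    ``orientation_mode='inverted'`` (the read strand corresponding to a
    sense-oriented splice acceptor depends on which side of the vector
    the sequencing primer sits).  A site overlapping k genes counts in
    all k.  Returns the per-gene table and the number of intergenic
    sites.
    """
    if orientation_mode not in ("as_aligned", "inverted"):
        raise ValueError(f"unknown orientation_mode: {orientation_mode!r}")
    index = _GeneIndex(genes)
    flip = {"+": "-", "-": "+"}
    rows = {
        g.gene_name: {"n_exonic": 0, "n_intron_sense": 0, "n_intron_anti": 0}
        for g in genes
    }
    n_sites = 0
    intergenic = 0
    for site in sites:
        n_sites += 1
        hits = index.overlapping(site.chrom, site.position)
        if not hits:
            intergenic += 1
            continue
        strand = site.strand if orientation_mode == "as_aligned" else flip[site.strand]
        for gi in hits:
            gene = index.genes[gi]
            row = rows[gene.gene_name]
            if _in_exon_union(gene, site.position):
                row["n_exonic"] += 1
            elif strand == gene.strand:
                row["n_intron_sense"] += 1
            else:
                row["n_intron_anti"] += 1
    table = pd.DataFrame.from_dict(rows, orient="index").sort_index()
    table.index.name = "gene"
    table = derive_statistics(table, pseudocount)
    logger.info(
        "assign_insertions: %d sites, %d intergenic, %d genes",
        n_sites, intergenic, len(table),
    )
    return table, intergenic


def aggregate_replicates(
    tables: Sequence[pd.DataFrame],
    mode: AggregationMode = "sum",
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> pd.DataFrame:
    """Combine per-replicate gene tables component-wise.

    ``sum`` pools all replicates; ``median`` takes per-gene component
    medians (the midpoint of the two central values for even replicate
    counts, so medians may be non-integer).  Derived columns are
    recomputed from the aggregated components.  All replicates must share
    one gene universe.
    """
    if not tables:
        raise ValueError("at least one replicate table is required")
    if mode not in ("sum", "median"):
        raise ValueError(f"unknown aggregation mode: {mode!r}")
    universe = tables[0].index
    for i, t in enumerate(tables[1:], start=2):
        diff = universe.symmetric_difference(t.index)
        if len(diff):
            raise ValueError(
                f"replicate {i} gene universe mismatch: {sorted(diff)[:10]}"
            )
    stack = pd.concat(
        [t.loc[universe, COMPONENT_COLUMNS] for t in tables],
        keys=range(len(tables)),
    )
    grouped = stack.groupby(level=1, sort=False)
    agg = grouped.sum() if mode == "sum" else grouped.median()
    return derive_statistics(agg.loc[universe], pseudocount)


def write_gene_table(table: pd.DataFrame, path_or_handle) -> None:
    """Write the per-gene statistics as tab-separated text."""
    table.to_csv(path_or_handle, sep="\t", index_label="gene")


def read_gene_table(path_or_handle) -> pd.DataFrame:
    """Read a table written by :func:`write_gene_table`."""
    return pd.read_csv(path_or_handle, sep="\t", index_col="gene")


def write_gene_workbook(table: pd.DataFrame, path: str) -> None:
    """Optional spreadsheet export (requires openpyxl)."""
    table.to_excel(path, index_label="gene")
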