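"""Candidate tables, per-gene SVG insertion plots and method overlaps.

The gene plot mirrors the screen's reading of an insertion pattern: a
gene axis with exon boxes and an intron line, one lollipop per
independent insertion, colored red when the insertion's effective
orientation matches the direction of transcription (mutagenic splice
acceptor) and green when it opposes it (neutral in introns).  Panels are
stacked with the selected pool above the control pool so enrichment and
orientation bias are visible at a glance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from xml.etree import ElementTree as ET

import pandas as pd

from .annotation import GeneModel
from .insertion_core import InsertionSite

logger = logging.getLogger(__name__)

SENSE_COLOR = "#d62728"  # red: splice acceptor aligned with transcription
ANTISENSE_COLOR = "#2ca02c"  # green: opposed, neutral in introns

_PANEL_WIDTH = 800
_PANEL_HEIGHT = 120
_MARGIN = 50
_AXIS_Y = 90
_EXON_HALF = 8
_LOLLIPOP_TOP = 30


@dataclass
class GenePlotSpec:
    """Inputs for one gene's insertion plot.

    ``datasets`` maps a panel label to that pool's insertion sites, in
    panel order (selected first, control below).  ``orientation_mode``
    matches the quantification setting so plotted colors agree with the
    counted sense/antisense assignment.
    """

    gene: GeneModel
    datasets: dict[str, list[InsertionSite]] = field(default_factory=dict)
    orientation_mode: str = "as_aligned"


def _effective_strand(strand: str, mode: str) -> str:
    if mode == "inverted":
        return {"+": "-", "-": "+"}[strand]
    return strand


def render_gene_svg(spec: GenePlotSpec) -> str:
    """Render one gene's insertion pattern as a standalone SVG document.

    Pure and deterministic: identical specs give byte-identical output.
    Insertions outside the gene span are rejected.
    """
    gene = spec.gene
    span_start, span_end = gene.span
    span_len = max(span_end - span_start + 1, 1)
    n_panels = max(len(spec.datasets), 1)
    height = n_panels * _PANEL_HEIGHT + 30

    def x_of(position: int) -> float:
        return _MARGIN + (position - span_start) / span_len * (_PANEL_WIDTH - 2 * _MARGIN)

    svg = ET.Element("svg", {
        "xmlns": "http://www.w3.org/2000/svg",
        "width": str(_PANEL_WIDTH),
        "height": str(height),
        "viewBox": f"0 0 {_PANEL_WIDTH} {height}",
    })
    title = ET.SubElement(svg, "text", {
        "x": str(_MARGIN), "y": "18", "font-size": "14", "font-family": "sans-serif",
    })
    title.text = f"{gene.gene_name} ({gene.chrom}:{span_start}-{span_end}, {gene.strand})"

    for panel, (label, sites) in enumerate(spec.datasets.items() or {"": []}.items()):
        top = 30 + panel * _PANEL_HEIGHT
        group = ET.SubElement(svg, "g", {"transform": f"translate(0,{top})"})
        caption = ET.SubElement(group, "text", {
            "x": str(_MARGIN), "y": "14", "font-size": "12",
            "font-family": "sans-serif", "fill": "#555555",
        })
        caption.text = label
        # intron line across the span, exon boxes on top
        ET.SubElement(group, "line", {
            "x1": f"{x_of(span_start):.2f}", "y1": str(_AXIS_Y),
            "x2": f"{x_of(span_end):.2f}", "y2": str(_AXIS_Y),
            "stroke": "#333333", "stroke-width": "2",
        })
        for exon_start, exon_end in gene.exon_union:
            ET.SubElement(group, "rect", {
                "x": f"{x_of(exon_start):.2f}",
                "y": str(_AXIS_Y - _EXON_HALF),
                "width": f"{max(x_of(exon_end) - x_of(exon_start), 1.0):.2f}",
                "height": str(2 * _EXON_HALF),
                "fill": "#4c72b0",
                "class": "exon",
            })
        for site in sorted(sites):
            if not span_start <= site.position <= span_end:
                raise ValueError(
                    f"insertion {site.chrom}:{site.position} lies outside the "
                    f"span of {gene.gene_name}"
                )
            color = (
                SENSE_COLOR
                if _effective_strand(site.strand, spec.orientation_mode) == gene.strand
                else ANTISENSE_COLOR
            )
            x = f"{x_of(site.position):.2f}"
            ET.SubElement(group, "line", {
                "x1": x, "y1": str(_AXIS_Y - _EXON_HALF),
                "x2": x, "y2": str(_LOLLIPOP_TOP + 5),
                "stroke": color, "stroke-width": "1",
            })
            ET.SubElement(group, "circle", {
                "cx": x, "cy": str(_LOLLIPOP_TOP), "r": "4",
                "fill": color, "class": "insertion",
            })
    return ET.tostring(svg, encoding="unicode")


def plot_gene(
    gene_name: str,
    genes: list[GeneModel],
    datasets: dict[str, list[InsertionSite]],
    orientation_mode: str = "as_aligned",
) -> str:
    """Plot a gene by name, restricting each dataset to sites in its span."""
    by_name = {g.gene_name: g for g in genes}
    if gene_name not in by_name:
        raise KeyError(f"gene {gene_name!r} is absent from the annotation")
    gene = by_name[gene_name]
    in_span = {
        label: [
            s for s in sites
            if s.chrom == gene.chrom and gene.span[0] <= s.position <= gene.span[1]
        ]
        for label, sites in datasets.items()
    }
    return render_gene_svg(GenePlotSpec(gene, in_span, orientation_mode))


def overlap_summary(
    candidates: dict[str, pd.DataFrame], top_n: int = 20
) -> tuple[pd.DataFrame, int]:
    """Pairwise and total overlap of the top-n gene sets across methods."""
    if len(candidates) < 2:
        raise ValueError("overlap_summary needs at least two methods")
    tops = {
        m: set(df.sort_values("rank_position")["gene"].head(top_n))
        for m, df in candidates.items()
    }
    names = list(tops)
    matrix = pd.DataFrame(index=names, columns=names, dtype=int)
    for m in names:
        matrix.loc[m, m] = len(tops[m])
    for a, b in combinations(names, 2):
        n = len(tops[a] & tops[b])
        matrix.loc[a, b] = n
        matrix.loc[b, a] = n
    total = len(set.intersection(*tops.values()))
    return matrix.astype(int), total


def write_candidate_table(
    candidates: pd.DataFrame,
    enrichment: pd.DataFrame,
    selected_counts: pd.DataFrame,
    control_counts: pd.DataFrame,
    path_or_handle,
) -> pd.DataFrame:
    """Write the user-facing candidate table as tab-separated text.

    Columns: gene, method, score, rank, the three fold enrichments, and
    the raw per-pool counts behind them.
    """
    table = candidates.merge(
        enrichment, left_on="gene", right_index=True, how="left"
    )
    for label, counts in (("sel", selected_counts), ("ctl", control_counts)):
        sub = counts[["n_II", "n_DI", "bias"]].add_suffix(f"_{label}")
        table = table.merge(sub, left_on="gene", right_index=True, how="left")
    table.to_csv(path_or_handle, sep="\t", index=False)
    return table


def read_candidate_table(path_or_handle) -> pd.DataFrame:
    """Read a table written by :func:`write_candidate_table`."""
    return pd.read_csv(path_or_handle, sep="\t")


def write_candidate_workbook(tables: dict[str, pd.DataFrame], path) -> None:
    """Optional spreadsheet export, one sheet per method (needs openpyxl)."""
    with pd.ExcelWriter(path) as writer:
        for method, table in tables.items():
            table.to_excel(writer, sheet_name=method, index=False)
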