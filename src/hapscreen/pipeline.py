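"""End-to-end orchestration: alignments -> insertions -> counts -> candidates.

Thin glue over the stage modules, plus the run-configuration file format
(INI-style ``key = value`` sections) that the command-line interface
consumes.  Every stage logs its input/output record counts, so the count
conservation of the pipeline can be audited from the log alone.
"""

from __future__ import annotations

import configparser
import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from . import insertion_core, quantify, ranking
from .annotation import GeneModel
from .insertion_core import InsertionSite
from .sequence_io import AlignedFlank

logger = logging.getLogger(__name__)

METHODS = ("LOF", "FT", "Rank")


@dataclass
class ScreenResult:
    """Everything produced by one control-vs-selected analysis."""

    control_counts: pd.DataFrame
    selected_counts: pd.DataFrame
    control_sites: list[InsertionSite]
    selected_sites: list[InsertionSite]
    enrichment: pd.DataFrame
    candidates: dict[str, pd.DataFrame]
    #: genes with no insertions in either pool, excluded from ranking
    inactive_genes: tuple[str, ...] = field(default=())
    intergenic: dict[str, int] = field(default_factory=dict)


def collapse_flanks(
    flanks: Iterable[AlignedFlank],
    window: int = insertion_core.DEFAULT_WINDOW,
    min_reads: int = insertion_core.DEFAULT_MIN_READS,
) -> list[InsertionSite]:
    """Tally read starts and collapse them into independent insertions."""
    return insertion_core.collapse_insertions(
        insertion_core.tally_starts(flanks), window=window, min_reads=min_reads
    )


def run_screen(
    control_flanks: Iterable[AlignedFlank],
    selected_flanks: Iterable[AlignedFlank],
    genes: Sequence[GeneModel],
    window: int = insertion_core.DEFAULT_WINDOW,
    min_reads: int = insertion_core.DEFAULT_MIN_READS,
    min_reads_control: int | None = None,
    orientation_mode: quantify.OrientationMode = "as_aligned",
    pseudocount: float = quantify.DEFAULT_PSEUDOCOUNT,
    lof_k: int = ranking.DEFAULT_LOF_K,
    lof_log_features: bool = False,
    methods: Sequence[str] = METHODS,
) -> ScreenResult:
    """Run the full analysis for one selected pool against one control.

    ``min_reads_control`` allows a different read threshold for the
    control pool, compensating for unequal sampling depth between pools.
    Genes without a single insertion in either pool are excluded from
    ranking (their enrichment vector would be the pseudocount identity
    and only dilute the gene cloud) and reported separately.
    """
    unknown = set(methods) - set(METHODS)
    if unknown:
        raise ValueError(f"unknown ranking method(s): {sorted(unknown)}")
    control_sites = collapse_flanks(
        control_flanks, window,
        min_reads if min_reads_control is None else min_reads_control,
    )
    selected_sites = collapse_flanks(selected_flanks, window, min_reads)
    control_counts, inter_ctl = quantify.assign_insertions(
        control_sites, genes, orientation_mode, pseudocount
    )
    selected_counts, inter_sel = quantify.assign_insertions(
        selected_sites, genes, orientation_mode, pseudocount
    )
    active = (control_counts["n_II"] + selected_counts["n_II"]) > 0
    inactive = tuple(control_counts.index[~active])
    ctl, sel = control_counts[active], selected_counts[active]
    logger.info(
        "run_screen: %d genes, %d active, %d inactive",
        len(control_counts), len(ctl), len(inactive),
    )
    enrichment = ranking.fold_enrichment(sel, ctl, pseudocount)
    candidates: dict[str, pd.DataFrame] = {}
    if "LOF" in methods:
        candidates["LOF"] = ranking.lof_rank(enrichment, k=lof_k,
                                             log_features=lof_log_features)
    if "FT" in methods:
        candidates["FT"] = ranking.fisher_rank(sel, ctl, pseudocount)
    if "Rank" in methods:
        candidates["Rank"] = ranking.rank_method(sel, ctl)
    return ScreenResult(
        control_counts=control_counts,
        selected_counts=selected_counts,
        control_sites=control_sites,
        selected_sites=selected_sites,
        enrichment=enrichment,
        candidates=candidates,
        inactive_genes=inactive,
        intergenic={"control": inter_ctl, "selected": inter_sel},
    )


def load_run_config(path) -> dict[str, dict[str, str]]:
    """Parse the INI-style run configuration file into nested dicts."""
    parser = configparser.ConfigParser()
    read = parser.read(path)
    if not read:
        raise FileNotFoundError(path)
    return {section: dict(parser[section]) for section in parser.sections()}
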