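"""Candidate gene ranking from fold-enrichment vectors.

Every gene is summarized by a 3-dimensional vector of fold enrichments of
its insertion statistics in the selected pool relative to the control
pool: (fe_II, fe_DI, fe_bias).  Genes whose mutations confer no advantage
form a dense cluster near (1, 1, 1); genes under selection diverge in one
or more components.  The primary ranking method scores that divergence
with the Local Outlier Factor (LOF), a density-based outlier statistic:
points deep inside the cluster score about 1, points in sparse regions
relative to their neighbours score much higher.

Two comparator methods are provided: a per-gene one-sided Fisher's exact
test on disruptive-insertion (D.I.) counts against the dataset totals,
and a rank-difference method scoring the change of a gene's D.I. rank
between pools on a logarithmic scale.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from scipy.stats import hypergeom, rankdata

logger = logging.getLogger(__name__)

DEFAULT_LOF_K = 20
DEFAULT_PSEUDOCOUNT = 1.0

#: floor on the mean reachability distance; points in zero-extent
#: neighbourhoods (exact duplicates) hit the floor, get equal local
#: densities and therefore LOF = 1 exactly
_LRD_FLOOR = 1e-10

ENRICHMENT_COLUMNS = ["fe_II", "fe_DI", "fe_bias"]
SCORE_COLUMNS = ["gene", "method", "score", "rank_position"]


def fold_enrichment(
    selected: pd.DataFrame,
    control: pd.DataFrame,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> pd.DataFrame:
    """Per-gene fold enrichment of I.I., D.I. and Bias (selected/control).

    Insertion counts are pseudocounted on both sides; Bias carries its own
    pseudocount from quantification and is divided directly.  No
    library-size normalization is applied.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    diff = selected.index.symmetric_difference(control.index)
    if len(diff):
        raise ValueError(f"gene universe mismatch: {sorted(diff)[:10]}")
    control = control.loc[selected.index]
    out = pd.DataFrame(index=selected.index.copy())
    out["fe_II"] = (selected["n_II"] + pseudocount) / (control["n_II"] + pseudocount)
    out["fe_DI"] = (selected["n_DI"] + pseudocount) / (control["n_DI"] + pseudocount)
    out["fe_bias"] = selected["bias"] / control["bias"]
    return out


# ---------------------------------------------------------------------------
# Local Outlier Factor
# ---------------------------------------------------------------------------

def local_outlier_factor(points: np.ndarray, k: int, chunk: int = 2048) -> np.ndarray:
    """LOF scores with Euclidean distance and neighbourhood size ``k``.

    Implements the classical definition: the k-distance of a point is its
    distance to the k-th nearest other point; its neighbourhood contains
    every other point within that distance (ties included, so it may hold
    more than k points).  The reachability distance of p from o is
    max(k-distance(o), d(p, o)); the local reachability density is the
    inverse mean reachability distance over the neighbourhood; the LOF is
    the mean ratio of neighbour densities to the point's own density.

    Exact duplicates repeated more than k times have zero-extent
    neighbourhoods; their densities are capped (see ``_LRD_FLOOR``) so
    such points score exactly 1.
    """
    X = np.asarray(points, dtype=float)
    if X.ndim != 2:
        raise ValueError("points must be a 2-D array")
    n = len(X)
    if not 1 <= k < n:
        raise ValueError(f"k must satisfy 1 <= k < n_points; got k={k}, n={n}")

    kdist = np.empty(n)
    nb_idx: list[np.ndarray] = []
    nb_dist: list[np.ndarray] = []
    for start in range(0, n, chunk):
        rows = slice(start, min(start + chunk, n))
        dmat = cdist(X[rows], X)
        for local, p in enumerate(range(rows.start, rows.stop)):
            drow = dmat[local]
            drow[p] = np.inf  # exclude the point itself
            kd = np.partition(drow, k - 1)[k - 1]
            kdist[p] = kd
            nb = np.flatnonzero(drow <= kd)
            nb_idx.append(nb)
            nb_dist.append(drow[nb])

    lrd = np.empty(n)
    for p in range(n):
        reach = np.maximum(kdist[nb_idx[p]], nb_dist[p])
        lrd[p] = 1.0 / max(reach.mean(), _LRD_FLOOR)

    lof = np.empty(n)
    for p in range(n):
        lof[p] = (lrd[nb_idx[p]] / lrd[p]).mean()
    return lof


def lof_rank(vectors: pd.DataFrame, k: int = DEFAULT_LOF_K,
             log_features: bool = False) -> pd.DataFrame:
    """Rank genes by LOF on their fold-enrichment vectors.

    Features are the raw fold enrichments by default; ``log_features``
    switches to natural-log enrichments.  Candidates are sorted by LOF
    descending, ties broken by gene name.
    """
    if len(vectors) <= k:
        raise ValueError(
            f"LOF needs more than k={k} genes; got {len(vectors)}"
        )
    X = vectors[ENRICHMENT_COLUMNS].to_numpy(dtype=float)
    if log_features:
        X = np.log(X)
    scores = local_outlier_factor(X, k)
    out = pd.DataFrame({"gene": vectors.index, "method": "LOF", "score": scores})
    out = out.sort_values(["score", "gene"], ascending=[False, True],
                          kind="mergesort", ignore_index=True)
    out["rank_position"] = np.arange(1, len(out) + 1)
    return out[SCORE_COLUMNS]


# ---------------------------------------------------------------------------
# Comparator methods
# ---------------------------------------------------------------------------

def _rounded_di(table: pd.DataFrame) -> np.ndarray:
    """Integer D.I. counts; median-aggregated halves round half-up."""
    return np.floor(table["n_DI"].to_numpy(dtype=float) + 0.5).astype(np.int64)


def fisher_enrichment_pvalues(di_gene_sel, di_gene_ctl,
                              di_total_sel: int, di_total_ctl: int) -> np.ndarray:
    """One-sided Fisher p-values for D.I. enrichment, vectorized.

    For the 2x2 table [[a, total_sel - a], [c, total_ctl - c]] the
    one-sided (enrichment) p-value is the upper tail P(X >= a) of the
    hypergeometric distribution with the table's margins.
    """
    a = np.asarray(di_gene_sel, dtype=np.int64)
    c = np.asarray(di_gene_ctl, dtype=np.int64)
    return hypergeom.sf(a - 1, di_total_sel + di_total_ctl, di_total_sel, a + c)


def fisher_rank(selected: pd.DataFrame, control: pd.DataFrame,
                pseudocount: float = DEFAULT_PSEUDOCOUNT) -> pd.DataFrame:
    """Rank genes by one-sided Fisher's exact test on D.I. enrichment.

    For each gene the 2x2 table contrasts its D.I. count with the rest of
    the dataset's D.I. in selected vs control pools; the one-sided
    (enrichment) p-value is the upper hypergeometric tail.  Candidates
    are sorted by p ascending, ties broken by descending D.I. fold
    enrichment, then gene name.
    """
    diff = selected.index.symmetric_difference(control.index)
    if len(diff):
        raise ValueError(f"gene universe mismatch: {sorted(diff)[:10]}")
    control = control.loc[selected.index]
    di_sel = _rounded_di(selected)
    di_ctl = _rounded_di(control)
    total_sel = int(di_sel.sum())
    total_ctl = int(di_ctl.sum())
    if total_sel == 0 or total_ctl == 0:
        raise ValueError("zero total D.I. in selected or control dataset")
    pvals = fisher_enrichment_pvalues(di_sel, di_ctl, total_sel, total_ctl)
    fe_di = (di_sel + pseudocount) / (di_ctl + pseudocount)
    out = pd.DataFrame({
        "gene": selected.index, "method": "FT", "score": pvals, "_fe": fe_di,
    })
    out = out.sort_values(["score", "_fe", "gene"], ascending=[True, False, True],
                          kind="mergesort", ignore_index=True)
    out["rank_position"] = np.arange(1, len(out) + 1)
    return out[SCORE_COLUMNS]


def rank_method(selected: pd.DataFrame, control: pd.DataFrame) -> pd.DataFrame:
    """Rank genes by the log rank-position difference of their D.I. counts.

    Within each pool genes are ranked by D.I. descending (rank 1 = most
    disrupted; ties share the mean of their rank positions); the score is
    ln(rank in selected) - ln(rank in control), so strongly enriched
    genes go negative.  Candidates are sorted by score ascending.
    """
    diff = selected.index.symmetric_difference(control.index)
    if len(diff):
        raise ValueError(f"gene universe mismatch: {sorted(diff)[:10]}")
    control = control.loc[selected.index]
    rank_sel = rankdata(-selected["n_DI"].to_numpy(dtype=float), method="average")
    rank_ctl = rankdata(-control["n_DI"].to_numpy(dtype=float), method="average")
    scores = np.log(rank_sel) - np.log(rank_ctl)
    out = pd.DataFrame({"gene": selected.index, "method": "Rank", "score": scores})
    out = out.sort_values(["score", "gene"], ascending=[True, True],
                          kind="mergesort", ignore_index=True)
    out["rank_position"] = np.arange(1, len(out) + 1)
    return out[SCORE_COLUMNS]
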