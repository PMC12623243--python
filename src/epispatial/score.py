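"""Per-cell gene-set activity (AUCell) and regulon specificity scores.

AUCell ranks each cell's genes by expression and scores a gene set by the
normalized area under its recovery curve over the top fraction of the
ranking — a rank-based activity that ignores normalization and depth. The
regulon specificity score (RSS) contrasts a regulon's activity
distribution across cells against a cell-class indicator distribution via
the Jensen-Shannon divergence: RSS = 1 - sqrt(JSD), 1 for activity
confined exactly to the class, 0 for disjoint support.
"""

from __future__ import annotations

import math

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.spatial.distance import jensenshannon

from .annotate import rank_sum_compare

__all__ = ["aucell", "aucell_matrix", "regulon_specificity", "enhanced_regulons"]


def _dense(X) -> np.ndarray:
    return X.toarray() if sp.issparse(X) else np.asarray(X, dtype=float)


def aucell(
    expression: np.ndarray | sp.spmatrix | ad.AnnData,
    gene_set: list[str] | set[str],
    genes: list[str] | None = None,
    top_fraction: float = 0.05,
    seed: int = 0,
) -> np.ndarray:
    """AUCell score per cell for one gene set.

    Per cell, genes are ranked by expression descending (ties broken by a
    seeded random shuffle); with N genes, T = ceil(top_fraction * N) and
    hits(x) the number of set genes at rank <= x, the raw AUC is
    sum_{x=1..T} hits(x), normalized by its maximum sum_{x=1..T} min(x, |S|)
    so scores live in [0, 1]. Strictly monotone transforms of a cell's
    expression leave the score unchanged.
    """
    if isinstance(expression, ad.AnnData):
        genes = list(expression.var_names)
        expression = expression.X
    X = _dense(expression)
    if genes is None:
        raise ValueError("gene identifiers are required")
    if not 0 < top_fraction < 1:
        raise ValueError("top_fraction must be in (0, 1)")
    member = np.isin(np.asarray(genes), list(gene_set))
    n_set = int(member.sum())
    if n_set == 0:
        raise ValueError("gene set does not overlap the expression universe")

    n_cells, n_genes = X.shape
    T = math.ceil(top_fraction * n_genes)
    rng = np.random.default_rng(seed)
    # random tie-break: a fixed shuffled gene order as secondary sort key
    tiebreak = rng.permutation(n_genes)
    order = np.lexsort((np.broadcast_to(tiebreak, X.shape), -X), axis=1)

    # rank position (0-based) of each gene per cell
    member_at_rank = member[order]             # cells x genes, True where a
    top = member_at_rank[:, :T]                # set gene occupies that rank
    # raw AUC = sum over set genes in top T of (T - rank0), rank0 0-based
    weights = T - np.arange(T)
    raw = (top * weights).sum(axis=1)
    max_raw = sum(min(x, n_set) for x in range(1, T + 1))
    return raw / max_raw


def aucell_matrix(
    cells: ad.AnnData,
    gene_sets: dict[str, list[str]],
    top_fraction: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """AUCell scores for a collection of sets; cells x sets DataFrame."""
    scores = {
        name: aucell(cells, gs, top_fraction=top_fraction, seed=seed)
        for name, gs in gene_sets.items()
    }
    return pd.DataFrame(scores, index=cells.obs_names)


def regulon_specificity(
    activity: pd.DataFrame, labels: np.ndarray | pd.Series
) -> pd.DataFrame:
    """Regulon x class RSS table.

    For regulon r and class c: P is the activity column normalized to sum
    one over cells, Q the class-indicator distribution; RSS = 1 -
    sqrt(JSD(P, Q)) with base-2 logs so the divergence lies in [0, 1].
    All-zero activity columns yield NaN (reported missing).
    """
    labels = np.asarray(labels)
    classes = [c for c in pd.unique(labels) if c is not None]
    if len(classes) < 2:
        raise ValueError("need at least two classes")
    if (activity.to_numpy() < 0).any():
        raise ValueError("activity must be non-negative")
    out = pd.DataFrame(index=activity.columns, columns=classes, dtype=float)
    for c in classes:
        q = (labels == c).astype(float)
        q /= q.sum()
        for reg in activity.columns:
            p = activity[reg].to_numpy(dtype=float)
            tot = p.sum()
            if tot == 0:
                out.loc[reg, c] = np.nan
                continue
            out.loc[reg, c] = 1.0 - jensenshannon(p / tot, q, base=2)
    return out


def enhanced_regulons(
    activity: pd.DataFrame,
    labels: np.ndarray | pd.Series,
    target_class: str,
    alpha: float = 0.05,
) -> list[str]:
    """Regulons specifically elevated in ``target_class``.

    A regulon qualifies when its RSS in the target class exceeds its RSS
    in every other class and its activity differs from the remaining
    cells by a rank-sum test at level ``alpha``.
    """
    labels = np.asarray(labels)
    rss = regulon_specificity(activity, labels)
    others = [c for c in rss.columns if c != target_class]
    in_cls = labels == target_class
    chosen = []
    for reg in rss.index:
        row = rss.loc[reg]
        if row.isna().any() or not (row[target_class] > row[others].max()):
            continue
        _, p = rank_sum_compare(
            activity.loc[in_cls, reg], activity.loc[~in_cls, reg]
        )
        if p < alpha:
            chosen.append(reg)
    return chosen
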