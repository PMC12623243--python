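"""Gene-set enrichment against PC loadings and generic over-representation.

``loading_rank_test`` asks whether a marker panel (e.g. cutaneous SCC
markers) sits high in the loading ranks of a principal component, using a
one-sided rank-sum test — threshold-free and matching a ranked-loading
display. ``ora_test`` is a plain hypergeometric over-representation test
for user-supplied gene sets, with Benjamini-Hochberg adjustment across
sets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "CoverageError",
    "loading_rank_test",
    "ora_test",
    "ora_table",
]


class CoverageError(ValueError):
    """Marker set does not overlap (or degenerately equals) the universe."""


@dataclass
class LoadingRankResult:
    statistic: float
    pvalue: float
    marker_ranks: pd.Series  # 1-based rank by descending loading, per marker


def loading_rank_test(
    loadings: pd.Series | dict[str, float],
    markers: set[str] | list[str],
    alternative: str = "greater",
) -> LoadingRankResult:
    """Rank-sum test of marker loadings against the rest of the universe.

    Genes are ranked by loading value (descending, rank 1 = top). With
    ``alternative='greater'`` the test asks whether markers load higher
    than non-markers on the component. Returns the per-marker ranks for
    plotting alongside the test result.
    """
    loadings = pd.Series(loadings, dtype=float)
    markers = set(markers)
    present = sorted(markers & set(loadings.index))
    if not present:
        raise CoverageError("no marker overlaps the loading universe")
    if len(present) == len(loadings):
        raise CoverageError("markers equal the whole universe; test is degenerate")

    is_marker = loadings.index.isin(present)
    a = loadings[is_marker].to_numpy()
    b = loadings[~is_marker].to_numpy()
    pooled = np.concatenate([a, b])
    has_ties = len(np.unique(pooled)) < pooled.size
    method = "exact" if (pooled.size <= 25 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative=alternative, method=method)
    ranks = loadings.rank(ascending=False, method="average")[present]
    return LoadingRankResult(
        statistic=float(res.statistic), pvalue=float(res.pvalue), marker_ranks=ranks
    )


def ora_test(overlap: int, universe: int, set_size: int, n_drawn: int) -> float:
    """Hypergeometric upper-tail over-representation p-value.

    ``P(X >= overlap)`` for X ~ Hypergeom(universe, set_size, n_drawn):
    the chance of drawing at least the observed number of set members in
    ``n_drawn`` draws without replacement from the universe.
    """
    if not (0 <= set_size <= universe and 0 <= n_drawn <= universe):
        raise ValueError("set size and draw count must not exceed the universe")
    if overlap > min(set_size, n_drawn) or overlap < 0:
        raise ValueError("overlap inconsistent with set/draw sizes")
    return float(stats.hypergeom.sf(overlap - 1, universe, set_size, n_drawn))


def ora_table(
    hits: set[str] | list[str],
    gene_sets: dict[str, list[str]],
    universe: set[str] | list[str],
) -> pd.DataFrame:
    """ORA across a gene-set collection with BH adjustment.

    ``hits`` is the drawn gene list (e.g. significantly upregulated
    genes); sets and hits are intersected with ``universe`` first.
    """
    universe = set(universe)
    hits = set(hits) & universe
    rows = []
    for name, genes in gene_sets.items():
        members = set(genes) & universe
        overlap = sorted(hits & members)
        p = ora_test(len(overlap), len(universe), len(members), len(hits))
        rows.append({
            "set": name, "set_size": len(members), "n_drawn": len(hits),
            "overlap": len(overlap), "p": p, "overlap_genes": ",".join(overlap),
        })
    table = pd.DataFrame(rows)
    if len(table):
        table["p_adj"] = multipletests(table["p"], method="fdr_bh")[1]
    else:
        table["p_adj"] = []
    return table.sort_values("p", ignore_index=True)
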