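"""Region assignment, marker-positive selection and rank-sum comparison.

Stands in for histomorphological cell selection: cells are assigned to
annotated tissue regions by polygon containment of their centroid, tumor
cells are kept by non-zero expression of a marker gene (CCER2 in the
intended use), and per-gene expression between two groups is compared with
the Mann-Whitney/Wilcoxon rank-sum test.
"""

from __future__ import annotations

import logging

import anndata as ad
import numpy as np
import scipy.sparse as sp
from scipy import stats
from shapely.geometry import Point, Polygon

logger = logging.getLogger(__name__)

__all__ = [
    "REGION_CLASSES",
    "AnnotationError",
    "GeneNotFoundError",
    "assign_regions",
    "select_marker_positive",
    "rank_sum_compare",
]

REGION_CLASSES = ("epidermis", "tumor_core", "perivascular", "follicle", "background")

UNASSIGNED = "unassigned"


class AnnotationError(ValueError):
    """Degenerate or invalid region annotation."""


class GeneNotFoundError(KeyError):
    """Requested gene absent from the matrix's gene universe."""


def assign_regions(
    cells: ad.AnnData, regions: list[tuple[str, Polygon, str]]
) -> np.ndarray:
    """Class label per cell by polygon containment of its centroid.

    Boundary points count as inside; a centroid covered by several
    polygons takes the class of the smallest-area polygon (so nested
    annotations resolve to the most specific region); centroids outside
    every polygon are ``"unassigned"``. Centroids are read from obs
    ``row``/``col`` and matched against polygon (x, y) = (col, row).
    """
    for label, poly, ann_id in regions:
        if poly.is_empty or len(poly.exterior.coords) < 4:  # ring repeats start
            raise AnnotationError(f"degenerate polygon in annotation {ann_id!r}")
        if not poly.is_valid:
            raise AnnotationError(f"self-intersecting polygon {ann_id!r}")

    order = sorted(range(len(regions)), key=lambda i: regions[i][1].area)
    out = np.full(cells.n_obs, UNASSIGNED, dtype=object)
    pts = [Point(c, r) for r, c in zip(cells.obs["row"], cells.obs["col"])]
    for i, pt in enumerate(pts):
        for j in order:  # smallest area first -> first hit wins
            label, poly, _ = regions[j]
            if poly.covers(pt):
                out[i] = label
                break
    return out


def select_marker_positive(cells: ad.AnnData, marker: str) -> ad.AnnData:
    """Retain cells with a raw count > 0 for ``marker``.

    Zero/non-zero is decided on raw counts, which is invariant to any
    normalization choice.
    """
    if marker not in cells.var_names:
        raise GeneNotFoundError(marker)
    col = cells[:, marker].X
    vals = np.asarray(col.todense()).ravel() if sp.issparse(col) else np.asarray(col).ravel()
    keep = vals > 0
    frac = keep.mean() if cells.n_obs else 0.0
    logger.info("marker %s positive in %.1f%% of cells", marker, 100 * frac)
    if not keep.any():
        logger.warning("no cells express %s; returning empty selection", marker)
    return cells[keep].copy()


def rank_sum_compare(
    group_a: np.ndarray, group_b: np.ndarray, alternative: str = "two-sided"
) -> tuple[float, float]:
    """Mann-Whitney U test between two expression vectors.

    Uses the exact null distribution when the combined sample size is at
    most 25 and the pooled data are tie-free, and the tie-corrected normal
    approximation otherwise. P-values are unadjusted. Two identical
    constant groups carry no rank information and return p = 1.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    if np.ptp(pooled) == 0:
        return a.size * b.size / 2.0, 1.0
    has_ties = len(np.unique(pooled)) < pooled.size
    method = "exact" if (pooled.size <= 25 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative=alternative, method=method)
    return float(res.statistic), float(res.pvalue)
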