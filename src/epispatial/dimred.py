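"""Pooled normalization, keratin-excluded PCA and multivariate-t ellipses.

The selected cells from all samples are pooled, depth-normalized and
log-transformed; keratin genes are removed so that strong structural
keratin expression does not dominate the embedding; a gene-centered SVD
yields scores, unit-norm loadings and explained-variance ratios; batch
structure is reduced by per-sample centering of the scores (a declared
surrogate, not Harmony); and each cell-type cluster is summarized by a 95%
confidence ellipse of a fitted bivariate t-distribution.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import scanpy as sc
import scipy.sparse as sp
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = ["PCAResult", "EllipseFit", "preprocess", "fit_pooled_pca", "fit_t_ellipse"]


@dataclass
class PCAResult:
    scores: np.ndarray                 # cells x components
    loadings: np.ndarray               # genes x components, orthonormal columns
    explained_variance_ratio: np.ndarray
    genes: list[str]
    centering: np.ndarray              # per-gene mean subtracted before SVD
    batch_corrected: bool = False
    metadata: dict = field(default_factory=dict)


@dataclass
class EllipseFit:
    """Confidence ellipse of a fitted bivariate t-distribution.

    ``boundary_r2`` is the squared Mahalanobis radius of the ellipse:
    since (x-mu)' Sigma^-1 (x-mu) / 2 ~ F(2, df) under the fitted t, the
    level-``level`` ellipse uses r^2 = 2 * F^-1(level; 2, df), making the
    ellipse an exact quantile region of the fitted model.
    """

    center: np.ndarray
    scatter: np.ndarray
    df: float
    level: float
    boundary_r2: float

    def mahalanobis_sq(self, points: np.ndarray) -> np.ndarray:
        diff = np.atleast_2d(points) - self.center
        sol = np.linalg.solve(self.scatter, diff.T)
        return np.einsum("ij,ji->i", diff, sol)

    def contains(self, points: np.ndarray) -> np.ndarray:
        """Membership test: inside or on the ellipse boundary."""
        return self.mahalanobis_sq(points) <= self.boundary_r2

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Draw from the fitted bivariate t."""
        L = np.linalg.cholesky(self.scatter)
        z = rng.standard_normal((n, 2))
        u = rng.chisquare(self.df, size=n)
        return self.center + (z @ L.T) * np.sqrt(self.df / u)[:, None]


def preprocess(
    cells: ad.AnnData,
    exclude_pattern: str = "^KRT",
    target_sum: float = 1e4,
) -> ad.AnnData:
    """Depth-normalize to ``target_sum``, log1p, and drop excluded genes.

    Cells with zero total counts are removed with a warning. The returned
    AnnData carries the excluded gene list in ``.uns['excluded_genes']``.
    """
    totals = np.asarray(cells.X.sum(axis=1)).ravel()
    nonzero = totals > 0
    if not nonzero.all():
        logger.warning("excluding %d cells with zero total counts",
                       int((~nonzero).sum()))
    out = cells[nonzero].copy()
    sc.pp.normalize_total(out, target_sum=target_sum)
    sc.pp.log1p(out)
    pat = re.compile(exclude_pattern) if exclude_pattern else None
    excluded = [g for g in out.var_names if pat and pat.search(g)]
    if excluded:
        out = out[:, [g for g in out.var_names if g not in set(excluded)]].copy()
    out.uns["excluded_genes"] = excluded
    out.uns["normalization_target"] = target_sum
    return out


def fit_pooled_pca(
    matrix: np.ndarray | sp.spmatrix | ad.AnnData,
    sample_ids: np.ndarray | None = None,
    n_components: int = 30,
    batch_correct: bool = False,
    genes: list[str] | None = None,
) -> PCAResult:
    """Gene-centered SVD of the pooled normalized matrix.

    Loadings have unit-norm columns with the sign convention that each
    column's largest-magnitude entry is positive, so loadings are
    comparable across runs. ``explained_variance_ratio`` is relative to
    the total variance of the centered matrix. With ``batch_correct``,
    the per-sample mean of each score component is subtracted — a
    per-sample centering surrogate for batch integration, recorded in
    metadata (this is not Harmony).
    """
    if isinstance(matrix, ad.AnnData):
        genes = list(matrix.var_names)
        if sample_ids is None and "sample_id" in matrix.obs:
            sample_ids = matrix.obs["sample_id"].to_numpy()
        matrix = matrix.X
    X = matrix.toarray() if sp.issparse(matrix) else np.asarray(matrix, dtype=float)
    n, g = X.shape
    if n < 2 or g < 2:
        raise ValueError("need at least 2 cells and 2 genes")
    if n_components > min(n, g):
        raise ValueError("n_components exceeds min(cells, genes)")

    mean = X.mean(axis=0)
    Xc = X - mean
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    U, s, Vt = U[:, :n_components], s[:n_components], Vt[:n_components]

    loadings = Vt.T
    scores = U * s
    # sign convention: largest-magnitude loading entry positive
    flip = np.sign(loadings[np.abs(loadings).argmax(axis=0), np.arange(loadings.shape[1])])
    flip[flip == 0] = 1.0
    loadings = loadings * flip
    scores = scores * flip

    total_var = (Xc**2).sum()
    evr = (s**2) / total_var if total_var > 0 else np.zeros_like(s)

    corrected = False
    if batch_correct:
        if sample_ids is None:
            raise ValueError("batch_correct requires sample_ids")
        sample_ids = np.asarray(sample_ids)
        for sid in np.unique(sample_ids):
            mask = sample_ids == sid
            scores[mask] -= scores[mask].mean(axis=0)
        corrected = True

    return PCAResult(
        scores=scores,
        loadings=loadings,
        explained_variance_ratio=evr,
        genes=list(genes) if genes is not None else [f"g{i}" for i in range(g)],
        centering=mean,
        batch_corrected=corrected,
        metadata={"batch_correction": "per-sample score centering" if corrected else "none"},
    )


def fit_t_ellipse(
    points: np.ndarray, level: float = 0.95, df: float = 4.0, tol: float = 1e-10,
    max_iter: int = 500,
) -> EllipseFit:
    """Fit a bivariate t (fixed df) by EM and return its ``level`` ellipse.

    Location/scatter are the maximum-likelihood estimates for a t with
    fixed degrees of freedom, via the standard iteratively-reweighted EM
    (weights (df+2)/(df+delta_i) with delta the squared Mahalanobis
    distance). The heavy-tailed df=4 default keeps the ellipse robust to
    the outlying cells typical of sparse expression embeddings.
    """
    X = np.asarray(points, dtype=float)
    if X.ndim != 2 or X.shape[1] != 2:
        raise ValueError("points must be n x 2")
    n = X.shape[0]
    if n < 3:
        raise ValueError("need at least 3 points")
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")

    mu = X.mean(axis=0)
    Sigma = np.cov(X, rowvar=False)
    if np.linalg.matrix_rank(Sigma) < 2:
        raise ValueError("points are collinear; scatter is singular")
    for _ in range(max_iter):
        diff = X - mu
        delta = np.einsum("ij,ji->i", diff, np.linalg.solve(Sigma, diff.T))
        w = (df + 2) / (df + delta)
        mu_new = (w[:, None] * X).sum(axis=0) / w.sum()
        diff = X - mu_new
        Sigma_new = (w[:, None] * diff).T @ diff / n
        shift = np.abs(mu_new - mu).max() + np.abs(Sigma_new - Sigma).max()
        mu, Sigma = mu_new, Sigma_new
        if shift < tol:
            break
    if np.linalg.matrix_rank(Sigma) < 2:
        raise ValueError("degenerate scatter after fitting")

    r2 = 2.0 * stats.f.ppf(level, 2, df)
    return EllipseFit(center=mu, scatter=Sigma, df=df, level=level, boundary_r2=r2)
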