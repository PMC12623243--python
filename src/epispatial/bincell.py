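"""Bin-to-cell reconstruction from 2 µm spatial bins.

Nuclear labels are expanded by nearest-seed assignment up to a distance cap,
bin counts are aggregated per label into a cell x gene matrix, and cells are
QC-filtered on genes/UMIs. This reproduces, on synthetic inputs, the
segmentation-and-aggregation step used to recover single-cell profiles from
high-definition spatial sequencing.
"""

from __future__ import annotations

import logging

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp

from .synthio import BinGrid

logger = logging.getLogger(__name__)

__all__ = ["expand_labels", "aggregate_bins", "qc_filter", "qc_report"]


def expand_labels(label_image: np.ndarray, d_max: float) -> np.ndarray:
    """Expand nuclear labels to unlabeled bins within Euclidean ``d_max``.

    Every unlabeled bin within distance ``d_max`` of some seed bin receives
    the label of the nearest seed bin; exact distance ties go to the
    smaller label id; already-labeled bins never change. Distances are
    Euclidean between bin centers.
    """
    if d_max < 0:
        raise ValueError("d_max must be non-negative")
    label_image = np.asarray(label_image)
    out = label_image.copy()
    if d_max == 0 or not (label_image > 0).any():
        return out

    seed_r, seed_c = np.nonzero(label_image > 0)
    seed_lab = label_image[seed_r, seed_c]
    # sort seeds by label so that the first minimum found is the smallest id
    order = np.argsort(seed_lab, kind="stable")
    seed_r, seed_c, seed_lab = seed_r[order], seed_c[order], seed_lab[order]

    tgt_r, tgt_c = np.nonzero(label_image == 0)
    if len(tgt_r) == 0:
        return out
    d2_max = float(d_max) ** 2

    # chunked brute force: exact integer distances, deterministic tie-break
    chunk = max(1, int(2e7 // max(1, len(seed_r))))
    for start in range(0, len(tgt_r), chunk):
        tr = tgt_r[start : start + chunk].astype(np.int64)
        tc = tgt_c[start : start + chunk].astype(np.int64)
        d2 = (tr[:, None] - seed_r[None, :]) ** 2 + (tc[:, None] - seed_c[None, :]) ** 2
        best = np.argmin(d2, axis=1)  # first occurrence -> smallest label
        best_d2 = d2[np.arange(len(tr)), best]
        ok = best_d2 <= d2_max
        out[tr[ok], tc[ok]] = seed_lab[best[ok]]
    return out


def aggregate_bins(grid: BinGrid, labels: np.ndarray) -> ad.AnnData:
    """Sum bin counts per cell label into a cell x gene AnnData.

    Centroids are the unweighted mean of each label's bin coordinates in
    the label image; bins with label 0 are discarded. Returns an AnnData
    with obs columns ``row``/``col`` (centroid), ``n_genes``, ``n_umis``.
    """
    labels = np.asarray(labels)
    if labels.shape != grid.grid_shape:
        raise ValueError("label grid shape does not match the bin grid")
    bin_labels = labels[grid.coords[:, 0], grid.coords[:, 1]]
    cell_ids = np.unique(labels[labels > 0])
    if len(cell_ids) == 0:
        logger.warning("no labeled bins; returning empty cell matrix")
        return ad.AnnData(
            X=sp.csr_matrix((0, len(grid.gene_ids))),
            obs=pd.DataFrame({"row": [], "col": [], "n_genes": [], "n_umis": []}),
            var=pd.DataFrame(index=grid.gene_ids),
        )

    pos = {cid: i for i, cid in enumerate(cell_ids)}
    keep = bin_labels > 0
    rows = np.array([pos[l] for l in bin_labels[keep]], dtype=np.int64)
    indicator = sp.coo_matrix(
        (np.ones(keep.sum()), (rows, np.nonzero(keep)[0])),
        shape=(len(cell_ids), grid.counts.shape[0]),
    ).tocsr()
    X = sp.csr_matrix(indicator @ grid.counts)

    lab_r, lab_c = np.nonzero(labels > 0)
    lab_ids = labels[lab_r, lab_c]
    cent = pd.DataFrame({"lab": lab_ids, "row": lab_r, "col": lab_c}) \
        .groupby("lab", sort=True).mean()
    obs = pd.DataFrame({
        "row": cent["row"].to_numpy(),
        "col": cent["col"].to_numpy(),
        "n_genes": np.asarray((X > 0).sum(axis=1)).ravel(),
        "n_umis": np.asarray(X.sum(axis=1)).ravel(),
    }, index=[f"cell_{cid}" for cid in cell_ids])
    obs["label_id"] = cell_ids
    adata = ad.AnnData(X=X, obs=obs)
    adata.var_names = list(grid.gene_ids)
    return adata


def qc_filter(
    cells: ad.AnnData,
    min_genes: int = 20,
    min_umis: float = 50,
    max_umis: float = np.inf,
) -> ad.AnnData:
    """Retain cells with ``n_genes >= min_genes`` and UMIs in [min, max].

    Thresholds default to a permissive floor suitable for shallow segmented
    HD data (per-cell means of a few hundred UMIs). Order is preserved; a
    summary of the filter is logged.
    """
    if min(min_genes, min_umis) < 0:
        raise ValueError("thresholds must be non-negative")
    if min_umis > max_umis:
        raise ValueError("min_umis exceeds max_umis")
    n_genes = cells.obs["n_genes"].to_numpy()
    n_umis = cells.obs["n_umis"].to_numpy()
    keep = (n_genes >= min_genes) & (n_umis >= min_umis) & (n_umis <= max_umis)
    if not keep.any():
        logger.warning("QC filter removed all %d cells", cells.n_obs)
    logger.info("QC filter retained %d / %d cells", int(keep.sum()), cells.n_obs)
    return cells[keep].copy()


def qc_report(cells: ad.AnnData, sample_col: str = "sample_id") -> pd.DataFrame:
    """Per-sample median genes/UMIs, for analyst-driven sample exclusion.

    A sample whose medians fall far below its peers (insufficient
    sequencing) is dropped by configuration, not automatically.
    """
    obs = cells.obs.copy()
    if sample_col not in obs:
        obs[sample_col] = "all"
    rep = obs.groupby(sample_col, observed=True).agg(
        n_cells=("n_umis", "size"),
        median_genes=("n_genes", "median"),
        median_umis=("n_umis", "median"),
    )
    return rep.reset_index()
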