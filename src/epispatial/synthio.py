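"""Synthetic spatial and single-cell transcriptomics with known ground truth.

Emulates the data layout of a high-definition (2 µm bin) spatial run on a
skin tumor with epidermotropic Merkel cell carcinoma (MCC), plus a matching
dissociated scRNA-seq experiment:

* a tissue plan with an epidermis band (basal + suprabasal keratinocytes and
  intraepidermal ``epiMCC`` nests), a dermal tumor nodule (``cMCC``), a
  perivascular disk inside the nodule (``vasMCC``), a hair-follicle strip and
  dermal background;
* per-cell UMI counts drawn gene-wise from a negative binomial whose mean is
  the cell's library size times a type-specific gene proportion, then split
  multinomially over the cell's bin footprint — so bin-level counts sum back
  to the cell-level draw exactly;
* near-zero ambient background counts on every bin to exercise QC;
* marker programs (MCC core, keratinocyte, epidermal/cSCC-like, EMT) planted
  as log-fold effects so downstream gating, PCA ordering and scoring can be
  validated against the planted truth.

Coordinates are 0-based ``(row, col)`` bin indices; polygon vertices are in
bin units as ``(x, y) = (col, row)``. Fixed seeds give byte-identical output.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp
from shapely.geometry import Point, Polygon, box

from . import io as eio

__all__ = [
    "SimConfig",
    "GroundTruth",
    "BinGrid",
    "SizingError",
    "CELL_TYPES",
    "MARKER_PROGRAMS",
    "generate_spatial_truth",
    "generate_bin_counts",
    "generate_scrnaseq",
    "default_gene_sets",
    "default_regulons",
    "write_simulation",
]


class SizingError(ValueError):
    """Grid too small to place the requested cells."""


CELL_TYPES = ("epiMCC", "cMCC", "vasMCC", "bK", "sbK", "other")

# Marker programs planted in the simulation. The gene names follow the real
# biology they emulate: CCER2/SOX2/HES6/ATOH1/CHGA for the MCC lineage,
# KRT20 as the classical MCC cytokeratin, KRT5/KRT1/KRT10/CSTA for
# keratinocytes, an epidermal differentiation / cSCC-like program, and an
# EMT-like collagen program for perivascular tumor cells.
MARKER_PROGRAMS: dict[str, list[str]] = {
    "mcc_core": ["CCER2", "SOX2", "HES6", "ATOH1", "CHGA"],
    "mcc_keratin": ["KRT20"],
    "keratinocyte": ["KRT5", "KRT1", "KRT10", "CSTA"],
    "epidermal_cscc": [
        "SFN", "S100A2", "S100A8", "S100A9", "S100A16",
        "CALML3", "CALML5", "FABP5", "SPRR1B", "KRT6A", "KRT6B", "PERP",
    ],
    "emt": ["COL1A1", "COL3A1", "VIM"],
}

MARKER_GENES: list[str] = sorted({g for p in MARKER_PROGRAMS.values() for g in p})

# Per-type program template: +1 defining program, +0.5 secondary program,
# -3 actively silenced (scaled by SimConfig.marker_effect). Silencing is
# finite so that a zero marker effect makes all types exchangeable.
_DEFINING, _SECONDARY, _OFF = 1.0, 0.5, -3.0
_TYPE_PROGRAM_TEMPLATE: dict[str, dict[str, float]] = {
    "epiMCC": {"mcc_core": _DEFINING, "epidermal_cscc": _DEFINING,
               "keratinocyte:KRT5": _DEFINING, "mcc_keratin": _SECONDARY,
               "emt": _OFF},
    "cMCC": {"mcc_core": _DEFINING, "mcc_keratin": _DEFINING,
             "keratinocyte": _OFF, "epidermal_cscc": _OFF, "emt": _OFF},
    "vasMCC": {"mcc_core": _DEFINING, "mcc_keratin": _DEFINING,
               "emt": _DEFINING, "keratinocyte": _OFF, "epidermal_cscc": _OFF},
    "bK": {"keratinocyte:KRT5": _DEFINING, "keratinocyte:KRT1": _SECONDARY,
           "keratinocyte:KRT10": _SECONDARY, "keratinocyte:CSTA": _SECONDARY,
           "epidermal_cscc": _SECONDARY, "mcc_core": _OFF, "mcc_keratin": _OFF,
           "emt": _OFF},
    "sbK": {"keratinocyte": _DEFINING, "epidermal_cscc": _DEFINING,
            "mcc_core": _OFF, "mcc_keratin": _OFF, "emt": _OFF},
    "other": {"emt": _SECONDARY, "mcc_core": _OFF, "mcc_keratin": _OFF},
}


@dataclass
class SimConfig:
    """Parameters of the synthetic tissue and count model.

    ``grid_shape`` is (rows, cols) in 2 µm bins; ``cell_radius_range`` the
    inclusive range of cell footprint radii in bins; ``mean_umis`` the
    per-type mean library size for the spatial arm (defaults span the
    shallow 150-650 UMI/cell regime of segmented HD data) and
    ``scrna_mean_umis`` the deeper dissociated-cell depth; ``dispersion``
    the shared negative-binomial size parameter; ``marker_effect`` the
    log-fold scale of the planted programs; ``ambient_lambda`` the Poisson
    rate of ambient background per bin per gene.
    """

    grid_shape: tuple[int, int] = (200, 300)
    bin_pitch_um: float = 2.0
    cell_radius_range: tuple[int, int] = (2, 3)
    nucleus_radius: int = 1
    n_genes: int = 300
    cells_per_type: dict[str, int] = field(default_factory=lambda: {
        "epiMCC": 40, "cMCC": 60, "vasMCC": 25, "bK": 25, "sbK": 25,
        "other": 40,
    })
    mean_umis: dict[str, float] = field(default_factory=lambda: {
        "epiMCC": 400.0, "cMCC": 450.0, "vasMCC": 450.0, "bK": 300.0,
        "sbK": 300.0, "other": 250.0,
    })
    dispersion: float = 2.0
    marker_effect: float = 3.0
    ambient_lambda: float = 0.001
    dropout_rate: float = 0.0
    scrna_cells_per_type: dict[str, int] = field(default_factory=lambda: {
        "epiMCC": 300, "cMCC": 1000, "vasMCC": 500, "bK": 400, "sbK": 300,
        "other": 500,
    })
    scrna_mean_umis: float = 2000.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.grid_shape = tuple(self.grid_shape)
        self.cell_radius_range = tuple(self.cell_radius_range)
        if self.bin_pitch_um != 2.0:
            raise ValueError("bin pitch is fixed at 2 µm")
        if self.n_genes < len(MARKER_GENES):
            raise ValueError(
                f"n_genes must be >= {len(MARKER_GENES)} to hold all markers"
            )
        r0, r1 = self.cell_radius_range
        if not (0 < r0 <= r1):
            raise ValueError("cell_radius_range must be positive and ordered")
        for d in (self.cells_per_type, self.mean_umis, self.scrna_cells_per_type):
            bad = set(d) - set(CELL_TYPES)
            if bad:
                raise ValueError(f"unknown cell types: {sorted(bad)}")
        if any(v < 0 for v in self.cells_per_type.values()):
            raise ValueError("cell counts must be non-negative")
        if min(self.mean_umis.values()) <= 0 or self.scrna_mean_umis <= 0:
            raise ValueError("mean UMIs must be positive")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")
        if not 0 <= self.dropout_rate < 1:
            raise ValueError("dropout_rate must be in [0, 1)")

    # -- gene universe -----------------------------------------------------
    def gene_ids(self) -> list[str]:
        n_fill = self.n_genes - len(MARKER_GENES)
        fillers = [f"GENE{i:04d}" for i in range(1, n_fill + 1)]
        return MARKER_GENES + fillers

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(dataclasses.asdict(self), indent=1))
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "SimConfig":
        raw = json.loads(Path(path).read_text())
        for key in ("grid_shape", "cell_radius_range"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


@dataclass
class GroundTruth:
    """Planted truth emitted by the generator.

    ``cells`` carries one row per cell (cell_id, cell_type, row, col,
    radius); ``program_effects`` the gene x type log-fold effect matrix;
    ``dropout_mask`` flags entries zeroed technically after a positive
    draw; ``cell_counts`` the pre-split cell x gene draws (set by
    :func:`generate_bin_counts` / :func:`generate_scrnaseq`).
    """

    cells: pd.DataFrame
    program_effects: pd.DataFrame
    seed: int
    dropout_mask: sp.spmatrix | None = None
    cell_counts: sp.spmatrix | None = None


@dataclass
class BinGrid:
    """Sparse gene counts on occupied 2 µm bins."""

    coords: np.ndarray          # (n_bins, 2) int (row, col), unique
    counts: sp.csr_matrix       # n_bins x n_genes, non-negative ints
    gene_ids: list[str]
    grid_shape: tuple[int, int]


# --------------------------------------------------------------- expression

def build_program_effects(config: SimConfig) -> pd.DataFrame:
    """Gene x type log-fold effect matrix from the program templates."""
    genes = config.gene_ids()
    eff = pd.DataFrame(0.0, index=genes, columns=list(CELL_TYPES))
    for ctype, progs in _TYPE_PROGRAM_TEMPLATE.items():
        for prog, scale in progs.items():
            if ":" in prog:  # single gene of a program, e.g. keratinocyte:KRT5
                prog_name, gene = prog.split(":")
                members = [gene]
            else:
                members = MARKER_PROGRAMS[prog]
            for g in members:
                eff.loc[g, ctype] = scale * config.marker_effect
    return eff


def _type_proportions(config: SimConfig) -> pd.DataFrame:
    """Per-type gene proportion matrix (columns sum to 1)."""
    rng = np.random.default_rng([config.seed, 17])
    genes = config.gene_ids()
    base = np.ones(len(genes))
    n_marker = len(MARKER_GENES)
    # heterogeneous baseline abundances for filler genes
    base[n_marker:] = rng.lognormal(mean=0.0, sigma=1.0, size=len(genes) - n_marker)
    eff = build_program_effects(config)
    weights = base[:, None] * np.exp(eff.to_numpy())
    props = weights / weights.sum(axis=0, keepdims=True)
    return pd.DataFrame(props, index=genes, columns=eff.columns)


def _draw_cell_counts(
    types: np.ndarray,
    mean_umis: np.ndarray,
    props: pd.DataFrame,
    config: SimConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Dense cell x gene negative-binomial draws (mean = library * proportion)."""
    theta = config.dispersion
    p_mat = props.to_numpy().T  # type x gene
    type_idx = pd.Categorical(types, categories=props.columns).codes
    mu = mean_umis[:, None] * p_mat[type_idx]
    # NB with mean mu and size theta: p = theta / (theta + mu)
    with np.errstate(divide="ignore"):
        p = theta / (theta + mu)
    counts = rng.negative_binomial(theta, p)
    counts[mu == 0] = 0
    return counts


def _apply_dropout(
    counts: np.ndarray, rate: float, rng: np.random.Generator
) -> sp.csr_matrix:
    """Zero positive entries with probability ``rate``; returns the mask."""
    if rate <= 0:
        return sp.csr_matrix(counts.shape, dtype=bool)
    pos = counts > 0
    drop = pos & (rng.random(counts.shape) < rate)
    counts[drop] = 0
    return sp.csr_matrix(drop)


# ------------------------------------------------------------------- layout

def _disk_offsets(radius: int) -> np.ndarray:
    rr, cc = np.mgrid[-radius : radius + 1, -radius : radius + 1]
    keep = rr**2 + cc**2 <= radius**2
    return np.stack([rr[keep], cc[keep]], axis=1)


@dataclass
class _TissuePlan:
    epidermis_rows: tuple[int, int]       # [0, end)
    basal_rows: tuple[int, int]           # bottom band of the epidermis
    tumor_center: tuple[int, int]
    tumor_radius: int
    vessel_center: tuple[int, int]
    vessel_radius: int
    follicle_cols: tuple[int, int]
    follicle_rows: tuple[int, int]


def _plan(config: SimConfig) -> _TissuePlan:
    rows, cols = config.grid_shape
    e_end = max(12, rows // 6)
    tumor_r = min(rows, cols) // 3
    t_center = (e_end + (rows - e_end) // 2, cols // 2 - cols // 10)
    vessel_r = max(4, tumor_r // 2)
    v_center = (t_center[0], t_center[1] + (tumor_r - vessel_r) // 2)
    f0 = min(cols - 8, cols * 4 // 5)
    return _TissuePlan(
        epidermis_rows=(0, e_end),
        basal_rows=(max(0, e_end - e_end // 3), e_end),
        tumor_center=t_center,
        tumor_radius=tumor_r,
        vessel_center=v_center,
        vessel_radius=vessel_r,
        follicle_cols=(f0, min(cols, f0 + 14)),
        follicle_rows=(e_end, min(rows, e_end + rows // 2)),
    )


def _region_polygons(plan: _TissuePlan, grid_shape: tuple[int, int]) -> list[tuple[str, Polygon, str]]:
    """Region annotations in (x, y) = (col, row) coordinates."""
    rows, cols = grid_shape
    e0, e1 = plan.epidermis_rows
    regions = [
        ("epidermis", box(0, e0, cols - 1, e1 - 0.5), "reg_epidermis"),
        ("tumor_core",
         Point(plan.tumor_center[1], plan.tumor_center[0]).buffer(
             plan.tumor_radius + 0.5, quad_segs=32),
         "reg_tumor"),
        ("perivascular",
         Point(plan.vessel_center[1], plan.vessel_center[0]).buffer(
             plan.vessel_radius + 0.5, quad_segs=32),
         "reg_vessel"),
        ("follicle",
         box(plan.follicle_cols[0], plan.follicle_rows[0],
             plan.follicle_cols[1] - 1, plan.follicle_rows[1] - 1),
         "reg_follicle"),
        ("background", box(0, 0, cols - 1, rows - 1), "reg_background"),
    ]
    return regions


def _lattice_sites(
    mask: np.ndarray, spacing: int, rng: np.random.Generator
) -> list[tuple[int, int]]:
    """Jittered lattice positions where ``mask`` is True, shuffled.

    The lattice is anchored to the mask's bounding box so that narrow
    bands (e.g. the basal monolayer) still receive a full row of sites.
    """
    rows, cols = mask.shape
    if not mask.any():
        return []
    rr, cc = np.nonzero(mask)
    r0, r1, c0, c1 = rr.min(), rr.max(), cc.min(), cc.max()
    sites = []
    for r in range(int(r0), int(r1) + 1, spacing):
        for c in range(int(c0), int(c1) + 1, spacing):
            jr = int(np.clip(r + rng.integers(-1, 2), 0, rows - 1))
            jc = int(np.clip(c + rng.integers(-1, 2), 0, cols - 1))
            if mask[jr, jc]:
                sites.append((jr, jc))
    rng.shuffle(sites)
    return sites


def generate_spatial_truth(
    config: SimConfig,
) -> tuple[np.ndarray, list[tuple[str, Polygon, str]], GroundTruth]:
    """Lay out the tissue: nuclear-seed label image, regions and cell truth.

    Cells are placed on a jittered lattice within their home region so that
    footprints of distinct cells never overlap; each cell's nuclear seed (a
    disk of ``nucleus_radius``) is painted into the label image with the
    cell's 1-based integer id.
    """
    rng = np.random.default_rng([config.seed, 29])
    rows, cols = config.grid_shape
    plan = _plan(config)
    r_max = config.cell_radius_range[1]
    spacing = 2 * r_max + 3

    rr, cc = np.mgrid[0:rows, 0:cols]
    d_tumor = (rr - plan.tumor_center[0]) ** 2 + (cc - plan.tumor_center[1]) ** 2
    d_vessel = (rr - plan.vessel_center[0]) ** 2 + (cc - plan.vessel_center[1]) ** 2
    e0, e1 = plan.epidermis_rows
    b0, b1 = plan.basal_rows
    in_follicle = (
        (cc >= plan.follicle_cols[0]) & (cc < plan.follicle_cols[1])
        & (rr >= plan.follicle_rows[0]) & (rr < plan.follicle_rows[1])
    )
    margin = r_max + 1
    masks = {
        "epidermis": (rr >= e0) & (rr < e1),
        "basal": (rr >= b0) & (rr < b1),
        # keep a 2*r_max gap below the suprabasal band so basal and
        # suprabasal footprints cannot overlap
        "suprabasal": (rr >= e0) & (rr < b0 - 2 * r_max),
        "tumor": (d_tumor <= (plan.tumor_radius - margin) ** 2)
                 & (d_vessel > (plan.vessel_radius + margin) ** 2),
        "vessel": d_vessel <= (plan.vessel_radius - margin) ** 2,
        "dermis_bg": (rr >= e1 + margin)
                     & (d_tumor > (plan.tumor_radius + margin) ** 2)
                     & ~in_follicle,
    }
    # keep footprints inside the grid
    inner = (rr >= margin) & (rr < rows - margin) & (cc >= margin) & (cc < cols - margin)
    edge_ok = (rr >= 0) & (cc >= margin) & (cc < cols - margin) & (rr < rows - margin)
    for k in masks:
        masks[k] &= edge_ok if k in ("epidermis", "basal", "suprabasal") else inner

    # allocate lattice sites region by region
    basal_sites = _lattice_sites(masks["basal"], spacing, rng)
    supra_sites = _lattice_sites(masks["suprabasal"], spacing, rng)
    tumor_sites = _lattice_sites(masks["tumor"], spacing, rng)
    vessel_sites = _lattice_sites(masks["vessel"], spacing, rng)
    bg_sites = _lattice_sites(masks["dermis_bg"], spacing, rng)

    want = {t: config.cells_per_type.get(t, 0) for t in CELL_TYPES}
    placements: list[tuple[str, int, int]] = []

    def take(sites: list[tuple[int, int]], n: int, ctype: str) -> None:
        if len(sites) < n:
            raise SizingError(
                f"grid too small: need {n} sites for {ctype}, have {len(sites)}"
            )
        for _ in range(n):
            r, c = sites.pop()
            placements.append((ctype, r, c))

    take(basal_sites, want["bK"], "bK")
    take(supra_sites, want["sbK"], "sbK")
    epi_pool = basal_sites + supra_sites
    rng.shuffle(epi_pool)
    take(epi_pool, want["epiMCC"], "epiMCC")
    take(tumor_sites, want["cMCC"], "cMCC")
    take(vessel_sites, want["vasMCC"], "vasMCC")
    take(bg_sites, want["other"], "other")

    n_cells = len(placements)
    radii = rng.integers(
        config.cell_radius_range[0], config.cell_radius_range[1] + 1, size=n_cells
    ) if n_cells else np.zeros(0, dtype=int)
    cells = pd.DataFrame(
        placements, columns=["cell_type", "row", "col"]
    )
    cells.insert(0, "cell_id", np.arange(1, n_cells + 1))
    cells["radius"] = radii

    label_image = np.zeros((rows, cols), dtype=np.int32)
    nuc = _disk_offsets(config.nucleus_radius)
    for cid, r, c in zip(cells["cell_id"], cells["row"], cells["col"]):
        pts = nuc + (r, c)
        ok = (pts[:, 0] >= 0) & (pts[:, 0] < rows) & (pts[:, 1] >= 0) & (pts[:, 1] < cols)
        label_image[pts[ok, 0], pts[ok, 1]] = cid

    truth = GroundTruth(
        cells=cells, program_effects=build_program_effects(config), seed=config.seed
    )
    return label_image, _region_polygons(plan, config.grid_shape), truth


# ------------------------------------------------------------------- counts

def generate_bin_counts(
    label_image: np.ndarray, truth: GroundTruth, config: SimConfig
) -> BinGrid:
    """Draw cell-level counts and split them multinomially over bin footprints.

    Each cell's gene counts are negative binomial (mean = per-type library
    size x type-specific gene proportion, shared dispersion); every UMI is
    then assigned uniformly at random to one bin of the cell's disk
    footprint, so bin sums reproduce the cell draw exactly. Ambient
    background adds Poisson(``ambient_lambda``) per bin per gene. The
    pre-split draws are stored on ``truth.cell_counts``.
    """
    rng = np.random.default_rng([config.seed, 43])
    rows, cols = label_image.shape
    genes = config.gene_ids()
    n_genes = len(genes)
    cells = truth.cells
    props = _type_proportions(config)

    mean_umis = cells["cell_type"].map(config.mean_umis).to_numpy(dtype=float)
    counts = _draw_cell_counts(
        cells["cell_type"].to_numpy(), mean_umis, props, config, rng
    ) if len(cells) else np.zeros((0, n_genes), dtype=int)
    truth.dropout_mask = _apply_dropout(counts, config.dropout_rate, rng)
    truth.cell_counts = sp.csr_matrix(counts)

    bin_rows: list[np.ndarray] = []
    bin_cols: list[np.ndarray] = []
    gene_idx: list[np.ndarray] = []
    for i in range(len(cells)):
        r0, c0, rad = cells["row"].iat[i], cells["col"].iat[i], cells["radius"].iat[i]
        foot = _disk_offsets(int(rad)) + (r0, c0)
        ok = (
            (foot[:, 0] >= 0) & (foot[:, 0] < rows)
            & (foot[:, 1] >= 0) & (foot[:, 1] < cols)
        )
        foot = foot[ok]
        gvec = counts[i]
        total = int(gvec.sum())
        if total == 0 or len(foot) == 0:
            continue
        per_umi_gene = np.repeat(np.arange(n_genes), gvec)
        per_umi_bin = rng.integers(0, len(foot), size=total)
        bin_rows.append(foot[per_umi_bin, 0])
        bin_cols.append(foot[per_umi_bin, 1])
        gene_idx.append(per_umi_gene)

    # ambient background over the whole grid
    n_ambient = rng.poisson(config.ambient_lambda * rows * cols * n_genes)
    if n_ambient:
        amb_flat = rng.integers(0, rows * cols, size=n_ambient)
        bin_rows.append(amb_flat // cols)
        bin_cols.append(amb_flat % cols)
        gene_idx.append(rng.integers(0, n_genes, size=n_ambient))

    if bin_rows:
        all_r = np.concatenate(bin_rows)
        all_c = np.concatenate(bin_cols)
        all_g = np.concatenate(gene_idx)
        flat = all_r.astype(np.int64) * cols + all_c
        occupied, inverse = np.unique(flat, return_inverse=True)
        mat = sp.coo_matrix(
            (np.ones(len(all_g), dtype=np.int64), (inverse, all_g)),
            shape=(len(occupied), n_genes),
        ).tocsr()
        coords = np.stack([occupied // cols, occupied % cols], axis=1)
    else:
        mat = sp.csr_matrix((0, n_genes), dtype=np.int64)
        coords = np.zeros((0, 2), dtype=np.int64)

    return BinGrid(coords=coords, counts=mat, gene_ids=genes,
                   grid_shape=(rows, cols))


def generate_scrnaseq(config: SimConfig) -> tuple[ad.AnnData, GroundTruth]:
    """Simulate the dissociated scRNA-seq validation arm.

    Planted expression follows the same program templates as the spatial
    arm but at scRNA-seq depth, so the boolean gating rules (CCER2/KRT5/
    CALML3-5 for epiMCC; CCER2/KRT20 without collagens or KRT5 for cMCC;
    CCER2/KRT20 with collagens for vasMCC) recover the planted labels.
    """
    rng = np.random.default_rng([config.seed, 57])
    genes = config.gene_ids()
    props = _type_proportions(config)
    types = np.concatenate([
        np.repeat(t, config.scrna_cells_per_type.get(t, 0)) for t in CELL_TYPES
    ]) if any(config.scrna_cells_per_type.values()) else np.array([], dtype=str)
    n = len(types)
    mean_umis = np.full(n, config.scrna_mean_umis)
    counts = _draw_cell_counts(types, mean_umis, props, config, rng) \
        if n else np.zeros((0, len(genes)), dtype=int)
    dropout = _apply_dropout(counts, config.dropout_rate, rng)

    X = sp.csr_matrix(counts)
    obs = pd.DataFrame({
        "sample_id": "sc1",
        "true_type": pd.Categorical(types, categories=list(CELL_TYPES)),
        "n_umis": np.asarray(X.sum(axis=1)).ravel().astype(int),
        "n_genes": (X > 0).sum(axis=1).A.ravel() if n else np.zeros(0, dtype=int),
    }, index=[f"sc_cell_{i}" for i in range(n)])
    adata = ad.AnnData(X=X, obs=obs)
    adata.var_names = genes
    cells = pd.DataFrame({
        "cell_id": np.arange(1, n + 1), "cell_type": types,
        "row": -1, "col": -1, "radius": 0,
    })
    truth = GroundTruth(
        cells=cells, program_effects=build_program_effects(config),
        seed=config.seed, dropout_mask=dropout, cell_counts=sp.csr_matrix(counts),
    )
    return adata, truth


# -------------------------------------------------------- gene-set fixtures

def default_gene_sets() -> dict[str, list[str]]:
    """Synthetic marker/metaprogram gene sets matching the planted programs.

    ``cSCC_markers`` mirrors a cutaneous SCC marker panel, ``MP12_EMT`` an
    EMT-flavored tumor metaprogram, ``MP_epithelial`` an epithelial
    differentiation program; these are synthetic stand-ins keyed to the
    generator's planted effects, not published gene lists.
    """
    return {
        "cSCC_markers": list(MARKER_PROGRAMS["epidermal_cscc"]),
        "MP12_EMT": list(MARKER_PROGRAMS["emt"]),
        "MP_epithelial": ["SFN", "SPRR1B", "PERP", "CALML3", "CALML5", "FABP5"],
        "MCC_core": list(MARKER_PROGRAMS["mcc_core"]),
    }


def default_regulons() -> dict[str, list[str]]:
    """Synthetic TF regulons (name = TF, members = positive targets)."""
    return {
        "TP63": ["PERP", "SFN", "SPRR1B", "KRT6A", "KRT6B", "S100A2"],
        "SNAI2": ["COL1A1", "COL3A1", "VIM"],
        "ATOH1": ["CCER2", "SOX2", "HES6", "CHGA"],
    }


# ----------------------------------------------------------------- bundling

def write_simulation(config: SimConfig, outdir: str | Path) -> Path:
    """Write a full fixture bundle: bins, labels, regions, truth, gene sets."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    label_image, regions, truth = generate_spatial_truth(config)
    grid = generate_bin_counts(label_image, truth, config)

    import scipy.io as sio
    bdir = outdir / "bins"
    bdir.mkdir(exist_ok=True)
    sio.mmwrite(str(bdir / "matrix.mtx"), grid.counts.T.tocoo())
    pd.Series(grid.gene_ids).to_csv(bdir / "features.tsv", sep="\t",
                                    index=False, header=False)
    pd.DataFrame(grid.coords, columns=["row", "col"]).to_csv(
        bdir / "bin_coords.tsv", sep="\t", index=False)
    eio.write_pgm(label_image, outdir / "labels.pgm")
    eio.write_regions_geojson(regions, outdir / "regions.geojson")
    truth.cells.to_csv(outdir / "truth_cells.tsv", sep="\t", index=False)
    eio.write_gmt({**default_gene_sets(), **default_regulons()},
                  outdir / "gene_sets.gmt")
    config.to_json(outdir / "config.json")

    sc_adata, sc_truth = generate_scrnaseq(config)
    eio.write_cell_matrix(sc_adata, outdir / "scrnaseq")
    sc_truth.cells.to_csv(outdir / "truth_scrnaseq.tsv", sep="\t", index=False)
    return outdir


def read_bin_grid(indir: str | Path, grid_shape: tuple[int, int] | None = None) -> BinGrid:
    """Read a bin bundle written by :func:`write_simulation`."""
    import scipy.io as sio
    indir = Path(indir)
    counts = sp.csr_matrix(sio.mmread(str(indir / "matrix.mtx")).T)
    genes = pd.read_csv(indir / "features.tsv", sep="\t", header=None)[0].tolist()
    coords = pd.read_csv(indir / "bin_coords.tsv", sep="\t").to_numpy()
    if grid_shape is None:
        grid_shape = (int(coords[:, 0].max()) + 1, int(coords[:, 1].max()) + 1)
    return BinGrid(coords=coords, counts=counts, gene_ids=genes,
                   grid_shape=grid_shape)
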