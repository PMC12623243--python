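"""End-to-end orchestration: simulate → segment → annotate → PCA → enrich →
impute → score → gate → DGE → report.

Every stage consumes the previous stage's in-memory objects, uses a seed
derived deterministically from the global seed, and contributes a
JSON-serializable block to the run report, so two runs with the same
config produce identical reports.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import annotate, bincell, dimred, enrich, gate, impute, score, synthio, viz

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """Stage parameters and toggles for a full synthetic run."""

    seed: int = 0
    outdir: str | None = None
    sim: dict = field(default_factory=dict)      # SimConfig overrides
    d_max: float = 4.0
    min_genes: int = 20
    min_umis: float = 50.0
    max_umis: float = float("inf")
    exclude_pattern: str = "^KRT"
    n_components: int = 20
    batch_correct: bool = True
    ellipse_level: float = 0.95
    ellipse_df: float = 4.0
    top_fraction: float = 0.05
    alpha: float = 0.05
    stages: list[str] = field(default_factory=lambda: [
        "simulate", "segment", "annotate", "pca", "enrich", "impute",
        "score", "gate", "dge",
    ])
    make_figures: bool = False

    def to_json(self, path: str | Path) -> Path:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=1))
        return Path(path)

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        return cls(**json.loads(Path(path).read_text()))


class StageError(RuntimeError):
    """Failure inside one pipeline stage, tagged with the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def _stage_seed(seed: int, stage: str) -> int:
    # stable per-stage child seed below 2^31 (crc32 is process-independent)
    import zlib

    return int(np.random.SeedSequence([seed, zlib.crc32(stage.encode())])
               .generate_state(1)[0] % (2**31))


def _selection_classes(cells, regions) -> np.ndarray:
    """Histomorphological-selection surrogate: region + CCER2 status.

    CCER2-positive cells in the epidermis are epiMCC, in the perivascular
    disk vasMCC and in the tumor core cMCC; CCER2-negative epidermal
    cells are keratinocytes; everything else is unselected.
    """
    region = annotate.assign_regions(cells, regions)
    ccer2 = np.asarray(cells[:, "CCER2"].X.todense()).ravel()
    out = np.full(cells.n_obs, "unselected", dtype=object)
    tumor = ccer2 > 0
    out[(region == "epidermis") & tumor] = "epiMCC"
    out[(region == "perivascular") & tumor] = "vasMCC"
    out[(region == "tumor_core") & tumor] = "cMCC"
    out[(region == "epidermis") & ~tumor] = "keratinocyte"
    return out


def run_pipeline(config: RunConfig) -> dict:
    """Execute the enabled stages in dependency order; return the report."""
    report: dict = {"seed": config.seed, "stages": list(config.stages)}
    enabled = set(config.stages)
    outdir = Path(config.outdir) if config.outdir else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)

    state: dict = {}
    order = ["simulate", "segment", "annotate", "pca", "enrich", "impute",
             "score", "gate", "dge"]
    deps = {
        "segment": ["simulate"], "annotate": ["segment"], "pca": ["annotate"],
        "enrich": ["pca"], "impute": ["pca"], "score": ["pca"],
        "gate": ["simulate"], "dge": ["gate"],
    }
    done: set[str] = set()
    for st in order:
        if st not in enabled:
            continue
        missing = [d for d in deps.get(st, []) if d not in done]
        if missing:
            raise StageError(st, RuntimeError(f"missing upstream stage(s) {missing}"))
        try:
            _STAGES[st](config, state, report, outdir)
        except StageError:
            raise
        except Exception as exc:  # halt with stage tag
            raise StageError(st, exc) from exc
        done.add(st)

    if outdir:
        (outdir / "report.json").write_text(json.dumps(report, indent=1, sort_keys=True))
    return report


# ------------------------------------------------------------------- stages

def _stage_simulate(config, state, report, outdir):
    sim_cfg = synthio.SimConfig(**{"seed": _stage_seed(config.seed, "simulate"),
                                   **config.sim})
    label_image, regions, truth = synthio.generate_spatial_truth(sim_cfg)
    grid = synthio.generate_bin_counts(label_image, truth, sim_cfg)
    sc_cells, sc_truth = synthio.generate_scrnaseq(sim_cfg)
    state.update(sim_cfg=sim_cfg, label_image=label_image, regions=regions,
                 truth=truth, grid=grid, sc_cells=sc_cells, sc_truth=sc_truth)
    report["simulate"] = {
        "n_spatial_cells": int(len(truth.cells)),
        "n_scrnaseq_cells": int(sc_cells.n_obs),
        "n_genes": sim_cfg.n_genes,
        "grid_shape": list(sim_cfg.grid_shape),
        "sim_seed": sim_cfg.seed,
    }
    if outdir:
        synthio.write_simulation(sim_cfg, outdir / "fixtures")


def _stage_segment(config, state, report, outdir):
    expanded = bincell.expand_labels(state["label_image"], config.d_max)
    cells = bincell.aggregate_bins(state["grid"], expanded)
    cells.obs["sample_id"] = "s1"
    filtered = bincell.qc_filter(cells, config.min_genes, config.min_umis,
                                 config.max_umis)
    state["cells"] = filtered
    qc = bincell.qc_report(filtered)
    report["segment"] = {
        "n_cells_segmented": int(cells.n_obs),
        "n_cells_after_qc": int(filtered.n_obs),
        "median_genes": float(qc["median_genes"].iloc[0]) if len(qc) else 0.0,
        "median_umis": float(qc["median_umis"].iloc[0]) if len(qc) else 0.0,
        "d_max": config.d_max,
    }


def _stage_annotate(config, state, report, outdir):
    cells = state["cells"]
    sel = _selection_classes(cells, state["regions"])
    cells.obs["selection_class"] = sel
    # map planted truth onto segmented cells via the label id, for validation
    truth_types = state["truth"].cells.set_index("cell_id")["cell_type"]
    cells.obs["true_type"] = [
        truth_types.get(lid, "unknown") for lid in cells.obs["label_id"]
    ]
    selected = cells[sel != "unselected"].copy()
    state["selected"] = selected
    counts = pd.Series(sel).value_counts().to_dict()
    report["annotate"] = {"selection_counts": {k: int(v) for k, v in counts.items()}}


def _stage_pca(config, state, report, outdir):
    selected = state["selected"]
    norm = dimred.preprocess(selected, exclude_pattern=config.exclude_pattern)
    ncomp = min(config.n_components, norm.n_obs - 1, norm.n_vars - 1)
    pca = dimred.fit_pooled_pca(norm, n_components=ncomp,
                                batch_correct=config.batch_correct)
    # orient PC1 toward the epidermal pole (keratinocytes positive)
    classes = norm.obs["selection_class"].to_numpy()
    pc1 = pca.scores[:, 0]
    if np.mean(pc1[classes == "keratinocyte"]) < np.mean(pc1[classes == "cMCC"]):
        pca.scores[:, 0] *= -1
        pca.loadings[:, 0] *= -1
    state.update(norm=norm, pca=pca)

    centroids = {c: float(np.mean(pca.scores[classes == c, 0]))
                 for c in pd.unique(classes)}
    ellipses = {}
    for c in pd.unique(classes):
        pts = pca.scores[classes == c, :2]
        if len(pts) >= 3:
            try:
                ell = dimred.fit_t_ellipse(pts, level=config.ellipse_level,
                                           df=config.ellipse_df)
                ellipses[c] = {"center": ell.center.tolist(),
                               "scatter": ell.scatter.tolist(),
                               "df": ell.df, "level": ell.level}
            except ValueError:
                pass
    between = (min(centroids.get("cMCC", 0), centroids.get("keratinocyte", 0))
               < centroids.get("epiMCC", 0)
               < max(centroids.get("cMCC", 0), centroids.get("keratinocyte", 0)))
    report["pca"] = {
        "explained_variance_ratio": pca.explained_variance_ratio[:5].tolist(),
        "n_excluded_keratins": len(norm.uns["excluded_genes"]),
        "pc1_centroids": centroids,
        "epiMCC_between_cMCC_and_keratinocyte": bool(between),
        "batch_correction": pca.metadata["batch_correction"],
        "ellipses": ellipses,
    }
    if config.make_figures and outdir:
        viz.spatial_class_map(state["selected"].obs, classes,
                              outdir / "class_map.png")


def _stage_enrich(config, state, report, outdir):
    pca, norm = state["pca"], state["norm"]
    loadings = pd.Series(pca.loadings[:, 0], index=pca.genes)
    markers = set(synthio.default_gene_sets()["cSCC_markers"])
    res = enrich.loading_rank_test(loadings, markers & set(pca.genes))
    report["enrich"] = {
        "cscc_pc1_p": res.pvalue,
        "cscc_pc1_U": res.statistic,
        "n_markers_tested": int(len(res.marker_ranks)),
        "median_marker_rank": float(res.marker_ranks.median()),
        "universe_size": int(len(loadings)),
    }
    if config.make_figures and outdir:
        viz.ranked_loading_plot(loadings, markers, outdir / "loading_rank.png")


def _stage_impute(config, state, report, outdir):
    norm = state["norm"]
    res = impute.alra(norm.X)
    state["imputed"] = res
    imputed_pos = (res.imputed > 0).mean()
    orig_pos = float((np.asarray(norm.X.todense()) > 0).mean())
    report["impute"] = {
        "rank": res.rank,
        "fraction_nonzero_before": orig_pos,
        "fraction_nonzero_after": float(imputed_pos),
    }


def _stage_score(config, state, report, outdir):
    norm = state["norm"]
    seed = _stage_seed(config.seed, "score")
    sets = synthio.default_gene_sets()
    sets = {k: [g for g in v if g in set(norm.var_names)] for k, v in sets.items()}
    activity = score.aucell_matrix(norm, sets, top_fraction=config.top_fraction,
                                   seed=seed)
    classes = norm.obs["selection_class"].to_numpy()
    emt = activity["MP12_EMT"].to_numpy()
    _, p_emt = annotate.rank_sum_compare(emt[classes == "vasMCC"],
                                         emt[classes == "cMCC"])
    rss = score.regulon_specificity(activity, classes)
    report["score"] = {
        "mp12_emt_mean": {c: float(np.mean(emt[classes == c]))
                          for c in pd.unique(classes)},
        "mp12_emt_vas_vs_core_p": p_emt,
        "rss": {reg: {c: (None if pd.isna(v) else float(v))
                      for c, v in row.items()}
                for reg, row in rss.iterrows()},
    }
    state["activity"] = activity
    if config.make_figures and outdir:
        viz.activity_heatmap(rss.astype(float), outdir / "rss_heatmap.png",
                             title="regulon specificity")


def _stage_gate(config, state, report, outdir):
    sc_cells, sc_truth = state["sc_cells"], state["sc_truth"]
    labels = gate.apply_gates(sc_cells)
    sc_cells.obs["gated"] = labels
    truth_types = sc_truth.cells["cell_type"].to_numpy()
    per_class = {}
    for c in ("epiMCC", "cMCC", "vasMCC"):
        tp = int(((labels == c) & (truth_types == c)).sum())
        fp = int(((labels == c) & (truth_types != c)).sum())
        fn = int(((labels != c) & (truth_types == c)).sum())
        per_class[c] = {
            "gated": int((labels == c).sum()),
            "precision": tp / (tp + fp) if tp + fp else 0.0,
            "recall": tp / (tp + fn) if tp + fn else 0.0,
        }
    state["gate_labels"] = labels
    report["gate"] = {"per_class": per_class}


def _stage_dge(config, state, report, outdir):
    sc_cells = state["sc_cells"]
    labels = state["gate_labels"]
    seed = _stage_seed(config.seed, "dge")
    idx = gate.balanced_subsample(
        np.where(np.isin(labels, ["epiMCC", "cMCC", "vasMCC"]), labels,
                 gate.UNLABELED),
        seed=seed,
    )
    sub = sc_cells[idx].copy()
    sub_labels = labels[idx]
    table = gate.wilcoxon_dge(sub, sub_labels, "epiMCC", "cMCC")
    sig_up = set(table.loc[(table.p_adj < config.alpha) & (table.log2_fc > 0),
                           "gene"])
    # regulons elevated in epiMCC by activity on the subsampled cells
    seed2 = _stage_seed(config.seed, "dge_regulons")
    regulons = synthio.default_regulons()
    reg_sets = {k: [g for g in v if g in set(sub.var_names)]
                for k, v in regulons.items()}
    norm_sub = dimred.preprocess(sub, exclude_pattern="")
    activity = score.aucell_matrix(norm_sub, reg_sets,
                                   top_fraction=config.top_fraction, seed=seed2)
    enhanced = score.enhanced_regulons(
        activity, norm_sub.obs["gated"].to_numpy(), "epiMCC", alpha=config.alpha)
    inter, prov = gate.tf_target_intersect(
        sig_up, {tf: regulons[tf] for tf in enhanced})
    report["dge"] = {
        "n_per_class_after_subsampling": int(len(idx) // 3) if len(idx) else 0,
        "n_significant_up_epiMCC": int(len(sig_up)),
        "enhanced_regulons_epiMCC": sorted(enhanced),
        "n_upregulated_tf_targets": int(len(inter)),
        "tf_target_genes": sorted(inter),
    }
    if outdir:
        table.to_csv(outdir / "dge_epiMCC_vs_cMCC.tsv", sep="\t", index=False)


_STAGES = {
    "simulate": _stage_simulate,
    "segment": _stage_segment,
    "annotate": _stage_annotate,
    "pca": _stage_pca,
    "enrich": _stage_enrich,
    "impute": _stage_impute,
    "score": _stage_score,
    "gate": _stage_gate,
    "dge": _stage_dge,
}
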