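"""Static figure rendering: spatial maps, ranked loadings, heatmaps.

All figures render deterministically (Agg backend, no timestamps in the
PNG metadata) and never mutate their inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

__all__ = ["FigureSpec", "render", "spatial_class_map", "ranked_loading_plot",
           "coexpression_map", "violin_summary", "activity_heatmap"]

_SAVE_KW = {"dpi": 120, "metadata": {"Software": None}}

_CLASS_COLORS = {
    "epiMCC": "#d62728", "cMCC": "#1f77b4", "vasMCC": "#9467bd",
    "bK": "#2ca02c", "sbK": "#bcbd22", "other": "#7f7f7f",
    "unassigned": "#cccccc", "unlabeled": "#cccccc",
}


@dataclass
class FigureSpec:
    kind: str                       # class_map | loading_rank | coexpr | violin | heatmap
    out: str | Path
    data: dict = field(default_factory=dict)


def _finish(fig, out: str | Path) -> Path:
    out = Path(out)
    out.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(out, **_SAVE_KW)
    plt.close(fig)
    return out


def spatial_class_map(coords: pd.DataFrame, labels, out: str | Path) -> Path:
    """Cell centroids colored by class; (row, col) in bin units."""
    fig, ax = plt.subplots(figsize=(6, 5))
    labels = np.asarray(labels)
    for cls in pd.unique(labels):
        m = labels == cls
        ax.scatter(coords.loc[m, "col"], coords.loc[m, "row"], s=8,
                   color=_CLASS_COLORS.get(cls, "#333333"), label=str(cls))
    ax.invert_yaxis()
    ax.set_aspect("equal")
    ax.legend(fontsize=7, markerscale=2)
    ax.set_xlabel("col (bins)")
    ax.set_ylabel("row (bins)")
    return _finish(fig, out)


def ranked_loading_plot(loadings: pd.Series, markers, out: str | Path) -> Path:
    """Genes ranked by loading, member genes of the set highlighted."""
    srt = loadings.sort_values(ascending=False)
    ranks = np.arange(1, len(srt) + 1)
    is_m = srt.index.isin(set(markers))
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(ranks, srt.to_numpy(), color="#999999", lw=1)
    ax.scatter(ranks[is_m], srt.to_numpy()[is_m], color="#d62728", s=18,
               zorder=3, label="marker genes")
    for r, (g, v) in zip(ranks[is_m][:8], srt[is_m].items()):
        ax.annotate(g, (r, v), fontsize=6, rotation=45)
    ax.set_xlabel("loading rank")
    ax.set_ylabel("PC loading")
    ax.legend(fontsize=7)
    return _finish(fig, out)


def coexpression_map(
    coords: pd.DataFrame, expr_a, expr_b, gene_a: str, gene_b: str,
    out: str | Path,
) -> Path:
    """Two-color spatial co-expression: each cell blends both intensities."""
    a = np.asarray(expr_a, dtype=float)
    b = np.asarray(expr_b, dtype=float)
    a = a / a.max() if len(a) and a.max() > 0 else a
    b = b / b.max() if len(b) and b.max() > 0 else b
    colors = np.stack([a, np.zeros_like(a), b], axis=1) if len(a) else np.zeros((0, 3))
    fig, ax = plt.subplots(figsize=(6, 5))
    if len(a):
        ax.scatter(coords["col"], coords["row"], c=np.clip(colors, 0, 1), s=10)
    ax.invert_yaxis()
    ax.set_aspect("equal")
    ax.set_title(f"{gene_a} (red) / {gene_b} (blue)", fontsize=9)
    return _finish(fig, out)


def violin_summary(values: pd.DataFrame, group_col: str, value_col: str,
                   out: str | Path) -> Path:
    """Per-class violin of one expression/score column."""
    groups = [g for g in values[group_col].unique()]
    data = [values.loc[values[group_col] == g, value_col].to_numpy() for g in groups]
    fig, ax = plt.subplots(figsize=(5, 4))
    if any(len(d) for d in data):
        ax.violinplot([d for d in data if len(d)], showmedians=True)
        ax.set_xticks(range(1, 1 + sum(1 for d in data if len(d))))
        ax.set_xticklabels([g for g, d in zip(groups, data) if len(d)], fontsize=8)
    ax.set_ylabel(value_col)
    return _finish(fig, out)


def activity_heatmap(table: pd.DataFrame, out: str | Path, title: str = "") -> Path:
    """Heatmap of a scores table (e.g. RSS regulon x class, MP x class)."""
    fig, ax = plt.subplots(figsize=(4 + 0.3 * len(table.columns),
                                    1 + 0.3 * len(table)))
    vals = table.to_numpy(dtype=float)
    im = ax.imshow(vals, cmap="viridis", aspect="auto")
    ax.set_xticks(range(len(table.columns)))
    ax.set_xticklabels(table.columns, fontsize=7, rotation=45)
    ax.set_yticks(range(len(table)))
    ax.set_yticklabels(table.index, fontsize=7)
    fig.colorbar(im, ax=ax, shrink=0.8)
    if title:
        ax.set_title(title, fontsize=9)
    return _finish(fig, out)


def render(spec: FigureSpec) -> Path:
    """Dispatch a figure specification to the matching renderer."""
    kind = spec.kind
    d = spec.data
    if kind == "class_map":
        return spatial_class_map(d["coords"], d["labels"], spec.out)
    if kind == "loading_rank":
        return ranked_loading_plot(d["loadings"], d["markers"], spec.out)
    if kind == "coexpr":
        return coexpression_map(d["coords"], d["expr_a"], d["expr_b"],
                                d["gene_a"], d["gene_b"], spec.out)
    if kind == "violin":
        return violin_summary(d["values"], d["group_col"], d["value_col"], spec.out)
    if kind == "heatmap":
        return activity_heatmap(d["table"], spec.out, d.get("title", ""))
    raise ValueError(f"unknown figure kind: {kind!r}")
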