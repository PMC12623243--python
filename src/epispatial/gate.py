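"""Rule-based MCC subtype gating, balanced subsampling and Wilcoxon DGE.

The three tumor subpopulations are called from raw counts with ordered
boolean rules (first match wins):

* epiMCC — CCER2 > 0 and KRT5 > 0 and (CALML3 > 0 or CALML5 > 0)
* vasMCC — CCER2 > 0 and KRT20 > 0 and (COL3A1 > 0 or COL1A1 > 0)
* cMCC  — CCER2 > 0 and KRT20 > 0 and COL3A1 == 0 and COL1A1 == 0 and KRT5 == 0

The epiMCC-before-vasMCC precedence resolves the overlap a literal reading
of the rules leaves open (a KRT5+/CALML+/collagen+ cell), giving the rarer,
more specific epidermal call priority. Class sizes are balanced by seeded
subsampling to the smallest class before differential expression, which is
a per-gene rank-sum test on normalized expression with BH adjustment and a
fold-change ranking.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd
import scanpy as sc
import scipy.sparse as sp
from statsmodels.stats.multitest import multipletests

from .annotate import rank_sum_compare

logger = logging.getLogger(__name__)

__all__ = [
    "GatingRules",
    "DEFAULT_RULES",
    "UNLABELED",
    "apply_gates",
    "balanced_subsample",
    "wilcoxon_dge",
    "tf_target_intersect",
]

UNLABELED = "unlabeled"

_IDENT = re.compile(r"[A-Za-z_][A-Za-z0-9_.\-]*")
_ALLOWED = re.compile(r"^[\w\s()&|><=.\-]+$")


@dataclass
class GatingRules:
    """Ordered (class, boolean expression) pairs; order is precedence.

    Expressions combine ``gene > 0`` / ``gene == 0`` atoms with ``&``,
    ``|`` and parentheses, e.g. ``"CCER2>0 & (CALML3>0 | CALML5>0)"``.
    """

    rules: list[tuple[str, str]] = field(default_factory=lambda: list(DEFAULT_RULES))

    def genes(self) -> set[str]:
        return {
            tok for _, expr in self.rules for tok in _IDENT.findall(expr)
        }

    def validate(self, universe: list[str] | set[str]) -> None:
        missing = self.genes() - set(universe)
        if missing:
            raise KeyError(f"gating rules reference missing genes: {sorted(missing)}")


DEFAULT_RULES: tuple[tuple[str, str], ...] = (
    ("epiMCC", "CCER2>0 & KRT5>0 & (CALML3>0 | CALML5>0)"),
    ("vasMCC", "CCER2>0 & KRT20>0 & (COL3A1>0 | COL1A1>0)"),
    ("cMCC", "CCER2>0 & KRT20>0 & COL3A1==0 & COL1A1==0 & KRT5==0"),
)


_ATOM = re.compile(r"[A-Za-z_][\w.\-]*\s*(?:>=|<=|==|>|<)\s*\d+(?:\.\d+)?")


def _eval_rule(expr: str, env: dict[str, np.ndarray]) -> np.ndarray:
    if not _ALLOWED.match(expr):
        raise ValueError(f"unsupported characters in rule: {expr!r}")
    # wrap comparison atoms in parentheses: Python's & binds tighter than >
    wrapped = _ATOM.sub(lambda m: f"({m.group(0)})", expr)
    return eval(wrapped, {"__builtins__": {}}, dict(env))  # noqa: S307 - sanitized


def apply_gates(
    cells: ad.AnnData, rules: GatingRules | None = None
) -> np.ndarray:
    """Class per cell from raw-count boolean rules, first match wins.

    Atoms are evaluated on raw counts (non-zero iff count > 0), so the
    calls are invariant to normalization. Unmatched cells are
    ``"unlabeled"``. Per-class counts are logged.
    """
    rules = rules or GatingRules()
    rules.validate(cells.var_names)
    X = cells.X.tocsc() if sp.issparse(cells.X) else np.asarray(cells.X)
    env: dict[str, np.ndarray] = {}
    for g in rules.genes():
        j = cells.var_names.get_loc(g)
        col = X[:, [j]].toarray().ravel() if sp.issparse(X) else X[:, j]
        env[g] = col
    out = np.full(cells.n_obs, UNLABELED, dtype=object)
    unassigned = np.ones(cells.n_obs, dtype=bool)
    for cls, expr in rules.rules:
        hit = np.asarray(_eval_rule(expr, env), dtype=bool) & unassigned
        out[hit] = cls
        unassigned &= ~hit
    counts = pd.Series(out).value_counts()
    logger.info("gated classes: %s", counts.to_dict())
    return out


def balanced_subsample(
    labels: np.ndarray | pd.Series, seed: int = 0
) -> np.ndarray:
    """Indices of a per-class subsample down to the smallest class size.

    Unlabeled cells are dropped; sampling is without replacement and
    reproducible under a fixed seed. The returned index array is sorted.
    """
    labels = np.asarray(labels)
    classes = [c for c in pd.unique(labels) if c != UNLABELED]
    if not classes:
        raise ValueError("no labeled cells to subsample")
    rng = np.random.default_rng(seed)
    n_min = min(int((labels == c).sum()) for c in classes)
    keep: list[np.ndarray] = []
    for c in sorted(classes):
        idx = np.nonzero(labels == c)[0]
        keep.append(rng.choice(idx, size=n_min, replace=False))
    return np.sort(np.concatenate(keep))


def wilcoxon_dge(
    cells: ad.AnnData,
    labels: np.ndarray | pd.Series,
    group_a: str,
    group_b: str,
    pseudocount: float = 1e-9,
    target_sum: float = 1e4,
) -> pd.DataFrame:
    """Per-gene rank-sum differential expression between two gated classes.

    Expression is depth-normalized and log1p-transformed; per gene the
    Mann-Whitney p (exact for tiny tie-free groups, tie-corrected normal
    approximation otherwise) is BH-adjusted across genes, and the log2
    fold change uses group means of normalized expression with a small
    pseudocount. Sort by ``abs(log2_fc)`` among ``p_adj < alpha`` rows to
    reproduce a significance-filtered, fold-change-ranked table.
    """
    labels = np.asarray(labels)
    mask_a, mask_b = labels == group_a, labels == group_b
    if mask_a.sum() < 2 or mask_b.sum() < 2:
        raise ValueError("both groups need at least 2 cells")
    norm = cells.copy()
    sc.pp.normalize_total(norm, target_sum=target_sum)
    sc.pp.log1p(norm)
    X = norm.X.toarray() if sp.issparse(norm.X) else np.asarray(norm.X)
    A, B = X[mask_a], X[mask_b]

    pvals = np.empty(X.shape[1])
    stat = np.empty(X.shape[1])
    for j in range(X.shape[1]):
        stat[j], pvals[j] = rank_sum_compare(A[:, j], B[:, j])
    p_adj = multipletests(pvals, method="fdr_bh")[1]
    log2_fc = np.log2((A.mean(axis=0) + pseudocount) / (B.mean(axis=0) + pseudocount))
    table = pd.DataFrame({
        "gene": list(cells.var_names),
        "log2_fc": log2_fc,
        "U": stat,
        "p": pvals,
        "p_adj": p_adj,
        "direction": np.where(log2_fc > 0, f"up_{group_a}", f"up_{group_b}"),
    })
    return table


def tf_target_intersect(
    upregulated: set[str] | list[str],
    regulons: dict[str, list[str]],
) -> tuple[set[str], dict[str, list[str]]]:
    """Upregulated genes covered by the enhanced regulons, with provenance.

    Returns the intersection of ``upregulated`` with the union of regulon
    targets, and a map gene -> list of covering regulons.
    """
    upregulated = set(upregulated)
    provenance: dict[str, list[str]] = {}
    for tf, targets in regulons.items():
        for g in set(targets) & upregulated:
            provenance.setdefault(g, []).append(tf)
    return set(provenance), {g: sorted(v) for g, v in provenance.items()}
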