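"""Boolean subtype gating, balanced subsampling and Wilcoxon DGE."""

from itertools import combinations
from math import comb

import anndata as ad
import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from epispatial import gate


GENES = ["CCER2", "KRT5", "KRT20", "CALML3", "CALML5", "COL1A1", "COL3A1"]


def _cells(rows, genes=GENES):
    X = sp.csr_matrix(np.asarray(rows, dtype=float))
    a = ad.AnnData(X=X, obs=pd.DataFrame(index=[f"c{i}" for i in range(len(rows))]))
    a.var_names = list(genes)
    return a


def _row(**kw):
    return [kw.get(g, 0) for g in GENES]


class TestApplyGates:
    def test_four_cell_toy(self):
        cells = _cells([
            _row(CCER2=2, KRT5=1, CALML3=1),
            _row(CCER2=1, KRT20=3, COL1A1=2),
            _row(CCER2=1, KRT20=2),
            _row(KRT5=9),
        ])
        out = gate.apply_gates(cells)
        assert list(out) == ["epiMCC", "vasMCC", "cMCC", gate.UNLABELED]

    def test_all_zero_cell_unlabeled(self):
        assert gate.apply_gates(_cells([_row()]))[0] == gate.UNLABELED

    def test_missing_gene_rejected(self):
        cells = _cells([[1, 1]], genes=["CCER2", "KRT5"])
        with pytest.raises(KeyError):
            gate.apply_gates(cells)

    def test_epi_and_core_rules_provably_disjoint(self, rng):
        """cMCC demands KRT5 == 0 while epiMCC demands KRT5 > 0."""
        X = rng.integers(0, 3, size=(300, len(GENES)))
        cells = _cells(X)
        rules = dict(gate.DEFAULT_RULES)
        epi = gate._eval_rule(rules["epiMCC"],
                              {g: X[:, i] for i, g in enumerate(GENES)})
        core = gate._eval_rule(rules["cMCC"],
                               {g: X[:, i] for i, g in enumerate(GENES)})
        assert not (np.asarray(epi) & np.asarray(core)).any()

    def test_gating_invariant_to_cell_order(self, rng):
        X = rng.integers(0, 3, size=(60, len(GENES)))
        base = gate.apply_gates(_cells(X))
        perm = rng.permutation(60)
        assert np.array_equal(gate.apply_gates(_cells(X[perm])), base[perm])

    def test_precedence_resolves_epi_vas_overlap(self):
        # satisfies both the epiMCC and vasMCC written rules
        cell = _row(CCER2=1, KRT5=1, CALML3=1, KRT20=1, COL1A1=1)
        assert gate.apply_gates(_cells([cell]))[0] == "epiMCC"


class TestBalancedSubsample:
    def test_equal_sizes_keep_everything(self):
        labels = np.repeat(["a", "b", "c"], 5)
        idx = gate.balanced_subsample(labels, seed=0)
        assert len(idx) == 15

    def test_downsample_to_min_class(self):
        labels = np.array(["a"] * 10 + ["b"] * 4 + ["c"] * 7)
        idx = gate.balanced_subsample(labels, seed=3)
        out = pd.Series(labels[idx]).value_counts()
        assert set(out) == {4}

    def test_deterministic_and_drops_unlabeled(self):
        labels = np.array(["a"] * 6 + [gate.UNLABELED] * 3 + ["b"] * 4)
        i1 = gate.balanced_subsample(labels, seed=9)
        i2 = gate.balanced_subsample(labels, seed=9)
        assert np.array_equal(i1, i2)
        assert gate.UNLABELED not in labels[i1]

    def test_empty_labeling_rejected(self):
        with pytest.raises(ValueError):
            gate.balanced_subsample(np.array([gate.UNLABELED] * 3))


def _exact_two_sided_p(a, b):
    """Enumerate all C(n1+n2, n1) rank splits of the pooled sample."""
    pooled = np.concatenate([a, b])
    n1 = len(a)
    ranks = pd.Series(pooled).rank().to_numpy()
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2
    n = len(pooled)
    us = []
    for idx in combinations(range(n), n1):
        us.append(ranks[list(idx)].sum() - n1 * (n1 + 1) / 2)
    us = np.asarray(us)
    p_ge = (us >= u_obs).mean()
    p_le = (us <= u_obs).mean()
    return min(1.0, 2 * min(p_ge, p_le))


class TestWilcoxonDge:
    def _adata(self, A, B):
        X = np.vstack([A, B])
        a = ad.AnnData(X=sp.csr_matrix(X.astype(float)),
                       obs=pd.DataFrame(index=[f"c{i}" for i in range(len(X))]))
        a.var_names = [f"g{i}" for i in range(X.shape[1])]
        labels = np.array(["A"] * len(A) + ["B"] * len(B))
        return a, labels

    def test_identical_groups_null_table(self, rng):
        block = rng.integers(1, 10, size=(4, 5))
        a, labels = self._adata(block, block)
        t = gate.wilcoxon_dge(a, labels, "A", "B")
        assert (t.p == 1.0).all()
        assert np.allclose(t.log2_fc, 0.0)

    def test_shifted_gene_dominates(self, rng):
        # shift gene 2 up in group A while keeping library sizes equal, so
        # normalization does not smear the shift across other genes
        A = rng.integers(1, 5, size=(8, 6)).astype(float)
        A[:, 5] = 200.0
        B = A.copy()
        A[:, 2] += 100
        A[:, 5] -= 100
        a, labels = self._adata(A, B)
        t = gate.wilcoxon_dge(a, labels, "A", "B")
        # the shifted gene (and its donor gene 5) dominate the table
        assert t.loc[2, "p"] == t.drop(index=5).p.min()
        assert t.loc[2, "log2_fc"] > 0
        assert t.loc[2, "direction"] == "up_A"
        assert t.loc[[0, 1, 3, 4], "p"].min() > t.loc[2, "p"]

    def test_single_gene_matches_exhaustive_enumeration(self):
        # equal library sizes keep normalization monotone per gene, so the
        # exact rank enumeration applies to the raw values directly
        g0_a, g0_b = [1.0, 5.0, 9.0, 13.0], [2.0, 3.0, 4.0, 20.0]
        A = np.array([[v, 30.0 - v] for v in g0_a])
        B = np.array([[v, 30.0 - v] for v in g0_b])
        a, labels = self._adata(A, B)
        t = gate.wilcoxon_dge(a, labels, "A", "B")
        assert t.loc[0, "p"] == pytest.approx(
            _exact_two_sided_p(np.array(g0_a), np.array(g0_b)))

    def test_tiny_group_rejected(self, rng):
        a, labels = self._adata(rng.integers(0, 5, (1, 3)),
                                rng.integers(0, 5, (4, 3)))
        with pytest.raises(ValueError):
            gate.wilcoxon_dge(a, labels, "A", "B")


class TestTfTargetIntersect:
    def test_empty_regulons(self):
        inter, prov = gate.tf_target_intersect({"A", "B"}, {})
        assert inter == set() and prov == {}

    def test_set_algebra_with_provenance(self):
        inter, prov = gate.tf_target_intersect(
            {"A", "B", "C"}, {"TF1": ["B", "C", "D"], "TF2": ["C", "E"]})
        assert inter == {"B", "C"}
        assert prov == {"B": ["TF1"], "C": ["TF1", "TF2"]}


def test_planted_subtype_recovery(default_scrna):
    """Gating recovers planted labels with precision/recall >= 0.9 per class."""
    adata, truth = default_scrna
    labels = gate.apply_gates(adata)
    types = truth.cells.cell_type.to_numpy()
    for c in ("epiMCC", "cMCC", "vasMCC"):
        tp = ((labels == c) & (types == c)).sum()
        fp = ((labels == c) & (types != c)).sum()
        fn = ((labels != c) & (types == c)).sum()
        assert tp / (tp + fp) >= 0.9, c
        assert tp / (tp + fn) >= 0.9, c
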