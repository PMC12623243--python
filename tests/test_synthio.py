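"""Ground-truth generator: conservation, determinism, calibration."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from epispatial import synthio
from epispatial.synthio import SimConfig


def _zero_cells():
    return {t: 0 for t in synthio.CELL_TYPES}


class TestSpatialTruth:
    def test_zero_cells_gives_empty_outputs(self):
        cfg = SimConfig(seed=0, cells_per_type=_zero_cells(),
                        scrna_cells_per_type=_zero_cells())
        img, regions, truth = synthio.generate_spatial_truth(cfg)
        assert img.max() == 0
        assert len(truth.cells) == 0
        assert {r[0] for r in regions} == set(
            ("epidermis", "tumor_core", "perivascular", "follicle", "background")
        )

    def test_label_count_matches_requested_cells(self, small_config, small_spatial):
        img, _, truth, _ = small_spatial
        n_req = sum(small_config.cells_per_type.values())
        assert len(np.unique(img[img > 0])) == n_req == len(truth.cells)

    def test_deterministic_under_fixed_seed(self, small_config):
        a = synthio.generate_spatial_truth(small_config)
        b = synthio.generate_spatial_truth(small_config)
        assert np.array_equal(a[0], b[0])
        pd.testing.assert_frame_equal(a[2].cells, b[2].cells)

    def test_types_sit_in_their_home_regions(self, small_spatial):
        from epispatial.annotate import assign_regions
        import anndata as ad

        img, regions, truth, _ = small_spatial
        cells = ad.AnnData(
            X=np.zeros((len(truth.cells), 1)),
            obs=truth.cells[["row", "col"]].astype(float),
        )
        region = assign_regions(cells, regions)
        home = {"epiMCC": "epidermis", "bK": "epidermis", "sbK": "epidermis",
                "cMCC": "tumor_core", "vasMCC": "perivascular"}
        for ctype, expect in home.items():
            got = region[truth.cells.cell_type.to_numpy() == ctype]
            assert set(got) == {expect}

    def test_grid_too_small_raises(self):
        cfg = SimConfig(seed=0, grid_shape=(40, 40))
        with pytest.raises(synthio.SizingError):
            synthio.generate_spatial_truth(cfg)


class TestBinCounts:
    def test_bin_sums_conserve_cell_draws(self, small_config):
        """Summing a cell's bins recovers its pre-split draw exactly."""
        cfg = SimConfig(seed=7, ambient_lambda=0.0, **{
            k: getattr(small_config, k)
            for k in ("grid_shape", "cells_per_type", "scrna_cells_per_type")
        })
        img, regions, truth = synthio.generate_spatial_truth(cfg)
        grid = synthio.generate_bin_counts(img, truth, cfg)
        assert grid.counts.sum() == truth.cell_counts.sum()
        # totals per gene also conserved
        assert np.array_equal(
            np.asarray(grid.counts.sum(axis=0)).ravel(),
            np.asarray(truth.cell_counts.sum(axis=0)).ravel(),
        )

    def test_mean_umis_within_ten_percent(self):
        cfg = SimConfig(seed=3, scrna_mean_umis=200.0)
        adata, _ = synthio.generate_scrnaseq(cfg)
        assert abs(adata.obs.n_umis.mean() - 200) < 20

    def test_poisson_limit_variance_over_mean_near_one(self):
        """dispersion -> inf reduces the negative binomial to Poisson."""
        cfg = SimConfig(seed=5, dispersion=1e7, marker_effect=0.0,
                        scrna_cells_per_type={**_zero_cells(), "cMCC": 1500},
                        scrna_mean_umis=500.0)
        adata, _ = synthio.generate_scrnaseq(cfg)
        X = adata.X.toarray()
        means = X.mean(axis=0)
        keep = means > 1.0
        ratio = X.var(axis=0, ddof=1)[keep] / means[keep]
        assert abs(np.median(ratio) - 1.0) < 0.1

    def test_dropout_mask_only_marks_positive_entries(self):
        cfg = SimConfig(seed=11, dropout_rate=0.3)
        adata, truth = synthio.generate_scrnaseq(cfg)
        drop = truth.dropout_mask.toarray()
        observed = adata.X.toarray()
        # dropped entries are zero in the output
        assert (observed[drop] == 0).all()
        assert drop.sum() > 0


class TestScrnaseq:
    def test_empty(self):
        cfg = SimConfig(seed=0, cells_per_type=_zero_cells(),
                        scrna_cells_per_type=_zero_cells())
        adata, truth = synthio.generate_scrnaseq(cfg)
        assert adata.n_obs == 0 and len(truth.cells) == 0

    def test_deterministic(self):
        cfg = SimConfig(seed=9)
        a, _ = synthio.generate_scrnaseq(cfg)
        b, _ = synthio.generate_scrnaseq(cfg)
        assert (a.X != b.X).nnz == 0

    def test_zero_marker_effect_makes_types_exchangeable(self):
        """With no planted effects all types share one gene distribution."""
        cfg = SimConfig(seed=0, marker_effect=0.0)
        props = synthio._type_proportions(cfg)
        for t in synthio.CELL_TYPES[1:]:
            np.testing.assert_allclose(props[t], props[synthio.CELL_TYPES[0]])
        # and a marker-gene rank-sum between two types is unremarkable
        cfg2 = SimConfig(
            seed=2, marker_effect=0.0,
            scrna_cells_per_type={**_zero_cells(), "epiMCC": 50, "cMCC": 50},
        )
        adata, truth = synthio.generate_scrnaseq(cfg2)
        from epispatial.annotate import rank_sum_compare

        ccer2 = adata[:, "CCER2"].X.toarray().ravel()
        types = truth.cells.cell_type.to_numpy()
        _, p = rank_sum_compare(ccer2[types == "epiMCC"], ccer2[types == "cMCC"])
        assert p > 0.01


def test_config_validation_errors():
    with pytest.raises(ValueError):
        SimConfig(bin_pitch_um=8.0)
    with pytest.raises(ValueError):
        SimConfig(dispersion=-1)
    with pytest.raises(ValueError):
        SimConfig(n_genes=5)
    with pytest.raises(ValueError):
        SimConfig(cells_per_type={"weird_type": 3})


def test_config_json_roundtrip(tmp_path):
    cfg = SimConfig(seed=4, n_genes=120)
    cfg.to_json(tmp_path / "c.json")
    assert SimConfig.from_json(tmp_path / "c.json") == cfg
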