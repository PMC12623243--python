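"""Shared fixtures: one small and one default-size synthetic dataset.

Session scope keeps the expensive simulations to a single run each.
"""

import numpy as np
import pytest

from epispatial import synthio


SMALL_KW = dict(
    grid_shape=[120, 180],  # JSON-stable; SimConfig coerces to tuple
    cells_per_type={"epiMCC": 10, "cMCC": 14, "vasMCC": 6, "bK": 8, "sbK": 8,
                    "other": 10},
    scrna_cells_per_type={"epiMCC": 30, "cMCC": 60, "vasMCC": 30, "bK": 20,
                          "sbK": 20, "other": 40},
)


@pytest.fixture(scope="session")
def small_config():
    return synthio.SimConfig(seed=7, **SMALL_KW)


@pytest.fixture(scope="session")
def small_spatial(small_config):
    label_image, regions, truth = synthio.generate_spatial_truth(small_config)
    grid = synthio.generate_bin_counts(label_image, truth, small_config)
    return label_image, regions, truth, grid


@pytest.fixture(scope="session")
def default_scrna():
    """Default-condition scRNA-seq arm (3000 cells), seed 1."""
    cfg = synthio.SimConfig(seed=1)
    return synthio.generate_scrnaseq(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
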