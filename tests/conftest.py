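"""Shared fixtures: small synthetic datasets and a cheaply trained model."""

import numpy as np
import pytest

from spatialvelo import (
    PreprocessConfig,
    SimConfig,
    SpatialVelocityModel,
    preprocess,
    simulate,
)


@pytest.fixture(scope="session")
def small_sim():
    """Two-batch synthetic dataset with ground truth (150 cells, 15+30 genes)."""
    cfg = SimConfig(n_cells_per_batch=75, n_genes=15, n_background_genes=30,
                    n_batches=2, n_cell_types=4, seed=11)
    return simulate(cfg)


@pytest.fixture(scope="session")
def small_preprocessed(small_sim):
    ds, gt = small_sim
    pp = preprocess(ds, PreprocessConfig(min_shared_counts=5, n_neighbors=10,
                                         n_pcs=10))
    return pp, gt


@pytest.fixture(scope="session")
def trained_model(small_preprocessed):
    """A briefly trained model; enough for interface/shape/consistency tests."""
    pp, gt = small_preprocessed
    model = SpatialVelocityModel(epochs=40, n_graph_neighbors=8, seed=3)
    model.fit(pp)
    return model, pp, gt


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
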