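"""Shared fixtures.

``desk_runs`` performs the three seeded desk-scale studies once per session
(synthetic three-gas fixture, m = 1750, 9:1 holdout, 100 training epochs)
and is shared by the acceptance tests; everything else is cheap and local.
"""

from __future__ import annotations

import numpy as np
import pytest

from specblend import DEFAULT_CONDITIONS, SpectralGrid, demo_gas_set
from specblend import pipeline

DESK_SEEDS = (1, 2, 3)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_grid():
    return SpectralGrid(2950.0, 3150.0, 401)


@pytest.fixture(scope="session")
def conditions():
    return DEFAULT_CONDITIONS


@pytest.fixture(scope="session")
def demo_units(small_grid, conditions):
    """Three-gas synthetic fixture on a coarse grid (fast unit tests)."""
    return demo_gas_set(small_grid, conditions, seed=7)


@pytest.fixture(scope="session")
def desk_runs():
    """The three seeded desk-scale studies: seed -> (model, dataset, split,
    report, unit_spectra)."""
    out = {}
    for seed in DESK_SEEDS:
        cfg = pipeline.desk_config()
        model, ds, split, report = pipeline.run_holdout_study(cfg, seed=seed)
        units = pipeline.build_unit_spectra(cfg)
        out[seed] = (model, ds, split, report, units)
    return out


@pytest.fixture(scope="session")
def tiny_cli_config(tmp_path_factory):
    """A miniature end-to-end config for CLI tests (seconds, not minutes)."""
    import yaml

    cfg = {
        "grid": {"start": 2950.0, "end": 3150.0, "n_points": 333},
        "dataset": {"m": 21, "allocation": None, "perturbations": {}},
        "model": {"hidden_layer_sizes": [16, 8, 12], "cr_max": [200.0, 200.0, 8000.0]},
        "train": {"epochs": 3, "batch_size": 8, "learning_rate": 0.002,
                  "lr_schedule": "cosine", "augment": True},
        "seed": 5,
    }
    path = tmp_path_factory.mktemp("cli") / "tiny.yaml"
    path.write_text(yaml.safe_dump(cfg))
    return path
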