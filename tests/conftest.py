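"""Shared fixtures: the three full Monte Carlo grids, computed once.

The grids reproduce the study conditions — 1000 replicates of n=1000
panels — and are session-scoped so the bias checks and the experiment-level
assertions share one computation.
"""

from __future__ import annotations

import numpy as np
import pytest

from changepanel import DGPParams, GridSpec, run_grid
from changepanel.dgp import GENERATORS
from changepanel.estimators import ESTIMATORS
from changepanel.oracle import SUPPORTED_COMBINATIONS, expected_probability_limit

BASE_SEED = 0
REPLICATES = 1000

THETA_GRID = tuple(np.round(np.arange(0.0, 1.01, 0.1), 10))
RHO_GRID = THETA_GRID
OMEGA_GRID = tuple(np.round(np.arange(-1.0, 1.01, 0.2), 10))


@pytest.fixture(scope="session")
def theta_grid_cells():
    """Confounding sweep: all four models on the baseline process."""
    spec = GridSpec(
        dgp_id="baseline",
        varied_parameter="theta",
        grid=THETA_GRID,
        estimator_ids=(
            "concurrent_cc",
            "cross_sectional",
            "change_score",
            "lagged_cc",
        ),
        replicates=REPLICATES,
        base_params=DGPParams(waves=3),
        base_seed=BASE_SEED,
    )
    return run_grid(spec)


@pytest.fixture(scope="session")
def rho_grid_cells():
    """Lagged-outcome feed-forward sweep, concurrent model only (theta=1)."""
    spec = GridSpec(
        dgp_id="se_violation",
        varied_parameter="rho",
        grid=RHO_GRID,
        estimator_ids=("concurrent_cc",),
        replicates=REPLICATES,
        base_params=DGPParams(theta=1.0, waves=2),
        base_seed=BASE_SEED,
    )
    return run_grid(spec)


@pytest.fixture(scope="session")
def omega_grid_cells():
    """Heterogeneous-trend sweep, concurrent model only (theta=1)."""
    spec = GridSpec(
        dgp_id="ct_violation",
        varied_parameter="omega",
        grid=OMEGA_GRID,
        estimator_ids=("concurrent_cc",),
        replicates=REPLICATES,
        base_params=DGPParams(theta=1.0, waves=2),
        base_seed=BASE_SEED,
    )
    return run_grid(spec)


def cells_by(cells, estimator_id):
    return {c.parameter_value: c for c in cells if c.estimator_id == estimator_id}


# large-n gate for the closed-form probability limits; shared between the
# oracle unit tests and the grid-level bias checks
PLIM_VALIDATION_CASES = [
    ("concurrent_cc", "baseline", dict(theta=0.7, waves=3)),
    ("cross_sectional", "baseline", dict(theta=0.5, waves=3)),
    ("change_score", "baseline", dict(theta=0.5, waves=3)),
    ("lagged_cc", "baseline", dict(theta=1.0, waves=3)),
    ("concurrent_cc", "se_violation", dict(theta=1.0, rho=0.6, waves=2)),
    ("concurrent_cc", "ct_violation", dict(theta=1.0, omega=-0.4, waves=2)),
]


def large_sample_gap(estimator_id, dgp_id, kwargs, n=1_000_000, seed=12345):
    """|single huge-sample fit - closed form| for one supported cell."""
    assert (estimator_id, dgp_id) in SUPPORTED_COMBINATIONS
    params = DGPParams(n=n, **kwargs)
    panel = GENERATORS[dgp_id](params, seed=seed)
    fit = ESTIMATORS[estimator_id](panel)
    plim = expected_probability_limit(estimator_id, dgp_id, params)
    return abs(fit.x_coefficient - plim)
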