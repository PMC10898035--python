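"""Monte Carlo bias-evaluation engine.

Runs repeated generate-then-fit cycles over a grid of one structural
parameter and aggregates the exposure-coefficient estimates per cell:
mean estimate, empirical standard deviation across replicates, and the mean
of the model-based standard errors.  Replicate ``r`` of a cell draws from a
generator seeded with ``(base_seed, r)``, so every cell is reproducible on
its own and the whole grid is order-independent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .dgp import DGPParams, GENERATORS
from .errors import ConfigurationError
from .estimators import ESTIMATORS
from .oracle import SUPPORTED_COMBINATIONS, expected_probability_limit

__all__ = ["GridSpec", "CellSummary", "run_cell", "run_grid", "summaries_to_frame"]

#: Waves each generating process produces.
_DGP_WAVES = {"baseline": 3, "se_violation": 2, "ct_violation": 2}

#: Minimum waves each estimator needs.
_ESTIMATOR_MIN_WAVES = {
    "concurrent_cc": 2,
    "change_score": 2,
    "lagged_cc": 3,
    "cross_sectional": 1,
}


@dataclass(frozen=True)
class GridSpec:
    """One simulation experiment: a parameter grid crossed with estimators."""

    dgp_id: str
    varied_parameter: str
    grid: tuple[float, ...]
    estimator_ids: tuple[str, ...]
    replicates: int = 1000
    base_params: DGPParams = field(default_factory=DGPParams)
    base_seed: int = 0

    def __post_init__(self) -> None:
        if self.dgp_id not in GENERATORS:
            raise ConfigurationError(
                f"unknown dgp_id {self.dgp_id!r}; choose from {sorted(GENERATORS)}"
            )
        grid = tuple(float(v) for v in self.grid)
        if not grid or not np.isfinite(grid).all():
            raise ConfigurationError("grid values must be finite and non-empty")
        object.__setattr__(self, "grid", grid)
        object.__setattr__(self, "estimator_ids", tuple(self.estimator_ids))
        for est in self.estimator_ids:
            if est not in ESTIMATORS:
                raise ConfigurationError(
                    f"unknown estimator {est!r}; choose from {sorted(ESTIMATORS)}"
                )
        if self.replicates < 1:
            raise ConfigurationError("replicates must be >= 1")
        if not hasattr(self.base_params, self.varied_parameter):
            raise ConfigurationError(
                f"varied_parameter {self.varied_parameter!r} is not a "
                "generator parameter"
            )


@dataclass(frozen=True)
class CellSummary:
    """Aggregated Monte Carlo results for one (parameter value, estimator)."""

    dgp_id: str
    parameter_name: str | None
    parameter_value: float | None
    estimator_id: str
    mean_estimate: float
    empirical_sd: float
    mean_model_se: float
    replicates: int

    def oracle_plim(self, base_params: DGPParams | None = None) -> float | None:
        """Probability limit for this cell, if a closed form exists."""
        if (self.estimator_id, self.dgp_id) not in SUPPORTED_COMBINATIONS:
            return None
        base = base_params if base_params is not None else DGPParams()
        overrides = {"waves": _DGP_WAVES[self.dgp_id]}
        if self.parameter_name is not None:
            overrides[self.parameter_name] = self.parameter_value
        params = base.with_(**overrides)
        return expected_probability_limit(self.estimator_id, self.dgp_id, params)


def _check_compatible(dgp_id: str, estimator_id: str) -> None:
    if dgp_id not in GENERATORS:
        raise ConfigurationError(f"unknown dgp_id {dgp_id!r}")
    if estimator_id not in ESTIMATORS:
        raise ConfigurationError(f"unknown estimator {estimator_id!r}")
    need = _ESTIMATOR_MIN_WAVES[estimator_id]
    have = _DGP_WAVES[dgp_id]
    if have < need:
        raise ConfigurationError(
            f"estimator {estimator_id!r} needs {need} waves but process "
            f"{dgp_id!r} generates {have}"
        )


def run_cell(
    dgp_id: str,
    params: DGPParams,
    estimator_id: str,
    replicates: int,
    base_seed: int,
    parameter_name: str | None = None,
    parameter_value: float | None = None,
) -> CellSummary:
    """Generate/fit ``replicates`` panels and aggregate the x coefficient."""
    _check_compatible(dgp_id, estimator_id)
    generate = GENERATORS[dgp_id]
    fit = ESTIMATORS[estimator_id]
    estimates = np.empty(replicates)
    model_ses = np.empty(replicates)
    for r in range(replicates):
        panel = generate(params, seed=(base_seed, r))
        result = fit(panel)
        estimates[r] = result.x_coefficient
        model_ses[r] = result.x_std_error
    return CellSummary(
        dgp_id=dgp_id,
        parameter_name=parameter_name,
        parameter_value=parameter_value,
        estimator_id=estimator_id,
        mean_estimate=float(estimates.mean()),
        empirical_sd=float(estimates.std(ddof=1)) if replicates > 1 else 0.0,
        mean_model_se=float(model_ses.mean()),
        replicates=replicates,
    )


def run_grid(spec: GridSpec) -> list[CellSummary]:
    """Run every (grid value, estimator) cell of an experiment.

    Cells are returned ordered by (parameter value, estimator order in the
    spec) and are individually reproducible from ``spec.base_seed``.
    """
    for est in spec.estimator_ids:
        _check_compatible(spec.dgp_id, est)
    out: list[CellSummary] = []
    for value in spec.grid:
        params = spec.base_params.with_(**{spec.varied_parameter: value})
        for est in spec.estimator_ids:
            try:
                cell = run_cell(
                    spec.dgp_id, params, est, spec.replicates, spec.base_seed
                )
            except Exception as exc:  # annotate with cell context
                raise type(exc)(
                    f"cell ({spec.varied_parameter}={value}, {est}): {exc}"
                ) from exc
            out.append(
                CellSummary(
                    dgp_id=cell.dgp_id,
                    parameter_name=spec.varied_parameter,
                    parameter_value=float(value),
                    estimator_id=est,
                    mean_estimate=cell.mean_estimate,
                    empirical_sd=cell.empirical_sd,
                    mean_model_se=cell.mean_model_se,
                    replicates=cell.replicates,
                )
            )
    return out


def summaries_to_frame(
    cells: Sequence[CellSummary],
    include_oracle: bool = False,
    base_params: DGPParams | None = None,
) -> pd.DataFrame:
    """Tabulate cell summaries, optionally with the analytic limit column."""
    rows = []
    for c in cells:
        row = {
            "dgp": c.dgp_id,
            "parameter_name": c.parameter_name,
            "parameter_value": c.parameter_value,
            "estimator": c.estimator_id,
            "mean_estimate": c.mean_estimate,
            "empirical_sd": c.empirical_sd,
            "mean_model_se": c.mean_model_se,
            "replicates": c.replicates,
        }
        if include_oracle:
            row["oracle_plim"] = c.oracle_plim(base_params)
        rows.append(row)
    return pd.DataFrame(rows)
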