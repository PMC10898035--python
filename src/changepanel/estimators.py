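"""The four analysis models compared throughout the package.

Each model is an ordinary least-squares regression with one row per
individual, built from the observable panel columns only:

* ``concurrent_cc``   — outcome change on exposure change over the same
  interval (the first-difference fixed-effects estimator).
* ``change_score``    — outcome change on *baseline* exposure and covariate.
* ``lagged_cc``       — later outcome change on the previous interval's
  exposure change (lagged first difference; needs three waves).
* ``cross_sectional`` — outcome level on exposure level within one wave.

``fit_ols`` is the shared closed-form core: coefficients solve the normal
equations, standard errors are the classical homoskedastic ones with the
residual variance on ``rows - columns`` degrees of freedom.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .dgp import PanelData
from .errors import (
    InsufficientDataError,
    InsufficientWavesError,
    SingularDesignError,
)

__all__ = [
    "FitResult",
    "fit_ols",
    "concurrent_change_change",
    "change_score",
    "lagged_change_change",
    "cross_sectional",
    "ESTIMATORS",
]

#: Canonical term names, shared by all four models.
INTERCEPT, X_TERM, Z_TERM = "intercept", "x", "z"


@dataclass(frozen=True)
class FitResult:
    """Coefficients and classical standard errors of one fitted model."""

    model_id: str
    coefficients: dict[str, float]
    std_errors: dict[str, float]
    n_used: int
    waves_used: frozenset[int] = field(default_factory=frozenset)

    @property
    def x_coefficient(self) -> float:
        return self.coefficients[X_TERM]

    @property
    def x_std_error(self) -> float:
        return self.std_errors[X_TERM]

    def to_record(self) -> str:
        """Flat ``key = value`` text serialization."""
        lines = [f"model = {self.model_id}", f"n_used = {self.n_used}"]
        lines.append(
            "waves_used = " + ",".join(str(w) for w in sorted(self.waves_used))
        )
        for term, value in self.coefficients.items():
            lines.append(f"coef.{term} = {value!r}")
        for term, value in self.std_errors.items():
            lines.append(f"se.{term} = {value!r}")
        return "\n".join(lines) + "\n"


def fit_ols(
    response: np.ndarray,
    design: np.ndarray,
    term_names: Sequence[str],
    model_id: str = "ols",
    waves_used: Sequence[int] = (),
) -> FitResult:
    """Least squares with classical standard errors.

    ``design`` carries the intercept column explicitly (by convention the
    leading column).  Raises :class:`SingularDesignError` on rank-deficient
    designs and :class:`InsufficientDataError` when there are fewer rows than
    columns.
    """
    y = np.asarray(response, dtype=float).ravel()
    X = np.atleast_2d(np.asarray(design, dtype=float))
    n, k = X.shape
    if len(term_names) != k:
        raise ValueError(f"{k} design columns but {len(term_names)} term names")
    if n < k:
        raise InsufficientDataError(
            f"{n} observations cannot identify {k} coefficients"
        )
    q, r = np.linalg.qr(X)
    diag = np.abs(np.diag(r))
    tol = max(n, k) * np.finfo(float).eps * (diag.max() if k else 0.0)
    if k and (diag <= tol).any():
        bad = [term_names[j] for j in np.flatnonzero(diag <= tol)]
        raise SingularDesignError(f"collinear design; offending terms: {bad}")
    beta = np.linalg.solve(r, q.T @ y)
    resid = y - X @ beta
    if n > k:
        sigma2 = float(resid @ resid) / (n - k)
    else:
        sigma2 = 0.0
    rinv = np.linalg.inv(r)
    se = np.sqrt(sigma2 * np.sum(rinv * rinv, axis=1))
    return FitResult(
        model_id=model_id,
        coefficients={t: float(b) for t, b in zip(term_names, beta)},
        std_errors={t: float(s) for t, s in zip(term_names, se)},
        n_used=n,
        waves_used=frozenset(int(w) for w in waves_used),
    )


def _as_panel(panel) -> PanelData:
    if isinstance(panel, PanelData):
        return panel
    if isinstance(panel, pd.DataFrame):
        return PanelData.from_frame(panel)
    raise TypeError(f"expected PanelData or DataFrame, got {type(panel).__name__}")


def _design(*columns: np.ndarray) -> np.ndarray:
    cols = [np.ones_like(columns[0]), *columns]
    return np.column_stack(cols)


def concurrent_change_change(
    panel, later_wave: int = 1, earlier_wave: int = 0
) -> FitResult:
    """Regress the outcome change on the contemporaneous exposure change.

    ``y_l - y_e ~ 1 + (x_l - x_e) + (z_l - z_e)`` across individuals.  The
    x-term estimates the contemporaneous effect; differencing removes every
    individual-constant term, so the estimate is invariant to time-invariant
    confounding.  The intercept estimates the common time-effect contrast
    between the two waves.
    """
    p = _as_panel(panel)
    if later_wave <= earlier_wave:
        raise ValueError(
            f"later_wave ({later_wave}) must exceed earlier_wave ({earlier_wave})"
        )
    l, e = p.require_wave(later_wave), p.require_wave(earlier_wave)
    dy = p.y[:, l] - p.y[:, e]
    dx = p.x[:, l] - p.x[:, e]
    dz = p.z[:, l] - p.z[:, e]
    return fit_ols(
        dy,
        _design(dx, dz),
        (INTERCEPT, X_TERM, Z_TERM),
        model_id="concurrent_cc",
        waves_used=(e, l),
    )


def change_score(panel) -> FitResult:
    """Regress the wave-1 minus wave-0 outcome change on *baseline* levels.

    ``y1 - y0 ~ 1 + x0 + z0``.  Mirrors the common cohort practice of
    relating baseline exposure to subsequent marker change.
    """
    p = _as_panel(panel)
    p.require_wave(0), p.require_wave(1)
    dy = p.y[:, 1] - p.y[:, 0]
    return fit_ols(
        dy,
        _design(p.x[:, 0], p.z[:, 0]),
        (INTERCEPT, X_TERM, Z_TERM),
        model_id="change_score",
        waves_used=(0, 1),
    )


def lagged_change_change(panel) -> FitResult:
    """Regress the later outcome change on the earlier exposure change.

    ``y2 - y1 ~ 1 + (x1 - x0) + (z1 - z0)``; requires three waves.
    """
    p = _as_panel(panel)
    if p.waves < 3:
        raise InsufficientWavesError(
            f"lagged change-change analysis needs 3 waves, panel has {p.waves}"
        )
    dy = p.y[:, 2] - p.y[:, 1]
    dx = p.x[:, 1] - p.x[:, 0]
    dz = p.z[:, 1] - p.z[:, 0]
    return fit_ols(
        dy,
        _design(dx, dz),
        (INTERCEPT, X_TERM, Z_TERM),
        model_id="lagged_cc",
        waves_used=(0, 1, 2),
    )


def cross_sectional(panel, wave: int = 0) -> FitResult:
    """Regress the outcome level on the exposure level within one wave.

    ``y_w ~ 1 + x_w + z_w``.  Consistent for the contemporaneous effect only
    when there is no unobserved confounding.
    """
    p = _as_panel(panel)
    w = p.require_wave(wave)
    return fit_ols(
        p.y[:, w],
        _design(p.x[:, w], p.z[:, w]),
        (INTERCEPT, X_TERM, Z_TERM),
        model_id="cross_sectional",
        waves_used=(w,),
    )


#: Registry keyed by model id, used by the Monte Carlo engine and CLI.
ESTIMATORS = {
    "concurrent_cc": concurrent_change_change,
    "change_score": change_score,
    "lagged_cc": lagged_change_change,
    "cross_sectional": cross_sectional,
}
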