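"""Closed-form probability limits of the exposure coefficient.

For each supported (estimator, data-generating process) pair this module
returns the value the estimated exposure coefficient converges to as the
number of individuals grows.  The formulas follow from covariance algebra on
the linear generating models; each is validated in the test suite against a
single very large simulated fit before the Monte Carlo grids rely on it.

With sigma_u = sd_u, sigma_nu = sd_nu, sigma_lam = sd_lambda_it:

===================  ==============  =============================================
estimator            process         probability limit of the x coefficient
===================  ==============  =============================================
concurrent_cc        baseline        beta
cross_sectional      baseline        beta + theta*sigma_u^2 / (theta^2*sigma_u^2 + sigma_nu^2)
change_score         baseline        -beta*sigma_nu^2 / (theta^2*sigma_u^2 + sigma_nu^2)
lagged_cc            baseline        -beta / 2
concurrent_cc        se_violation    beta * (1 - rho/2)
concurrent_cc        ct_violation    beta + omega*sigma_lam^2 / (sigma_lam^2 + sigma_nu^2)
===================  ==============  =============================================

At unit variances these reduce to ``beta``, ``beta + theta/(theta^2+1)``,
``-beta/(theta^2+1)``, ``-beta/2``, ``beta(1-rho/2)`` and ``beta + omega/2``.

Sketch of the derivations (unit-variance case, beta/gamma/delta free):

* Differencing removes ``u`` entirely, so the concurrent first-difference
  regression recovers ``beta`` exactly under the baseline process.
* Cross-sectional: partialling ``z`` out of ``x`` leaves ``theta*u + nu``;
  ``u`` loads on ``y`` with coefficient 1, giving the omitted-variable term
  ``theta*sigma_u^2 / (theta^2 sigma_u^2 + sigma_nu^2)``.
* Change-score: ``Cov(y1 - y0, x0)`` is dominated by the ``-Var(x0)`` term;
  solving the 2x2 normal equations collapses to ``-beta sigma_nu^2 /
  (theta^2 sigma_u^2 + sigma_nu^2)`` — the gamma and delta terms cancel.
* Lagged: the covariance vector of ``(dy2, (dx1, dz1))`` equals ``-1/2``
  times the regressor covariance matrix applied to ``(beta, gamma)``, hence
  the slope ``-beta/2`` for any confounding strength.
* Lagged-outcome feed-forward adds ``rho * (y0 - y_init)`` to the outcome
  difference; its projection on the regressors contributes ``-rho*beta/2``.
* A shared individual time-varying term adds ``omega * dlambda`` to the
  outcome difference while ``dlambda + dnu`` is the part of ``dx`` orthogonal
  to ``dz``, contributing ``omega*sigma_lam^2/(sigma_lam^2 + sigma_nu^2)``.
"""

from __future__ import annotations

from .dgp import DGPParams
from .errors import UnsupportedCombinationError

__all__ = ["expected_probability_limit", "SUPPORTED_COMBINATIONS"]


def _plim_concurrent_baseline(p: DGPParams) -> float:
    return p.beta


def _plim_cross_sectional_baseline(p: DGPParams) -> float:
    var_u, var_nu = p.sd_u**2, p.sd_nu**2
    return p.beta + p.u_effect_on_y * p.theta * var_u / (
        p.theta**2 * var_u + var_nu
    )


def _plim_change_score_baseline(p: DGPParams) -> float:
    var_u, var_nu = p.sd_u**2, p.sd_nu**2
    return -p.beta * var_nu / (p.theta**2 * var_u + var_nu)


def _plim_lagged_baseline(p: DGPParams) -> float:
    return -p.beta / 2.0


def _plim_concurrent_se(p: DGPParams) -> float:
    return p.beta * (1.0 - p.rho / 2.0)


def _plim_concurrent_ct(p: DGPParams) -> float:
    var_lam, var_nu = p.sd_lambda_it**2, p.sd_nu**2
    return p.beta + p.omega * var_lam / (var_lam + var_nu)


_PLIMS = {
    ("concurrent_cc", "baseline"): _plim_concurrent_baseline,
    ("cross_sectional", "baseline"): _plim_cross_sectional_baseline,
    ("change_score", "baseline"): _plim_change_score_baseline,
    ("lagged_cc", "baseline"): _plim_lagged_baseline,
    ("concurrent_cc", "se_violation"): _plim_concurrent_se,
    ("concurrent_cc", "ct_violation"): _plim_concurrent_ct,
}

SUPPORTED_COMBINATIONS = frozenset(_PLIMS)


def expected_probability_limit(
    estimator_id: str, dgp_id: str, params: DGPParams
) -> float:
    """Large-sample limit of the x coefficient for the given cell.

    Raises :class:`UnsupportedCombinationError` for pairs with no derived
    closed form (e.g. change-score under the common-trend violation).
    """
    try:
        formula = _PLIMS[(estimator_id, dgp_id)]
    except KeyError:
        raise UnsupportedCombinationError(
            f"no probability limit implemented for estimator "
            f"{estimator_id!r} under process {dgp_id!r}"
        ) from None
    return float(formula(params))
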