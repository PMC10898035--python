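"""Exact DAG analysis of what each model estimates at infinite data.

Builds the three-wave panel DAG (per wave: Z->X, Z->Y, X->Y, and the
unobserved U into every X and Y), computes total causal effects of each
exposure on the outcome changes by path tracing, evaluates the population
regression of each analysis model on the implied moments, and enumerates
the backdoor paths from X0 to the first outcome change with their
d-separation status under the concurrent model's conditioning set.
"""

from changepanel import (
    DGPParams,
    build_panel_sem,
    enumerate_noncausal_paths,
    outcome_change,
    regression_from_covariance,
    total_effect,
)
from changepanel.experiments import outcome_contrast

sem = build_panel_sem(DGPParams(theta=1.0), waves=3)
dy1, dy2 = outcome_change(1), outcome_change(2)

print("total causal effects (sum over directed paths):")
for cause, effect in [("X0", dy1), ("X0", dy2), ("X1", dy2), ("X0", "Y0")]:
    label = effect if isinstance(effect, str) else effect.name
    print(f"  {cause} -> {label}: {total_effect(sem, cause, effect):+.1f}")

print("\npopulation regressions on the implied covariance (infinite data):")
models = {
    "concurrent_cc": (dy1, [outcome_contrast("X", 1), outcome_contrast("Z", 1)]),
    "change_score": (dy1, ["X0", "Z0"]),
    "lagged_cc": (dy2, [outcome_contrast("X", 1), outcome_contrast("Z", 1)]),
}
for model_id, (response, regressors) in models.items():
    coefs = regression_from_covariance(sem, response, regressors)
    pretty = ", ".join(f"{k}={v:+.3f}" for k, v in coefs.items())
    print(f"  {model_id:14s} {pretty}")

print("\nbackdoor paths X0 -> dY1 given {Z0, X1, Z1}:")
for path in enumerate_noncausal_paths(sem, "X0", dy1, {"Z0", "X1", "Z1"}):
    status = "OPEN   " if path.is_open else "blocked"
    print(f"  [{status}] {path}")

print(
    "\nThe concurrent model recovers the structural coefficients exactly"
    "\n(x-term +1.000 = beta, intercept +0.500 = the time-effect contrast);"
    "\nthe two open U-paths into Y0 and Y1 carry equal and opposite"
    "\nconfounding and cancel.  The change-score x-term (-0.500 at theta=1)"
    "\nis neither beta nor -beta, and the lagged model is pinned at -beta/2."
)
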