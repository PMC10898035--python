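"""Generate one synthetic marker panel and fit all four analysis models.

Builds a three-wave balanced panel (n=1000) with strong time-invariant
confounding (theta=1), fits the concurrent change-change, cross-sectional,
change-score and lagged change-change regressions, and prints each exposure
coefficient next to its analytic large-sample limit.
"""

from changepanel import (
    DGPParams,
    change_score,
    concurrent_change_change,
    cross_sectional,
    expected_probability_limit,
    generate_baseline_panel,
    lagged_change_change,
)

params = DGPParams(theta=1.0, n=1000, waves=3)
panel = generate_baseline_panel(params, seed=7)
print(f"panel: {panel.n} individuals x {panel.waves} waves; true effect beta = 1\n")

fits = {
    "concurrent_cc": concurrent_change_change(panel),
    "cross_sectional": cross_sectional(panel, wave=0),
    "change_score": change_score(panel),
    "lagged_cc": lagged_change_change(panel),
}
print(f"{'model':18s} {'estimate':>9s} {'model SE':>9s} {'plim':>7s}")
for model_id, fit in fits.items():
    plim = expected_probability_limit(model_id, "baseline", params)
    print(
        f"{model_id:18s} {fit.x_coefficient:9.3f} "
        f"{fit.x_std_error:9.3f} {plim:7.2f}"
    )

print(
    "\nOnly the concurrent change-change estimate sits on the true effect 1.0:"
    "\ndifferencing removes the individual heterogeneity u, while the"
    "\ncross-sectional fit absorbs it (bias +0.5 at theta=1) and the"
    "\nchange-score / lagged models estimate a different, sign-flipped estimand."
)
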