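"""Bias of the concurrent change-change model when its assumptions fail.

Two-wave panels, 200 replicates per cell.  First sweep: the previous
outcome feeds forward into the current one with coefficient rho (strict
exogeneity broken).  Second sweep: an unobserved individual time-varying
term enters the exposure and, scaled by omega, the outcome (common trends
broken).  The analytic probability limits are printed alongside.
"""

import numpy as np

from changepanel import DGPParams, GridSpec, run_grid, summaries_to_frame

for name, dgp_id, parameter, grid in [
    ("feed-forward (rho)", "se_violation", "rho", np.arange(0.0, 1.01, 0.25)),
    ("heterogeneous trend (omega)", "ct_violation", "omega", np.arange(-1.0, 1.01, 0.5)),
]:
    spec = GridSpec(
        dgp_id=dgp_id,
        varied_parameter=parameter,
        grid=tuple(np.round(grid, 10)),
        estimator_ids=("concurrent_cc",),
        replicates=200,
        base_params=DGPParams(theta=1.0, waves=2),
        base_seed=0,
    )
    table = summaries_to_frame(run_grid(spec), include_oracle=True)
    print(f"\n{name}:")
    print(
        table[["parameter_value", "mean_estimate", "empirical_sd", "oracle_plim"]]
        .round(3)
        .to_string(index=False)
    )

print(
    "\nThe true effect is 1.0 in both settings.  Bias grows linearly with the"
    "\nviolation: the estimate falls to ~0.5 at rho=1 (plim 1 - rho/2) and"
    "\nruns from ~0.5 to ~1.5 across omega (plim 1 + omega/2)."
)
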