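"""Monte Carlo sweep of confounding strength for the four analysis models.

Reproduces the central bias comparison at reduced cost (200 replicates per
cell instead of 1000): mean exposure-coefficient estimates over replicated
n=1000 panels, as the loading theta of the unobserved heterogeneity on the
exposure grows from 0 to 1.
"""

import numpy as np

from changepanel import DGPParams, GridSpec, run_grid, summaries_to_frame

spec = GridSpec(
    dgp_id="baseline",
    varied_parameter="theta",
    grid=tuple(np.round(np.arange(0.0, 1.01, 0.2), 10)),
    estimator_ids=("concurrent_cc", "cross_sectional", "change_score", "lagged_cc"),
    replicates=200,
    base_params=DGPParams(waves=3),
    base_seed=0,
)
cells = run_grid(spec)
table = summaries_to_frame(cells, include_oracle=True)
print(
    table.pivot(index="parameter_value", columns="estimator", values="mean_estimate")
    .round(3)
    .to_string()
)

print(
    "\nEach column is the mean estimate over 200 replicates; the true effect"
    "\nis 1.0.  Concurrent change-change stays unbiased at every theta;"
    "\ncross-sectional bias climbs to ~1.5; change-score moves from ~-1.0 to"
    "\n~-0.5; lagged change-change stays near -0.5 regardless of theta."
)
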