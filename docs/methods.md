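# Methods

## The structural model

All generators and exact results derive from one linear panel model for a
continuous marker `y`, a continuous exposure `x` and an observed
time-varying covariate `z`, measured on `n` individuals over 2–3 waves:

    x_it = δ z_it + θ u_i + ν_it
    y_it = β x_it + γ z_it + u_i + λ_t + ε_it

`u_i` is unobserved time-invariant heterogeneity that loads on the exposure
with strength θ (the confounding dial) and on the outcome with a fixed unit
loading; `λ_t` are common time effects; `z, u, ν, ε` are independent
Gaussians.  Defaults follow the canonical setting β = γ = 1, δ = 0.5,
λ = (0.5, 1, 1.5), all standard deviations 1, n = 1000, three waves.  The
`sd_*` fields of `DGPParams` exist to support property tests and
extensions; the shipped experiments never move them.

Two violation processes perturb exactly one assumption each, on two-wave
panels with θ = 1:

* **Strict-exogeneity violation** adds `ρ · y_{i,t−1}` to the outcome
  equation, with a pre-sample outcome `y_{i,−1} = u_i + ε_{i,−1}`.  The
  common time effects λ₀ = 0.5, λ₁ = 1 are retained.
* **Common-trend violation** replaces the common λ_t with an individual
  iid standard-normal term `λ_it` entering the exposure with unit loading
  and the outcome with loading ω.  The printed equations of this process
  contain no common time effect on top of `λ_it`, and the generator follows
  them literally.

Latent draws (`u`, `λ_it`, `y_init`) are retained on `PanelData` for
diagnostics but live outside the observable table; the estimator layer
rejects any input table carrying latent-named columns, so oracle
information can never leak into a fit.

Seeding is counter-based: replicate `r` of a Monte Carlo cell uses the
numpy seed sequence `(base_seed, r)`.  Cells are therefore bit-reproducible
in isolation, identical under re-ordering or parallelisation, and two
different cells of a grid share replicate seeds (common random numbers),
which slightly smooths bias curves without affecting any marginal result.

## Estimators

All four analysis models are ordinary least squares with an intercept and
one row per individual; coefficients solve the normal equations via QR and
standard errors are classical (homoskedastic, `n − k` denominator).
Cluster/robust variances are deliberately out of scope: each model already
collapses the panel to one row per individual, so there is nothing to
cluster over.  Differences are always later-minus-earlier; wave indexing is
0-based; the cross-sectional model defaults to wave 0.

Two identities anchor the implementation and are asserted to 1e-10 in the
tests: the two-wave first-difference fit equals the within (individually
demeaned, with demeaned wave indicator) fit, and the concurrent estimate is
invariant to adding an arbitrary per-individual constant to the outcome.

## Probability limits

The `oracle` module carries closed-form large-sample limits for the
exposure coefficient of every supported estimator × process pair, derived
by covariance algebra on the generating equations (the derivation sketches
live in the module docstring).  In the general-variance form:

| estimator / process | plim of the x coefficient |
|---|---|
| concurrent, baseline | β |
| cross-sectional, baseline | β + θσ_u² / (θ²σ_u² + σ_ν²) |
| change-score, baseline | −βσ_ν² / (θ²σ_u² + σ_ν²) |
| lagged, baseline | −β/2 |
| concurrent, feed-forward | β(1 − ρ/2) |
| concurrent, heterogeneous trend | β + ωσ_λ² / (σ_λ² + σ_ν²) |

Each formula is gated by an independent brute-force check — a single
generate-and-fit run at n = 10⁶ must agree within 0.01 — before the Monte
Carlo machinery treats it as ground truth.  The gate runs in the test
suite, including non-unit-variance settings that exercise the general
forms.  Combinations without a derived form (e.g. change-score under the
trend violation) raise rather than guess.

Notable consequences encoded in these formulas: the lagged change-change
limit −β/2 is free of θ (it removes heterogeneity but targets a mis-timed
estimand under the concurrent-effect model, and the difference constraint
pins its coefficient to an average of −β and 0); the change-score limit is
neither β nor −β whenever θ > 0.

## The SEM/DAG engine

`build_panel_sem` binds the panel DAG to the same parameter object: per
wave `Z_t→X_t` (δ), `Z_t→Y_t` (γ), `X_t→Y_t` (β), `U→X_t` (θ), `U→Y_t`
(1) — 15 edges on three waves, with λ_t entering as wave-specific outcome
means, so the SEM's implied law coincides with the baseline generator.
Implied moments use the standard identity Σ = (I−A)⁻¹Ψ(I−A)⁻ᵀ; total
effects are entries of (I−A)⁻¹ (the sum over directed paths of
edge-coefficient products); population regressions are solved on the
implied moments with contrasts (ΔY₁, ΔX₁, …) expanded as linear
functionals, and intercepts recovered from the implied means.

Backdoor-path enumeration walks all simple paths in the graph skeleton,
keeps those whose first edge points into the cause, and labels each
open/blocked by the d-separation rules (a conditioned non-collider blocks;
a collider blocks unless it or a descendant is conditioned).  A contrast
target is grafted onto the graph as a child of both of its components.
For X₀ → ΔY₁ under the concurrent conditioning set {Z₀, X₁, Z₁} this
yields eight simple noncausal paths: the five canonical ones (the Z₀ path
blocked, the two U-paths into Y₀ and Y₁ open but mutually cancelling, the
mediated U→X₁ path blocked by conditioning on X₁, and the collider path
re-blocked by Z₁) plus three longer paths blocked at the collider Y₀.  The
enumerator reports all of them with status labels rather than asserting a
count of five; a brute-force DFS over the skeleton serves as the test
oracle for completeness.

One subtlety the exact engine makes visible: the offsetting of the two
open U-paths is a property of the *coefficient of X₀ in the unconstrained
regression* of ΔY₁ on (X₀, X₁, Z₀, Z₁) — exactly −β for any equal pair of
U→Y loadings, departing once the loadings differ.  The constrained
difference regression of ΔY₁ on (ΔX₁, ΔZ₁) is immune even to unequal
loadings, because U cancels inside ΔX₁ itself when its loadings on X₀ and
X₁ are equal.  Both facts are asserted in the tests.

## Monte Carlo experiments and problem sizes

The three shipped experiments mirror the study design: a θ-grid
(0…1 by 0.1) over all four estimators on the baseline process, and ρ- and
ω-grids (0…1 by 0.1 and −1…1 by 0.2, θ = 1) for the concurrent estimator
on the violation processes — 1000 replicates of n = 1000 panels per cell
throughout.  At these sizes the full θ-grid takes roughly 15 s and either
violation grid a few seconds on one CPU; the acceptance script, which
recomputes only the headline cells, runs in ~3 s.  Example scripts use 200
replicates per cell to stay instant while remaining within ~0.004 of the
1000-replicate means.

Per cell the engine reports both the empirical SD of the estimates and the
mean of the model-based SEs; the summary phrase "standard errors" is
ambiguous between the two, so both columns are always emitted.  Experiment
CSVs round to three decimals (the precision at which such results are
conventionally reported); the exact `sem_checks` table keeps full
precision.  Manifest files carry the run timestamp so CSV bodies remain
byte-identical across re-runs.

## What the generators do and do not emulate

The synthetic panels reproduce the *structure* that drives estimator bias —
linear effects, Gaussian errors, a single time-invariant confounder, exact
balance, no missingness — and deliberately nothing else.  Real cohort data
add measurement error in diet instruments, skewed and heteroskedastic
markers, attrition, unbalanced waves and effect heterogeneity, none of
which are modelled.  Passing tests therefore demonstrate that each
estimator converges to its analytic limit under its stated causal model,
i.e. that bias of the documented magnitude and direction *must* appear
whenever these mechanisms operate; they do not quantify bias magnitudes
for any particular real study.

## Numerical choices and degenerate inputs

OLS uses QR with a rank tolerance of `max(n,k)·eps·max|diag R|`;
rank-deficient designs raise with the offending terms named, as do designs
with fewer rows than columns.  Implied covariance matrices are symmetrised
(`(Σ+Σᵀ)/2`) against floating-point drift and tested for eigenvalues
≥ −1e-10.  Grid values are rounded to 10 decimals when constructed from
`arange` so that cell keys compare exactly.  Panel tables must be balanced
with waves labelled 0…W−1; anything else is a configuration error, not a
silent repair.

## Known limitations

No dynamic-panel estimation (instrumental variables / GMM for the
feed-forward process), no individual-slope fixed effects for the trend
violation, no unbalanced panels, no robust or clustered variances, and no
latent-projection (ADMG) machinery in the DAG engine — path queries operate
on the fully specified graph including U.
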