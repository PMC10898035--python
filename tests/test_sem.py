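"""Linear-SEM engine: implied moments, path tracing, population regressions
and backdoor-path bookkeeping on the three-wave panel DAG."""

import numpy as np
import pytest

from changepanel import (
    DGPParams,
    DerivedContrast,
    LinearSEM,
    build_panel_sem,
    enumerate_noncausal_paths,
    fit_ols,
    implied_covariance,
    implied_means,
    outcome_change,
    regression_from_covariance,
    simulate_sem,
    total_effect,
)
from changepanel.errors import ConfigurationError, SingularDesignError
from changepanel.experiments import outcome_contrast


@pytest.fixture(scope="module")
def sem():
    return build_panel_sem(DGPParams(theta=1.0), waves=3)


class TestConstruction:
    def test_three_wave_dag_has_five_edges_per_wave(self, sem):
        assert len(sem.edges) == 15
        assert set(sem.variables) == {
            "U",
            *(f"{p}{t}" for p in "XYZ" for t in range(3)),
        }

    def test_cycle_rejected(self):
        with pytest.raises(ConfigurationError, match="cycle"):
            LinearSEM(("A", "B"), {("A", "B"): 1.0, ("B", "A"): 1.0}, {"A": 1, "B": 1})

    def test_missing_variance_rejected(self):
        with pytest.raises(ConfigurationError, match="variance"):
            LinearSEM(("A", "B"), {("A", "B"): 1.0}, {"A": 1.0})

    def test_text_roundtrip(self, sem):
        back = LinearSEM.from_text(sem.to_text())
        assert back == sem


class TestImpliedMoments:
    def test_no_edges_gives_diagonal(self):
        m = LinearSEM(("A", "B"), {}, {"A": 2.0, "B": 3.0})
        np.testing.assert_allclose(
            implied_covariance(m).to_numpy(), np.diag([2.0, 3.0])
        )

    def test_single_edge_hand_algebra(self):
        m = LinearSEM(("X", "Y"), {("X", "Y"): 2.0}, {"X": 1.0, "Y": 1.0})
        sigma = implied_covariance(m)
        assert sigma.loc["Y", "Y"] == pytest.approx(5.0)  # beta^2 + 1
        assert sigma.loc["X", "Y"] == pytest.approx(2.0)  # beta

    def test_panel_dag_key_entries(self, sem):
        sigma = implied_covariance(sem)
        # Var(X0) = delta^2 + theta^2 + 1
        assert sigma.loc["X0", "X0"] == pytest.approx(2.25)
        # Cov(X0, Y0) = beta Var(X0) + gamma delta + theta
        assert sigma.loc["X0", "Y0"] == pytest.approx(3.75)
        # cross-wave exposure correlation flows only through U
        assert sigma.loc["X0", "X1"] == pytest.approx(1.0)

    def test_removing_u_disconnects_waves(self):
        sem0 = build_panel_sem(DGPParams(theta=0.0, u_effect_on_y=0.0), waves=3)
        sigma = implied_covariance(sem0)
        assert sigma.loc["X0", "X1"] == pytest.approx(0.0)
        assert sigma.loc["Y0", "Y1"] == pytest.approx(0.0)

    def test_symmetric_positive_semidefinite(self, sem):
        sigma = implied_covariance(sem).to_numpy()
        np.testing.assert_allclose(sigma, sigma.T)
        assert np.linalg.eigvalsh(sigma).min() >= -1e-10

    def test_wave_means_are_the_time_effects(self, sem):
        mu = implied_means(sem)
        # E[Y_t] = lambda_t + beta*theta*0 ... all parent means are zero
        np.testing.assert_allclose(
            mu[["Y0", "Y1", "Y2"]], [0.5, 1.0, 1.5], atol=1e-12
        )
        assert mu["X0"] == 0.0

    def test_implied_moments_match_topological_simulation(self, sem):
        n = 200_000
        data = simulate_sem(sem, n, seed=17)
        sample = np.cov(data.to_numpy().T)
        sigma = implied_covariance(sem).to_numpy()
        # entrywise 3-standard-error band for a sample covariance
        se = np.sqrt(
            (np.outer(np.diag(sigma), np.diag(sigma)) + sigma**2) / n
        )
        assert (np.abs(sample - sigma) < 3.2 * se).all()
        np.testing.assert_allclose(
            data.mean(), implied_means(sem), atol=4 * np.sqrt(sigma.max() / n)
        )


class TestTotalEffects:
    @pytest.mark.parametrize("beta", [1.0, 2.0])
    def test_effects_on_outcome_changes(self, beta):
        sem = build_panel_sem(DGPParams(beta=beta, theta=1.0), waves=3)
        assert total_effect(sem, "X0", outcome_change(1)) == pytest.approx(-beta)
        assert total_effect(sem, "X0", outcome_change(2)) == pytest.approx(0.0)
        assert total_effect(sem, "X1", outcome_change(2)) == pytest.approx(-beta)
        assert total_effect(sem, "X0", "Y0") == pytest.approx(beta)

    def test_unknown_variable_raises(self, sem):
        with pytest.raises(KeyError):
            total_effect(sem, "X9", "Y0")


class TestPopulationRegressions:
    def test_concurrent_model_recovers_structural_coefficients(self, sem):
        coefs = regression_from_covariance(
            sem, outcome_change(1), [outcome_contrast("X", 1), outcome_contrast("Z", 1)]
        )
        assert coefs["dX1"] == pytest.approx(1.0, abs=1e-12)
        assert coefs["dZ1"] == pytest.approx(1.0, abs=1e-12)
        assert coefs["intercept"] == pytest.approx(0.5, abs=1e-12)  # lambda1-lambda0

    def test_change_score_model_is_neither_beta_nor_minus_beta(self):
        for theta in (0.5, 1.0):
            sem = build_panel_sem(DGPParams(theta=theta), waves=3)
            coefs = regression_from_covariance(sem, outcome_change(1), ["X0", "Z0"])
            assert coefs["X0"] == pytest.approx(-1.0 / (theta**2 + 1.0), abs=1e-12)
            assert coefs["X0"] != pytest.approx(1.0, abs=0.1)
            assert coefs["X0"] != pytest.approx(-1.0, abs=0.1)

    def test_lagged_model_halves_and_flips_the_effect(self, sem):
        coefs = regression_from_covariance(
            sem, outcome_change(2), [outcome_contrast("X", 1), outcome_contrast("Z", 1)]
        )
        assert coefs["dX1"] == pytest.approx(-0.5, abs=1e-12)

    def test_matches_least_squares_on_simulated_data(self, sem):
        n = 1_000_000
        data = simulate_sem(sem, n, seed=23)
        cases = [
            (
                data["Y1"] - data["Y0"],
                [data["X1"] - data["X0"], data["Z1"] - data["Z0"]],
                regression_from_covariance(
                    sem,
                    outcome_change(1),
                    [outcome_contrast("X", 1), outcome_contrast("Z", 1)],
                ),
            ),
            (
                data["Y1"] - data["Y0"],
                [data["X0"], data["Z0"]],
                regression_from_covariance(sem, outcome_change(1), ["X0", "Z0"]),
            ),
            (
                data["Y2"] - data["Y1"],
                [data["X1"] - data["X0"], data["Z1"] - data["Z0"]],
                regression_from_covariance(
                    sem,
                    outcome_change(2),
                    [outcome_contrast("X", 1), outcome_contrast("Z", 1)],
                ),
            ),
        ]
        for response, regressors, population in cases:
            design = np.column_stack([np.ones(n), *regressors])
            fit = fit_ols(response.to_numpy(), design, ("intercept", "a", "b"))
            values = list(population.values())
            np.testing.assert_allclose(
                list(fit.coefficients.values()), values, atol=0.01
            )

    def test_unequal_confounder_loadings_break_the_cancellation(self):
        """The backdoor paths through U into Y0 and into Y1 offset only when
        U loads equally on both outcomes.  The cancellation is visible on
        the coefficient of X0 in the unconstrained regression of the
        outcome change on all four wave-level regressors: exactly -beta for
        any equal loading, departing once the loadings differ."""
        base = build_panel_sem(DGPParams(theta=1.0), waves=3)

        def fit(load0, load1, constrained):
            edges = dict(base.edges)
            edges[("U", "Y0")] = load0
            edges[("U", "Y1")] = load1
            sem = LinearSEM(
                base.variables, edges, base.exogenous_variances, base.means
            )
            if constrained:
                return regression_from_covariance(
                    sem,
                    outcome_change(1),
                    [outcome_contrast("X", 1), outcome_contrast("Z", 1)],
                )["dX1"]
            return regression_from_covariance(
                sem, outcome_change(1), ["X0", "X1", "Z0", "Z1"]
            )["X0"]

        for load in (0.0, 0.7, 2.0):
            assert fit(load, load, constrained=False) == pytest.approx(
                -1.0, abs=1e-12
            )
            assert fit(load, load, constrained=True) == pytest.approx(
                1.0, abs=1e-12
            )
        assert abs(fit(1.0, 2.0, constrained=False) + 1.0) > 0.05
        # the constrained difference regression is immune even to unequal
        # loadings: U cancels inside the exposure difference itself
        assert fit(1.0, 2.0, constrained=True) == pytest.approx(1.0, abs=1e-12)

    def test_collinear_regressors_rejected(self, sem):
        with pytest.raises(SingularDesignError):
            regression_from_covariance(sem, "Y0", ["X0", "X0"])


def _brute_force_skeleton_paths(sem, cause, target, extra_edges=()):
    """Independent exhaustive DFS over simple paths in the skeleton."""
    directed = set(sem.edges) | set(extra_edges)
    neighbors: dict[str, set[str]] = {}
    for a, b in directed:
        neighbors.setdefault(a, set()).add(b)
        neighbors.setdefault(b, set()).add(a)
    out = []

    def walk(path):
        node = path[-1]
        if node == target:
            out.append(tuple(path))
            return
        for nxt in neighbors.get(node, ()):
            if nxt not in path:
                walk(path + [nxt])

    walk([cause])
    return out


class TestBackdoorPaths:
    def test_single_edge_dag_has_no_backdoor_paths(self):
        m = LinearSEM(("X", "Y"), {("X", "Y"): 1.0}, {"X": 1.0, "Y": 1.0})
        assert enumerate_noncausal_paths(m, "X", "Y") == []

    def test_the_five_documented_paths_and_their_statuses(self, sem):
        dy1 = outcome_change(1)
        paths = enumerate_noncausal_paths(sem, "X0", dy1, {"Z0", "X1", "Z1"})
        by_str = {str(p): p for p in paths}
        # confounding via the measured covariate: blocked by conditioning
        assert not by_str["X0 <- Z0 -> Y0 -> dY1"].is_open
        assert by_str["X0 <- Z0 -> Y0 -> dY1"].blocked_by == ("Z0",)
        # the two U paths into the change components stay open (they cancel
        # in the regression, but d-separation alone does not close them)
        assert by_str["X0 <- U -> Y0 -> dY1"].is_open
        assert by_str["X0 <- U -> Y1 -> dY1"].is_open
        # mediated through the later exposure: blocked by conditioning on X1
        assert not by_str["X0 <- U -> X1 -> Y1 -> dY1"].is_open
        assert "X1" in by_str["X0 <- U -> X1 -> Y1 -> dY1"].blocked_by
        # collider at X1 is opened by conditioning, then re-blocked by Z1
        p5 = by_str["X0 <- U -> X1 <- Z1 -> Y1 -> dY1"]
        assert p5.colliders == ("X1",)
        assert p5.opened_colliders == ("X1",)
        assert p5.blocked_by == ("Z1",)
        assert not p5.is_open

    def test_every_path_starts_with_an_arrow_into_the_cause(self, sem):
        for p in enumerate_noncausal_paths(sem, "X0", outcome_change(1)):
            assert p.arrows[0] == "<-"

    def test_path_set_matches_exhaustive_enumeration(self, sem):
        """The enumerator finds exactly the simple skeleton paths that start
        with an edge into the cause, per an independent DFS oracle."""
        dy1 = outcome_change(1)
        found = {p.nodes for p in enumerate_noncausal_paths(sem, "X0", dy1)}
        extra = (("Y0", "dY1"), ("Y1", "dY1"))
        brute = _brute_force_skeleton_paths(sem, "X0", "dY1", extra_edges=extra)
        directed = set(sem.edges) | set(extra)
        expected = {
            nodes
            for nodes in brute
            if (nodes[1], nodes[0]) in directed  # first edge points into X0
        }
        assert found == expected

    def test_conditioning_argument_errors(self, sem):
        dy1 = outcome_change(1)
        with pytest.raises(ValueError):
            enumerate_noncausal_paths(sem, "X0", dy1, {"X0"})
        with pytest.raises(KeyError):
            enumerate_noncausal_paths(sem, "X0", dy1, {"W9"})
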