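"""Linear structural equation model on a DAG, with path queries.

The three-wave panel DAG behind the change-analysis comparison has, per wave
``t``: ``Z_t -> X_t`` (delta), ``Z_t -> Y_t`` (gamma), ``X_t -> Y_t``
(beta), and an unobserved time-invariant node ``U`` pointing into every
``X_t`` (theta) and every ``Y_t`` (1).  There are no cross-wave arrows among
the observables — the only cross-wave connector is ``U``.

The module computes exact implied moments by the structural recursion,
total causal effects by path tracing, population regressions on the implied
moments (what each analysis model estimates at infinite data), and
enumerates noncausal (backdoor) paths with their d-separation status under a
conditioning set.  Outcome *changes* such as ``Y1 - Y0`` are handled as
derived contrasts: linear functionals of the SEM variables which, for path
queries, are grafted onto the graph as a child of both components.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence, Union

import networkx as nx
import numpy as np
import pandas as pd

from .dgp import DGPParams
from .errors import ConfigurationError, SingularDesignError

__all__ = [
    "LinearSEM",
    "DerivedContrast",
    "PathInfo",
    "build_panel_sem",
    "outcome_change",
    "implied_covariance",
    "implied_means",
    "simulate_sem",
    "total_effect",
    "regression_from_covariance",
    "enumerate_noncausal_paths",
]

Term = Union[str, "DerivedContrast"]


@dataclass(frozen=True)
class DerivedContrast:
    """A difference of two SEM variables, e.g. ``dY1 = Y1 - Y0``."""

    name: str
    positive: str
    negative: str


def outcome_change(wave: int) -> DerivedContrast:
    """The outcome change ending at ``wave``: ``Y{wave} - Y{wave-1}``."""
    if wave < 1:
        raise ValueError("outcome change needs wave >= 1")
    return DerivedContrast(f"dY{wave}", f"Y{wave}", f"Y{wave - 1}")


@dataclass(frozen=True)
class LinearSEM:
    """A DAG with linear edge coefficients, exogenous variances and means.

    ``edges`` maps ``(parent, child)`` to the path coefficient.  Every
    variable owns one exogenous disturbance with variance
    ``exogenous_variances[v]`` and mean ``means.get(v, 0)``; structural
    values are the disturbance plus the coefficient-weighted parents.
    """

    variables: tuple[str, ...]
    edges: Mapping[tuple[str, str], float]
    exogenous_variances: Mapping[str, float]
    means: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "variables", tuple(self.variables))
        object.__setattr__(self, "edges", dict(self.edges))
        object.__setattr__(self, "exogenous_variances", dict(self.exogenous_variances))
        object.__setattr__(self, "means", dict(self.means))
        known = set(self.variables)
        for parent, child in self.edges:
            if parent not in known or child not in known:
                raise ConfigurationError(
                    f"edge ({parent}, {child}) references unknown variables"
                )
        missing = [v for v in self.variables if v not in self.exogenous_variances]
        if missing:
            raise ConfigurationError(f"missing exogenous variances for {missing}")
        bad = [v for v, s2 in self.exogenous_variances.items() if not s2 > 0]
        if bad:
            raise ConfigurationError(f"non-positive exogenous variances for {bad}")
        if not nx.is_directed_acyclic_graph(self.graph()):
            raise ConfigurationError("edge set contains a cycle")

    def graph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.variables)
        g.add_edges_from(self.edges)
        return g

    def index(self, name: str) -> int:
        try:
            return self.variables.index(name)
        except ValueError:
            raise KeyError(f"unknown variable {name!r}") from None

    def coefficient_matrix(self) -> np.ndarray:
        """``A[child, parent]`` = edge coefficient; zero elsewhere."""
        k = len(self.variables)
        a = np.zeros((k, k))
        for (parent, child), coef in self.edges.items():
            a[self.index(child), self.index(parent)] = coef
        return a

    def total_effect_matrix(self) -> np.ndarray:
        """``T = (I - A)^-1``: sums of path products over all directed paths."""
        k = len(self.variables)
        return np.linalg.inv(np.eye(k) - self.coefficient_matrix())

    # ------------------------------------------------------------------ #
    # plain-text serialization                                           #
    # ------------------------------------------------------------------ #
    def to_text(self) -> str:
        lines = ["[variables]", " ".join(self.variables), "", "[edges]"]
        for (parent, child), coef in self.edges.items():
            lines.append(f"{parent} {child} {coef!r}")
        lines += ["", "[variances]"]
        for v in self.variables:
            lines.append(f"{v} {self.exogenous_variances[v]!r}")
        lines += ["", "[means]"]
        for v in self.variables:
            mean = self.means.get(v, 0.0)
            if mean:
                lines.append(f"{v} {mean!r}")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_text(cls, text: str) -> "LinearSEM":
        section = None
        variables: tuple[str, ...] = ()
        edges: dict[tuple[str, str], float] = {}
        variances: dict[str, float] = {}
        means: dict[str, float] = {}
        for raw in text.splitlines():
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if line.startswith("[") and line.endswith("]"):
                section = line[1:-1]
                continue
            parts = line.split()
            if section == "variables":
                variables = variables + tuple(parts)
            elif section == "edges":
                edges[(parts[0], parts[1])] = float(parts[2])
            elif section == "variances":
                variances[parts[0]] = float(parts[1])
            elif section == "means":
                means[parts[0]] = float(parts[1])
            else:
                raise ConfigurationError(f"line outside a known section: {raw!r}")
        return cls(variables, edges, variances, means)


def build_panel_sem(params: DGPParams, waves: int = 3) -> LinearSEM:
    """The panel DAG bound to the generating-model coefficients.

    Per wave: ``Z_t -> X_t`` (delta), ``Z_t -> Y_t`` (gamma), ``X_t -> Y_t``
    (beta), ``U -> X_t`` (theta), ``U -> Y_t`` (u_effect_on_y); the common
    time effects enter as wave-specific outcome means.  The implied law
    coincides with the baseline generating process at equal parameters.
    """
    if waves < 1:
        raise ConfigurationError("waves must be >= 1")
    if len(params.lambda_t) < waves:
        raise ConfigurationError(
            f"lambda_t needs at least {waves} entries, got {len(params.lambda_t)}"
        )
    variables = (
        ["U"]
        + [f"Z{t}" for t in range(waves)]
        + [f"X{t}" for t in range(waves)]
        + [f"Y{t}" for t in range(waves)]
    )
    edges: dict[tuple[str, str], float] = {}
    variances = {"U": params.sd_u**2}
    means: dict[str, float] = {}
    for t in range(waves):
        edges[(f"Z{t}", f"X{t}")] = params.delta
        edges[(f"Z{t}", f"Y{t}")] = params.gamma
        edges[(f"X{t}", f"Y{t}")] = params.beta
        edges[("U", f"X{t}")] = params.theta
        edges[("U", f"Y{t}")] = params.u_effect_on_y
        variances[f"Z{t}"] = params.sd_z**2
        variances[f"X{t}"] = params.sd_nu**2
        variances[f"Y{t}"] = params.sd_eps**2
        means[f"Y{t}"] = params.lambda_t[t]
    return LinearSEM(tuple(variables), edges, variances, means)


# ---------------------------------------------------------------------- #
# implied moments                                                        #
# ---------------------------------------------------------------------- #
def implied_covariance(sem: LinearSEM) -> pd.DataFrame:
    """Exact implied covariance matrix via the structural recursion.

    With ``A`` the coefficient matrix, ``Psi`` the diagonal of exogenous
    variances and ``T = (I - A)^-1``, the implied covariance is
    ``T Psi T'`` — symmetric positive semi-definite by construction.
    """
    t = sem.total_effect_matrix()
    psi = np.diag([sem.exogenous_variances[v] for v in sem.variables])
    sigma = t @ psi @ t.T
    sigma = (sigma + sigma.T) / 2.0
    return pd.DataFrame(sigma, index=sem.variables, columns=sem.variables)


def implied_means(sem: LinearSEM) -> pd.Series:
    t = sem.total_effect_matrix()
    m = np.array([sem.means.get(v, 0.0) for v in sem.variables])
    return pd.Series(t @ m, index=sem.variables)


def simulate_sem(sem: LinearSEM, n: int, seed) -> pd.DataFrame:
    """Draw ``n`` observations by sampling variables in topological order."""
    rng = np.random.default_rng(seed)
    values: dict[str, np.ndarray] = {}
    parents: dict[str, list[tuple[str, float]]] = {v: [] for v in sem.variables}
    for (parent, child), coef in sem.edges.items():
        parents[child].append((parent, coef))
    for v in nx.topological_sort(sem.graph()):
        total = rng.normal(
            sem.means.get(v, 0.0), np.sqrt(sem.exogenous_variances[v]), size=n
        )
        for parent, coef in parents[v]:
            total = total + coef * values[parent]
        values[v] = total
    return pd.DataFrame({v: values[v] for v in sem.variables})


# ---------------------------------------------------------------------- #
# effects and population regressions                                     #
# ---------------------------------------------------------------------- #
def _weights(sem: LinearSEM, term: Term) -> np.ndarray:
    """Linear-functional weights of a term over the SEM variables."""
    w = np.zeros(len(sem.variables))
    if isinstance(term, DerivedContrast):
        w[sem.index(term.positive)] += 1.0
        w[sem.index(term.negative)] -= 1.0
    else:
        w[sem.index(term)] = 1.0
    return w


def _term_name(term: Term) -> str:
    return term.name if isinstance(term, DerivedContrast) else term


def total_effect(sem: LinearSEM, cause: str, effect: Term) -> float:
    """Total causal effect: sum over directed paths of edge-coefficient
    products; for a contrast, the effect on the positive component minus the
    effect on the negative one."""
    t = sem.total_effect_matrix()
    w = _weights(sem, effect)
    value = float(w @ t[:, sem.index(cause)])
    if _term_name(effect) == cause:
        value -= 1.0  # exclude the empty path
    return value


def regression_from_covariance(
    sem_or_moments: LinearSEM | tuple[pd.DataFrame, pd.Series],
    response: Term,
    regressors: Sequence[Term],
) -> dict[str, float]:
    """Population least-squares coefficients from implied moments.

    Returns a map with an ``"intercept"`` entry (from the implied means) and
    one entry per regressor term.  Contrasts are expanded linearly.
    """
    if isinstance(sem_or_moments, LinearSEM):
        sigma = implied_covariance(sem_or_moments)
        mu = implied_means(sem_or_moments)
        sem = sem_or_moments
        index = {v: i for i, v in enumerate(sem.variables)}
    else:
        sigma, mu = sem_or_moments
        index = {v: i for i, v in enumerate(sigma.index)}

    def weights(term: Term) -> np.ndarray:
        w = np.zeros(len(index))
        if isinstance(term, DerivedContrast):
            w[index[term.positive]] += 1.0
            w[index[term.negative]] -= 1.0
        else:
            w[index[term]] = 1.0
        return w

    sig = sigma.to_numpy()
    means = mu.to_numpy()
    wy = weights(response)
    wr = np.array([weights(r) for r in regressors])
    s_rr = wr @ sig @ wr.T
    s_ry = wr @ sig @ wy
    if np.linalg.matrix_rank(s_rr) < len(regressors):
        raise SingularDesignError(
            f"collinear regressors: {[_term_name(r) for r in regressors]}"
        )
    slopes = np.linalg.solve(s_rr, s_ry)
    intercept = float(wy @ means - slopes @ (wr @ means))
    out = {"intercept": intercept}
    for term, slope in zip(regressors, slopes):
        out[_term_name(term)] = float(slope)
    return out


# ---------------------------------------------------------------------- #
# backdoor-path enumeration                                              #
# ---------------------------------------------------------------------- #
@dataclass(frozen=True)
class PathInfo:
    """One simple noncausal path with its d-separation status."""

    nodes: tuple[str, ...]
    arrows: tuple[str, ...]  # "->" or "<-" between consecutive nodes
    is_open: bool
    blocked_by: tuple[str, ...]  # conditioned non-colliders on the path
    colliders: tuple[str, ...]  # collider nodes on the path
    opened_colliders: tuple[str, ...]  # colliders unblocked by conditioning

    def __str__(self) -> str:
        parts = [self.nodes[0]]
        for arrow, node in zip(self.arrows, self.nodes[1:]):
            parts.append(arrow)
            parts.append(node)
        return " ".join(parts)


def _augmented_graph(sem: LinearSEM, effect: Term) -> tuple[nx.DiGraph, str]:
    g = sem.graph()
    if isinstance(effect, DerivedContrast):
        sem.index(effect.positive), sem.index(effect.negative)
        g.add_edge(effect.positive, effect.name)
        g.add_edge(effect.negative, effect.name)
        return g, effect.name
    return g, effect if effect in g else sem.variables[sem.index(effect)]


def enumerate_noncausal_paths(
    sem: LinearSEM,
    cause: str,
    effect: Term,
    conditioning_set: Iterable[str] = (),
) -> list[PathInfo]:
    """All simple noncausal (backdoor) paths from ``cause`` to ``effect``.

    A noncausal path starts with an arrow *into* the cause.  Each path is
    labeled open or blocked under the conditioning set by the d-separation
    rules: a conditioned non-collider blocks; a collider blocks unless it or
    one of its descendants is conditioned.  A contrast effect is grafted
    onto the graph as a child of both of its components, so paths end with
    an arrow into the contrast node.
    """
    sem.index(cause)
    graph, target = _augmented_graph(sem, effect)
    z = set(conditioning_set)
    for v in z:
        if v not in graph:
            raise KeyError(f"unknown conditioning variable {v!r}")
    if cause in z or target in z:
        raise ValueError("conditioning set must not contain the cause or effect")

    descendants = {v: nx.descendants(graph, v) for v in graph}
    skeleton = graph.to_undirected(as_view=False)
    results: list[PathInfo] = []
    for nodes in nx.all_simple_paths(skeleton, cause, target):
        # arrow direction between consecutive nodes (DAG: only one exists)
        arrows = tuple(
            "->" if graph.has_edge(a, b) else "<-" for a, b in zip(nodes, nodes[1:])
        )
        if arrows[0] != "<-":
            continue  # causal or mediated path, not a backdoor path
        blocked_by: list[str] = []
        colliders: list[str] = []
        opened: list[str] = []
        for i in range(1, len(nodes) - 1):
            v = nodes[i]
            is_collider = arrows[i - 1] == "->" and arrows[i] == "<-"
            if is_collider:
                colliders.append(v)
                if v in z or descendants[v] & z:
                    opened.append(v)
            elif v in z:
                blocked_by.append(v)
        is_open = not blocked_by and len(opened) == len(colliders)
        results.append(
            PathInfo(
                nodes=tuple(nodes),
                arrows=arrows,
                is_open=is_open,
                blocked_by=tuple(blocked_by),
                colliders=tuple(colliders),
                opened_colliders=tuple(opened),
            )
        )
    results.sort(key=lambda p: (len(p.nodes), p.nodes))
    return results
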