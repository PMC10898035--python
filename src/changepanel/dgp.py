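"""Synthetic balanced-panel generators.

Three linear data-generating processes for an exposure ``x``, a continuous
outcome marker ``y`` and an observed time-varying covariate ``z`` measured on
``n`` individuals over two or three survey waves:

* **baseline** — unobserved time-invariant heterogeneity ``u`` confounds the
  exposure/outcome relation with strength ``theta``::

      x_it = delta * z_it + theta * u_i + nu_it
      y_it = beta * x_it + gamma * z_it + u_i + lambda_t + eps_it

* **strict-exogeneity violation** — the previous outcome feeds forward into
  the current outcome with coefficient ``rho`` (two waves, plus an initial
  outcome ``y_init = u + eps``), breaking the strict-exogeneity condition
  that first-difference estimation relies on.

* **common-trend violation** — an unobserved *individual* time-varying term
  ``lambda_it`` enters both the exposure and (scaled by ``omega``) the
  outcome, so individual time trends are no longer parallel.

All disturbances are independent Gaussians; the defaults reproduce
standard-normal errors and the canonical coefficient setting
``beta = gamma = 1``, ``delta = 0.5``, common time effects
``lambda = (0.5, 1, 1.5)``.

Latent draws (``u``, ``lambda_it``, ``y_init``) are retained on the
:class:`PanelData` for diagnostics but live outside the observable table;
estimators can never consume them.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, LatentColumnError

__all__ = [
    "DGPParams",
    "PanelData",
    "generate_baseline_panel",
    "generate_se_violation_panel",
    "generate_ct_violation_panel",
    "LATENT_COLUMNS",
    "OBSERVED_COLUMNS",
]

#: Columns an estimator is allowed to see, in serialization order.
OBSERVED_COLUMNS = ("id", "wave", "x", "y", "z")

#: Diagnostic-only columns; offering these to an estimator is an error.
LATENT_COLUMNS = ("u", "lambda_it", "y_init")


@dataclass(frozen=True)
class DGPParams:
    """Structural coefficients and noise scales of the generating models.

    Parameters
    ----------
    beta
        Contemporaneous effect of exposure on outcome (the estimand).
    gamma
        Effect of the observed covariate ``z`` on the outcome.
    delta
        Effect of ``z`` on the exposure.
    theta
        Loading of the time-invariant heterogeneity ``u`` on the exposure;
        the confounding strength. ``u`` always enters the outcome with
        loading ``u_effect_on_y`` (1 by construction of the model).
    rho
        Feed-forward effect of the lagged outcome (strict-exogeneity
        violation process only).
    omega
        Outcome loading of the individual time-varying confounder
        ``lambda_it`` (common-trend violation process only).
    lambda_t
        Common time effects, one per wave (extra entries are ignored).
    sd_z, sd_u, sd_nu, sd_eps, sd_lambda_it
        Standard deviations of the Gaussian draws; all default to 1.
    n
        Individuals per generated dataset.
    waves
        Number of panel waves: 3 for the baseline process, 2 for the two
        violation processes.
    """

    beta: float = 1.0
    gamma: float = 1.0
    delta: float = 0.5
    theta: float = 1.0
    rho: float = 0.0
    omega: float = 0.0
    lambda_t: tuple[float, ...] = (0.5, 1.0, 1.5)
    u_effect_on_y: float = 1.0
    sd_z: float = 1.0
    sd_u: float = 1.0
    sd_nu: float = 1.0
    sd_eps: float = 1.0
    sd_lambda_it: float = 1.0
    n: int = 1000
    waves: int = 3

    def __post_init__(self) -> None:
        for name in ("sd_z", "sd_u", "sd_nu", "sd_eps", "sd_lambda_it"):
            value = getattr(self, name)
            if not value > 0:
                raise ConfigurationError(
                    f"{name} must be strictly positive, got {value!r}"
                )
        if int(self.n) != self.n or self.n < 2:
            raise ConfigurationError(f"n must be an integer >= 2, got {self.n!r}")
        if self.waves not in (2, 3):
            raise ConfigurationError(f"waves must be 2 or 3, got {self.waves!r}")
        if len(self.lambda_t) < self.waves:
            raise ConfigurationError(
                f"lambda_t needs at least {self.waves} entries, "
                f"got {len(self.lambda_t)}"
            )
        object.__setattr__(self, "lambda_t", tuple(float(v) for v in self.lambda_t))

    def with_(self, **updates) -> "DGPParams":
        """Return a copy with the given fields replaced."""
        return replace(self, **updates)


@dataclass(frozen=True)
class PanelData:
    """A balanced individual-by-wave panel of (x, y, z).

    Observable data are stored as ``(n, waves)`` arrays whose column index is
    the wave number.  Latent generator state (``u``, ``lambda_it``,
    ``y_init``) is kept on separate attributes so that estimators, which read
    only ``x``/``y``/``z``, can never consume it.  ``params`` and ``seed``
    record the provenance of generated panels; both are ``None`` for panels
    loaded from user tables.
    """

    x: np.ndarray
    y: np.ndarray
    z: np.ndarray
    u: np.ndarray | None = None
    lambda_it: np.ndarray | None = None
    y_init: np.ndarray | None = None
    params: DGPParams | None = None
    seed: object = None
    ids: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        x, y, z = (np.asarray(a, dtype=float) for a in (self.x, self.y, self.z))
        if not (x.shape == y.shape == z.shape) or x.ndim != 2:
            raise ConfigurationError(
                f"x, y, z must share one (n, waves) shape; got "
                f"{x.shape}, {y.shape}, {z.shape}"
            )
        for name, arr in (("x", x), ("y", y), ("z", z)):
            if not np.isfinite(arr).all():
                raise ConfigurationError(f"column {name} contains missing values")
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)
        object.__setattr__(self, "z", z)
        if self.ids is None:
            object.__setattr__(self, "ids", np.arange(x.shape[0]))

    @property
    def n(self) -> int:
        return self.x.shape[0]

    @property
    def waves(self) -> int:
        return self.x.shape[1]

    @property
    def wave_labels(self) -> range:
        return range(self.waves)

    def require_wave(self, wave: int) -> int:
        if wave not in self.wave_labels:
            from .errors import WaveNotFoundError

            raise WaveNotFoundError(
                f"wave {wave} not in panel (waves 0..{self.waves - 1})"
            )
        return wave

    # ------------------------------------------------------------------ #
    # serialization                                                      #
    # ------------------------------------------------------------------ #
    def to_frame(self, include_latent: bool = False) -> pd.DataFrame:
        """Long-format table: one row per (individual, wave)."""
        n, w = self.n, self.waves
        frame = pd.DataFrame(
            {
                "id": np.repeat(self.ids, w),
                "wave": np.tile(np.arange(w), n),
                "x": self.x.ravel(),
                "y": self.y.ravel(),
                "z": self.z.ravel(),
            }
        )
        if include_latent:
            if self.u is not None:
                frame["u"] = np.repeat(self.u, w)
            if self.lambda_it is not None:
                frame["lambda_it"] = self.lambda_it.ravel()
            if self.y_init is not None:
                frame["y_init"] = np.repeat(self.y_init, w)
        return frame

    def to_csv(self, path, include_latent: bool = False) -> None:
        self.to_frame(include_latent=include_latent).to_csv(path, index=False)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, allow_latent: bool = False) -> "PanelData":
        """Build a panel from a long-format table with columns id, wave, x, y, z.

        Latent columns are rejected unless ``allow_latent`` is set, in which
        case they are quarantined onto the latent attributes.
        """
        missing = [c for c in OBSERVED_COLUMNS if c not in frame.columns]
        if missing:
            raise ConfigurationError(f"table lacks required columns: {missing}")
        latent_present = [c for c in LATENT_COLUMNS if c in frame.columns]
        if latent_present and not allow_latent:
            raise LatentColumnError(
                f"latent columns {latent_present} are diagnostic-only; "
                "estimators consume id, wave, x, y, z"
            )
        if frame[list(OBSERVED_COLUMNS)].isna().any().any():
            raise ConfigurationError("table contains missing values")

        tidy = frame.sort_values(["id", "wave"])
        waves = np.sort(tidy["wave"].unique())
        if not np.array_equal(waves, np.arange(len(waves))):
            raise ConfigurationError(f"waves must be 0..{len(waves) - 1}, got {waves}")
        counts = tidy.groupby("id")["wave"].count()
        if counts.nunique() != 1 or counts.iloc[0] != len(waves):
            raise ConfigurationError("panel is unbalanced: some individuals miss waves")

        n, w = len(counts), len(waves)
        ids = counts.index.to_numpy()
        wide = {c: tidy[c].to_numpy().reshape(n, w) for c in ("x", "y", "z")}
        latent: dict[str, np.ndarray | None] = {c: None for c in LATENT_COLUMNS}
        if allow_latent:
            if "u" in tidy:
                latent["u"] = tidy["u"].to_numpy().reshape(n, w)[:, 0]
            if "lambda_it" in tidy:
                latent["lambda_it"] = tidy["lambda_it"].to_numpy().reshape(n, w)
            if "y_init" in tidy:
                latent["y_init"] = tidy["y_init"].to_numpy().reshape(n, w)[:, 0]
        return cls(ids=ids, **wide, **latent)

    @classmethod
    def read_csv(cls, path, allow_latent: bool = False) -> "PanelData":
        return cls.from_frame(pd.read_csv(path), allow_latent=allow_latent)


# ---------------------------------------------------------------------- #
# generators                                                             #
# ---------------------------------------------------------------------- #
def _rng(seed) -> np.random.Generator:
    return np.random.default_rng(seed)


def _require_waves(params: DGPParams, expected: int, process: str) -> None:
    if params.waves != expected:
        raise ConfigurationError(
            f"waves must be {expected} for the {process} process, "
            f"got waves={params.waves}"
        )


def _common_draws(params: DGPParams, rng: np.random.Generator):
    n, w = params.n, params.waves
    z = rng.normal(0.0, params.sd_z, size=(n, w))
    u = rng.normal(0.0, params.sd_u, size=n)
    nu = rng.normal(0.0, params.sd_nu, size=(n, w))
    eps = rng.normal(0.0, params.sd_eps, size=(n, w))
    return z, u, nu, eps


def generate_baseline_panel(params: DGPParams, seed) -> PanelData:
    """Three-wave panel with time-invariant confounding of strength theta.

    ``rho`` and ``omega`` are ignored.  Deterministic given ``(params, seed)``.
    """
    _require_waves(params, 3, "baseline")
    rng = _rng(seed)
    z, u, nu, eps = _common_draws(params, rng)
    lam = np.asarray(params.lambda_t[: params.waves])
    x = params.delta * z + params.theta * u[:, None] + nu
    y = (
        params.beta * x
        + params.gamma * z
        + params.u_effect_on_y * u[:, None]
        + lam[None, :]
        + eps
    )
    return PanelData(x=x, y=y, z=z, u=u, params=params, seed=seed)


def generate_se_violation_panel(params: DGPParams, seed) -> PanelData:
    """Two-wave panel in which the lagged outcome feeds forward with ``rho``.

    The pre-sample outcome is ``y_init = u + eps_init``; it is stored as a
    latent column, never handed to estimators.
    """
    _require_waves(params, 2, "strict-exogeneity violation")
    rng = _rng(seed)
    z, u, nu, eps = _common_draws(params, rng)
    eps_init = rng.normal(0.0, params.sd_eps, size=params.n)
    lam = params.lambda_t
    x = params.delta * z + params.theta * u[:, None] + nu

    y_init = params.u_effect_on_y * u + eps_init
    y = np.empty_like(x)
    prev = y_init
    for t in range(2):
        y[:, t] = (
            params.beta * x[:, t]
            + params.gamma * z[:, t]
            + params.rho * prev
            + params.u_effect_on_y * u
            + lam[t]
            + eps[:, t]
        )
        prev = y[:, t]
    return PanelData(x=x, y=y, z=z, u=u, y_init=y_init, params=params, seed=seed)


def generate_ct_violation_panel(params: DGPParams, seed) -> PanelData:
    """Two-wave panel with an individual time-varying confounder lambda_it.

    ``lambda_it`` enters the exposure with unit loading and the outcome with
    loading ``omega``; it replaces the common time effects, so individual
    trends are parallel only at ``omega = 0``.
    """
    _require_waves(params, 2, "common-trend violation")
    rng = _rng(seed)
    z, u, nu, eps = _common_draws(params, rng)
    lam_it = rng.normal(0.0, params.sd_lambda_it, size=(params.n, 2))
    x = params.delta * z + params.theta * u[:, None] + lam_it + nu
    y = (
        params.beta * x
        + params.gamma * z
        + params.u_effect_on_y * u[:, None]
        + params.omega * lam_it
        + eps
    )
    return PanelData(x=x, y=y, z=z, u=u, lambda_it=lam_it, params=params, seed=seed)


#: Registry keyed by process id, used by the Monte Carlo engine and CLI.
GENERATORS = {
    "baseline": generate_baseline_panel,
    "se_violation": generate_se_violation_panel,
    "ct_violation": generate_ct_violation_panel,
}
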