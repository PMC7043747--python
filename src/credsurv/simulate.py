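"""Synthetic two-arm survival data and ground-truth evaluation.

Two generating mechanisms are provided, matching the conditions the package's
simulation studies run under:

* **Proportional hazards.**  Baseline cumulative hazard ``H_0(t) = lambda *
  t^nu_w`` (Weibull-type, scale 0.05 and shape 1.1 by default); covariates
  ``x1 = z1 ~ Bernoulli(1/2)``, ``x2 = z2 ~ Uniform(-3, 3)``; predictive
  vector ``z = (1, z1, z2)``; arms assigned with equal probability; event
  times by inverse-transform ``T = [-log U / (lambda e^{x'beta + theta
  z'gamma})]^{1/nu_w}``; independent exponential censoring at rate 0.02.

* **Non-proportional hazards.**  The treatment arm has constant baseline rate
  0.01; the control arm's baseline rate jumps from 0.01 to 0.1 at a change
  point ``t_c = 30``.  The arm-1 hazard is further multiplied by
  ``e^{z'gamma}``; both arms share the prognostic factor ``e^{x'beta}``.
  The between-arm hazard ratio is ``e^{z'gamma}`` before ``t_c`` and drops
  abruptly to ``e^{z'gamma}/10`` after.

The true benefiting subgroup ``B`` and true PTE surfaces are computed from
the known parameters — linearly for the log hazard ratio, and by integrating
the known parametric survival curves for the RMST difference.  A fitted
credible pair is scored against the truth with five metrics: total coverage
(the joint event ``D subset B subset S``), pair size, sensitivity and
specificity of D, and mean squared error of the posterior-mean surface.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data import CovariateGrid, SurvivalDataset
from .exceptions import ConfigurationError
from .subgroups import CredibleSubgroupPair

__all__ = [
    "PHSimConfig",
    "NonPHSimConfig",
    "simulate_ph",
    "simulate_nonph",
    "invert_ph_time",
    "default_grid",
    "true_benefit_set",
    "SubgroupMetrics",
    "evaluate_pair",
]


@dataclass
class PHSimConfig:
    """Proportional-hazards generator settings (defaults are the study conditions)."""

    n: int
    beta: tuple[float, float] = (0.0, 0.0)
    gamma: tuple[float, float, float] = (0.0, 0.0, 0.0)
    weibull_scale: float = 0.05
    weibull_shape: float = 1.1
    censor_rate: float = 0.02
    seed: int | None = None
    force_balance: bool = False  # exact 50/50 arm split instead of Bernoulli(1/2)

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ConfigurationError("need n >= 2")
        if min(self.weibull_scale, self.weibull_shape, self.censor_rate) <= 0:
            raise ConfigurationError("scale, shape and censor rate must be positive")


@dataclass
class NonPHSimConfig:
    """Non-proportional-hazards generator settings (piecewise control baseline)."""

    n: int
    beta: tuple[float, float] = (0.7, 0.7)
    gamma: tuple[float, float, float] = (0.5, -0.5, -0.5)
    base_rate: float = 0.01
    post_change_rate: float = 0.1
    change_time: float = 30.0
    censor_rate: float = 0.02
    seed: int | None = None
    force_balance: bool = False

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ConfigurationError("need n >= 2")
        if min(self.base_rate, self.post_change_rate, self.change_time, self.censor_rate) <= 0:
            raise ConfigurationError("rates and change time must be positive")


def _covariates(n: int, rng: np.random.Generator, force_balance: bool):
    x1 = rng.integers(0, 2, n).astype(float)
    x2 = rng.uniform(-3.0, 3.0, n)
    if force_balance:
        arm = np.zeros(n, dtype=int)
        arm[rng.permutation(n)[: n // 2]] = 1
    else:
        arm = rng.integers(0, 2, n)
    return x1, x2, arm


def invert_ph_time(u, lp, weibull_scale: float, weibull_shape: float):
    """Inverse-transform event time ``T = [-log u / (lambda e^lp)]^{1/nu_w}``."""
    return (-np.log(u) / (weibull_scale * np.exp(lp))) ** (1.0 / weibull_shape)


def simulate_ph(config: PHSimConfig, rng: np.random.Generator | None = None) -> SurvivalDataset:
    """Draw a proportional-hazards dataset; seeded and reproducible."""
    rng = np.random.default_rng(config.seed) if rng is None else rng
    n = config.n
    x1, x2, arm = _covariates(n, rng, config.force_balance)
    b1, b2 = config.beta
    g = np.asarray(config.gamma, dtype=float)
    lp = b1 * x1 + b2 * x2 + arm * (g[0] + g[1] * x1 + g[2] * x2)
    T = invert_ph_time(rng.uniform(size=n), lp, config.weibull_scale, config.weibull_shape)
    C = rng.exponential(1.0 / config.censor_rate, n)
    return SurvivalDataset(
        time=np.minimum(T, C),
        event=(T <= C).astype(int),
        arm=arm,
        prognostic=np.column_stack([x1, x2]),
        predictive=np.column_stack([x1, x2]),
        prognostic_names=("x1", "x2"),
        predictive_names=("z1", "z2"),
    )


def _nonph_control_cumhaz_inverse(E, c0, c1, t_c):
    """Invert H(t) = c0*t (t < t_c), c0*t_c + c1*(t - t_c) at exponential draws E."""
    knee = c0 * t_c
    return np.where(E < knee, E / c0, t_c + (E - knee) / c1)


def simulate_nonph(config: NonPHSimConfig, rng: np.random.Generator | None = None) -> SurvivalDataset:
    """Draw a dataset whose control arm's baseline rate jumps at the change point."""
    rng = np.random.default_rng(config.seed) if rng is None else rng
    n = config.n
    x1, x2, arm = _covariates(n, rng, config.force_balance)
    b1, b2 = config.beta
    g = np.asarray(config.gamma, dtype=float)
    prog = b1 * x1 + b2 * x2
    E = rng.exponential(1.0, n)
    # treatment: constant rate base_rate * e^{x'beta + z'gamma}
    rate1 = config.base_rate * np.exp(prog + g[0] + g[1] * x1 + g[2] * x2)
    # control: piecewise baseline scaled by e^{x'beta}
    c0 = config.base_rate * np.exp(prog)
    c1 = config.post_change_rate * np.exp(prog)
    T = np.where(
        arm == 1,
        E / rate1,
        _nonph_control_cumhaz_inverse(E, c0, c1, config.change_time),
    )
    C = rng.exponential(1.0 / config.censor_rate, n)
    return SurvivalDataset(
        time=np.minimum(T, C),
        event=(T <= C).astype(int),
        arm=arm,
        prognostic=np.column_stack([x1, x2]),
        predictive=np.column_stack([x1, x2]),
        prognostic_names=("x1", "x2"),
        predictive_names=("z1", "z2"),
    )


# ---------------------------------------------------------------------------
# evaluation grid and truth
# ---------------------------------------------------------------------------


def default_grid(n_z2: int = 61, include_intercept: bool = True) -> CovariateGrid:
    """Subgroup-evaluation grid: z1 in {0,1} crossed with n_z2 z2 values on [-3,3].

    Companion prognostic vectors reuse (z1, z2), matching the generators where
    x1 = z1 and x2 = z2.
    """
    z2 = np.linspace(-3.0, 3.0, n_z2)
    z1 = np.repeat([0.0, 1.0], n_z2)
    z2 = np.tile(z2, 2)
    raw = np.column_stack([z1, z2])
    pts = np.column_stack([np.ones(raw.shape[0]), raw]) if include_intercept else raw
    labels = [f"z1={int(a)}, z2={b:.2f}" for a, b in raw]
    return CovariateGrid(points=pts, companion_prognostic=raw.copy(), labels=labels)


def _ph_true_rmstd(grid: CovariateGrid, config: PHSimConfig, nu: float, n_nodes: int = 128) -> np.ndarray:
    """True RMSTd surface by Gauss-Legendre integration of the Weibull-type curves."""
    nodes, weights = np.polynomial.legendre.leggauss(n_nodes)
    t = 0.5 * nu * (nodes + 1.0)
    w = 0.5 * nu * weights
    H0 = config.weibull_scale * t ** config.weibull_shape  # (T,)
    b = np.asarray(config.beta, dtype=float)
    g = np.asarray(config.gamma, dtype=float)
    pts = grid.points
    if pts.shape[1] == g.size - 1:
        pts = np.column_stack([np.ones(pts.shape[0]), pts])
    lp0 = grid.companion_prognostic @ b  # (G,)
    lp1 = lp0 + pts @ g
    S0 = np.exp(-np.exp(lp0)[:, None] * H0[None, :])
    S1 = np.exp(-np.exp(lp1)[:, None] * H0[None, :])
    return ((S1 - S0) * w[None, :]).sum(axis=1)


def _nonph_true_rmstd(
    grid: CovariateGrid,
    config: NonPHSimConfig,
    nu: float,
    window_start: float = 0.0,
) -> np.ndarray:
    """True RMSTd surface in closed form for the piecewise-exponential truth."""
    b = np.asarray(config.beta, dtype=float)
    g = np.asarray(config.gamma, dtype=float)
    pts = grid.points
    if pts.shape[1] == g.size - 1:
        pts = np.column_stack([np.ones(pts.shape[0]), pts])
    prog = np.exp(grid.companion_prognostic @ b)
    rate1 = config.base_rate * np.exp(grid.companion_prognostic @ b + pts @ g)
    c0 = config.base_rate * prog
    c1 = config.post_change_rate * prog
    t_c = config.change_time

    def rmst_exp(rate, t):  # int_0^t e^{-rate s} ds
        return -np.expm1(-rate * t) / rate

    def rmst_control(t):
        t = np.minimum(t, t_c), np.maximum(t - t_c, 0.0)
        return rmst_exp(c0, t[0]) + np.exp(-c0 * t_c) * rmst_exp(c1, t[1]) * (t[1] > 0)

    def rmst_treat(t):
        return rmst_exp(rate1, t)

    hi = rmst_treat(nu) - rmst_control(np.full_like(c0, nu))
    if window_start > 0:
        lo = rmst_treat(window_start) - rmst_control(np.full_like(c0, window_start))
        return hi - lo
    return hi


def true_benefit_set(
    grid: CovariateGrid,
    measure: str,
    delta: float,
    config: PHSimConfig | NonPHSimConfig,
    nu: float | None = None,
    window_start: float = 0.0,
) -> tuple[np.ndarray, np.ndarray]:
    """True benefiting subgroup B (boolean mask) and true PTE surface on the grid.

    For ``measure="log_hr"`` membership is ``z'gamma < log(delta)``; for
    ``"rmstd"`` the surface is the exact RMST difference of the generating
    survival curves over ``[window_start, nu]`` and membership is
    ``surface > delta``.
    """
    g = np.asarray(config.gamma, dtype=float)
    pts = grid.points
    if pts.shape[1] == g.size - 1:
        # intercept-free grid (stratified fits): truth still uses the full gamma
        pts = np.column_stack([np.ones(pts.shape[0]), pts])
    if pts.shape[1] != g.size:
        raise ConfigurationError("grid width incompatible with the true gamma")
    if measure == "log_hr":
        if isinstance(config, NonPHSimConfig):
            raise ConfigurationError(
                "log-HR truth is time-varying under the non-proportional mechanism"
            )
        surface = pts @ g
        return surface < np.log(delta), surface
    if measure == "rmstd":
        if nu is None:
            raise ConfigurationError("rmstd truth requires a restriction time nu")
        if grid.companion_prognostic is None:
            raise ConfigurationError("rmstd truth requires companion prognostic vectors")
        if isinstance(config, PHSimConfig):
            if window_start:
                raise ConfigurationError("window_start is only supported for the non-PH truth")
            surface = _ph_true_rmstd(grid, config, nu)
        else:
            surface = _nonph_true_rmstd(grid, config, nu, window_start)
        return surface > delta, surface
    raise ConfigurationError(f"unknown measure {measure!r}")


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------


@dataclass
class SubgroupMetrics:
    """Per-replicate scores of a credible pair against the known truth.

    ``sensitivity`` is NaN when the true benefiting subgroup is empty;
    ``specificity`` is defined as 1 when its complement is empty (vacuous).
    """

    total_coverage: float
    pair_size: float
    sensitivity: float
    specificity: float
    mse: float

    def as_dict(self) -> dict:
        return {
            "total_coverage": self.total_coverage,
            "pair_size": self.pair_size,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "mse": self.mse,
        }


def evaluate_pair(
    pair: CredibleSubgroupPair,
    benefit_mask: np.ndarray,
    true_surface: np.ndarray,
    estimated_surface: np.ndarray,
) -> SubgroupMetrics:
    """Score one credible pair: coverage of D ⊆ B ⊆ S, pair size, sensitivity,
    specificity, and MSE of the posterior-mean surface."""
    B = np.asarray(benefit_mask, dtype=bool)
    D = pair.in_exclusive
    S = pair.in_inclusive
    if not (B.shape == D.shape == true_surface.shape == estimated_surface.shape):
        raise ConfigurationError("grid mismatch between pair, truth and estimate")
    covered = bool((~D | B).all() and (~B | S).all())
    n_B = int(B.sum())
    sens = float((D & B).sum() / n_B) if n_B else float("nan")
    n_Bc = int((~B).sum())
    spec = float((~D & ~B).sum() / n_Bc) if n_Bc else 1.0
    mse = float(np.mean((estimated_surface - true_surface) ** 2))
    return SubgroupMetrics(
        total_coverage=float(covered),
        pair_size=pair.pair_size,
        sensitivity=sens,
        specificity=spec,
        mse=mse,
    )
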