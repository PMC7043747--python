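"""Simultaneous credible bands and exclusive/inclusive credible subgroup pairs.

Given posterior PTE draws on a grid, the simultaneous band is

    Delta(z) in mean(z) +/- w_alpha * sd(z)   for all z jointly,

where ``w_alpha`` is the empirical ``1 - alpha`` quantile over draws of the
sup (over the grid) of the absolute standardized deviation
``|Delta^(m)(z) - mean(z)| / sd(z)``.  (The squared-scale statistic, whose
quantile would be used directly as the multiplier, is available for audit via
``scale="squared"``.)

The *exclusive* subgroup D collects the points whose whole band lies on the
benefit side of the clinical threshold; the *inclusive* subgroup S collects
every point whose band has not crossed entirely to the non-benefit side.
Jointly, ``P(D subset B subset S | data) > 1 - alpha`` for the true benefiting
subgroup B.  A multiplicity-uncorrected pointwise pair is provided for
comparison.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError
from .pte import PTEDraws

__all__ = [
    "SimultaneousBand",
    "CredibleSubgroupPair",
    "compute_sup_multiplier",
    "build_band",
    "credible_pair",
    "pointwise_pair",
    "classification_table",
    "plot_classification",
]

log = logging.getLogger(__name__)


@dataclass
class SimultaneousBand:
    """Pointwise mean/SD plus jointly calibrated band limits over the grid."""

    mean: np.ndarray
    sd: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    w_alpha: float
    level: float
    measure: str
    threshold: float
    benefit_direction: str
    zero_sd: np.ndarray  # mask of degenerate (zero-posterior-sd) points

    def __post_init__(self) -> None:
        if ((self.lower > self.mean + 1e-12) | (self.upper < self.mean - 1e-12)).any():
            raise ConfigurationError("band must contain the posterior mean pointwise")


@dataclass
class CredibleSubgroupPair:
    """Exclusive/inclusive subgroup pair (D, S) as boolean masks over the grid."""

    in_exclusive: np.ndarray
    in_inclusive: np.ndarray
    level: float
    threshold: float
    measure: str
    method: str  # "simultaneous" | "pointwise"

    def __post_init__(self) -> None:
        self.in_exclusive = np.asarray(self.in_exclusive, dtype=bool)
        self.in_inclusive = np.asarray(self.in_inclusive, dtype=bool)
        if (self.in_exclusive & ~self.in_inclusive).any():
            raise ConfigurationError("invariant violated: D must be a subset of S")

    @property
    def exclusive(self) -> np.ndarray:
        """Grid indices of D."""
        return np.flatnonzero(self.in_exclusive)

    @property
    def inclusive(self) -> np.ndarray:
        """Grid indices of S."""
        return np.flatnonzero(self.in_inclusive)

    @property
    def uncertainty(self) -> np.ndarray:
        """Grid indices of S \\ D (the needs-more-information region)."""
        return np.flatnonzero(self.in_inclusive & ~self.in_exclusive)

    @property
    def pair_size(self) -> float:
        """Proportion of grid points in the uncertainty region S \\ D."""
        return float((self.in_inclusive & ~self.in_exclusive).mean())


def compute_sup_multiplier(pte: PTEDraws, alpha: float, scale: str = "abs") -> float:
    """Empirical ``1 - alpha`` quantile of the sup standardized deviation.

    Zero-posterior-SD points are excluded from the sup (with a logged
    warning); if every point is degenerate the posterior cannot calibrate a
    band and an error is raised.
    """
    if not 0 < alpha < 1:
        raise ConfigurationError("alpha must lie in (0, 1)")
    if pte.M < 50:
        raise ConfigurationError("need at least 50 draws to calibrate the band")
    if scale not in ("abs", "squared"):
        raise ConfigurationError(f"unknown scale {scale!r}")
    mean = pte.values.mean(axis=0)
    sd = pte.values.std(axis=0, ddof=1)
    ok = sd > 0
    if not ok.any():
        raise ConfigurationError("degenerate posterior: zero variance at every grid point")
    if not ok.all():
        log.warning("excluding %d zero-variance grid points from the sup", (~ok).sum())
    dev = np.abs(pte.values[:, ok] - mean[ok]) / sd[ok]
    sups = dev.max(axis=1)
    if scale == "squared":
        sups = sups ** 2
    return float(np.quantile(sups, 1 - alpha, method="higher"))


def build_band(pte: PTEDraws, alpha: float, scale: str = "abs") -> SimultaneousBand:
    """Simultaneous band ``mean +/- w_alpha * sd`` at credible level ``1 - alpha``."""
    w = compute_sup_multiplier(pte, alpha, scale=scale)
    mean = pte.values.mean(axis=0)
    sd = pte.values.std(axis=0, ddof=1)
    return SimultaneousBand(
        mean=mean,
        sd=sd,
        lower=mean - w * sd,
        upper=mean + w * sd,
        w_alpha=w,
        level=1 - alpha,
        measure=pte.measure,
        threshold=pte.threshold,
        benefit_direction=pte.benefit_direction,
        zero_sd=sd == 0,
    )


def credible_pair(
    band: SimultaneousBand,
    delta: float | None = None,
    direction: str | None = None,
) -> CredibleSubgroupPair:
    """Exclusive/inclusive pair from a simultaneous band.

    For benefit-below (log HR, threshold log delta_H): D requires the upper
    limit strictly below the threshold, S admits any point whose lower limit
    is <= the threshold.  Benefit-above (RMSTd) mirrors this.  Degenerate
    zero-SD points are classified by comparing their (exact) posterior value
    to the threshold directly.
    """
    thr = band.threshold if delta is None else float(delta)
    direction = band.benefit_direction if direction is None else direction
    if direction != band.benefit_direction:
        raise ConfigurationError(
            f"direction {direction!r} inconsistent with measure {band.measure!r}"
        )
    if direction == "below":
        D = band.upper < thr
        S = band.lower <= thr
    else:
        D = band.lower > thr
        S = band.upper >= thr
    if band.zero_sd.any():
        z = band.zero_sd
        if direction == "below":
            D[z] = band.mean[z] < thr
            S[z] = band.mean[z] <= thr
        else:
            D[z] = band.mean[z] > thr
            S[z] = band.mean[z] >= thr
    ties = np.flatnonzero((band.lower == thr) | (band.upper == thr))
    if ties.size:
        log.info("band limit ties the threshold at grid points %s", ties.tolist())
    return CredibleSubgroupPair(D, S, band.level, thr, band.measure, "simultaneous")


def pointwise_pair(pte: PTEDraws, alpha: float, delta: float | None = None) -> CredibleSubgroupPair:
    """Multiplicity-uncorrected pair from per-point posterior benefit probabilities.

    D collects points whose posterior benefit probability strictly exceeds
    ``1 - alpha``; the companion S keeps every point with benefit probability
    at least ``alpha``.  Only meaningful for ``alpha < 0.5`` (otherwise the
    two rules can cross and D would not be nested in S).
    """
    if not 0 < alpha < 0.5:
        raise ConfigurationError("pointwise pairs require alpha in (0, 0.5)")
    if delta is not None:
        pte = PTEDraws(
            pte.values, pte.measure, pte.grid, float(delta), pte.benefit_direction,
            pte.restriction_time, pte.window_start,
        )
    prob = pte.benefit_indicators().mean(axis=0)
    D = prob > 1 - alpha
    S = prob >= alpha
    return CredibleSubgroupPair(D, S, 1 - alpha, pte.threshold, pte.measure, "pointwise")


def classification_table(band: SimultaneousBand, pair: CredibleSubgroupPair, grid) -> pd.DataFrame:
    """Per-grid-point table: covariates, band, and D / S\\D / S^C classification."""
    df = grid.to_dataframe()
    df["mean"] = band.mean
    df["sd"] = band.sd
    df["lower"] = band.lower
    df["upper"] = band.upper
    cls = np.where(pair.in_exclusive, "D", np.where(pair.in_inclusive, "S\\D", "S^C"))
    df["classification"] = cls
    df.insert(0, "point", np.arange(len(df)))
    return df


def plot_classification(table: pd.DataFrame, x: str, by: str | None = None, ax=None):
    """Three-color benefit/uncertain/no-benefit regions over one covariate.

    ``x`` names the continuous covariate column; ``by`` an optional binary
    covariate splitting the panel rows.  Returns the matplotlib axes.
    """
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    colors = {"D": "#2ca02c", "S\\D": "#1f77b4", "S^C": "#d62728"}
    if ax is None:
        _, ax = plt.subplots(figsize=(8, 2.5))
    groups = sorted(table[by].unique()) if by else [None]
    for row, g in enumerate(groups):
        sub = table if g is None else table[table[by] == g]
        for _, r in sub.iterrows():
            ax.plot(
                [r[x]], [row], marker="s", markersize=6,
                color=colors[r["classification"]], linestyle="none",
            )
    ax.set_yticks(range(len(groups)))
    ax.set_yticklabels([f"{by}={g}" for g in groups] if by else [""])
    ax.set_xlabel(x)
    return ax
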