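"""Right-censored two-arm survival data: containers, design matrices, I/O.

The data model mirrors the usual observed-data layout of a two-arm trial with
a time-to-event endpoint: for each subject we record the observed time
``Y = min(T, C)``, an event flag (1 = failure observed, 0 = censored), a
binary arm indicator, a vector of *prognostic* covariates ``x`` (affecting the
hazard in both arms) and a vector of *predictive* covariates ``z`` (entering
only through treatment interactions, hence driving the personalized treatment
effect).

Design construction produces the pair of matrices used by the Cox model
``lambda(t|x,z,theta) = lambda_0(t) exp(x'beta + theta z'gamma)``: the
prognostic matrix ``X`` and the treatment-interaction matrix ``theta * Z``,
where ``Z`` optionally carries a leading intercept (treatment main effect) and
B-spline expansions of continuous predictive covariates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import BSpline

from .exceptions import (
    ConfigurationError,
    DegenerateDesignError,
    ValidationError,
)

__all__ = [
    "SurvivalDataset",
    "CovariateGrid",
    "SplineSpec",
    "Design",
    "build_design",
    "read_survival_table",
    "write_survival_table",
]


def _check_binary(values: np.ndarray, name: str) -> None:
    bad = ~np.isin(values, (0, 1))
    if bad.any():
        row = int(np.flatnonzero(bad)[0])
        raise ValidationError(
            f"column '{name}' must be binary (0/1); row {row} has value {values[row]!r}"
        )


@dataclass
class SurvivalDataset:
    """Observed right-censored data for ``n`` subjects.

    Parameters
    ----------
    time : array of shape (n,)
        Observed times ``Y_i = min(T_i, C_i)``, non-negative.
    event : array of shape (n,)
        Failure indicators ``kappa_i`` (1 = event observed, 0 = censored).
    arm : array of shape (n,)
        Treatment indicators ``theta_i`` in {0, 1}.
    prognostic : array of shape (n, p)
        Prognostic covariates ``x_i``.
    predictive : array of shape (n, q)
        Predictive covariates ``z_i`` *without* an intercept column; design
        construction adds one by default.
    """

    time: np.ndarray
    event: np.ndarray
    arm: np.ndarray
    prognostic: np.ndarray
    predictive: np.ndarray
    prognostic_names: tuple[str, ...] = ()
    predictive_names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event)
        self.arm = np.asarray(self.arm)
        n = self.time.shape[0]
        self.prognostic = np.asarray(self.prognostic, dtype=float).reshape(n, -1)
        self.predictive = np.asarray(self.predictive, dtype=float).reshape(n, -1)
        if not self.prognostic_names:
            self.prognostic_names = tuple(f"x{i+1}" for i in range(self.prognostic.shape[1]))
        if not self.predictive_names:
            self.predictive_names = tuple(f"z{i+1}" for i in range(self.predictive.shape[1]))
        self._validate()

    def _validate(self) -> None:
        n = self.time.shape[0]
        for name, arr in (
            ("time", self.time),
            ("event", self.event),
            ("arm", self.arm),
        ):
            if arr.shape != (n,):
                raise ValidationError(f"column '{name}' has shape {arr.shape}, expected ({n},)")
        for name, arr in (
            ("time", self.time),
            ("prognostic", self.prognostic),
            ("predictive", self.predictive),
        ):
            if not np.isfinite(arr).all():
                idx = np.argwhere(~np.isfinite(np.atleast_2d(arr)))[0]
                raise ValidationError(f"missing/non-finite value in '{name}' at row {idx[-1 if arr.ndim == 1 else 0]}")
        if (self.time < 0).any():
            row = int(np.flatnonzero(self.time < 0)[0])
            raise ValidationError(f"column 'time' must be non-negative; row {row} has {self.time[row]}")
        _check_binary(self.event, "event")
        _check_binary(self.arm, "arm")
        self.event = self.event.astype(np.int8)
        self.arm = self.arm.astype(np.int8)
        if self.event.sum() < 1:
            raise ValidationError("dataset must contain at least one observed event")
        if len(self.prognostic_names) != self.prognostic.shape[1]:
            raise ValidationError("prognostic_names length mismatch")
        if len(self.predictive_names) != self.predictive.shape[1]:
            raise ValidationError("predictive_names length mismatch")

    @property
    def n(self) -> int:
        return self.time.shape[0]

    @property
    def n_events(self) -> int:
        return int(self.event.sum())

    @property
    def p(self) -> int:
        return self.prognostic.shape[1]

    @property
    def q(self) -> int:
        return self.predictive.shape[1]

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        time: str = "time",
        event: str = "event",
        arm: str = "arm",
        prognostic: Sequence[str] = (),
        predictive: Sequence[str] = (),
    ) -> "SurvivalDataset":
        for col in [time, event, arm, *prognostic, *predictive]:
            if col not in df.columns:
                raise ValidationError(f"column '{col}' not found in table")
            na = df[col].isna()
            if na.any():
                row = int(np.flatnonzero(na.to_numpy())[0])
                raise ValidationError(f"missing value in column '{col}' at row {row}")
        return cls(
            time=df[time].to_numpy(dtype=float),
            event=df[event].to_numpy(),
            arm=df[arm].to_numpy(),
            prognostic=df[list(prognostic)].to_numpy(dtype=float)
            if prognostic
            else np.empty((len(df), 0)),
            predictive=df[list(predictive)].to_numpy(dtype=float)
            if predictive
            else np.empty((len(df), 0)),
            prognostic_names=tuple(prognostic),
            predictive_names=tuple(predictive),
        )

    def to_dataframe(self) -> pd.DataFrame:
        out = pd.DataFrame({"time": self.time, "event": self.event, "arm": self.arm})
        for j, name in enumerate(self.prognostic_names):
            out[name] = self.prognostic[:, j]
        for j, name in enumerate(self.predictive_names):
            # a covariate may be both prognostic and predictive; keep one copy
            if name not in out.columns:
                out[name] = self.predictive[:, j]
        return out


def read_survival_table(path, column_map: dict) -> SurvivalDataset:
    """Load a delimited text table into a validated :class:`SurvivalDataset`.

    ``column_map`` names the special columns, e.g.::

        {"time": "time", "event": "event", "arm": "arm",
         "prognostic": ["x1", "x2"], "predictive": ["z1", "z2"]}
    """
    df = pd.read_csv(path)
    return SurvivalDataset.from_dataframe(
        df,
        time=column_map.get("time", "time"),
        event=column_map.get("event", "event"),
        arm=column_map.get("arm", "arm"),
        prognostic=column_map.get("prognostic", ()),
        predictive=column_map.get("predictive", ()),
    )


def write_survival_table(dataset: SurvivalDataset, path) -> None:
    dataset.to_dataframe().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# spline bases
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SplineSpec:
    """B-spline expansion of one continuous predictive covariate.

    ``df`` output columns are produced (the basis drops its leading column so
    that, together with the design intercept, the expansion is full rank).
    When ``interior_knots`` is None, ``df - degree`` interior knots are placed
    at quantiles of the observed covariate — one knot lands at the median when
    a single interior knot is requested.  Explicit knots override ``df``.
    """

    covariate_index: int
    degree: int = 3
    df: int = 3
    interior_knots: tuple[float, ...] | None = None

    def resolve(self, x: np.ndarray) -> "_ResolvedSpline":
        lo, hi = float(np.min(x)), float(np.max(x))
        if self.interior_knots is not None:
            knots = np.asarray(self.interior_knots, dtype=float)
            df = len(knots) + self.degree
        else:
            n_int = self.df - self.degree
            if n_int < 0:
                raise ConfigurationError(
                    f"spline df={self.df} below degree={self.degree}"
                )
            probs = np.arange(1, n_int + 1) / (n_int + 1)
            knots = np.quantile(x, probs) if n_int else np.empty(0)
            df = self.df
        if df < 1:
            raise ConfigurationError("spline basis must have at least one column")
        if knots.size and not ((knots > lo) & (knots < hi)).all():
            raise ConfigurationError(
                f"interior knots {knots.tolist()} not strictly inside data range ({lo}, {hi})"
            )
        return _ResolvedSpline(self.covariate_index, self.degree, df, tuple(knots), (lo, hi))


@dataclass(frozen=True)
class _ResolvedSpline:
    covariate_index: int
    degree: int
    df: int
    interior_knots: tuple[float, ...]
    boundary: tuple[float, float]

    @property
    def knot_vector(self) -> np.ndarray:
        lo, hi = self.boundary
        return np.r_[
            np.full(self.degree + 1, lo),
            np.asarray(self.interior_knots),
            np.full(self.degree + 1, hi),
        ]

    def basis(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        lo, hi = self.boundary
        if ((x < lo) | (x > hi)).any():
            raise ConfigurationError(
                f"spline evaluation outside fitted range ({lo}, {hi})"
            )
        # clip the right endpoint into the half-open support of the last basis
        xe = np.minimum(x, np.nextafter(hi, lo))
        full = BSpline.design_matrix(xe, self.knot_vector, self.degree).toarray()
        return full[:, 1:]  # drop the intercept-redundant leading column


# ---------------------------------------------------------------------------
# design construction
# ---------------------------------------------------------------------------


@dataclass
class _ColumnScale:
    center: float = 0.0
    scale: float = 1.0


@dataclass
class Design:
    """Design pair for the interaction Cox model plus its column bookkeeping.

    Attributes
    ----------
    prognostic : (n, p*) prognostic design matrix X
    interaction : (n, q*) treatment-interaction matrix, rows zero for arm 0
    predictive_expanded : (n, q*) expansion of z (intercept + splines), not
        multiplied by the arm indicator — the covariate space the subgroup
        grid lives in.
    column_map : per output column, the originating covariate / basis function
    """

    prognostic: np.ndarray
    interaction: np.ndarray
    predictive_expanded: np.ndarray
    prognostic_names: tuple[str, ...]
    interaction_names: tuple[str, ...]
    column_map: dict
    splines: tuple[_ResolvedSpline, ...]
    has_intercept: bool
    raw_predictive_names: tuple[str, ...]
    scales: dict = field(default_factory=dict)

    @property
    def combined(self) -> np.ndarray:
        """The combined matrix for the linear predictor x'beta + theta z'gamma."""
        return np.hstack([self.prognostic, self.interaction])

    @property
    def names(self) -> tuple[str, ...]:
        return self.prognostic_names + self.interaction_names

    @property
    def p(self) -> int:
        return self.prognostic.shape[1]

    @property
    def q(self) -> int:
        return self.interaction.shape[1]

    def expand_predictive(self, raw_points: np.ndarray) -> np.ndarray:
        """Map raw predictive covariate vectors into the expanded space.

        ``raw_points`` has one column per raw predictive covariate (no
        intercept); the output matches the columns of ``interaction``.
        """
        raw_points = np.atleast_2d(np.asarray(raw_points, dtype=float))
        if raw_points.shape[1] != len(self.raw_predictive_names):
            raise ConfigurationError(
                f"expected {len(self.raw_predictive_names)} raw predictive covariates, "
                f"got {raw_points.shape[1]}"
            )
        spline_of = {s.covariate_index: s for s in self.splines}
        blocks = []
        if self.has_intercept:
            blocks.append(np.ones((raw_points.shape[0], 1)))
        for j in range(raw_points.shape[1]):
            if j in spline_of:
                blocks.append(spline_of[j].basis(raw_points[:, j]))
            else:
                blocks.append(raw_points[:, [j]])
        return np.hstack(blocks)

    def grid(self, raw_points, prognostic=None, labels=None) -> "CovariateGrid":
        """Build a :class:`CovariateGrid` from raw predictive covariate points."""
        pts = self.expand_predictive(raw_points)
        return CovariateGrid(points=pts, companion_prognostic=prognostic, labels=labels)


def build_design(
    dataset: SurvivalDataset,
    splines: Sequence[SplineSpec] = (),
    add_intercept: bool = True,
    standardize: bool = False,
) -> Design:
    """Construct the (prognostic, treatment-interaction) design pair.

    The interaction matrix rows are identically zero for arm-0 subjects, so a
    coefficient on an interaction column is the (log-scale) modification of the
    hazard under treatment for a unit of that column.

    With ``standardize=True`` non-binary, non-intercept columns are centered
    and scaled for sampling; the model transforms posterior draws back to the
    original scale, so user-facing coefficients are unaffected.
    """
    for s in splines:
        if not 0 <= s.covariate_index < dataset.q:
            raise ConfigurationError(
                f"spline covariate_index {s.covariate_index} out of range for q={dataset.q}"
            )
    resolved = tuple(s.resolve(dataset.predictive[:, s.covariate_index]) for s in splines)
    spline_of = {s.covariate_index: s for s in resolved}

    X = dataset.prognostic.copy()
    prog_names = dataset.prognostic_names
    column_map: dict = {}
    for i, name in enumerate(prog_names):
        column_map[name] = {"block": "prognostic", "source": name}

    blocks, inames = [], []
    if add_intercept:
        blocks.append(np.ones((dataset.n, 1)))
        inames.append("treat")
        column_map["treat"] = {"block": "interaction", "source": "(intercept)"}
    for j, name in enumerate(dataset.predictive_names):
        if j in spline_of:
            B = spline_of[j].basis(dataset.predictive[:, j])
            blocks.append(B)
            for k in range(B.shape[1]):
                cname = f"{name}_bs{k+1}:treat"
                inames.append(cname)
                column_map[cname] = {"block": "interaction", "source": name, "basis": k + 1}
        else:
            blocks.append(dataset.predictive[:, [j]])
            cname = f"{name}:treat"
            inames.append(cname)
            column_map[cname] = {"block": "interaction", "source": name}
    Z = np.hstack(blocks) if blocks else np.empty((dataset.n, 0))

    # degeneracy check on informative columns (intercept exempt)
    for k, name in enumerate(prog_names):
        if np.ptp(X[:, k]) == 0:
            raise DegenerateDesignError(f"prognostic column '{name}' is constant")
    start = 1 if add_intercept else 0
    for k in range(start, Z.shape[1]):
        if np.ptp(Z[:, k]) == 0:
            raise DegenerateDesignError(
                f"predictive column '{inames[k]}' is constant after expansion"
            )

    scales: dict = {}
    if standardize:
        def _std_block(M, names, block_start, center_ok):
            for k in range(block_start, M.shape[1]):
                col = M[:, k]
                if set(np.unique(col)) <= {0.0, 1.0}:
                    continue
                c = float(col.mean()) if center_ok else 0.0
                s = float(col.std())
                if s == 0:
                    continue
                M[:, k] = (col - c) / s
                scales[names[k]] = _ColumnScale(c, s)

        # centering prognostic columns is absorbed by the baseline hazard;
        # centering interaction columns shifts into the treatment intercept
        _std_block(X, list(prog_names), 0, center_ok=True)
        _std_block(Z, inames, start, center_ok=add_intercept)

    TZ = Z * dataset.arm[:, None].astype(float)
    return Design(
        prognostic=X,
        interaction=TZ,
        predictive_expanded=Z,
        prognostic_names=tuple(prog_names),
        interaction_names=tuple(inames),
        column_map=column_map,
        splines=resolved,
        has_intercept=add_intercept,
        raw_predictive_names=dataset.predictive_names,
        scales=scales,
    )


@dataclass
class CovariateGrid:
    """Ordered covariate points over which subgroups are defined.

    ``points`` lives in the *expanded* predictive space (matching the
    interaction design columns).  ``companion_prognostic`` supplies the
    prognostic profile x for each point; it is required for RMST-difference
    PTEs, which condition on x as well as z.
    """

    points: np.ndarray
    companion_prognostic: np.ndarray | None = None
    labels: list | None = None

    def __post_init__(self) -> None:
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        if self.points.shape[0] < 1:
            raise ValidationError("grid must contain at least one point")
        if self.companion_prognostic is not None:
            self.companion_prognostic = np.atleast_2d(
                np.asarray(self.companion_prognostic, dtype=float)
            )
            if self.companion_prognostic.shape[0] != self.points.shape[0]:
                raise ValidationError("companion_prognostic row count mismatch")
        uniq = np.unique(self.points, axis=0)
        if uniq.shape[0] != self.points.shape[0]:
            raise ValidationError("grid contains duplicate points")
        if self.labels is not None and len(self.labels) != self.points.shape[0]:
            raise ValidationError("labels length mismatch")

    @property
    def G(self) -> int:
        return self.points.shape[0]

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.points, columns=[f"c{j}" for j in range(self.points.shape[1])])
        if self.labels is not None:
            df.insert(0, "label", self.labels)
        return df
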