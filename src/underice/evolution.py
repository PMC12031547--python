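"""Linear evolution of the characteristic parameters with freeze duration.

Each of the four C-type parameters identified per sampling date is
regressed on freeze duration ``t`` (days) with an ordinary least-squares
line ``Y(t) = alpha * t + beta``.  Composing the two stages —
per-parameter lines, then the biexponential profile — reconstructs the
full concentration surface ``HM(h, t)`` on any depth-by-time lattice.

The per-date fits must be in canonical ordering (``b <= d``) before the
stage-2 regression so each parameter's time series refers to a consistent
exponential term; label switching between dates would otherwise corrupt
the lines.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .ctype import CTypeParams, FitOptions, Profile, evaluate_profile
from .errors import DegenerateDesignError, ValidationError

__all__ = [
    "LinearLaw",
    "ParamEvolution",
    "SurfaceGrid",
    "fit_linear_evolution",
    "fit_param_evolution",
    "predict_params",
    "reconstruct_surface",
    "refine_evolution",
]

PARAM_NAMES = ("a", "b", "c", "d")


@dataclass(frozen=True)
class LinearLaw:
    """One parameter's line: slope ``alpha`` (units/day), intercept ``beta``."""

    alpha: float
    beta: float

    def predict(self, t: float) -> float:
        return self.alpha * t + self.beta


@dataclass(frozen=True)
class ParamEvolution:
    """Slope/intercept pairs for all four characteristic parameters."""

    a: LinearLaw
    b: LinearLaw
    c: LinearLaw
    d: LinearLaw
    metal: str | None = None

    def __post_init__(self):
        for name in PARAM_NAMES:
            law = getattr(self, name)
            if not (np.isfinite(law.alpha) and np.isfinite(law.beta)):
                raise ValidationError(
                    f"ParamEvolution({self.metal}): coefficients of '{name}' "
                    "must be finite"
                )

    def law(self, name: str) -> LinearLaw:
        if name not in PARAM_NAMES:
            raise ValidationError(f"unknown characteristic parameter '{name}'")
        return getattr(self, name)

    @classmethod
    def from_laws(
        cls, laws: Mapping[str, LinearLaw], metal: str | None = None
    ) -> "ParamEvolution":
        return cls(laws["a"], laws["b"], laws["c"], laws["d"], metal=metal)


@dataclass
class SurfaceGrid:
    """Reconstructed concentration field on a depth-by-time lattice.

    ``values[i, j]`` is the concentration (μg/L) at ``depth_axis[i]`` cm
    and ``time_axis[j]`` days.
    """

    depth_axis: np.ndarray
    time_axis: np.ndarray
    values: np.ndarray
    metal: str | None = None

    def __post_init__(self):
        self.depth_axis = np.asarray(self.depth_axis, dtype=float)
        self.time_axis = np.asarray(self.time_axis, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.depth_axis.size, self.time_axis.size):
            raise ValidationError("SurfaceGrid: values shape must match axes")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("SurfaceGrid: non-finite values")

    def value_at(self, depth: float, time: float, atol: float = 1e-9) -> float:
        """Exact-lookup of one cell; the coordinate must lie on the grid."""
        i = np.flatnonzero(np.abs(self.depth_axis - depth) <= atol)
        j = np.flatnonzero(np.abs(self.time_axis - time) <= atol)
        if i.size != 1 or j.size != 1:
            raise ValidationError(
                f"SurfaceGrid({self.metal}): coordinate (h={depth}, t={time}) "
                "is not on the grid"
            )
        return float(self.values[i[0], j[0]])

    def to_frame(self) -> pd.DataFrame:
        """Wide layout: first column depth_cm, one column per time point."""
        data = {"depth_cm": self.depth_axis}
        for j, t in enumerate(self.time_axis):
            data[f"t_{t:g}"] = self.values[:, j]
        return pd.DataFrame(data)


def fit_linear_evolution(
    times: Sequence[float], values: Sequence[float]
) -> LinearLaw:
    """Ordinary least-squares line through ``(times, values)``.

    Raises
    ------
    DegenerateDesignError
        If all times are identical (slope unidentifiable).
    ValidationError
        On mismatched lengths or fewer than two points.
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(values, dtype=float)
    if t.shape != y.shape or t.ndim != 1:
        raise ValidationError("fit_linear_evolution: times/values length mismatch")
    if t.size < 2:
        raise ValidationError("fit_linear_evolution: need at least 2 points")
    if np.ptp(t) == 0:
        raise DegenerateDesignError(
            "fit_linear_evolution: all times identical; slope unidentifiable"
        )
    alpha, beta = np.polyfit(t, y, 1)
    return LinearLaw(float(alpha), float(beta))


def fit_param_evolution(
    times: Sequence[float],
    params: Sequence[CTypeParams],
    metal: str | None = None,
) -> ParamEvolution:
    """Stage-2 regression: one line per characteristic parameter.

    ``params`` are canonicalised (``b <= d``) before regression.
    """
    canon = [p.canonical() for p in params]
    laws = {
        name: fit_linear_evolution(times, [getattr(p, name) for p in canon])
        for name in PARAM_NAMES
    }
    return ParamEvolution.from_laws(laws, metal=metal)


def predict_params(evolution: ParamEvolution, t: float) -> CTypeParams:
    """Characteristic parameters at freeze duration ``t`` (days)."""
    if t < 0:
        raise ValidationError(f"predict_params: t must be >= 0, got {t}")
    return CTypeParams(
        evolution.a.predict(t),
        evolution.b.predict(t),
        evolution.c.predict(t),
        evolution.d.predict(t),
    ).canonical()


def reconstruct_surface(
    evolution: ParamEvolution,
    depth_axis: Sequence[float],
    time_axis: Sequence[float],
) -> SurfaceGrid:
    """Exact composition of the two stages on a lattice — no smoothing."""
    h = np.asarray(depth_axis, dtype=float)
    t = np.asarray(time_axis, dtype=float)
    for name, axis in (("depth_axis", h), ("time_axis", t)):
        if axis.size == 0:
            raise ValidationError(f"reconstruct_surface: {name} is empty")
        if axis.size > 1 and np.any(np.diff(axis) <= 0):
            raise ValidationError(f"reconstruct_surface: {name} must be ascending")
    values = np.empty((h.size, t.size))
    for j, tj in enumerate(t):
        values[:, j] = evaluate_profile(predict_params(evolution, tj), h)
    return SurfaceGrid(h, t, values, metal=evolution.metal)


def refine_evolution(
    profiles: Iterable[Profile],
    evolution: ParamEvolution,
    options: FitOptions | None = None,
) -> ParamEvolution:
    """One-shot joint refinement of all eight coefficients.

    Minimises the pooled squared concentration residual over every sample
    of every profile, starting from the two-stage solution.  Provided as
    an optional polish; the default pipeline is strictly two-stage.
    """
    profs = list(profiles)
    if not profs:
        raise ValidationError("refine_evolution: no profiles")
    opts = options or FitOptions()
    t_all = np.concatenate([np.full(p.n_samples, p.time) for p in profs])
    h_all = np.concatenate([p.depths for p in profs])
    y_all = np.concatenate([p.concentrations for p in profs])

    def residuals(x: np.ndarray) -> np.ndarray:
        a = x[0] * t_all + x[1]
        b = x[2] * t_all + x[3]
        c = x[4] * t_all + x[5]
        d = x[6] * t_all + x[7]
        with np.errstate(over="ignore"):
            model = a * np.exp(np.clip(b, -opts.rate_bound, opts.rate_bound) * h_all)
            model = model + c * np.exp(
                np.clip(d, -opts.rate_bound, opts.rate_bound) * h_all
            )
        return model - y_all

    x0 = np.array(
        [
            evolution.a.alpha,
            evolution.a.beta,
            evolution.b.alpha,
            evolution.b.beta,
            evolution.c.alpha,
            evolution.c.beta,
            evolution.d.alpha,
            evolution.d.beta,
        ]
    )
    res = least_squares(residuals, x0, method="lm", max_nfev=2000)
    x = res.x
    return ParamEvolution(
        LinearLaw(float(x[0]), float(x[1])),
        LinearLaw(float(x[2]), float(x[3])),
        LinearLaw(float(x[4]), float(x[5])),
        LinearLaw(float(x[6]), float(x[7])),
        metal=evolution.metal,
    )
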