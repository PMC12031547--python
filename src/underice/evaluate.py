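"""Scoring of model and baseline predictions against observations.

The headline score is the mean absolute relative error in percent,
``mean(|predicted - observed| / observed) * 100``, computed per metal over
every observed (date, depth) sample jointly.  A relative-RMSE variant is
available behind the ``metric`` switch.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .ctype import Profile
from .errors import CoverageError, ValidationError
from .evolution import SurfaceGrid

__all__ = ["ErrorReport", "mean_relative_error", "relative_rmse", "compare_methods"]

MODEL_METHOD = "c-type"
BASELINE_METHODS = ("wavelet", "moving_average")
METRICS = ("mre", "rel_rmse")


@dataclass
class ErrorReport:
    """Per-(metal, method) errors in percent plus per-method ranges.

    ``per_metal`` is indexed by metal with one column per method;
    ``ranges`` maps each method to its (min, max) across metals.
    """

    per_metal: pd.DataFrame
    ranges: dict[str, tuple[float, float]]
    metric: str = "mre"

    def error(self, metal: str, method: str) -> float:
        return float(self.per_metal.loc[metal, method])


def _validate_pair(observed, predicted) -> tuple[np.ndarray, np.ndarray]:
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape or obs.ndim != 1:
        raise ValidationError("observed and predicted must be 1-D and equal length")
    if obs.size == 0:
        raise ValidationError("observed is empty")
    if np.any(obs <= 0):
        raise ValidationError(
            "mean relative error undefined: observed values must be > 0"
        )
    return obs, pred


def mean_relative_error(observed, predicted) -> float:
    """Mean of ``|predicted - observed| / observed`` in percent."""
    obs, pred = _validate_pair(observed, predicted)
    return float(np.mean(np.abs(pred - obs) / obs) * 100.0)


def relative_rmse(observed, predicted) -> float:
    """Root-mean-square of the relative residuals, in percent."""
    obs, pred = _validate_pair(observed, predicted)
    return float(np.sqrt(np.mean(((pred - obs) / obs) ** 2)) * 100.0)


_METRIC_FUNCS = {"mre": mean_relative_error, "rel_rmse": relative_rmse}


def compare_methods(
    observations: Iterable[Profile],
    model_surfaces: Mapping[str, SurfaceGrid],
    baseline_predictions: pd.DataFrame,
    metric: str = "mre",
) -> ErrorReport:
    """Score the C-type surface and both baselines per metal.

    Model predictions are read off each metal's surface at the observed
    (depth, time) coordinates, which must lie exactly on the grid;
    baseline predictions are matched by (method, metal, time, depth).
    Any coverage gap raises :class:`CoverageError` listing the missing
    coordinates.
    """
    if metric not in METRICS:
        raise ValidationError(f"unknown metric {metric!r}; expected one of {METRICS}")
    score = _METRIC_FUNCS[metric]
    profs = list(observations)
    if not profs:
        raise ValidationError("compare_methods: no observations")

    obs = pd.DataFrame(
        {
            "metal": np.repeat(
                [p.metal for p in profs], [p.n_samples for p in profs]
            ),
            "time_d": np.repeat(
                [p.time for p in profs], [p.n_samples for p in profs]
            ),
            "depth_cm": np.concatenate([p.depths for p in profs]),
            "observed": np.concatenate([p.concentrations for p in profs]),
        }
    )

    missing: list[tuple] = []
    model_pred = np.empty(len(obs))
    for i, row in enumerate(obs.itertuples(index=False)):
        surface = model_surfaces.get(row.metal)
        if surface is None:
            missing.append((row.metal, row.time_d, row.depth_cm))
            continue
        try:
            model_pred[i] = surface.value_at(row.depth_cm, row.time_d)
        except ValidationError:
            missing.append((row.metal, row.time_d, row.depth_cm))
    if missing:
        raise CoverageError(
            f"model surface does not cover {len(missing)} observed coordinate(s), "
            f"e.g. {missing[:5]}",
            missing=missing,
        )
    obs[MODEL_METHOD] = model_pred

    for method in BASELINE_METHODS:
        sub = baseline_predictions.loc[
            baseline_predictions["method"] == method,
            ["metal", "time_d", "depth_cm", "conc_pred_ugL"],
        ]
        merged = obs.merge(sub, on=["metal", "time_d", "depth_cm"], how="left")
        if merged["conc_pred_ugL"].isna().any():
            gaps = merged.loc[
                merged["conc_pred_ugL"].isna(), ["metal", "time_d", "depth_cm"]
            ]
            missing = list(gaps.itertuples(index=False, name=None))
            raise CoverageError(
                f"baseline {method!r} does not cover {len(missing)} observed "
                f"coordinate(s), e.g. {missing[:5]}",
                missing=missing,
            )
        obs[method] = merged["conc_pred_ugL"].to_numpy()

    methods = (MODEL_METHOD, *BASELINE_METHODS)
    metals = list(dict.fromkeys(obs["metal"]))
    table = pd.DataFrame(index=pd.Index(metals, name="metal"), columns=methods, dtype=float)
    for metal in metals:
        block = obs[obs["metal"] == metal]
        for method in methods:
            table.loc[metal, method] = score(block["observed"], block[method])
    ranges = {
        method: (float(table[method].min()), float(table[method].max()))
        for method in methods
    }
    return ErrorReport(per_metal=table, ranges=ranges, metric=metric)
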