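"""Layer and ice-stage stratification statistics.

The under-ice water column is split positionally into three layers — the
top 15 cm (upper), the bottom 15 cm (lower) and everything between
(middle) — and the freeze season into three calendar-bounded ice stages:
rapid growth, stable growth, and melting.  A profile whose middle-layer
mean sits strictly below both the upper and lower means is C-shaped, the
signature of solute rejection above and sediment release below.
"""

from __future__ import annotations

import datetime as dt
import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .ctype import Profile
from .errors import ValidationError

__all__ = [
    "LayerSummary",
    "StageSummary",
    "StageChange",
    "assign_layers",
    "layer_means",
    "classify_shape",
    "assign_stages",
    "stage_means",
    "stage_change",
    "StageBoundaries",
]

logger = logging.getLogger(__name__)

LAYERS = ("upper", "middle", "lower")
STAGES = ("rapid", "stable", "melting")
OFF_SEASON = "off-season"

#: Band thickness (cm) of the upper and lower layers.
LAYER_BAND_CM = 15.0


@dataclass(frozen=True)
class LayerSummary:
    """Per-metal mean concentration (μg/L) in each layer."""

    metal: str
    upper_mean: float
    middle_mean: float
    lower_mean: float

    def __post_init__(self):
        for name in ("upper_mean", "middle_mean", "lower_mean"):
            if getattr(self, name) < 0:
                raise ValidationError(f"LayerSummary({self.metal}): {name} < 0")


@dataclass(frozen=True)
class StageSummary:
    """Per-metal mean concentration (μg/L) in one ice stage."""

    stage: str
    metal: str
    mean_conc: float


@dataclass(frozen=True)
class StageChange:
    """Arithmetic of a stage-to-stage change in mean concentration.

    ``difference`` is previous minus current (μg/L); ``percent_change`` is
    the signed relative change of current versus previous (%);
    ``fold_decrease`` is previous over current.
    """

    difference: float
    percent_change: float
    fold_decrease: float


@dataclass(frozen=True)
class StageBoundaries:
    """Calendar bounds of the three ice stages (inclusive ends).

    Dates up to and including ``rapid_end`` are in the rapid-growth stage,
    dates after it up to and including ``stable_end`` in the stable-growth
    stage, and later dates in the melting stage.  Works equally with
    ``datetime.date`` values or freeze-duration days, as long as the
    queried values use the same representation.
    """

    rapid_end: object = dt.date(2018, 2, 2)
    stable_end: object = dt.date(2018, 3, 2)
    season_start: object | None = None
    season_end: object | None = None

    def __post_init__(self):
        if not self.rapid_end < self.stable_end:
            raise ValidationError(
                "StageBoundaries: rapid_end must precede stable_end"
            )


def assign_layers(
    depths: Sequence[float], water_column_depth: float
) -> list[str]:
    """Label each depth (cm below the ice-water interface) with its layer.

    Depths at exactly 15 cm from either end are assigned to the outer
    layer.  The column must be deeper than 30 cm or the bands overlap.
    """
    if water_column_depth <= 2 * LAYER_BAND_CM:
        raise ValidationError(
            f"assign_layers: water_column_depth must exceed {2 * LAYER_BAND_CM} cm "
            f"(got {water_column_depth}); upper and lower bands would overlap"
        )
    labels = []
    for h in depths:
        if h <= LAYER_BAND_CM:
            labels.append("upper")
        elif h >= water_column_depth - LAYER_BAND_CM:
            labels.append("lower")
        else:
            labels.append("middle")
    return labels


def layer_means(
    profiles: Iterable[Profile],
    water_column_depth: float | Mapping[float, float],
) -> dict[str, LayerSummary]:
    """Arithmetic mean concentration per (metal, layer), pooled over dates.

    ``water_column_depth`` is either a single depth (cm) or a mapping from
    sampling time to the column depth on that date (the column shrinks as
    the ice grows).
    """
    profs = list(profiles)
    if not profs:
        raise ValidationError("layer_means: no profiles")
    pools: dict[str, dict[str, list[float]]] = {}
    for p in profs:
        wcd = (
            water_column_depth[p.time]
            if isinstance(water_column_depth, Mapping)
            else float(water_column_depth)
        )
        labels = assign_layers(p.depths, wcd)
        store = pools.setdefault(p.metal, {layer: [] for layer in LAYERS})
        for label, conc in zip(labels, p.concentrations):
            store[label].append(float(conc))
    out = {}
    for metal, store in pools.items():
        for layer in LAYERS:
            if not store[layer]:
                raise ValidationError(
                    f"layer_means({metal}): the {layer} layer has no samples"
                )
        out[metal] = LayerSummary(
            metal,
            float(np.mean(store["upper"])),
            float(np.mean(store["middle"])),
            float(np.mean(store["lower"])),
        )
    return out


def classify_shape(summary: LayerSummary) -> str:
    """``"C-shaped"`` iff the middle mean is a strict interior minimum."""
    c_shaped = (
        summary.middle_mean < summary.upper_mean
        and summary.middle_mean < summary.lower_mean
    )
    return "C-shaped" if c_shaped else "not C-shaped"


def assign_stages(
    when: Sequence[object], boundaries: StageBoundaries | None = None
) -> list[str]:
    """Label each date (or freeze-duration value) with its ice stage.

    Values before ``season_start`` or after ``season_end`` (when those
    bounds are configured) receive the ``"off-season"`` sentinel and a
    warning rather than an error.
    """
    b = boundaries or StageBoundaries()
    labels = []
    for x in when:
        off = (b.season_start is not None and x < b.season_start) or (
            b.season_end is not None and x > b.season_end
        )
        if off:
            warnings.warn(
                f"assign_stages: {x!r} is outside the freeze season; "
                f"labelled {OFF_SEASON!r}",
                stacklevel=2,
            )
            logger.warning("assign_stages: %r outside the freeze season", x)
            labels.append(OFF_SEASON)
        elif x <= b.rapid_end:
            labels.append("rapid")
        elif x <= b.stable_end:
            labels.append("stable")
        else:
            labels.append("melting")
    return labels


def stage_means(
    profiles: Iterable[Profile], boundaries: StageBoundaries
) -> list[StageSummary]:
    """Mean concentration per (metal, stage), pooling all depths.

    ``boundaries`` must be expressed in the same representation as
    ``Profile.time`` (freeze-duration days).
    """
    profs = list(profiles)
    if not profs:
        raise ValidationError("stage_means: no profiles")
    frame = pd.DataFrame(
        {
            "metal": np.repeat([p.metal for p in profs], [p.n_samples for p in profs]),
            "stage": np.repeat(
                assign_stages([p.time for p in profs], boundaries),
                [p.n_samples for p in profs],
            ),
            "conc": np.concatenate([p.concentrations for p in profs]),
        }
    )
    grouped = frame.groupby(["metal", "stage"], sort=False)["conc"].mean()
    return [
        StageSummary(stage=stage, metal=metal, mean_conc=float(v))
        for (metal, stage), v in grouped.items()
    ]


def stage_change(previous_mean: float, current_mean: float) -> StageChange:
    """Stage-to-stage change arithmetic for one metal.

    Raises :class:`ValidationError` if ``previous_mean`` is not positive
    (the relative measures are undefined).
    """
    if previous_mean <= 0:
        raise ValidationError(
            f"stage_change: previous_mean must be > 0, got {previous_mean}"
        )
    difference = previous_mean - current_mean
    percent_change = (current_mean - previous_mean) / previous_mean * 100.0
    fold = previous_mean / current_mean if current_mean > 0 else float("inf")
    return StageChange(difference, percent_change, fold)
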