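"""Dataset container, CSV readers/writers, and the end-to-end pipeline.

All exchange formats are plain CSV:

* profiles — long format with header ``date,metal,depth_cm,conc_ugL``;
* ice records — ``date,thickness_mm,stage``;
* per-date fits — ``metal,time_d,a,b,c,d,rss,converged``;
* evolutions — ``metal,param,alpha,beta``;
* surfaces — wide matrices (first column ``depth_cm``, one column per
  time point);
* layer/stage summaries and the error report — metals as columns.

Calendar dates are ISO 8601 and converted on ingest to freeze duration
``t`` = days since the freeze onset supplied by the caller.  Units are
fixed throughout: depth cm, concentration μg/L, ice thickness mm, time
days.
"""

from __future__ import annotations

import datetime as dt
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__ as _version
from .ctype import CTypeParams, FitOptions, Profile, fit_profile
from .errors import PipelineError, UnderIceError, ValidationError
from .evaluate import ErrorReport, compare_methods
from .evolution import (
    LinearLaw,
    PARAM_NAMES,
    ParamEvolution,
    SurfaceGrid,
    fit_param_evolution,
    refine_evolution,
    reconstruct_surface,
)
from .smoothers import SmootherSettings, smooth_field
from .stratify import (
    LAYERS,
    LayerSummary,
    StageBoundaries,
    StageChange,
    classify_shape,
    layer_means,
    stage_change,
    stage_means,
)

logger = logging.getLogger(__name__)

__all__ = [
    "IceRecord",
    "Dataset",
    "PipelineConfig",
    "PipelineResult",
    "read_dataset",
    "write_dataset",
    "run_pipeline",
    "write_fits",
    "read_fits",
    "write_evolutions",
    "read_evolutions",
    "write_surface",
    "read_surface",
    "write_layer_table",
    "write_stage_table",
    "write_error_report",
]

PROFILE_HEADER = ["date", "metal", "depth_cm", "conc_ugL"]
ICE_HEADER = ["date", "thickness_mm", "stage"]
FLOAT_FORMAT = "%.10g"


@dataclass(frozen=True)
class IceRecord:
    """Ice thickness (mm) and growth stage at one freeze-duration day."""

    time: float
    thickness_mm: float
    stage: str

    def __post_init__(self):
        if self.thickness_mm <= 0:
            raise ValidationError(
                f"IceRecord(t={self.time}): thickness_mm must be > 0"
            )


@dataclass
class Dataset:
    """Profiles plus (optional) ice records sharing one freeze-onset origin."""

    profiles: list[Profile]
    ice: list[IceRecord] = field(default_factory=list)
    freeze_onset: dt.date = dt.date(2017, 11, 1)

    def __post_init__(self):
        if self.ice:
            ice_times = {r.time for r in self.ice}
            missing = sorted({p.time for p in self.profiles} - ice_times)
            if missing:
                raise ValidationError(
                    f"Dataset: profile times {missing} have no matching ice record"
                )

    @property
    def times(self) -> list[float]:
        return sorted({p.time for p in self.profiles})

    @property
    def metals(self) -> list[str]:
        return list(dict.fromkeys(p.metal for p in self.profiles))


def _t_to_date(t: float, onset: dt.date) -> str:
    """Freeze-duration day to ISO date (datetime when fractional)."""
    if float(t).is_integer():
        return (onset + dt.timedelta(days=int(t))).isoformat()
    stamp = dt.datetime.combine(onset, dt.time()) + dt.timedelta(days=float(t))
    return stamp.isoformat()


def _date_to_t(value: str, onset: dt.date, path: Path, line: int) -> float:
    try:
        stamp = pd.Timestamp(str(value))
    except (ValueError, TypeError):
        raise ValidationError(
            f"{path}: row {line}, column date: unparseable date {value!r}"
        ) from None
    origin = pd.Timestamp(dt.datetime.combine(onset, dt.time()))
    return float((stamp - origin).total_seconds() / 86400.0)


def read_dataset(
    profiles_path: str | Path,
    ice_path: str | Path | None = None,
    freeze_onset: dt.date = dt.date(2017, 11, 1),
) -> Dataset:
    """Read the long-format profile CSV (and optionally the ice CSV).

    Every row is validated; errors name the file, the CSV line number
    (header = line 1) and the offending column.
    """
    profiles_path = Path(profiles_path)
    frame = pd.read_csv(profiles_path, dtype=str)
    if list(frame.columns) != PROFILE_HEADER:
        raise ValidationError(
            f"{profiles_path}: malformed header {list(frame.columns)}; "
            f"expected {PROFILE_HEADER}"
        )
    records: dict[tuple[str, float], list[tuple[float, float]]] = {}
    for idx, row in enumerate(frame.itertuples(index=False)):
        line = idx + 2
        t = _date_to_t(row.date, freeze_onset, profiles_path, line)
        values = {}
        for column in ("depth_cm", "conc_ugL"):
            raw = getattr(row, column)
            try:
                values[column] = float(raw)
            except (TypeError, ValueError):
                raise ValidationError(
                    f"{profiles_path}: row {line}, column {column}: "
                    f"not a number: {raw!r}"
                ) from None
        if values["depth_cm"] <= 0:
            raise ValidationError(
                f"{profiles_path}: row {line}, column depth_cm: must be > 0, "
                f"got {values['depth_cm']}"
            )
        if values["conc_ugL"] < 0:
            raise ValidationError(
                f"{profiles_path}: row {line}, column conc_ugL: must be >= 0, "
                f"got {values['conc_ugL']}"
            )
        records.setdefault((str(row.metal), t), []).append(
            (values["depth_cm"], values["conc_ugL"])
        )
    profiles = []
    for (metal, t), samples in records.items():
        depths, concs = zip(*samples)
        profiles.append(
            Profile(metal=metal, time=t, depths=np.array(depths),
                    concentrations=np.array(concs))
        )
    ice = []
    if ice_path is not None:
        ice_path = Path(ice_path)
        iframe = pd.read_csv(ice_path, dtype=str)
        if list(iframe.columns) != ICE_HEADER:
            raise ValidationError(
                f"{ice_path}: malformed header {list(iframe.columns)}; "
                f"expected {ICE_HEADER}"
            )
        for idx, row in enumerate(iframe.itertuples(index=False)):
            line = idx + 2
            t = _date_to_t(row.date, freeze_onset, ice_path, line)
            try:
                thickness = float(row.thickness_mm)
            except (TypeError, ValueError):
                raise ValidationError(
                    f"{ice_path}: row {line}, column thickness_mm: "
                    f"not a number: {row.thickness_mm!r}"
                ) from None
            if thickness <= 0:
                raise ValidationError(
                    f"{ice_path}: row {line}, column thickness_mm: must be > 0"
                )
            ice.append(IceRecord(time=t, thickness_mm=thickness, stage=str(row.stage)))
    return Dataset(profiles=profiles, ice=ice, freeze_onset=freeze_onset)


def write_dataset(
    dataset: Dataset,
    profiles_path: str | Path,
    ice_path: str | Path | None = None,
) -> None:
    """Write the profile CSV (and the ice CSV when requested)."""
    rows = []
    for p in dataset.profiles:
        date = _t_to_date(p.time, dataset.freeze_onset)
        for h, conc in zip(p.depths, p.concentrations):
            rows.append((date, p.metal, h, conc))
    frame = pd.DataFrame(rows, columns=PROFILE_HEADER)
    frame.to_csv(profiles_path, index=False, float_format=FLOAT_FORMAT)
    if ice_path is not None:
        irows = [
            (_t_to_date(r.time, dataset.freeze_onset), r.thickness_mm, r.stage)
            for r in dataset.ice
        ]
        pd.DataFrame(irows, columns=ICE_HEADER).to_csv(
            ice_path, index=False, float_format=FLOAT_FORMAT
        )


# ---------------------------------------------------------------------------
# artifact tables
# ---------------------------------------------------------------------------

def write_fits(fits: pd.DataFrame, path: str | Path) -> None:
    fits.to_csv(path, index=False, float_format=FLOAT_FORMAT)


def read_fits(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_evolutions(
    evolutions: Mapping[str, ParamEvolution], path: str | Path
) -> None:
    rows = [
        (metal, name, evo.law(name).alpha, evo.law(name).beta)
        for metal, evo in evolutions.items()
        for name in PARAM_NAMES
    ]
    pd.DataFrame(rows, columns=["metal", "param", "alpha", "beta"]).to_csv(
        path, index=False, float_format=FLOAT_FORMAT
    )


def read_evolutions(path: str | Path) -> dict[str, ParamEvolution]:
    frame = pd.read_csv(path)
    expected = {"metal", "param", "alpha", "beta"}
    if set(frame.columns) != expected:
        raise ValidationError(f"{path}: malformed header {list(frame.columns)}")
    out = {}
    for metal, block in frame.groupby("metal", sort=False):
        laws = {
            str(row.param): LinearLaw(float(row.alpha), float(row.beta))
            for row in block.itertuples(index=False)
        }
        missing = [n for n in PARAM_NAMES if n not in laws]
        if missing:
            raise ValidationError(f"{path}: metal {metal} lacks params {missing}")
        out[str(metal)] = ParamEvolution.from_laws(laws, metal=str(metal))
    return out


def write_surface(surface: SurfaceGrid, path: str | Path) -> None:
    surface.to_frame().to_csv(path, index=False, float_format=FLOAT_FORMAT)


def read_surface(path: str | Path, metal: str | None = None) -> SurfaceGrid:
    frame = pd.read_csv(path)
    if frame.columns[0] != "depth_cm":
        raise ValidationError(f"{path}: first column must be depth_cm")
    times = [float(c.removeprefix("t_")) for c in frame.columns[1:]]
    return SurfaceGrid(
        depth_axis=frame["depth_cm"].to_numpy(),
        time_axis=np.array(times),
        values=frame.iloc[:, 1:].to_numpy(),
        metal=metal,
    )


def write_layer_table(
    summaries: Mapping[str, LayerSummary], path: str | Path
) -> None:
    """Layer means with metals as columns and layers as rows."""
    metals = list(summaries)
    data = {
        metal: [
            summaries[metal].upper_mean,
            summaries[metal].middle_mean,
            summaries[metal].lower_mean,
        ]
        for metal in metals
    }
    frame = pd.DataFrame(data, index=[f"{layer} layer" for layer in LAYERS])
    frame.index.name = "aquifer"
    frame.to_csv(path, float_format=FLOAT_FORMAT)


def write_stage_table(stage_table: pd.DataFrame, path: str | Path) -> None:
    stage_table.to_csv(path, float_format=FLOAT_FORMAT)


def write_error_report(report: ErrorReport, path: str | Path) -> None:
    """Error table with methods as rows and metals as columns."""
    report.per_metal.T.to_csv(path, float_format=FLOAT_FORMAT)


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PipelineConfig:
    """Settings for :func:`run_pipeline`.

    Stage boundaries are freeze-duration days (defaults are Feb 2 / Mar 2
    for a Nov 1 onset).  ``water_column_depth`` is the under-ice column
    depth used by the 15 cm layer rule, either one value or a per-date
    mapping.  ``joint_refine`` switches on the optional one-shot joint
    refinement of all eight evolution coefficients (off by default; the
    reference procedure is strictly two-stage).
    """

    fit: FitOptions = field(default_factory=FitOptions)
    smoothers: SmootherSettings = field(default_factory=SmootherSettings)
    water_column_depth: float | Mapping[float, float] = 150.0
    stage_boundaries: tuple[float, float] = (93.0, 121.0)
    metric: str = "mre"
    joint_refine: bool = False


@dataclass
class PipelineResult:
    """All artifacts of one end-to-end run."""

    fits: pd.DataFrame
    evolutions: dict[str, ParamEvolution]
    surfaces: dict[str, SurfaceGrid]
    baselines: pd.DataFrame
    layer_table: dict[str, LayerSummary]
    shape_classes: dict[str, str]
    stage_table: pd.DataFrame
    stage_changes: pd.DataFrame
    errors: ErrorReport

    def write(self, outdir: str | Path) -> None:
        """Write every artifact as CSV into ``outdir``."""
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        write_fits(self.fits, out / "fits.csv")
        write_evolutions(self.evolutions, out / "evolutions.csv")
        for metal, surface in self.surfaces.items():
            write_surface(surface, out / f"surface_{metal}.csv")
        self.baselines.to_csv(
            out / "baselines.csv", index=False, float_format=FLOAT_FORMAT
        )
        write_layer_table(self.layer_table, out / "layer_means.csv")
        pd.Series(self.shape_classes, name="shape").rename_axis("metal").to_csv(
            out / "shape_classes.csv"
        )
        write_stage_table(self.stage_table, out / "stage_means.csv")
        self.stage_changes.to_csv(
            out / "stage_changes.csv", index=False, float_format=FLOAT_FORMAT
        )
        write_error_report(self.errors, out / "error_report.csv")


def run_pipeline(
    dataset: Dataset, config: PipelineConfig | None = None
) -> PipelineResult:
    """Execute the full analysis on one dataset.

    Stages: per-(metal, date) C-type fits -> per-parameter linear
    evolutions -> surface reconstruction on the observed lattice ->
    baseline smoothers -> layer/stage stratification -> per-metal error
    report.  Deterministic: there is no randomness outside synthetic data
    generation.

    Raises
    ------
    ValidationError
        If fewer than three distinct sampling times are present (the
        stage-2 regression needs degrees of freedom).
    PipelineError
        Wrapping any stage failure with the stage name and offending unit.
    """
    cfg = config or PipelineConfig()
    times = dataset.times
    if len(times) < 3:
        raise ValidationError(
            f"run_pipeline: needs >= 3 sampling times for the stage-2 "
            f"regression, got {len(times)}"
        )
    logger.info(
        "run_pipeline: underice %s | %d metals x %d dates | metric=%s",
        _version, len(dataset.metals), len(times), cfg.metric,
    )

    by_metal: dict[str, list[Profile]] = {}
    for p in dataset.profiles:
        by_metal.setdefault(p.metal, []).append(p)

    # stage 1: per-date fits
    fit_rows = []
    fitted: dict[str, list[tuple[float, CTypeParams]]] = {}
    for metal, profs in by_metal.items():
        for p in sorted(profs, key=lambda q: q.time):
            try:
                params, diag = fit_profile(p, cfg.fit)
            except UnderIceError as exc:
                raise PipelineError("fit", f"metal {metal}, t={p.time}: {exc}", exc)
            fitted.setdefault(metal, []).append((p.time, params))
            fit_rows.append(
                (metal, p.time, params.a, params.b, params.c, params.d,
                 diag.residual_sum_of_squares, diag.converged)
            )
            logger.debug("fit %s t=%g: %s rss=%.3g", metal, p.time, params,
                         diag.residual_sum_of_squares)
    fits = pd.DataFrame(
        fit_rows,
        columns=["metal", "time_d", "a", "b", "c", "d", "rss", "converged"],
    )

    # stage 2: parameter evolutions (+ optional joint polish)
    evolutions = {}
    for metal, pairs in fitted.items():
        try:
            evo = fit_param_evolution(
                [t for t, _ in pairs], [prm for _, prm in pairs], metal=metal
            )
            if cfg.joint_refine:
                evo = refine_evolution(by_metal[metal], evo, cfg.fit)
        except UnderIceError as exc:
            raise PipelineError("evolution", f"metal {metal}: {exc}", exc)
        evolutions[metal] = evo

    # stage 3: surfaces on the observed lattice (exact alignment for scoring)
    depth_axis = np.unique(np.concatenate([p.depths for p in dataset.profiles]))
    surfaces = {}
    for metal, evo in evolutions.items():
        try:
            surfaces[metal] = reconstruct_surface(evo, depth_axis, times)
        except UnderIceError as exc:
            raise PipelineError("surface", f"metal {metal}: {exc}", exc)

    # stage 4: baselines
    try:
        baselines = pd.concat(
            [
                smooth_field(dataset.profiles, "wavelet", cfg.smoothers),
                smooth_field(dataset.profiles, "moving_average", cfg.smoothers),
            ],
            ignore_index=True,
        )
    except UnderIceError as exc:
        raise PipelineError("baselines", str(exc), exc)

    # stage 5: stratification
    try:
        layer_table = layer_means(dataset.profiles, cfg.water_column_depth)
        shape_classes = {m: classify_shape(s) for m, s in layer_table.items()}
        boundaries = StageBoundaries(
            rapid_end=cfg.stage_boundaries[0], stable_end=cfg.stage_boundaries[1]
        )
        summaries = stage_means(dataset.profiles, boundaries)
        stage_table = (
            pd.DataFrame(
                [(s.stage, s.metal, s.mean_conc) for s in summaries],
                columns=["stage", "metal", "mean_conc"],
            )
            .pivot(index="stage", columns="metal", values="mean_conc")
        )
        change_rows = []
        for metal in stage_table.columns:
            for prev, cur in (("rapid", "stable"), ("stable", "melting")):
                if prev in stage_table.index and cur in stage_table.index:
                    ch: StageChange = stage_change(
                        float(stage_table.loc[prev, metal]),
                        float(stage_table.loc[cur, metal]),
                    )
                    change_rows.append(
                        (metal, f"{prev}->{cur}", ch.difference,
                         ch.percent_change, ch.fold_decrease)
                    )
        stage_changes = pd.DataFrame(
            change_rows,
            columns=["metal", "transition", "difference_ugL",
                     "percent_change", "fold_decrease"],
        )
    except UnderIceError as exc:
        raise PipelineError("stratify", str(exc), exc)

    # stage 6: evaluation
    try:
        errors = compare_methods(
            dataset.profiles, surfaces, baselines, metric=cfg.metric
        )
    except UnderIceError as exc:
        raise PipelineError("evaluate", str(exc), exc)

    return PipelineResult(
        fits=fits,
        evolutions=evolutions,
        surfaces=surfaces,
        baselines=baselines,
        layer_table=layer_table,
        shape_classes=shape_classes,
        stage_table=stage_table,
        stage_changes=stage_changes,
        errors=errors,
    )
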