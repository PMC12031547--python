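"""Structured (YAML) configuration shared by all pipeline stages.

One file can carry a ``synthetic`` section (keys mirroring
:class:`~underice.synthetic.SyntheticConfig`) and a ``pipeline`` section
(keys mirroring :class:`~underice.io.PipelineConfig` and its nested fit
and smoother settings).  Unknown keys are rejected so typos fail loudly.
"""

from __future__ import annotations

import datetime as dt
from pathlib import Path

import yaml

from .ctype import FitOptions
from .errors import ValidationError
from .evolution import LinearLaw, PARAM_NAMES, ParamEvolution
from .io import PipelineConfig
from .smoothers import SmootherSettings
from .synthetic import (
    DEFAULT_METALS,
    IceTrajectoryConfig,
    SyntheticConfig,
    default_true_evolutions,
)

__all__ = [
    "load_config",
    "load_pipeline_config",
    "load_synthetic_config",
    "synthetic_config_to_dict",
    "save_synthetic_config",
]


def _check_keys(section: dict, allowed: set[str], where: str) -> None:
    unknown = set(section) - allowed
    if unknown:
        raise ValidationError(f"{where}: unknown configuration keys {sorted(unknown)}")


def _build_fit(section: dict) -> FitOptions:
    _check_keys(section, {f.name for f in FitOptions.__dataclass_fields__.values()}, "fit")
    if "b_starts" in section:
        section["b_starts"] = tuple(section["b_starts"])
    if "d_starts" in section:
        section["d_starts"] = tuple(section["d_starts"])
    return FitOptions(**section)


def _build_smoothers(section: dict) -> SmootherSettings:
    allowed = {f.name for f in SmootherSettings.__dataclass_fields__.values()}
    _check_keys(section, allowed, "smoothers")
    return SmootherSettings(**section)


def _build_pipeline(section: dict) -> PipelineConfig:
    allowed = {
        "fit", "smoothers", "water_column_depth", "stage_boundaries",
        "metric", "joint_refine",
    }
    _check_keys(section, allowed, "pipeline")
    kwargs = dict(section)
    if "fit" in kwargs:
        kwargs["fit"] = _build_fit(dict(kwargs["fit"]))
    if "smoothers" in kwargs:
        kwargs["smoothers"] = _build_smoothers(dict(kwargs["smoothers"]))
    if "stage_boundaries" in kwargs:
        kwargs["stage_boundaries"] = tuple(float(x) for x in kwargs["stage_boundaries"])
    return PipelineConfig(**kwargs)


def _build_evolutions(section: dict) -> dict[str, ParamEvolution]:
    out = {}
    for metal, laws in section.items():
        missing = [n for n in PARAM_NAMES if n not in laws]
        if missing:
            raise ValidationError(
                f"synthetic.true_evolutions.{metal}: missing params {missing}"
            )
        out[str(metal)] = ParamEvolution(
            **{
                n: LinearLaw(float(laws[n]["alpha"]), float(laws[n]["beta"]))
                for n in PARAM_NAMES
            },
            metal=str(metal),
        )
    return out


def _build_synthetic(section: dict) -> SyntheticConfig:
    allowed = {
        "metals", "true_evolutions", "sampling_times", "depth_grid",
        "noise_cv", "ice_endpoints", "seed", "freeze_onset",
    }
    _check_keys(section, allowed, "synthetic")
    kwargs: dict = {}
    if "metals" in section:
        kwargs["metals"] = tuple(str(m) for m in section["metals"])
    if "sampling_times" in section:
        kwargs["sampling_times"] = tuple(float(t) for t in section["sampling_times"])
    if "depth_grid" in section:
        kwargs["depth_grid"] = tuple(float(h) for h in section["depth_grid"])
    for key in ("noise_cv", "seed"):
        if key in section:
            kwargs[key] = section[key]
    if "freeze_onset" in section:
        raw = section["freeze_onset"]
        kwargs["freeze_onset"] = (
            raw if isinstance(raw, dt.date) else dt.date.fromisoformat(str(raw))
        )
    if "ice_endpoints" in section:
        ice = section["ice_endpoints"]
        kwargs["ice"] = IceTrajectoryConfig(
            knot_times=tuple(float(t) for t in ice["knot_times"]),
            thickness_mm=tuple(float(x) for x in ice["thickness_mm"]),
        )
    if "true_evolutions" in section:
        kwargs["true_evolutions"] = _build_evolutions(section["true_evolutions"])
    else:
        kwargs["true_evolutions"] = default_true_evolutions(
            kwargs.get("metals", DEFAULT_METALS)
        )
    return SyntheticConfig(**kwargs)


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValidationError(f"{path}: top level must be a mapping")
    _check_keys(data, {"synthetic", "pipeline"}, str(path))
    out = {}
    if "pipeline" in data:
        out["pipeline"] = _build_pipeline(dict(data["pipeline"]))
    if "synthetic" in data:
        out["synthetic"] = _build_synthetic(dict(data["synthetic"]))
    return out


def load_pipeline_config(path: str | Path) -> PipelineConfig:
    return load_config(path).get("pipeline", PipelineConfig())


def load_synthetic_config(path: str | Path) -> SyntheticConfig:
    cfg = load_config(path).get("synthetic")
    if cfg is None:
        raise ValidationError(f"{path}: no 'synthetic' section")
    return cfg


def synthetic_config_to_dict(config: SyntheticConfig) -> dict:
    """Mirror a SyntheticConfig as plain YAML-serialisable data."""
    return {
        "synthetic": {
            "metals": list(config.metals),
            "sampling_times": [float(t) for t in config.sampling_times],
            "depth_grid": [float(h) for h in config.depth_grid],
            "noise_cv": float(config.noise_cv),
            "seed": int(config.seed),
            "freeze_onset": config.freeze_onset.isoformat(),
            "ice_endpoints": {
                "knot_times": [float(t) for t in config.ice.knot_times],
                "thickness_mm": [float(x) for x in config.ice.thickness_mm],
            },
            "true_evolutions": {
                metal: {
                    name: {
                        "alpha": float(evo.law(name).alpha),
                        "beta": float(evo.law(name).beta),
                    }
                    for name in PARAM_NAMES
                }
                for metal, evo in config.true_evolutions.items()
            },
        }
    }


def save_synthetic_config(config: SyntheticConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(synthetic_config_to_dict(config), fh, sort_keys=False)
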