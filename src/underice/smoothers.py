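"""Comparison predictors: dyadic wavelet smoothing and moving averages.

Both baselines smooth each sampling date's depth series independently and
are scored at the observed sample points, exactly like the C-type model
surface.  The moving average uses a centred window that is truncated at
the series ends (the first point averages itself and one neighbour, and
so on).  The wavelet smoother performs an orthogonal discrete wavelet
decomposition with scales at powers of two, optionally shrinking or
zeroing the detail coefficients before inverting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import pywt

from .ctype import Profile
from .errors import ValidationError

__all__ = [
    "SmootherSettings",
    "moving_average",
    "wavelet_smooth",
    "smooth_field",
    "default_level",
]

THRESHOLD_RULES = ("none", "universal-soft", "approx-only")
METHODS = ("wavelet", "moving_average")


@dataclass(frozen=True)
class SmootherSettings:
    """Configuration for both baselines.

    Attributes
    ----------
    wavelet_family : str
        Any PyWavelets discrete family name (default Daubechies-4).
    decomposition_level : int or None
        Dyadic depth; ``None`` selects ``max(1, floor(log2 n) - 2)``.
    threshold_rule : str
        ``universal-soft`` (soft-threshold details at the universal level
        ``sigma * sqrt(2 ln n)``), ``approx-only`` (zero all details), or
        ``none`` (pure round trip).
    ma_span : int
        Odd centred window length for the moving average.
    """

    wavelet_family: str = "db4"
    decomposition_level: int | None = None
    threshold_rule: str = "universal-soft"
    ma_span: int = 3

    def __post_init__(self):
        if self.threshold_rule not in THRESHOLD_RULES:
            raise ValidationError(
                f"SmootherSettings.threshold_rule must be one of "
                f"{THRESHOLD_RULES}, got {self.threshold_rule!r}"
            )
        if self.ma_span < 1 or self.ma_span % 2 == 0:
            raise ValidationError(
                f"SmootherSettings.ma_span must be odd and >= 1, got {self.ma_span}"
            )
        if self.decomposition_level is not None and self.decomposition_level < 1:
            raise ValidationError(
                "SmootherSettings.decomposition_level must be >= 1 when given"
            )


def default_level(n: int) -> int:
    """Default dyadic decomposition depth for a length-``n`` series."""
    return max(1, int(math.floor(math.log2(n))) - 2)


def moving_average(series: Sequence[float], span: int) -> np.ndarray:
    """Centred moving average with windows truncated at the ends.

    Each point is replaced by the mean of the points within ``(span-1)/2``
    positions of it that actually exist, so the output has the same length
    as the input and the end points average over shorter windows.
    """
    x = np.asarray(series, dtype=float)
    if x.ndim != 1:
        raise ValidationError("moving_average: series must be 1-D")
    if span % 2 == 0 or span < 1:
        raise ValidationError(f"moving_average: span must be odd and >= 1, got {span}")
    if span > x.size:
        raise ValidationError(
            f"moving_average: span {span} exceeds series length {x.size}"
        )
    if span == 1:
        return x.copy()
    k = span // 2
    csum = np.concatenate(([0.0], np.cumsum(x)))
    idx = np.arange(x.size)
    lo = np.maximum(idx - k, 0)
    hi = np.minimum(idx + k, x.size - 1)
    return (csum[hi + 1] - csum[lo]) / (hi - lo + 1)


def wavelet_smooth(
    series: Sequence[float], settings: SmootherSettings | None = None
) -> np.ndarray:
    """Dyadic DWT smoothing of one series.

    Decomposes to the configured level with symmetric signal extension
    (which accommodates non-dyadic lengths), applies the threshold rule to
    every detail band, and inverts.  Output length equals input length.
    """
    st = settings or SmootherSettings()
    x = np.asarray(series, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValidationError("wavelet_smooth: series must be 1-D with length >= 2")
    wavelet = pywt.Wavelet(st.wavelet_family)
    max_level = pywt.dwt_max_level(x.size, wavelet.dec_len)
    max_level = max(max_level, 1)
    level = st.decomposition_level or min(default_level(x.size), max_level)
    if level > max_level:
        raise ValidationError(
            f"wavelet_smooth: level {level} exceeds dyadic maximum {max_level} "
            f"for length {x.size}"
        )
    coeffs = pywt.wavedec(x, wavelet, level=level, mode="symmetric")
    approx, details = coeffs[0], coeffs[1:]
    if st.threshold_rule == "approx-only":
        details = [np.zeros_like(d) for d in details]
    elif st.threshold_rule == "universal-soft":
        finest = details[-1]
        sigma = float(np.median(np.abs(finest))) / 0.6745 if finest.size else 0.0
        thr = sigma * math.sqrt(2.0 * math.log(x.size))
        details = [pywt.threshold(d, thr, mode="soft") for d in details]
    # rule "none": keep all coefficients (perfect reconstruction)
    rec = pywt.waverec([approx] + list(details), wavelet, mode="symmetric")
    return np.asarray(rec[: x.size], dtype=float)


def smooth_field(
    profiles: Iterable[Profile],
    method: str,
    settings: SmootherSettings | None = None,
) -> pd.DataFrame:
    """Smooth every profile along depth with one baseline method.

    Returns a long-format frame with columns ``metal``, ``time_d``,
    ``depth_cm``, ``conc_pred_ugL`` and ``method``, aligned row-for-row
    with the observed sample points.
    """
    st = settings or SmootherSettings()
    if method not in METHODS:
        raise ValidationError(
            f"smooth_field: unknown method {method!r}; expected one of {METHODS}"
        )
    profs = list(profiles)
    if not profs:
        raise ValidationError("smooth_field: no profiles")
    rows = []
    for p in profs:
        if method == "moving_average":
            pred = moving_average(p.concentrations, st.ma_span)
        else:
            pred = wavelet_smooth(p.concentrations, st)
        rows.append(
            pd.DataFrame(
                {
                    "metal": p.metal,
                    "time_d": p.time,
                    "depth_cm": p.depths,
                    "conc_pred_ugL": pred,
                    "method": method,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)
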