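"""Normalized behavioral variables: whisker asymmetry, pupil deviation,
and epoch time-warping.

Conventions used throughout the pipeline:

* Whisker angles increase with protraction; per-trial values are expressed
  as a percentage of the full range of deviation within that trial, after
  centering on the session median angle (the provisional zero).
* The head-centered eye axis is leftward-positive.  Per-eye normalized
  pupil positions run 0 (nasal) -> 1 (temporal), so the left eye's axis
  already points leftward while the right eye's must be flipped.
* Trial-direction signing: asymmetry is right-minus-left for left-turn
  trials and left-minus-right for right-turn trials, so positive values
  always point toward the cued turn.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import AnalysisError

__all__ = [
    "NormalizedTrace",
    "AsymmetryTrace",
    "interpolate_missing",
    "normalize_whisker",
    "asymmetry",
    "to_head_centered",
    "pupil_deviation",
    "time_normalize",
    "downsample_to_eye_clock",
    "epoch_summary",
]


@dataclass
class NormalizedTrace:
    values: np.ndarray  # percent units; NaN outside trials
    rate: float  # frames/s of the trace clock
    meta: dict = field(default_factory=dict)


@dataclass
class AsymmetryTrace:
    values: np.ndarray  # percentage points, signed toward the cued turn
    rate: float
    direction: str
    direction_convention: str


def interpolate_missing(values, max_missing_frac: float = 0.5):
    """Fill NaN runs by linear interpolation (edge values held).

    Returns (filled array, number of filled samples).  Raises if everything
    is missing or more than ``max_missing_frac`` of the samples are.
    """
    v = np.asarray(values, dtype=float).copy()
    if v.ndim != 1 or len(v) == 0:
        raise AnalysisError("interpolate_missing requires a non-empty 1D trace")
    missing = np.isnan(v)
    n_missing = int(missing.sum())
    if n_missing == 0:
        return v, 0
    if n_missing == len(v):
        raise AnalysisError("trace is entirely missing")
    if n_missing / len(v) > max_missing_frac:
        raise AnalysisError(
            f"missing fraction {n_missing / len(v):.2f} exceeds {max_missing_frac}"
        )
    idx = np.arange(len(v))
    v[missing] = np.interp(idx[missing], idx[~missing], v[~missing])
    return v, n_missing


def normalize_whisker(angles, trial_bounds, session_median: float | None = None) -> NormalizedTrace:
    """Session-median centering followed by per-trial range normalization.

    ``trial_bounds`` is a list of (start, end) frame ranges (end-exclusive).
    Within each trial, output = 100 * (angle - trial_min)/(trial_max - trial_min);
    frames outside any trial are NaN.  A constant trial raises.
    """
    a = np.asarray(angles, dtype=float)
    if a.ndim != 1:
        raise AnalysisError("angles must be a 1D trace")
    if session_median is None:
        session_median = float(np.nanmedian(a))
    centered = a - session_median
    out = np.full_like(centered, np.nan)
    per_trial = []
    for start, end in trial_bounds:
        if not (0 <= start < end <= len(a)):
            raise AnalysisError(f"trial bounds ({start}, {end}) outside trace of length {len(a)}")
        seg = centered[start:end]
        lo, hi = np.nanmin(seg), np.nanmax(seg)
        if not np.isfinite(lo) or not np.isfinite(hi) or hi - lo <= 0:
            raise AnalysisError(f"degenerate whisker range in trial frames ({start}, {end})")
        out[start:end] = 100.0 * (seg - lo) / (hi - lo)
        per_trial.append({"start": int(start), "end": int(end), "min": float(lo), "max": float(hi)})
    return NormalizedTrace(out, rate=np.nan, meta={"session_median": float(session_median), "trials": per_trial})


def asymmetry(w_left, w_right, direction: str, rate: float = np.nan) -> AsymmetryTrace:
    """Signed whisker asymmetry: right-minus-left for left turns, flipped for right."""
    wl = w_left.values if isinstance(w_left, NormalizedTrace) else np.asarray(w_left, dtype=float)
    wr = w_right.values if isinstance(w_right, NormalizedTrace) else np.asarray(w_right, dtype=float)
    if wl.shape != wr.shape:
        raise AnalysisError("left/right whisker traces must share a clock and length")
    if direction == "left":
        vals, conv = wr - wl, "right_minus_left"
    elif direction == "right":
        vals, conv = wl - wr, "left_minus_right"
    else:
        raise AnalysisError(f"unknown direction: {direction!r}")
    return AsymmetryTrace(vals, rate=rate, direction=direction, direction_convention=conv)


def to_head_centered(normalized_position, eye_side: str, reference: float | None = None):
    """Per-eye normalized pupil position -> head-centered leftward-positive deviation.

    Deviations are in percent of eye width, relative to ``reference``
    (default: session median of the trace).  The right eye's nasal->temporal
    axis points rightward, so it is negated.
    """
    p = np.asarray(normalized_position, dtype=float)
    if eye_side not in ("left", "right"):
        raise AnalysisError(f"unknown eye side: {eye_side!r}")
    if reference is None:
        reference = float(np.nanmedian(p))
    sign = 1.0 if eye_side == "left" else -1.0
    return sign * 100.0 * (p - reference)


def pupil_deviation(left_eye, right_eye, direction: str):
    """Mean of the two eyes' head-centered deviations, signed toward the turn.

    Both inputs must already be on the head-centered leftward-positive axis
    (see :func:`to_head_centered`).
    """
    le = left_eye.values if isinstance(left_eye, NormalizedTrace) else np.asarray(left_eye, dtype=float)
    re = right_eye.values if isinstance(right_eye, NormalizedTrace) else np.asarray(right_eye, dtype=float)
    if le.shape != re.shape:
        raise AnalysisError("eye traces must share a clock and length")
    mean_dev = (le + re) / 2.0
    if direction == "left":
        return mean_dev
    if direction == "right":
        return -mean_dev
    raise AnalysisError(f"unknown direction: {direction!r}")


def time_normalize(values, n_points: int):
    """Resample a trace onto the normalized [0, 1] epoch time base.

    Linear interpolation; endpoint values are preserved exactly.
    """
    v = np.asarray(values, dtype=float)
    if v.ndim != 1 or len(v) < 2:
        raise AnalysisError("time_normalize requires an epoch of >=2 samples")
    if n_points < 2:
        raise AnalysisError("n_points must be >=2")
    src = np.linspace(0.0, 1.0, len(v))
    dst = np.linspace(0.0, 1.0, n_points)
    return np.interp(dst, src, v)


def downsample_to_eye_clock(values, factor: int):
    """Average consecutive ``factor``-sample blocks (behavior -> eye clock)."""
    v = np.asarray(values, dtype=float)
    if factor < 1:
        raise AnalysisError("factor must be >=1")
    n = (len(v) // factor) * factor
    if n == 0:
        raise AnalysisError("trace shorter than one downsampling block")
    return v[:n].reshape(-1, factor).mean(axis=1)


def epoch_summary(grouped_traces, n_points: int = 101):
    """Median trace, IQR band, and per-epoch means per group.

    ``grouped_traces`` maps a group key (e.g. (state, direction)) to a list
    of epoch traces; each trace is resampled onto ``n_points`` normalized
    time points before summarizing.
    """
    out = {}
    for key, traces in grouped_traces.items():
        if len(traces) == 0:
            raise AnalysisError(f"group {key!r} has no epochs")
        resampled = np.vstack([time_normalize(t, n_points) for t in traces])
        out[key] = {
            "median": np.nanmedian(resampled, axis=0),
            "p25": np.nanpercentile(resampled, 25, axis=0),
            "p75": np.nanpercentile(resampled, 75, axis=0),
            "epoch_means": np.nanmean(resampled, axis=1),
            "n": len(traces),
        }
    return out
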