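"""Saccade-triggered whisker-asymmetry correlograms during backward movement.

Each retained saccade inside a backward epoch yields one lag-aligned
asymmetry trace; leftward and rightward events are pooled after signing the
raw (right-minus-left) asymmetry toward each event's direction.  The null
redraws every event time uniformly within its own trial's backward epoch.
Per-lag medians and IQR bands, 100-ms-bin medians per trace, and bin-wise
Mann-Whitney tests against the shuffled null quantify the coupling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import AnalysisError
from .saccade_detection import SaccadeEvent
from .stats_nonparametric import bonferroni, mann_whitney_u

__all__ = [
    "CorrelogramResult",
    "events_in_backward",
    "triggered_traces",
    "shuffle_event_times",
    "correlogram",
    "DEFAULT_WINDOW",
    "CORRELOGRAM_BIN_S",
]

DEFAULT_WINDOW = (-0.5, 0.8)  # seconds around saccade onset
CORRELOGRAM_BIN_S = 0.1


def events_in_backward(events, trials, eye_rate: float, behavior_rate: float):
    """Restrict events to backward epochs; returns (event, (start, end)) pairs
    with the parent epoch bounds converted to the eye clock."""
    factor = behavior_rate / eye_rate
    out = []
    for ev in events:
        for trial in trials:
            ep = trial.epoch("backward")
            if ep is None:
                continue
            s_eye, e_eye = ep[1] / factor, ep[2] / factor
            if s_eye <= ev.frame < e_eye:
                out.append((ev, (int(round(s_eye)), int(round(e_eye)))))
                break
    return out


def triggered_traces(asym_eye_clock, event_epoch_pairs, window=DEFAULT_WINDOW, rate: float = 100.0):
    """One lag-aligned trace per event; samples outside the epoch are NaN.

    ``asym_eye_clock`` is the raw right-minus-left asymmetry resampled to
    the eye clock; each trace is signed toward its event's direction so
    that positive values mean asymmetry toward where the eyes went.
    """
    asym = np.asarray(asym_eye_clock, dtype=float)
    lo, hi = window
    if hi <= lo:
        raise AnalysisError("window must satisfy lo < hi")
    lags = np.arange(int(round(lo * rate)), int(round(hi * rate)) + 1)
    traces = []
    for ev, (e_start, e_end) in event_epoch_pairs:
        idx = ev.frame + lags
        tr = np.full(len(lags), np.nan)
        ok = (idx >= e_start) & (idx < e_end) & (idx >= 0) & (idx < len(asym))
        tr[ok] = asym[idx[ok]]
        if ev.direction == "rightward":
            tr = -tr
        traces.append(tr)
    return np.asarray(traces), lags / rate


def shuffle_event_times(event_epoch_pairs, n_shuffles: int, seed: int = 0, rate: float = 100.0):
    """Surrogate event sets: each event's time redrawn uniformly within its
    own epoch; directions preserved; per-trial event counts preserved."""
    rng = np.random.default_rng(seed)
    surrogates = []
    for _ in range(n_shuffles):
        one = []
        for ev, (e_start, e_end) in event_epoch_pairs:
            f = int(rng.integers(e_start, e_end))
            one.append(
                (
                    SaccadeEvent(
                        frame=f,
                        time=f / rate,
                        direction=ev.direction,
                        amplitude=ev.amplitude,
                        peak_speed=ev.peak_speed,
                        eye_speeds=ev.eye_speeds,
                    ),
                    (e_start, e_end),
                )
            )
        surrogates.append(one)
    return surrogates


@dataclass
class CorrelogramResult:
    lags: np.ndarray  # seconds relative to saccade onset
    traces: np.ndarray  # (n_events, n_lags)
    median: np.ndarray
    p25: np.ndarray
    p75: np.ndarray
    null_median: np.ndarray
    null_p25: np.ndarray
    null_p75: np.ndarray
    bin_edges: np.ndarray  # seconds
    bin_medians: np.ndarray  # (n_events, n_bins) per-trace 100-ms bin medians
    null_bin_medians: np.ndarray
    bin_tests: list  # TestResult per bin, Bonferroni-corrected
    bin_p_uncorrected: np.ndarray

    @property
    def n_events(self) -> int:
        return len(self.traces)


def _bin_trace_medians(traces: np.ndarray, lags: np.ndarray, bin_s: float):
    lo, hi = lags[0], lags[-1]
    n_bins = int(round((hi - lo) / bin_s))
    edges = lo + np.arange(n_bins + 1) * bin_s
    meds = np.full((len(traces), n_bins), np.nan)
    for b in range(n_bins):
        sel = (lags >= edges[b] - 1e-9) & (lags < edges[b + 1] - 1e-9)
        if sel.any():
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                meds[:, b] = np.nanmedian(traces[:, sel], axis=1)
    return edges, meds


def correlogram(
    traces: np.ndarray,
    lags_s: np.ndarray,
    null_traces: np.ndarray,
    bin_s: float = CORRELOGRAM_BIN_S,
    min_count: int = 3,
    correct: bool = True,
):
    """Median/IQR correlogram with per-100-ms-bin statistics vs the null.

    Per-lag summaries are computed over available (non-NaN) traces only,
    masked where fewer than ``min_count`` traces contribute.  Bin-wise
    Mann-Whitney tests compare the distribution of per-trace bin medians
    between the real and shuffled event sets; with ``correct`` the p-values
    are Bonferroni-adjusted over the number of bins.
    """
    if len(traces) == 0:
        raise AnalysisError("correlogram requires at least one event trace")
    if traces.shape[1] != len(lags_s) or null_traces.shape[1] != len(lags_s):
        raise AnalysisError("real and shuffled traces must share the lag axis")

    def _summ(tr):
        counts = np.sum(np.isfinite(tr), axis=0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            med = np.nanmedian(tr, axis=0)
            p25 = np.nanpercentile(tr, 25, axis=0)
            p75 = np.nanpercentile(tr, 75, axis=0)
        bad = counts < min_count
        med[bad] = p25[bad] = p75[bad] = np.nan
        return med, p25, p75

    med, p25, p75 = _summ(traces)
    nmed, np25, np75 = _summ(null_traces)
    edges, bin_meds = _bin_trace_medians(traces, lags_s, bin_s)
    _, null_bin_meds = _bin_trace_medians(null_traces, lags_s, bin_s)
    n_bins = bin_meds.shape[1]
    tests, p_raw = [], np.full(n_bins, np.nan)
    for b in range(n_bins):
        x = bin_meds[:, b][np.isfinite(bin_meds[:, b])]
        y = null_bin_meds[:, b][np.isfinite(null_bin_meds[:, b])]
        if len(x) == 0 or len(y) == 0:
            tests.append(None)
            continue
        r = mann_whitney_u(x, y)
        p_raw[b] = r.p_value
        if correct:
            from .stats_nonparametric import TestResult

            r = TestResult(
                r.statistic,
                bonferroni(r.p_value, n_bins),
                r.method,
                r.n,
                correction=f"bonferroni(m={n_bins})",
            )
        tests.append(r)
    return CorrelogramResult(
        lags=lags_s,
        traces=traces,
        median=med,
        p25=p25,
        p75=p75,
        null_median=nmed,
        null_p25=np25,
        null_p75=np75,
        bin_edges=edges,
        bin_medians=bin_meds,
        null_bin_medians=null_bin_meds,
        bin_tests=tests,
        bin_p_uncorrected=p_raw,
    )
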