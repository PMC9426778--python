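"""Conjugate saccade detection from normalized pupil positions.

An event requires the absolute eye speed (first difference of normalized
pupil position, percent of eye width per frame) of BOTH eyes to cross the
threshold with the same sign within a small conjugacy window.  Trains of
candidate events closer together than the refractory interval are treated
as processing artifacts and discarded in full.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import AnalysisError

__all__ = [
    "SaccadeEvent",
    "SaccadeHistogram",
    "eye_speed",
    "detect_saccades",
    "saccade_histogram",
    "HISTOGRAM_STATES",
]

#: default detection threshold, percent of full eye width per frame
SPEED_THRESHOLD = 0.1
#: default refractory interval in seconds
REFRACTORY_S = 0.25

HISTOGRAM_STATES = ("end_of_lane", "backward", "turn", "forward")


@dataclass(frozen=True)
class SaccadeEvent:
    frame: int  # eye-clock position frame at which the step lands
    time: float  # seconds
    direction: str  # "leftward" | "rightward" on the head-centered axis
    amplitude: float  # net mean-eye displacement across the run, % eye width
    peak_speed: float  # mean-eye speed at the event frame, % width / frame
    eye_speeds: tuple[float, float]  # (left, right) speeds at the peak

    def __post_init__(self) -> None:
        if self.direction not in ("leftward", "rightward"):
            raise AnalysisError(f"bad saccade direction: {self.direction!r}")


def eye_speed(positions):
    """First difference of a position trace; element i is the step into frame i+1."""
    p = np.asarray(positions, dtype=float)
    if p.ndim != 1 or len(p) < 2:
        raise AnalysisError("eye_speed requires >=2 samples")
    return np.diff(p)


def _supra_masks(speed, threshold):
    """(positive, negative) supra-threshold masks; NaNs never fire."""
    with np.errstate(invalid="ignore"):
        pos = speed > threshold
        neg = speed < -threshold
    return pos, neg


def _dilate(mask, w):
    if w == 0:
        return mask.copy()
    out = mask.copy()
    for k in range(1, w + 1):
        out[k:] |= mask[:-k]
        out[:-k] |= mask[k:]
    return out


def detect_saccades(
    left_speed,
    right_speed,
    threshold: float = SPEED_THRESHOLD,
    refractory_s: float = REFRACTORY_S,
    rate: float = 100.0,
    conjugacy_frames: int = 1,
    keep_first_of_train: bool = False,
):
    """Detect conjugate saccades from the two eyes' speed traces.

    Speeds are in percent of eye width per frame on the head-centered
    leftward-positive axis.  Candidate events are contiguous runs where both
    eyes exceed ``threshold`` with the same sign within ``conjugacy_frames``;
    the event frame is the peak of the absolute mean two-eye speed within
    the run and the amplitude is the net mean displacement across the run.
    Any train of candidates with inter-event intervals shorter than
    ``refractory_s`` is discarded entirely (set ``keep_first_of_train`` to
    retain the first event of each train for sensitivity analyses).
    """
    ls = np.asarray(left_speed, dtype=float)
    rs = np.asarray(right_speed, dtype=float)
    if ls.shape != rs.shape or ls.ndim != 1:
        raise AnalysisError("left/right speed traces must be 1D and the same length")
    if threshold <= 0:
        raise AnalysisError("threshold must be positive")
    lp, ln = _supra_masks(ls, threshold)
    rp, rn = _supra_masks(rs, threshold)
    w = int(conjugacy_frames)
    conj_pos = (lp & _dilate(rp, w)) | (rp & _dilate(lp, w))
    conj_neg = (ln & _dilate(rn, w)) | (rn & _dilate(ln, w))

    mean_speed = (ls + rs) / 2.0
    candidates = []
    for mask, sign in ((conj_pos, 1.0), (conj_neg, -1.0)):
        idx = np.nonzero(mask)[0]
        if len(idx) == 0:
            continue
        # split into contiguous runs
        breaks = np.nonzero(np.diff(idx) > 1)[0]
        for run in np.split(idx, breaks + 1):
            seg = mean_speed[run]
            seg = np.where(np.isnan(seg), 0.0, seg)
            peak_pos = run[int(np.argmax(sign * seg))]
            amplitude = float(np.sum(seg))
            candidates.append(
                SaccadeEvent(
                    frame=int(peak_pos) + 1,
                    time=(int(peak_pos) + 1) / rate,
                    direction="leftward" if sign > 0 else "rightward",
                    amplitude=amplitude,
                    peak_speed=float(mean_speed[peak_pos]),
                    eye_speeds=(float(ls[peak_pos]), float(rs[peak_pos])),
                )
            )
    candidates.sort(key=lambda e: e.frame)

    # refractory rule: discard whole trains of closely spaced candidates
    refractory_frames = refractory_s * rate
    events: list[SaccadeEvent] = []
    i = 0
    while i < len(candidates):
        j = i
        while j + 1 < len(candidates) and candidates[j + 1].frame - candidates[j].frame < refractory_frames:
            j += 1
        if j == i:
            events.append(candidates[i])
        elif keep_first_of_train:
            events.append(candidates[i])
        i = j + 1
    return events


@dataclass
class SaccadeHistogram:
    """Saccade counts in 10 normalized-time bins per state, split by
    trial direction and event direction."""

    counts: dict  # counts[trial_dir][state][event_dir] -> np.ndarray(n_bins)
    unassigned: int
    n_bins: int

    def total(self) -> int:
        return int(
            sum(
                arr.sum()
                for per_state in self.counts.values()
                for per_dir in per_state.values()
                for arr in per_dir.values()
            )
        )


def _state_group(state: str) -> str | None:
    if state in ("turn_left", "turn_right"):
        return "turn"
    if state in HISTOGRAM_STATES:
        return state
    return None


def saccade_histogram(events, trials, eye_rate: float, behavior_rate: float, n_bins: int = 10) -> SaccadeHistogram:
    """Bin saccade times by within-epoch normalized time.

    Each event is assigned to the behavioral epoch enclosing it; its
    normalized time within the epoch is binned into ``n_bins`` equal bins.
    Events outside the covered states (or outside any trial) are counted
    as unassigned.
    """
    counts = {
        td: {st: {"leftward": np.zeros(n_bins, dtype=int), "rightward": np.zeros(n_bins, dtype=int)}
             for st in HISTOGRAM_STATES}
        for td in ("left", "right")
    }
    unassigned = 0
    for ev in events:
        bframe = ev.time * behavior_rate
        placed = False
        for trial in trials:
            for state, start, end in trial.epochs:
                if start <= bframe < end:
                    group = _state_group(state)
                    if group is None:
                        break
                    u = (bframe - start) / (end - start)
                    b = min(int(u * n_bins), n_bins - 1)
                    counts[trial.cued_direction][group][ev.direction][b] += 1
                    placed = True
                    break
            if placed:
                break
        if not placed:
            unassigned += 1
    return SaccadeHistogram(counts=counts, unassigned=unassigned, n_bins=n_bins)
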