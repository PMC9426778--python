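"""Synthetic plus-maze sessions with full ground truth.

The generator emulates the statistical structure the downstream analyses
assume: state-sequenced trials (end-of-lane -> backward -> turn -> forward
-> expect-reward -> lick), mirror-image turn-dependent whisker asymmetry
that ramps up during backward movement, conjugate stepwise pupil deviation
toward the upcoming turn, saccadic steps concentrated late in the backward
epoch, and (optionally) whisker-asymmetry rises leading each saccade by a
known lag.  Everything injected is recorded in a :class:`GroundTruth`
sidecar so recovery can be tested stage by stage.

Scaling note: injected whisker setpoint offsets are expressed in "angle
units" d = 2*A*e / (200 - e) where A is the whisking amplitude (deg) and e
the requested asymmetry effect in percentage points, so that after
per-trial range normalization the plateau asymmetry equals e exactly on
noiseless data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigError
from .io_formats import SessionRecord, TrialRecord

__all__ = [
    "GeneratorConfig",
    "GroundTruth",
    "generate_session",
    "generate_keypoints",
    "eye_pixel_model",
    "whisker_pixel_model",
    "write_ground_truth",
    "read_ground_truth",
]

DEFAULT_EPOCH_RANGES: dict[str, tuple[float, float]] = {
    "end_of_lane": (1.0, 2.0),
    "backward": (1.5, 3.0),
    "turn": (1.0, 2.0),
    "forward": (1.5, 2.5),
    "expect_reward": (1.0, 2.0),
    "lick": (0.5, 1.5),
}

#: slope cap (percent eye width / eye frame) for every non-saccadic change in
#: pupil deviation; kept well below the 0.1 detection threshold so drifts and
#: relaxations never masquerade as saccades
RELAX_SLOPE = 0.05

ACTIVE_STATES = ("backward", "turn_left", "turn_right", "forward")


@dataclass
class GeneratorConfig:
    n_trials: int = 20
    p_left: float = 0.5
    epoch_duration_ranges: dict = field(default_factory=lambda: dict(DEFAULT_EPOCH_RANGES))
    behavior_rate: float = 200.0
    eye_rate: float = 100.0
    asymmetry_effect: float = 40.0  # peak whisker asymmetry, % of trial range
    asymmetry_ramp: float = 0.5  # fraction of backward epoch over which asymmetry ramps
    eye_effect: float = 8.0  # peak smooth pupil drift toward turn, % eye width
    saccade_rate: float = 0.8  # events/s during active states
    saccade_amplitude: tuple[float, float] = (3.0, 0.5)  # % eye width (mean, sd)
    asymmetry_lead: float = 0.15  # s by which asymmetry rise precedes saccades
    coupling_strength: float = 15.0  # per-saccade asymmetry bump, % points
    couple_saccades: bool = True
    saccade_late_bias: float = 2.0  # 0 = uniform timing within backward epoch
    p_saccade_toward: float = 0.85  # probability a saccade points toward the turn
    min_saccade_separation: float = 0.35  # s, enforced between injected events
    noise_sd_whisker: float = 1.0  # deg
    noise_sd_eye: float = 0.02  # % eye width (well below the 0.1 %/frame threshold)
    whisk_freq: float = 10.0  # Hz
    whisk_amplitude: float = 20.0  # deg
    inter_trial_gap: float = 0.5  # s
    artifact_rate: float = 0.0  # monocular spike artifacts / s (rejection tests)
    seed: int = 0

    def validate(self) -> None:
        if int(self.n_trials) < 1:
            raise ConfigError("n_trials must be >= 1")
        if not (0.0 <= self.p_left <= 1.0):
            raise ConfigError("p_left must lie in [0, 1]")
        for name in ("behavior_rate", "eye_rate", "whisk_freq", "whisk_amplitude"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be strictly positive")
        factor = self.behavior_rate / self.eye_rate
        if abs(factor - round(factor)) > 1e-9 or round(factor) < 1:
            raise ConfigError("behavior_rate must be an integer multiple of eye_rate")
        for state, rng_ in self.epoch_duration_ranges.items():
            lo, hi = rng_
            if lo <= 0 or hi < lo:
                raise ConfigError(f"epoch_duration_ranges[{state!r}] must be 0 < min <= max")
        missing = set(DEFAULT_EPOCH_RANGES) - set(self.epoch_duration_ranges)
        if missing:
            raise ConfigError(f"epoch_duration_ranges missing states: {sorted(missing)}")
        if not (0.0 <= self.asymmetry_effect < 100.0):
            raise ConfigError("asymmetry_effect must lie in [0, 100)")
        if not (0.0 < self.asymmetry_ramp <= 1.0):
            raise ConfigError("asymmetry_ramp must lie in (0, 1]")
        if self.eye_effect < 0:
            raise ConfigError("eye_effect must be >= 0")
        if self.saccade_rate < 0:
            raise ConfigError("saccade_rate must be >= 0")
        if self.saccade_amplitude[0] <= 0 or self.saccade_amplitude[1] < 0:
            raise ConfigError("saccade_amplitude must be (mean > 0, sd >= 0)")
        if self.asymmetry_lead < 0:
            raise ConfigError("asymmetry_lead must be >= 0")
        if self.coupling_strength < 0:
            raise ConfigError("coupling_strength must be >= 0")
        if self.saccade_late_bias < 0:
            raise ConfigError("saccade_late_bias must be >= 0")
        if not (0.0 <= self.p_saccade_toward <= 1.0):
            raise ConfigError("p_saccade_toward must lie in [0, 1]")
        if self.min_saccade_separation <= 0:
            raise ConfigError("min_saccade_separation must be > 0")
        if self.noise_sd_whisker < 0 or self.noise_sd_eye < 0:
            raise ConfigError("noise scales must be >= 0")
        if self.inter_trial_gap < 0:
            raise ConfigError("inter_trial_gap must be >= 0")
        if self.artifact_rate < 0:
            raise ConfigError("artifact_rate must be >= 0")


@dataclass
class GroundTruth:
    directions: list[str]  # per-trial cued direction
    epochs: list[list[tuple[str, int, int]]]  # per-trial (state, start, end), behavior clock
    saccades: list[dict]  # {trial_id, eye_frame, time, direction, amplitude, state}
    asymmetry_profiles: list[np.ndarray]  # per-trial nominal asymmetry (% points), behavior clock
    eye_deviation: np.ndarray  # true head-centered deviation (% width), eye clock
    config: GeneratorConfig

    def saccade_times(self) -> np.ndarray:
        return np.array([s["time"] for s in self.saccades])


def _relax_limited(target: np.ndarray, step_delta: np.ndarray, max_slope: float) -> np.ndarray:
    """Follow ``target`` with per-frame slope capped at ``max_slope``, except
    that injected saccade jumps in ``step_delta`` pass through unattenuated."""
    out = np.zeros_like(target)
    prev = 0.0
    for i in range(len(target)):
        jump = step_delta[i]
        want = target[i] - prev - jump
        prev = prev + jump + float(np.clip(want, -max_slope, max_slope))
        out[i] = prev
    return out


def generate_session(config: GeneratorConfig) -> tuple[SessionRecord, GroundTruth]:
    """Generate one synthetic session plus its ground truth.

    Identical config (including seed) produces identical output.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    factor = int(round(config.behavior_rate / config.eye_rate))

    state_order = ["end_of_lane", "backward", "turn", "forward", "expect_reward", "lick"]
    gap_eye = int(round(config.inter_trial_gap * config.eye_rate))

    # ---- lay out trials on the eye clock (behavior clock = factor x) ----
    trials: list[TrialRecord] = []
    directions: list[str] = []
    all_epochs: list[list[tuple[str, int, int]]] = []
    cursor_eye = gap_eye
    trial_layouts = []  # (trial_id, direction, {state: (eye_start, eye_end)})
    for t in range(int(config.n_trials)):
        direction = "left" if rng.random() < config.p_left else "right"
        layout = {}
        epochs_b = []
        start_eye = cursor_eye
        for state in state_order:
            lo, hi = config.epoch_duration_ranges[state]
            dur = rng.uniform(lo, hi)
            n_eye = max(2, int(round(dur * config.eye_rate)))
            label = f"turn_{direction}" if state == "turn" else state
            layout[state] = (cursor_eye, cursor_eye + n_eye)
            epochs_b.append((label, cursor_eye * factor, (cursor_eye + n_eye) * factor))
            cursor_eye += n_eye
        cursor_eye += gap_eye
        trials.append(TrialRecord(trial_id=t, cued_direction=direction, epochs=epochs_b))
        directions.append(direction)
        all_epochs.append(epochs_b)
        trial_layouts.append((t, direction, layout, start_eye))
    n_eye_frames = cursor_eye
    n_behavior_frames = n_eye_frames * factor

    # ---- injected saccades ----
    saccades: list[dict] = []
    for t, direction, layout, _ in trial_layouts:
        for state in ("backward", "turn", "forward"):
            s_eye, e_eye = layout[state]
            dur = (e_eye - s_eye) / config.eye_rate
            n_events = rng.poisson(config.saccade_rate * dur)
            if n_events == 0:
                continue
            u = rng.random(n_events)
            if state == "backward" and config.saccade_late_bias > 0:
                u = u ** (1.0 / (1.0 + config.saccade_late_bias))  # late-weighted
            frames = s_eye + np.floor(u * (e_eye - s_eye - 2)).astype(int) + 1
            amps = np.abs(rng.normal(*config.saccade_amplitude, size=n_events))
            amps = np.maximum(amps, 0.5)  # keep every injected step detectable
            toward = rng.random(n_events) < config.p_saccade_toward
            for f, a, tw in zip(np.sort(frames), amps, toward):
                sacc_dir = direction if tw else ("right" if direction == "left" else "left")
                saccades.append(
                    {
                        "trial_id": t,
                        "eye_frame": int(f),
                        "time": float(f / config.eye_rate),
                        "direction": "leftward" if sacc_dir == "left" else "rightward",
                        "amplitude": float(a),
                        "state": state if state != "turn" else f"turn_{direction}",
                    }
                )
    # enforce minimum separation session-wide (greedy thinning)
    saccades.sort(key=lambda s: s["eye_frame"])
    min_sep_frames = config.min_saccade_separation * config.eye_rate
    kept: list[dict] = []
    for s in saccades:
        if not kept or s["eye_frame"] - kept[-1]["eye_frame"] >= min_sep_frames:
            kept.append(s)
    saccades = kept

    # ---- eye traces ----
    sign_of = {"left": 1.0, "right": -1.0}
    min_sep_eye = int(np.ceil(min_sep_frames))

    # recentering ("return") saccades during the expect-reward epoch cancel
    # the accumulated deviation; they are injected events like any other so
    # detector recall/precision bookkeeping stays exact
    for t, direction, layout, _ in trial_layouts:
        drift_peak = config.eye_effect * sign_of[direction]
        net = drift_peak + sum(
            s["amplitude"] * (1.0 if s["direction"] == "leftward" else -1.0)
            for s in saccades
            if s["trial_id"] == t
        )
        if abs(net) < 0.5:
            continue  # small residual: the slope-limited relaxation handles it
        e0, e1 = layout["expect_reward"]
        first = e0 + min_sep_eye
        max_k = max(1, (e1 - 2 - first) // min_sep_eye + 1)
        k = int(min(max(1, np.ceil(abs(net) / 4.0)), abs(net) // 0.5 or 1, max_k))
        amp = abs(net) / k
        for j in range(k):
            f = first + j * min_sep_eye
            saccades.append(
                {
                    "trial_id": t,
                    "eye_frame": int(f),
                    "time": float(f / config.eye_rate),
                    "direction": "rightward" if net > 0 else "leftward",
                    "amplitude": float(amp),
                    "state": "expect_reward",
                    "return_saccade": True,
                }
            )
    saccades.sort(key=lambda s: s["eye_frame"])

    step_delta = np.zeros(n_eye_frames)
    for s in saccades:
        step_delta[s["eye_frame"]] += s["amplitude"] * (
            1.0 if s["direction"] == "leftward" else -1.0
        )
    target = np.zeros(n_eye_frames)
    for t, direction, layout, start_eye in trial_layouts:
        b0, b1 = layout["backward"]
        l1 = layout["lick"][1]
        t_end = min(n_eye_frames, l1 + gap_eye)
        drift_peak = config.eye_effect * sign_of[direction]
        drift = np.zeros(t_end - start_eye)
        drift[b0 - start_eye : b1 - start_eye] = np.linspace(0.0, drift_peak, b1 - b0, endpoint=True)
        drift[b1 - start_eye :] = drift_peak
        local_steps = np.cumsum(step_delta[start_eye:t_end])
        target[start_eye:t_end] = drift + local_steps
    deviation = _relax_limited(target, step_delta, RELAX_SLOPE)

    pupil_left = 0.5 + deviation / 100.0
    pupil_right = 0.5 - deviation / 100.0
    if config.noise_sd_eye > 0:
        pupil_left = pupil_left + rng.normal(0.0, config.noise_sd_eye / 100.0, n_eye_frames)
        pupil_right = pupil_right + rng.normal(0.0, config.noise_sd_eye / 100.0, n_eye_frames)
    if config.artifact_rate > 0:
        # monocular spikes: single-eye, single-frame excursions (rejection tests)
        n_art = rng.poisson(config.artifact_rate * n_eye_frames / config.eye_rate)
        for _ in range(n_art):
            f = int(rng.integers(1, n_eye_frames - 1))
            eye = rng.random() < 0.5
            spike = rng.choice([-1.0, 1.0]) * rng.uniform(2.0, 5.0) / 100.0
            if eye:
                pupil_left[f] += spike
            else:
                pupil_right[f] += spike

    # ---- whisker traces ----
    # The setpoint offset profile is two-sided within each trial: it rises
    # to its positive maximum during backward movement (base ramp plus any
    # saccade-coupled bumps), dips to exactly minus that maximum during the
    # turn (mirroring the reversal seen in real trials), and returns
    # positive during forward motion.  The symmetric excursion makes each
    # whisker's trial range [-(A+m), A+m] with m the peak offset, so after
    # per-trial range normalization the asymmetry equals 100*off/(A+m)
    # exactly on noiseless data; with d = A e / (100 - e) the base plateau
    # is e percentage points.
    A = config.whisk_amplitude
    e_pct = config.asymmetry_effect
    d_base = A * e_pct / (100.0 - e_pct)
    d_coupling = A * config.coupling_strength / (100.0 - e_pct)

    tb = np.arange(n_behavior_frames) / config.behavior_rate
    whisk = np.zeros(n_behavior_frames)
    offset = np.zeros(n_behavior_frames)  # angle units, direction-agnostic
    nominal_pct = np.zeros(n_behavior_frames)  # true asymmetry in % points
    dir_sign = np.zeros(n_behavior_frames)
    for t, direction, layout, _ in trial_layouts:
        phase = rng.uniform(0.0, 2.0 * np.pi)
        for state in ("backward", "turn", "forward"):
            s_eye, e_eye = layout[state]
            sl = slice(s_eye * factor, e_eye * factor)
            whisk[sl] = A * np.sin(2.0 * np.pi * config.whisk_freq * tb[sl] + phase)
        b0, b1 = (layout["backward"][0] * factor, layout["backward"][1] * factor)
        u0, u1 = (layout["turn"][0] * factor, layout["turn"][1] * factor)
        f0, f1 = (layout["forward"][0] * factor, layout["forward"][1] * factor)
        e0, e1 = (layout["expect_reward"][0] * factor, layout["expect_reward"][1] * factor)
        t_start, t_end = layout["end_of_lane"][0] * factor, layout["lick"][1] * factor
        dir_sign[t_start:t_end] = sign_of[direction]

        off = np.zeros(n_behavior_frames)
        ramp_start = b0 + int(round((1.0 - config.asymmetry_ramp) * (b1 - b0)))
        if b1 > ramp_start:
            off[ramp_start:b1] = d_base * np.linspace(0.0, 1.0, b1 - ramp_start, endpoint=True)
        if config.couple_saccades and config.coupling_strength > 0:
            for s in saccades:
                if s["trial_id"] != t or s["state"] != "backward":
                    continue
                fs = s["eye_frame"] * factor
                # the setpoint shift COMPLETES asymmetry_lead seconds before
                # the saccade (a rapid ~40 ms rise), so the per-trace bin
                # medians show the full elevation from -lead onward
                top = max(b0, fs - int(round(config.asymmetry_lead * config.behavior_rate)))
                rise0 = max(b0, top - int(round(0.04 * config.behavior_rate)))
                hold1 = min(u0, fs + int(round(0.4 * config.behavior_rate)))
                decay1 = min(u0, hold1 + int(round(0.3 * config.behavior_rate)))
                if top > rise0:
                    off[rise0:top] += d_coupling * np.linspace(0.0, 1.0, top - rise0, endpoint=False)
                off[top:hold1] += d_coupling
                if decay1 > hold1:
                    off[hold1:decay1] += d_coupling * np.linspace(1.0, 0.0, decay1 - hold1, endpoint=False)
        off_max = float(off[b0:u0].max()) if u0 > b0 else 0.0
        if off_max > 0:
            # Reversal during the turn and a second reversal during forward
            # motion.  Transitions are fast and the two holds (at -off_max in
            # the turn, +off_max in forward) have equal duration, so both
            # whiskers spend matched time at their trial extremes; otherwise
            # additive noise would inflate the two trial ranges unequally and
            # bias the normalized asymmetry away from zero outside the ramp.
            trans = max(2, int(round(0.2 * config.behavior_rate)))
            hold = max(0, min(u1 - u0, f1 - f0) - 2 * trans)
            off[u0:u1] = 0.0
            off[f0:f1] = 0.0
            seg = min(trans, u1 - u0)
            off[u0 : u0 + seg] = np.linspace(off[u0 - 1], -off_max, seg, endpoint=True)
            off[u0 + seg : u0 + seg + hold] = -off_max
            back = min(trans, max(0, u1 - (u0 + seg + hold)))
            off[u0 + seg + hold : u0 + seg + hold + back] = np.linspace(
                -off_max, 0.0, back, endpoint=True
            )
            seg = min(trans, f1 - f0)
            off[f0 : f0 + seg] = np.linspace(0.0, off_max, seg, endpoint=True)
            off[f0 + seg : f0 + seg + hold] = off_max
            back = min(trans, max(0, f1 - (f0 + seg + hold)))
            off[f0 + seg + hold : f0 + seg + hold + back] = np.linspace(
                off_max, 0.0, back, endpoint=True
            )
            nominal_pct[t_start:t_end] = 100.0 * off[t_start:t_end] / (A + off_max)
        offset[t_start:t_end] = off[t_start:t_end]

    whisker_right = whisk + dir_sign * offset
    whisker_left = whisk - dir_sign * offset
    if config.noise_sd_whisker > 0:
        whisker_left = whisker_left + rng.normal(0.0, config.noise_sd_whisker, n_behavior_frames)
        whisker_right = whisker_right + rng.normal(0.0, config.noise_sd_whisker, n_behavior_frames)

    session = SessionRecord(
        animal_id="synthetic",
        session_id=f"synthetic-{config.seed}",
        behavior_rate=config.behavior_rate,
        eye_rate=config.eye_rate,
        trials=trials,
        whisker_traces={"left": whisker_left, "right": whisker_right},
        pupil_traces={"left": pupil_left, "right": pupil_right},
        meta={
            "generator": "whiskeye.synthetic_data",
            "eye_axis": {"left": "low_x_nasal", "right": "high_x_nasal"},
        },
    )
    profiles = [
        (nominal_pct * (dir_sign != 0))[t.start_frame : t.end_frame] for t in trials
    ]
    truth = GroundTruth(
        directions=directions,
        epochs=all_epochs,
        saccades=saccades,
        asymmetry_profiles=profiles,
        eye_deviation=deviation,
        config=config,
    )
    return session, truth


# ---------------------------------------------------------------------------
# raw keypoint emission (geometry-stage recovery)

#: pixel model used by generate_keypoints; exposed so tests can verify
#: recovery against the analytic truth
_EYE_CORNERS_X = (40.0, 150.0)
_EYE_CORNER_Y = 100.0
_TOP_ALPHA = 0.02
_BOTTOM_BETA = 0.015
_PUPIL_RADIUS = 12.0


def eye_pixel_model(side: str) -> dict:
    """Analytic pixel-space eye model used for keypoint emission."""
    x1, x2 = _EYE_CORNERS_X
    # top: y = yc - alpha (x - x1)(x2 - x); bottom: y = yc + beta (x - x1)(x2 - x)
    top = (_TOP_ALPHA, -_TOP_ALPHA * (x1 + x2), _TOP_ALPHA * x1 * x2 + _EYE_CORNER_Y)
    bottom = (-_BOTTOM_BETA, _BOTTOM_BETA * (x1 + x2), -_BOTTOM_BETA * x1 * x2 + _EYE_CORNER_Y)
    nasal = "low_x" if side == "left" else "high_x"
    nasal_pt = (x1, _EYE_CORNER_Y) if nasal == "low_x" else (x2, _EYE_CORNER_Y)
    temporal_pt = (x2, _EYE_CORNER_Y) if nasal == "low_x" else (x1, _EYE_CORNER_Y)
    return {
        "top_parabola": top,
        "bottom_parabola": bottom,
        "corners": (nasal_pt, temporal_pt),
        "nasal": nasal,
        "pupil_radius": _PUPIL_RADIUS,
    }


_WHISKER_CENTERS = {"left": (260.0, 300.0), "right": (60.0, 300.0)}
_WHISKER_RADIUS = 150.0


def whisker_pixel_model(side: str) -> dict:
    return {"center": _WHISKER_CENTERS[side], "radius": _WHISKER_RADIUS}


def _triplet_frame(bodyparts: list[str], xs, ys, scorer: str = "synthetic") -> pd.DataFrame:
    cols = pd.MultiIndex.from_product(
        [[scorer], bodyparts, ["x", "y", "likelihood"]],
        names=["scorer", "bodyparts", "coords"],
    )
    n = len(xs)
    data = np.empty((n, len(bodyparts) * 3))
    for j in range(len(bodyparts)):
        data[:, 3 * j] = xs[:, j]
        data[:, 3 * j + 1] = ys[:, j]
        data[:, 3 * j + 2] = 1.0
    out = pd.DataFrame(data, columns=cols)
    out.index.name = "frame"
    return out


def generate_keypoints(
    session: SessionRecord,
    truth: GroundTruth,
    config: GeneratorConfig,
    noise_px: float = 0.0,
) -> dict:
    """Emit raw keypoint tables consistent with the session's traces.

    Per eye and eye frame: 8 points on a circle of known radius centered at
    the true pupil pixel position (the normalized position mapped onto the
    analytic eye-width segment).  Per eye: eyelid point sets on the two
    known parabolas.  Per whisker side and behavior frame: one 2D point on
    a circular arc at the true whisker angle.  ``noise_px`` adds isotropic
    Gaussian pixel noise to every emitted point.
    """
    rng = np.random.default_rng(config.seed + 987654321)
    out: dict[str, pd.DataFrame] = {}
    phis = np.arange(8) * (2.0 * np.pi / 8.0)
    for side in ("left", "right"):
        model = eye_pixel_model(side)
        nasal = np.asarray(model["corners"][0])
        temporal = np.asarray(model["corners"][1])
        p = np.asarray(session.pupil_traces[side])
        centers = nasal[None, :] + p[:, None] * (temporal - nasal)[None, :]
        xs = centers[:, 0:1] + _PUPIL_RADIUS * np.cos(phis)[None, :]
        ys = centers[:, 1:2] + _PUPIL_RADIUS * np.sin(phis)[None, :]
        if noise_px > 0:
            xs = xs + rng.normal(0.0, noise_px, xs.shape)
            ys = ys + rng.normal(0.0, noise_px, ys.shape)
        out[f"pupil_{side}"] = _triplet_frame([f"pupil_{k + 1}" for k in range(8)], xs, ys)

        lid_x = np.linspace(_EYE_CORNERS_X[0] + 5, _EYE_CORNERS_X[1] - 5, 9)
        lids = {}
        for lid_name in ("top_parabola", "bottom_parabola"):
            a, b, c = model[lid_name]
            lid_y = a * lid_x**2 + b * lid_x + c
            px, py = lid_x.copy(), lid_y
            if noise_px > 0:
                px = px + rng.normal(0.0, noise_px, px.shape)
                py = py + rng.normal(0.0, noise_px, py.shape)
            lids[lid_name.split("_")[0]] = np.column_stack([px, py])
        out[f"eyelid_{side}"] = pd.DataFrame(
            {
                "lid": ["top"] * len(lid_x) + ["bottom"] * len(lid_x),
                "x": np.concatenate([lids["top"][:, 0], lids["bottom"][:, 0]]),
                "y": np.concatenate([lids["top"][:, 1], lids["bottom"][:, 1]]),
            }
        )

        wmodel = whisker_pixel_model(side)
        cx, cy = wmodel["center"]
        theta = np.radians(np.asarray(session.whisker_traces[side]))
        wx = cx + wmodel["radius"] * np.cos(theta)
        wy = cy + wmodel["radius"] * np.sin(theta)
        if noise_px > 0:
            wx = wx + rng.normal(0.0, noise_px, wx.shape)
            wy = wy + rng.normal(0.0, noise_px, wy.shape)
        out[f"whisker_{side}"] = _triplet_frame(
            ["whisker_c2"], wx[:, None], wy[:, None]
        )
    return out


# ---------------------------------------------------------------------------
# ground-truth sidecar


def write_ground_truth(truth: GroundTruth, path) -> None:
    payload = {
        "directions": truth.directions,
        "epochs": [[[s, int(a), int(b)] for s, a, b in tr] for tr in truth.epochs],
        "saccades": truth.saccades,
        "asymmetry_profiles": [p.tolist() for p in truth.asymmetry_profiles],
        "eye_deviation": truth.eye_deviation.tolist(),
        "config": asdict(truth.config),
    }
    Path(path).write_text(json.dumps(payload))


def read_ground_truth(path) -> GroundTruth:
    payload = json.loads(Path(path).read_text())
    cfg_raw = payload["config"]
    cfg_raw["saccade_amplitude"] = tuple(cfg_raw["saccade_amplitude"])
    cfg_raw["epoch_duration_ranges"] = {
        k: tuple(v) for k, v in cfg_raw["epoch_duration_ranges"].items()
    }
    return GroundTruth(
        directions=payload["directions"],
        epochs=[[(s, a, b) for s, a, b in tr] for tr in payload["epochs"]],
        saccades=payload["saccades"],
        asymmetry_profiles=[np.asarray(p) for p in payload["asymmetry_profiles"]],
        eye_deviation=np.asarray(payload["eye_deviation"]),
        config=GeneratorConfig(**cfg_raw),
    )
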