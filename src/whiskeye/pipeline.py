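"""End-to-end orchestration of the analysis stages on one or more sessions.

The run configuration is a plain mapping (usually loaded from YAML); every
tunable defaults to the published analysis constant: detection threshold
0.1 % of eye width per frame, 250 ms refractory interval, 5 prediction
bins, 10 histogram bins, 100 ms correlogram bins.
"""

from __future__ import annotations

import copy
import hashlib
import json
import time
from pathlib import Path

import numpy as np

from . import kinematics, saccade_detection, saccade_whisker_coupling, turn_prediction
from .errors import ConfigError
from .io_formats import SessionRecord, write_results, write_session
from .synthetic_data import GeneratorConfig, generate_session, write_ground_truth

__all__ = ["default_config", "run_pipeline", "session_saccades", "session_asymmetry_eye_clock"]


def default_config() -> dict:
    return {
        "seed": 0,
        "n_sessions": 1,
        "generator": {},  # overrides for GeneratorConfig fields
        "saccades": {
            "threshold": saccade_detection.SPEED_THRESHOLD,
            "refractory_s": saccade_detection.REFRACTORY_S,
            "histogram_bins": 10,
        },
        "prediction": {"n_bins": 5, "n_shuffles": 200},
        "coupling": {
            "window": list(saccade_whisker_coupling.DEFAULT_WINDOW),
            "n_shuffles": 20,
            "bin_s": saccade_whisker_coupling.CORRELOGRAM_BIN_S,
        },
        "stages": ["simulate", "saccades", "predict", "couple"],
    }


def _merge(base: dict, override: dict) -> dict:
    out = copy.deepcopy(base)
    for k, v in (override or {}).items():
        if k not in out:
            raise ConfigError(f"unknown run-config key: {k!r}")
        if isinstance(out[k], dict) and isinstance(v, dict):
            out[k] = {**out[k], **v}
        else:
            out[k] = v
    return out


def session_saccades(session: SessionRecord, threshold: float, refractory_s: float):
    """Head-centered eye speeds -> conjugate saccade events for one session."""
    hc_left = kinematics.to_head_centered(session.pupil_traces["left"], "left")
    hc_right = kinematics.to_head_centered(session.pupil_traces["right"], "right")
    ls = saccade_detection.eye_speed(hc_left)
    rs = saccade_detection.eye_speed(hc_right)
    return saccade_detection.detect_saccades(
        ls, rs, threshold=threshold, refractory_s=refractory_s, rate=session.eye_rate
    )


def session_asymmetry_eye_clock(session: SessionRecord) -> np.ndarray:
    """Raw right-minus-left normalized whisker asymmetry on the eye clock."""
    bounds = [(t.start_frame, t.end_frame) for t in session.trials]
    w_left = kinematics.normalize_whisker(session.whisker_traces["left"], bounds)
    w_right = kinematics.normalize_whisker(session.whisker_traces["right"], bounds)
    raw = w_right.values - w_left.values
    return kinematics.downsample_to_eye_clock(raw, session.clock_factor)


def run_pipeline(config: dict | None = None, outdir=None) -> dict:
    """Run the configured stages; returns the results bundle.

    With ``outdir`` set, writes session bundles, per-stage result JSON and
    a machine-readable provenance log.
    """
    cfg = _merge(default_config(), config or {})
    stages = list(cfg["stages"])
    seed = int(cfg["seed"])
    outdir = Path(outdir) if outdir is not None else None
    if outdir is not None:
        outdir.mkdir(parents=True, exist_ok=True)

    provenance = {
        "config": cfg,
        "config_hash": hashlib.sha256(json.dumps(cfg, sort_keys=True).encode()).hexdigest(),
        "seed": seed,
        "stages": {},
    }
    results: dict = {"config": cfg}

    if "simulate" not in stages:
        raise ConfigError("this pipeline runs on simulated sessions; enable the 'simulate' stage")

    t0 = time.perf_counter()
    sessions, truths = [], []
    for s in range(int(cfg["n_sessions"])):
        gen = GeneratorConfig(**{**cfg["generator"], "seed": seed + s})
        session, truth = generate_session(gen)
        session.session_id = f"synthetic-{seed + s}"
        sessions.append(session)
        truths.append(truth)
        if outdir is not None:
            d = write_session(session, outdir / f"session_{s:03d}")
            write_ground_truth(truth, d / "ground_truth.json")
    provenance["stages"]["simulate"] = {
        "duration_s": time.perf_counter() - t0,
        "n_sessions": len(sessions),
        "n_trials": sum(len(s.trials) for s in sessions),
    }

    events_per_session = None
    if "saccades" in stages:
        t0 = time.perf_counter()
        sc = cfg["saccades"]
        events_per_session = [
            session_saccades(s, sc["threshold"], sc["refractory_s"]) for s in sessions
        ]
        hists = [
            saccade_detection.saccade_histogram(
                ev, s.trials, s.eye_rate, s.behavior_rate, n_bins=sc["histogram_bins"]
            )
            for ev, s in zip(events_per_session, sessions)
        ]
        results["saccades"] = {
            "events": [
                [
                    {
                        "frame": e.frame,
                        "time": e.time,
                        "direction": e.direction,
                        "amplitude": e.amplitude,
                        "peak_speed": e.peak_speed,
                    }
                    for e in ev
                ]
                for ev in events_per_session
            ],
            "histograms": [
                {"counts": h.counts, "unassigned": h.unassigned, "n_bins": h.n_bins}
                for h in hists
            ],
        }
        provenance["stages"]["saccades"] = {
            "duration_s": time.perf_counter() - t0,
            "n_events": sum(len(e) for e in events_per_session),
        }
        if outdir is not None:
            write_results(results["saccades"], outdir / "saccades.json")

    if "predict" in stages:
        t0 = time.perf_counter()
        pc = cfg["prediction"]
        tables, all_epochs = [], []
        for s in sessions:
            epochs = turn_prediction.backward_epoch_predictors(s)
            all_epochs.extend(epochs)
            if len({e["label"] for e in epochs}) == 2:
                tables.append(turn_prediction.bin_predictors(epochs, n_bins=pc["n_bins"]))
        if not tables:
            raise ConfigError("no session had backward epochs of both turn directions")
        roc = turn_prediction.roc_analysis(tables, n_shuffles=pc["n_shuffles"], seed=seed)
        points = turn_prediction.bin_points(all_epochs, n_bins=pc["n_bins"])
        fid = turn_prediction.contribution_analysis(
            points, n_shuffles=max(20, pc["n_shuffles"] // 10), seed=seed
        )
        results["prediction"] = {
            "auc": {p: a.tolist() for p, a in roc.auc.items()},
            "null_auc": {p: a.tolist() for p, a in roc.null_auc.items()},
            "vs_null_p": {
                p: [None if r is None else r.p_value for r in roc.vs_null[p]] for p in roc.auc
            },
            "whisker_vs_eye_p": [None if r is None else r.p_value for r in roc.whisker_vs_eye],
            "fidelity": {
                "full_median": [float(np.median(f)) for f in fid.full],
                "null_median": [float(np.median(f)) for f in fid.null],
                "contribution": fid.contribution,
                "vs_null_p": [r.p_value for r in fid.vs_null],
            },
        }
        provenance["stages"]["predict"] = {
            "duration_s": time.perf_counter() - t0,
            "n_epochs": len(all_epochs),
            "n_sessions_used": len(tables),
        }
        if outdir is not None:
            write_results(results["prediction"], outdir / "prediction.json")

    if "couple" in stages:
        if events_per_session is None:
            raise ConfigError("the 'couple' stage requires the 'saccades' stage")
        t0 = time.perf_counter()
        cc = cfg["coupling"]
        all_traces, all_null = [], []
        lags = None
        n_backward_events = 0
        for s, ev in zip(sessions, events_per_session):
            pairs = saccade_whisker_coupling.events_in_backward(
                ev, s.trials, s.eye_rate, s.behavior_rate
            )
            if not pairs:
                continue
            n_backward_events += len(pairs)
            asym = session_asymmetry_eye_clock(s)
            tr, lags = saccade_whisker_coupling.triggered_traces(
                asym, pairs, window=tuple(cc["window"]), rate=s.eye_rate
            )
            all_traces.append(tr)
            for surrogate in saccade_whisker_coupling.shuffle_event_times(
                pairs, cc["n_shuffles"], seed=seed, rate=s.eye_rate
            ):
                ntr, _ = saccade_whisker_coupling.triggered_traces(
                    asym, surrogate, window=tuple(cc["window"]), rate=s.eye_rate
                )
                all_null.append(ntr)
        if not all_traces:
            results["coupling"] = {"n_events": 0}
        else:
            corr = saccade_whisker_coupling.correlogram(
                np.vstack(all_traces), lags, np.vstack(all_null), bin_s=cc["bin_s"]
            )
            results["coupling"] = {
                "n_events": corr.n_events,
                "lags": corr.lags.tolist(),
                "median": corr.median.tolist(),
                "null_median": corr.null_median.tolist(),
                "bin_edges": corr.bin_edges.tolist(),
                "bin_p_corrected": [None if t is None else t.p_value for t in corr.bin_tests],
                "bin_p_uncorrected": corr.bin_p_uncorrected.tolist(),
            }
        provenance["stages"]["couple"] = {
            "duration_s": time.perf_counter() - t0,
            "n_backward_events": n_backward_events,
        }
        if outdir is not None:
            write_results(results["coupling"], outdir / "coupling.json")

    if outdir is not None:
        write_results(provenance, outdir / "provenance.json")
    results["provenance"] = provenance
    return results
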