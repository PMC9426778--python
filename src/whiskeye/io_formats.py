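"""On-disk artifacts: keypoint tables, behavioral-state annotations,
session bundles, and results.

Formats:

* Keypoint tables are wide CSVs in the common pose-tracker dialect with a
  three-row header (scorer / bodyparts / coords) and an explicit frame
  index column.  Missing frames stay as NaN rows; they are never dropped.
* Annotations are JSON with 0-based, end-exclusive frame indices.
* Session bundles are a directory of small text files (meta YAML, trace
  CSVs, annotation JSON) so everything round-trips losslessly and diffs.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import FormatError

__all__ = [
    "VALID_STATES",
    "TrialRecord",
    "SessionRecord",
    "read_keypoints",
    "write_keypoints",
    "read_annotations",
    "write_annotations",
    "read_session",
    "write_session",
    "read_results",
    "write_results",
]

VALID_STATES = frozenset(
    {"end_of_lane", "backward", "turn_left", "turn_right", "forward", "expect_reward", "lick"}
)


@dataclass
class TrialRecord:
    trial_id: int
    cued_direction: str  # "left" | "right"
    epochs: list[tuple[str, int, int]]  # (state, start_frame, end_frame), end-exclusive

    def __post_init__(self) -> None:
        if self.cued_direction not in ("left", "right"):
            raise FormatError(f"trial {self.trial_id}: bad cued_direction {self.cued_direction!r}")
        prev_end = None
        for state, start, end in self.epochs:
            if state not in VALID_STATES:
                raise FormatError(f"trial {self.trial_id}: unknown state {state!r}")
            if not (0 <= start < end):
                raise FormatError(f"trial {self.trial_id}: non-monotone epoch frames ({start}, {end})")
            if prev_end is not None and start < prev_end:
                raise FormatError(
                    f"trial {self.trial_id}: epoch ({state}, {start}, {end}) overlaps previous epoch"
                )
            prev_end = end
        for state, _, _ in self.epochs:
            if state.startswith("turn_") and state != f"turn_{self.cued_direction}":
                raise FormatError(
                    f"trial {self.trial_id}: turn epoch {state!r} conflicts with cue "
                    f"{self.cued_direction!r}"
                )

    @property
    def start_frame(self) -> int:
        return self.epochs[0][1]

    @property
    def end_frame(self) -> int:
        return self.epochs[-1][2]

    def epoch(self, state_prefix: str) -> tuple[str, int, int] | None:
        for ep in self.epochs:
            if ep[0].startswith(state_prefix):
                return ep
        return None


@dataclass
class SessionRecord:
    animal_id: str
    session_id: str
    behavior_rate: float
    eye_rate: float
    trials: list[TrialRecord]
    whisker_traces: dict[str, np.ndarray]  # side -> angle trace, behavior clock
    pupil_traces: dict[str, np.ndarray]  # eye side -> normalized position, eye clock
    eye_geometry: dict = field(default_factory=dict)  # eye side -> EyeGeometry (optional)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for side in ("left", "right"):
            if side not in self.whisker_traces:
                raise FormatError(f"missing whisker trace for side {side!r}")
            if side not in self.pupil_traces:
                raise FormatError(f"missing pupil trace for eye {side!r}")
        nb = len(self.whisker_traces["left"])
        ne = len(self.pupil_traces["left"])
        if len(self.whisker_traces["right"]) != nb:
            raise FormatError("whisker traces have inconsistent lengths")
        if len(self.pupil_traces["right"]) != ne:
            raise FormatError("pupil traces have inconsistent lengths")
        factor = self.behavior_rate / self.eye_rate
        if abs(factor - round(factor)) > 1e-9:
            raise FormatError("behavior_rate must be an integer multiple of eye_rate")
        prev_end = None
        for t in self.trials:
            if t.end_frame > nb:
                raise FormatError(f"trial {t.trial_id} extends beyond whisker traces")
            if prev_end is not None and t.start_frame < prev_end:
                raise FormatError(f"trial {t.trial_id} overlaps the previous trial")
            prev_end = t.end_frame

    @property
    def clock_factor(self) -> int:
        return int(round(self.behavior_rate / self.eye_rate))


# ---------------------------------------------------------------------------
# keypoint tables (pose-tracker dialect)


def write_keypoints(table: pd.DataFrame, path) -> None:
    """Write a keypoint table with (scorer, bodypart, coord) column triplets."""
    if not isinstance(table.columns, pd.MultiIndex) or table.columns.nlevels != 3:
        raise FormatError("keypoint table must have (scorer, bodyparts, coords) columns")
    table.to_csv(path, index_label="frame")


def read_keypoints(path, layout: str = "triplet") -> pd.DataFrame:
    """Read a keypoint table; frame-indexed, missing frames preserved as NaN.

    ``layout='triplet'`` is the scorer/bodyparts/coords three-row header
    convention used by common pose trackers.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such keypoint file: {path}")
    if layout != "triplet":
        raise FormatError(f"unknown keypoint layout: {layout!r}")
    try:
        table = pd.read_csv(path, header=[0, 1, 2], index_col=0)
    except (ValueError, pd.errors.ParserError) as exc:
        raise FormatError(f"malformed keypoint table {path}: {exc}") from exc
    if table.columns.nlevels != 3:
        raise FormatError(f"{path}: expected a 3-row (scorer/bodyparts/coords) header")
    for col in table.columns:
        if col[2] not in ("x", "y", "likelihood"):
            raise FormatError(f"{path}: unexpected coordinate column {col!r}")
    idx = table.index
    if not np.issubdtype(idx.dtype, np.integer):
        raise FormatError(f"{path}: frame index must be integer")
    if idx.has_duplicates:
        dup = idx[idx.duplicated()][0]
        raise FormatError(f"{path}: duplicated frame index {dup}")
    # preserve gaps in the frame index as missing rows rather than dropping them
    full = pd.RangeIndex(int(idx.min()), int(idx.max()) + 1)
    table = table.reindex(full)
    table.index.name = "frame"
    return table


# ---------------------------------------------------------------------------
# behavioral-state annotations


def _trial_to_dict(trial: TrialRecord) -> dict:
    return {
        "trial_id": trial.trial_id,
        "cued_direction": trial.cued_direction,
        "epochs": [[s, int(a), int(b)] for s, a, b in trial.epochs],
    }


def write_annotations(trials: list[TrialRecord], path) -> None:
    payload = {"frame_convention": "0-based, end-exclusive", "trials": [_trial_to_dict(t) for t in trials]}
    Path(path).write_text(json.dumps(payload, indent=1))


def read_annotations(path) -> list[TrialRecord]:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such annotation file: {path}")
    try:
        payload = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise FormatError(f"malformed annotation JSON {path}: {exc}") from exc
    if "trials" not in payload:
        raise FormatError(f"{path}: missing 'trials' key")
    trials = []
    for t in payload["trials"]:
        try:
            trials.append(
                TrialRecord(
                    trial_id=int(t["trial_id"]),
                    cued_direction=t["cued_direction"],
                    epochs=[(s, int(a), int(b)) for s, a, b in t["epochs"]],
                )
            )
        except (KeyError, TypeError, ValueError) as exc:
            raise FormatError(f"{path}: bad trial record {t!r}: {exc}") from exc
    return trials


# ---------------------------------------------------------------------------
# session bundles


def write_session(session: SessionRecord, directory) -> Path:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    meta = {
        "animal_id": session.animal_id,
        "session_id": session.session_id,
        "behavior_rate": float(session.behavior_rate),
        "eye_rate": float(session.eye_rate),
        "meta": session.meta,
    }
    (d / "meta.yaml").write_text(yaml.safe_dump(meta, sort_keys=True))
    write_annotations(session.trials, d / "annotations.json")
    pd.DataFrame(
        {"left": session.whisker_traces["left"], "right": session.whisker_traces["right"]}
    ).to_csv(d / "whisker_angles.csv", index_label="frame", float_format="%.10g")
    pd.DataFrame(
        {"left": session.pupil_traces["left"], "right": session.pupil_traces["right"]}
    ).to_csv(d / "pupil_positions.csv", index_label="frame", float_format="%.10g")
    return d


def read_session(directory) -> SessionRecord:
    d = Path(directory)
    meta_path = d / "meta.yaml"
    if not meta_path.exists():
        raise FormatError(f"no session bundle at {d} (missing meta.yaml)")
    meta = yaml.safe_load(meta_path.read_text())
    trials = read_annotations(d / "annotations.json")
    wh = pd.read_csv(d / "whisker_angles.csv", index_col="frame")
    pu = pd.read_csv(d / "pupil_positions.csv", index_col="frame")
    return SessionRecord(
        animal_id=str(meta["animal_id"]),
        session_id=str(meta["session_id"]),
        behavior_rate=float(meta["behavior_rate"]),
        eye_rate=float(meta["eye_rate"]),
        trials=trials,
        whisker_traces={"left": wh["left"].to_numpy(), "right": wh["right"].to_numpy()},
        pupil_traces={"left": pu["left"].to_numpy(), "right": pu["right"].to_numpy()},
        meta=meta.get("meta", {}),
    )


# ---------------------------------------------------------------------------
# results


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj.tolist()]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        v = float(obj)
        return None if np.isnan(v) else v
    if isinstance(obj, float) and np.isnan(obj):
        return None
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    return obj


def write_results(results: dict, path) -> None:
    """Serialize an analysis results mapping to JSON (NaN -> null)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    try:
        path.write_text(json.dumps(_jsonable(results), indent=1))
    except OSError as exc:
        raise FormatError(f"cannot write results to {path}: {exc}") from exc


def read_results(path) -> dict:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such results file: {path}")
    return json.loads(path.read_text())
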