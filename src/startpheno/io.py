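"""Readers and writers for cohort sessions, feature tables and summary tables.

Cohort files are line-delimited JSON (UTF-8): the first line is a header
object carrying ``format_version``; each further line is one child record
with deterministically ordered keys, so rewriting the same cohort is
byte-identical.  The raw storage schema is this package's own invention
(the source platform's storage format is not public).

Feature tables are CSV with header ``child_id,group,<16 slots>``; an empty
field is the missing marker.  Summary tables are CSV with columns
``measure,group,n,mean,sd``.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Sequence, Union

import numpy as np
import pandas as pd

from .types import (
    FEATURE_SLOTS,
    TASK_NAMES,
    BubbleTouch,
    ButtonTrial,
    ChildRecord,
    ColouringSession,
    FaceFrame,
    FeatureVector,
    Gaze,
    GazeFrame,
    Group,
    GroupSummary,
    MotorTrial,
    PCICoding,
    PreferentialTrial,
    QuestionnaireResponse,
    ValidationError,
    WheelTrial,
    validate_cohort,
)

FORMAT_VERSION = 1

PathLike = Union[str, Path]


def packaged_data(name: str) -> Path:
    """Path to a CSV shipped with the package (printed-table fixtures)."""
    from importlib import resources

    return Path(str(resources.files("startpheno").joinpath("data", name)))


class CohortParseError(ValueError):
    """A cohort file line failed to parse; the message names the line."""


# ---------------------------------------------------------------------------
# child record <-> plain JSON-able dicts


def _arr(a: np.ndarray) -> list:
    return np.asarray(a, dtype=float).tolist()


def _task_to_json(name: str, value) -> object:
    if name == "preferential":
        return [
            {
                "social_on_left": tr.social_on_left,
                "frames": [[f.t_ms, int(f.eye_detected), f.gaze.value] for f in tr.frames],
            }
            for tr in value
        ]
    if name == "button":
        return [{"completed": tr.completed, "choice": tr.choice} for tr in value]
    if name == "wheel":
        return [
            {
                "completed": tr.completed,
                "play_duration_s": tr.play_duration_s,
                "max_duration_s": tr.max_duration_s,
                "face_frames": [
                    [f.t_ms, int(f.face_detected), f.distance_mm, int(f.gaze_on_wheel)]
                    for f in tr.face_frames
                ],
            }
            for tr in value
        ]
    if name == "motor":
        return [{"target": _arr(tr.target), "touch": _arr(tr.touch)} for tr in value]
    if name == "bubble":
        return [
            {
                "bubble_center": list(b.bubble_center),
                "touch_point": list(b.touch_point),
                "pressure": b.pressure,
                "popped": b.popped,
            }
            for b in value
        ]
    if name == "colouring":
        return [
            {
                "figure_outline": _arr(s.figure_outline),
                "screen_px": list(s.screen_px),
                "strokes": [_arr(st) for st in s.strokes],
                "brush_radius_px": s.brush_radius_px,
            }
            for s in value
        ]
    if name == "pci":
        return [
            {
                "coder_id": c.coder_id,
                "child_initiation_prop": c.child_initiation_prop,
                "caregiver_sync_prop": c.caregiver_sync_prop,
                "child_opportunities": c.child_opportunities,
                "caregiver_opportunities": c.caregiver_opportunities,
            }
            for c in value
        ]
    if name == "questionnaire":
        return {
            "items": [int(x) for x in value.items],
            "reverse_coded": list(value.reverse_coded),
        }
    raise ValidationError(f"unknown task name {name!r}")


def _task_from_json(name: str, value):
    if name == "preferential":
        return [
            PreferentialTrial(
                social_on_left=tr["social_on_left"],
                frames=[GazeFrame(int(t), bool(d), Gaze(g)) for t, d, g in tr["frames"]],
            )
            for tr in value
        ]
    if name == "button":
        return [ButtonTrial(completed=tr["completed"], choice=tr["choice"]) for tr in value]
    if name == "wheel":
        return [
            WheelTrial(
                completed=tr["completed"],
                play_duration_s=tr["play_duration_s"],
                max_duration_s=tr["max_duration_s"],
                face_frames=[
                    FaceFrame(int(t), bool(d), dist, bool(g))
                    for t, d, dist, g in tr["face_frames"]
                ],
            )
            for tr in value
        ]
    if name == "motor":
        return [
            MotorTrial(
                target=np.asarray(tr["target"], dtype=float).reshape(-1, 3),
                touch=np.asarray(tr["touch"], dtype=float).reshape(-1, 4),
            )
            for tr in value
        ]
    if name == "bubble":
        return [
            BubbleTouch(
                bubble_center=tuple(b["bubble_center"]),
                touch_point=tuple(b["touch_point"]),
                pressure=b["pressure"],
                popped=b["popped"],
            )
            for b in value
        ]
    if name == "colouring":
        return [
            ColouringSession(
                figure_outline=np.asarray(s["figure_outline"], dtype=float).reshape(-1, 2),
                screen_px=tuple(s["screen_px"]),
                strokes=[np.asarray(st, dtype=float).reshape(-1, 4) for st in s["strokes"]],
                brush_radius_px=s["brush_radius_px"],
            )
            for s in value
        ]
    if name == "pci":
        return [
            PCICoding(
                coder_id=c["coder_id"],
                child_initiation_prop=c["child_initiation_prop"],
                caregiver_sync_prop=c["caregiver_sync_prop"],
                child_opportunities=int(c["child_opportunities"]),
                caregiver_opportunities=int(c["caregiver_opportunities"]),
            )
            for c in value
        ]
    if name == "questionnaire":
        return QuestionnaireResponse(
            items=[bool(x) for x in value["items"]],
            reverse_coded=tuple(int(i) for i in value["reverse_coded"]),
        )
    raise CohortParseError(f"unknown task name {name!r}")


def record_to_json(rec: ChildRecord) -> dict:
    return {
        "child_id": rec.child_id,
        "group": rec.group.value,
        "age_years": rec.age_years,
        "sex": rec.sex,
        "tasks": {
            name: _task_to_json(name, rec.tasks[name])
            for name in TASK_NAMES
            if name in rec.tasks
        },
    }


def record_from_json(obj: dict) -> ChildRecord:
    tasks = {}
    for name, value in obj.get("tasks", {}).items():
        if name not in TASK_NAMES:
            raise CohortParseError(f"unknown task name {name!r}")
        tasks[name] = _task_from_json(name, value)
    return ChildRecord(
        child_id=obj["child_id"],
        group=Group(obj["group"]),
        age_years=obj["age_years"],
        sex=obj["sex"],
        tasks=tasks,
    )


# ---------------------------------------------------------------------------
# cohort files


def write_cohort(cohort: Sequence[ChildRecord], path: PathLike) -> None:
    """Serialise a validated cohort to line-delimited JSON (deterministic)."""
    validate_cohort(cohort)
    lines = [json.dumps({"format_version": FORMAT_VERSION, "n_children": len(cohort)})]
    for rec in cohort:
        lines.append(json.dumps(record_to_json(rec), sort_keys=True, allow_nan=False))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_cohort(path: PathLike, validate: bool = True) -> list[ChildRecord]:
    """Read and validate a cohort file; parse errors name the offending line."""
    text = Path(path).read_text(encoding="utf-8")
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        return []
    try:
        header = json.loads(lines[0])
    except json.JSONDecodeError as exc:
        raise CohortParseError(f"line 1: malformed header ({exc})") from exc
    if not isinstance(header, dict) or "format_version" not in header:
        raise CohortParseError("line 1: missing format_version header")
    if header["format_version"] != FORMAT_VERSION:
        raise CohortParseError(
            f"line 1: unsupported format_version {header['format_version']!r}"
        )
    cohort = []
    for i, ln in enumerate(lines[1:], start=2):
        try:
            cohort.append(record_from_json(json.loads(ln)))
        except json.JSONDecodeError as exc:
            raise CohortParseError(f"line {i}: malformed record ({exc})") from exc
        except (KeyError, TypeError) as exc:
            raise CohortParseError(f"line {i}: bad record schema ({exc})") from exc
    if validate:
        validate_cohort(cohort)
    return cohort


# ---------------------------------------------------------------------------
# feature tables


def feature_frame(vectors: Iterable[FeatureVector]) -> pd.DataFrame:
    """Feature vectors as a DataFrame (missing -> NaN), fixed column order."""
    rows = []
    for v in vectors:
        row: dict = {"child_id": v.child_id, "group": v.group.value}
        for slot in FEATURE_SLOTS:
            x = v.values[slot]
            row[slot] = np.nan if x is None else x
        rows.append(row)
    return pd.DataFrame(rows, columns=["child_id", "group", *FEATURE_SLOTS])


def write_feature_table(vectors: Sequence[FeatureVector], path: PathLike) -> None:
    """One row per child, one column per slot; missing rendered as empty field."""
    df = feature_frame(vectors)
    # shortest round-trip float rendering so read_feature_table is lossless
    df.to_csv(path, index=False, na_rep="", float_format=lambda x: repr(float(x)))


def read_feature_table(path: PathLike) -> list[FeatureVector]:
    df = pd.read_csv(path, dtype={"child_id": str}, float_precision="round_trip")
    expected = ["child_id", "group", *FEATURE_SLOTS]
    if list(df.columns) != expected:
        raise ValidationError(f"feature table columns {list(df.columns)} != {expected}")
    out = []
    for _, row in df.iterrows():
        values = {
            slot: (None if pd.isna(row[slot]) else float(row[slot]))
            for slot in FEATURE_SLOTS
        }
        out.append(FeatureVector(row["child_id"], Group(row["group"]), values))
    return out


# ---------------------------------------------------------------------------
# printed summary tables


def read_summary_table(path: PathLike) -> list[GroupSummary]:
    """Read ``measure,group,n,mean,sd`` rows into one summary per measure.

    Every measure must carry exactly the three groups.
    """
    df = pd.read_csv(path)
    required = {"measure", "group", "n", "mean", "sd"}
    if not required.issubset(df.columns):
        raise ValidationError(f"summary table needs columns {sorted(required)}")
    out = []
    for measure, sub in df.groupby("measure", sort=False):
        groups = [Group(g) for g in sub["group"]]
        if sorted(g.value for g in groups) != sorted(g.value for g in Group):
            raise ValidationError(
                f"measure {measure!r}: needs exactly the three groups, got "
                f"{[g.value for g in groups]}"
            )
        stats = {
            Group(row.group): (int(row.n), float(row.mean), float(row.sd))
            for row in sub.itertuples()
        }
        out.append(GroupSummary(measure=str(measure), stats=stats))
    return out
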