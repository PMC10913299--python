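"""Domain types for raw assessment sessions and derived feature tables.

A session battery comprises eight tasks administered on a tablet to
2-to-7-year-old children from three groups: autism spectrum (AS),
intellectual disability (ID) and typically developing (TD).  Raw task
streams (gaze frames, touch samples, trial outcomes, questionnaire
responses, dyadic-interaction codes) are held per child in a
:class:`ChildRecord`; the feature layer reduces them to a
:class:`FeatureVector` of per-task metrics.

Coordinate convention: screen pixels, origin top-left, x rightward,
y downward; timestamps in integer milliseconds.  Missing values are the
explicit marker ``None``, never a sentinel number.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Any, Optional, Sequence, Union

import numpy as np

__all__ = [
    "Group",
    "Gaze",
    "GazeFrame",
    "PreferentialTrial",
    "ButtonTrial",
    "FaceFrame",
    "WheelTrial",
    "TouchSample",
    "MotorTrial",
    "BubbleTouch",
    "ColouringSession",
    "QuestionnaireResponse",
    "PCICoding",
    "ChildRecord",
    "FeatureVector",
    "GroupSummary",
    "FEATURE_SLOTS",
    "TASK_NAMES",
    "ValidationError",
    "validate_record",
    "validate_cohort",
]


class ValidationError(ValueError):
    """A record or cohort violates a documented invariant."""


class Group(str, Enum):
    """Participant group label."""

    TD = "TD"
    AS = "AS"
    ID = "ID"


class Gaze(str, Enum):
    """Frame-level gaze classification for the preferential-looking task."""

    SOCIAL = "social_side"
    NONSOCIAL = "nonsocial_side"
    ELSEWHERE = "elsewhere_on_tablet"
    OFF = "off_tablet"
    UNDETECTED = "undetected"


#: Gaze labels that count as "on the tablet" for the 50% inclusion filter.
ON_TABLET = frozenset({Gaze.SOCIAL, Gaze.NONSOCIAL, Gaze.ELSEWHERE})

#: The eight task sub-record names, in battery order.
TASK_NAMES = (
    "preferential",
    "button",
    "wheel",
    "motor",
    "bubble",
    "colouring",
    "pci",
    "questionnaire",
)

#: Named slots of the derived feature vector, in serialisation order.
FEATURE_SLOTS = (
    "social_preference",
    "social_choice",
    "wheel_looking",
    "wheel_dist_min",
    "wheel_dist_max",
    "motor_rmse",
    "fft_gain_x",
    "fft_gain_y",
    "jerk",
    "pop_force",
    "pop_dist_x",
    "pop_dist_y",
    "colour_crossings",
    "pci_child_init",
    "pci_caregiver_sync",
    "questionnaire_score",
)


@dataclass(slots=True)
class GazeFrame:
    """One camera frame of the preferential-looking task.

    ``gaze`` is :attr:`Gaze.UNDETECTED` iff ``eye_detected`` is False.
    """

    t_ms: int
    eye_detected: bool
    gaze: Gaze


@dataclass(slots=True)
class PreferentialTrial:
    """One paired social/nonsocial video presentation."""

    social_on_left: bool
    frames: list[GazeFrame]


@dataclass(slots=True)
class ButtonTrial:
    """One two-button choice trial; ``choice`` is 'none' iff not completed."""

    completed: bool
    choice: str  # "social" | "nonsocial" | "none"


@dataclass(slots=True)
class FaceFrame:
    """One camera frame of the spinning-wheel task.

    ``distance_mm`` is present iff the face was detected.
    """

    t_ms: int
    face_detected: bool
    distance_mm: Optional[float]
    gaze_on_wheel: bool


@dataclass(slots=True)
class WheelTrial:
    completed: bool
    play_duration_s: float
    face_frames: list[FaceFrame] = field(default_factory=list)
    max_duration_s: float = 15.0


@dataclass(slots=True)
class TouchSample:
    t_ms: int
    x_px: float
    y_px: float
    pressure: float


@dataclass(slots=True)
class MotorTrial:
    """Target trajectory and finger trace of one butterfly-following trial.

    ``target``: float array of shape (n, 3) with columns (t_ms, x_px, y_px).
    ``touch``: float array of shape (m, 4) with columns
    (t_ms, x_px, y_px, pressure); may be empty when the child never touched.
    """

    target: np.ndarray
    touch: np.ndarray


@dataclass(slots=True)
class BubbleTouch:
    """One touch aimed at a floating bubble."""

    bubble_center: tuple[float, float]
    touch_point: tuple[float, float]
    pressure: float
    popped: bool


@dataclass
class ColouringSession:
    """Strokes of one figure-colouring trial.

    ``figure_outline``: closed simple polygon, float array (k, 2) of vertices
    (the closing edge last-vertex-to-first is implicit).
    ``strokes``: list of float arrays (n, 4) with columns
    (t_ms, x_px, y_px, pressure), each time-ordered.
    """

    figure_outline: np.ndarray
    screen_px: tuple[int, int]
    strokes: list[np.ndarray]
    brush_radius_px: float


@dataclass
class QuestionnaireResponse:
    """14 binary parent-report items; 8 are reverse-coded (scored 1 for 'no')."""

    items: list[bool]  # True = "yes"
    reverse_coded: tuple[int, ...]


@dataclass(slots=True)
class PCICoding:
    """One coder's summary of the videotaped caregiver-child play session."""

    coder_id: str
    child_initiation_prop: float
    caregiver_sync_prop: float
    child_opportunities: int
    caregiver_opportunities: int


TaskRecord = Union[
    "list[PreferentialTrial]",
    "list[ButtonTrial]",
    "list[WheelTrial]",
    "list[MotorTrial]",
    "list[BubbleTouch]",
    "list[ColouringSession]",
    "list[PCICoding]",
    QuestionnaireResponse,
]


@dataclass
class ChildRecord:
    """One child's group label, demographics and raw task sub-records.

    ``tasks`` maps a name from :data:`TASK_NAMES` to its raw sub-record; any
    subset of the eight tasks may be absent (attrition).
    """

    child_id: str
    group: Group
    age_years: float
    sex: str  # "F" | "M"
    tasks: dict[str, Any] = field(default_factory=dict)


@dataclass
class FeatureVector:
    """Per-child derived metrics; ``None`` marks a slot missing."""

    child_id: str
    group: Group
    values: dict[str, Optional[float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for slot in FEATURE_SLOTS:
            self.values.setdefault(slot, None)
        extra = set(self.values) - set(FEATURE_SLOTS)
        if extra:
            raise ValidationError(f"unknown feature slots: {sorted(extra)}")

    def __getitem__(self, slot: str) -> Optional[float]:
        return self.values[slot]

    def __setitem__(self, slot: str, value: Optional[float]) -> None:
        if slot not in FEATURE_SLOTS:
            raise ValidationError(f"unknown feature slot: {slot}")
        self.values[slot] = value


@dataclass
class GroupSummary:
    """(n, mean, SD) per group for one measure; bridges printed tables to stats."""

    measure: str
    stats: dict[Group, tuple[int, float, float]]

    def __post_init__(self) -> None:
        for g, (n, _m, sd) in self.stats.items():
            if n <= 1:
                raise ValidationError(
                    f"measure {self.measure!r}, group {g.value}: n must be > 1"
                )
            if sd < 0:
                raise ValidationError(
                    f"measure {self.measure!r}, group {g.value}: sd must be >= 0"
                )

    @property
    def groups(self) -> list[Group]:
        return list(self.stats)


# ---------------------------------------------------------------------------
# validation


def _check(cond: bool, where: str, msg: str) -> None:
    if not cond:
        raise ValidationError(f"{where}: {msg}")


def _validate_time_ordered(t: Sequence[float], where: str) -> None:
    arr = np.asarray(t, dtype=float)
    if arr.size > 1:
        _check(bool(np.all(np.diff(arr) > 0)), where, "timestamps not strictly increasing")


def validate_record(
    rec: ChildRecord,
    age_range: tuple[float, float] = (2.0, 7.99),
    screen_px: Optional[tuple[int, int]] = None,
) -> None:
    """Check the documented invariants of one record; raise :class:`ValidationError`.

    ``screen_px`` enables the coordinate-bounds check for touch streams when given.
    """
    cid = rec.child_id
    _check(isinstance(rec.group, Group), cid, f"bad group {rec.group!r}")
    _check(rec.sex in ("F", "M"), cid, f"bad sex {rec.sex!r}")
    _check(
        age_range[0] <= rec.age_years <= age_range[1],
        cid,
        f"age {rec.age_years} outside [{age_range[0]}, {age_range[1]}]",
    )
    unknown = set(rec.tasks) - set(TASK_NAMES)
    _check(not unknown, cid, f"unknown task names {sorted(unknown)}")

    for trial in rec.tasks.get("preferential", []):
        _validate_time_ordered([f.t_ms for f in trial.frames], f"{cid}/preferential")
        for f in trial.frames:
            _check(f.t_ms >= 0, f"{cid}/preferential", "negative frame time")
            _check(
                (f.gaze is Gaze.UNDETECTED) == (not f.eye_detected),
                f"{cid}/preferential",
                "gaze=undetected must coincide with eye_detected=False",
            )
    for trial in rec.tasks.get("button", []):
        _check(
            (trial.choice == "none") == (not trial.completed),
            f"{cid}/button",
            "choice='none' must coincide with completed=False",
        )
        _check(trial.choice in ("social", "nonsocial", "none"), f"{cid}/button", "bad choice")
    for trial in rec.tasks.get("wheel", []):
        _check(
            0.0 <= trial.play_duration_s <= trial.max_duration_s,
            f"{cid}/wheel",
            "play duration outside [0, max]",
        )
        _validate_time_ordered([f.t_ms for f in trial.face_frames], f"{cid}/wheel")
        for f in trial.face_frames:
            _check(
                (f.distance_mm is not None) == f.face_detected,
                f"{cid}/wheel",
                "distance_mm present iff face_detected",
            )
            if f.distance_mm is not None:
                _check(f.distance_mm > 0, f"{cid}/wheel", "non-positive face distance")
    for trial in rec.tasks.get("motor", []):
        _check(trial.target.ndim == 2 and trial.target.shape[1] == 3, f"{cid}/motor", "bad target shape")
        _check(trial.touch.ndim == 2 and trial.touch.shape[1] == 4, f"{cid}/motor", "bad touch shape")
        _validate_time_ordered(trial.target[:, 0], f"{cid}/motor")
        _validate_time_ordered(trial.touch[:, 0], f"{cid}/motor")
    for touch in rec.tasks.get("bubble", []):
        _check(0.0 <= touch.pressure <= 1.0, f"{cid}/bubble", "pressure outside [0, 1]")
    for sess in rec.tasks.get("colouring", []):
        _check(sess.figure_outline.shape[0] >= 3, f"{cid}/colouring", "outline needs >=3 vertices")
        _check(sess.brush_radius_px > 0, f"{cid}/colouring", "non-positive brush radius")
        for stroke in sess.strokes:
            _validate_time_ordered(stroke[:, 0], f"{cid}/colouring")
            if screen_px is not None:
                w, h = screen_px
                _check(
                    bool(
                        np.all(stroke[:, 1] >= 0)
                        and np.all(stroke[:, 1] <= w)
                        and np.all(stroke[:, 2] >= 0)
                        and np.all(stroke[:, 2] <= h)
                    ),
                    f"{cid}/colouring",
                    "stroke coordinates outside screen bounds",
                )
    for coding in rec.tasks.get("pci", []):
        _check(
            0.0 <= coding.child_initiation_prop <= 1.0
            and 0.0 <= coding.caregiver_sync_prop <= 1.0,
            f"{cid}/pci",
            "proportions outside [0, 1]",
        )
        _check(
            coding.child_opportunities > 0 and coding.caregiver_opportunities > 0,
            f"{cid}/pci",
            "opportunity counts must be > 0",
        )
    q = rec.tasks.get("questionnaire")
    if q is not None:
        _check(len(q.items) == 14, f"{cid}/questionnaire", f"{len(q.items)} items, expected 14")
        _check(
            len(set(q.reverse_coded)) == 8,
            f"{cid}/questionnaire",
            "exactly 8 distinct reverse-coded indices required",
        )
        _check(
            all(0 <= i < 14 for i in q.reverse_coded),
            f"{cid}/questionnaire",
            "reverse-coded index out of range",
        )


def validate_cohort(
    cohort: Sequence[ChildRecord],
    age_range: tuple[float, float] = (2.0, 7.99),
) -> None:
    """Validate every record and the cohort-level unique-id invariant."""
    seen: set[str] = set()
    for rec in cohort:
        if rec.child_id in seen:
            raise ValidationError(f"duplicate child_id {rec.child_id!r}")
        seen.add(rec.child_id)
        validate_record(rec, age_range=age_range)
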