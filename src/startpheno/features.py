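"""Per-task inclusion filters and dependent-variable computations.

Each operation turns one task's raw sub-record into its derived metric(s)
together with a :class:`FilterOutcome` describing whether the child's data
pass the pre-set quality filters:

* preferential looking — eyes detected on >=50% of frames and gaze on the
  tablet on >=50% of frames; social preference = social frames /
  (social + nonsocial frames);
* button — >=50% of scheduled trials completed; social choice proportion;
* wheel — >=2 completed trials and face detected on more than 25% of
  frames; looking time summed over completed trials divided by the maximum
  possible duration; min/max face-screen distance;
* motor following — a trial is valid when the finger trace covers >=50% of
  the target's time support; children need >=2 valid trials; metrics are
  trajectory RMSE, band-limited spectral frequency gain per axis, and a
  normalised jerk (movement-smoothness) index;
* bubble popping — >=1 popped bubble; mean pressure and mean |x|/|y| offset
  from bubble centres;
* colouring — >=25% of screen pixels painted; outline crossings counted as
  consecutive-sample inside/outside flips;
* caregiver-child interaction — one coder chosen at random when several
  coded the video;
* questionnaire — sum of 14 binary items, 8 reverse-coded.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass
from enum import Enum
from typing import Optional, Sequence

import numpy as np
import shapely
from shapely.geometry import Polygon

from .types import (
    ON_TABLET,
    BubbleTouch,
    ButtonTrial,
    ChildRecord,
    ColouringSession,
    FeatureVector,
    Gaze,
    MotorTrial,
    PCICoding,
    PreferentialTrial,
    QuestionnaireResponse,
    ValidationError,
    WheelTrial,
)

__all__ = [
    "ExtractionConfig",
    "FilterOutcome",
    "FilterReason",
    "social_preference",
    "button_social_choice",
    "wheel_looking",
    "wheel_face_distance",
    "motor_rmse",
    "motor_frequency_gain",
    "motor_jerk",
    "bubble_features",
    "colouring_crossings",
    "colouring_coverage",
    "questionnaire_score",
    "pci_features",
    "extract_features",
    "extract_cohort",
]


class FilterReason(str, Enum):
    OK = "ok"
    MISSING_TASK = "missing_task"
    EYE_DETECTION_BELOW_HALF = "eye_detection_below_half"
    GAZE_ON_TABLET_BELOW_HALF = "gaze_on_tablet_below_half"
    FEWER_THAN_HALF_TRIALS = "fewer_than_half_trials"
    FEWER_THAN_TWO_TRIALS = "fewer_than_two_trials"
    FACE_DETECTION_AT_OR_BELOW_QUARTER = "face_detection_at_or_below_quarter"
    NO_BUBBLES_POPPED = "no_bubbles_popped"
    COVERAGE_BELOW_THRESHOLD = "coverage_below_threshold"


@dataclass
class FilterOutcome:
    """Whether a task's data passed its inclusion filter, and why not."""

    task_name: str
    included: bool
    reason: FilterReason

    def __post_init__(self) -> None:
        if (self.reason is FilterReason.OK) != self.included:
            raise ValidationError("reason must be 'ok' iff included")


def _ok(task: str) -> FilterOutcome:
    return FilterOutcome(task, True, FilterReason.OK)


def _excluded(task: str, reason: FilterReason) -> FilterOutcome:
    return FilterOutcome(task, False, reason)


@dataclass(frozen=True)
class ExtractionConfig:
    """Thresholds and numerical conventions of the feature layer.

    The inclusion thresholds follow the battery's pre-set criteria: the
    "at least 50%" filters are inclusive (>=) while the wheel face filter
    excludes at exactly 25% ("25% or fewer").  ``fft_band_hz`` and the
    frequency weighting define the spectral gain; ``jerk_scale_s3`` is the
    dimensionless-jerk scale constant (see docs/methods.md).
    ``coverage_denominator`` selects whether colouring coverage is counted
    against the whole screen (the battery's stated rule) or only the
    figure interior.
    """

    eye_detection_min: float = 0.5
    gaze_on_tablet_min: float = 0.5
    button_scheduled_trials: int = 8
    button_completed_min_frac: float = 0.5
    wheel_min_completed_trials: int = 2
    wheel_face_detection_excl: float = 0.25  # exclude when fraction <= this
    motor_min_valid_trials: int = 2
    motor_overlap_min_frac: float = 0.5
    resample_ms: float = 50.0
    fft_band_hz: tuple[float, float] = (0.2, 5.0)
    jerk_scale_s3: float = 2.0e3
    screen_px: tuple[int, int] = (2560, 1600)
    coverage_min: float = 0.25
    coverage_denominator: str = "screen"  # "screen" | "figure"
    coverage_grid_step: int = 1
    pci_seed: int = 0


# ---------------------------------------------------------------------------
# social domain


def social_preference(
    trials: Sequence[PreferentialTrial], config: ExtractionConfig = ExtractionConfig()
) -> tuple[Optional[float], FilterOutcome]:
    """Fraction of on-stimulus gaze frames directed at the social video."""
    task = "preferential"
    frames = [f for tr in trials for f in tr.frames]
    if not frames:
        return None, _excluded(task, FilterReason.MISSING_TASK)
    n = len(frames)
    detected = sum(f.eye_detected for f in frames)
    if detected / n < config.eye_detection_min:
        return None, _excluded(task, FilterReason.EYE_DETECTION_BELOW_HALF)
    on_tablet = sum(f.gaze in ON_TABLET for f in frames)
    if on_tablet / n < config.gaze_on_tablet_min:
        return None, _excluded(task, FilterReason.GAZE_ON_TABLET_BELOW_HALF)
    social = sum(f.gaze is Gaze.SOCIAL for f in frames)
    nonsocial = sum(f.gaze is Gaze.NONSOCIAL for f in frames)
    if social + nonsocial == 0:
        # filters passed but no on-stimulus frames: degenerate, value missing
        return None, _ok(task)
    return social / (social + nonsocial), _ok(task)


def button_social_choice(
    trials: Sequence[ButtonTrial], config: ExtractionConfig = ExtractionConfig()
) -> tuple[Optional[float], FilterOutcome]:
    """Social choices as a fraction of completed trials."""
    task = "button"
    if not trials:
        return None, _excluded(task, FilterReason.MISSING_TASK)
    completed = [tr for tr in trials if tr.completed]
    scheduled = config.button_scheduled_trials
    if len(completed) < config.button_completed_min_frac * scheduled:
        return None, _excluded(task, FilterReason.FEWER_THAN_HALF_TRIALS)
    social = sum(tr.choice == "social" for tr in completed)
    return social / len(completed), _ok(task)


# ---------------------------------------------------------------------------
# sensory domain


def _wheel_filter(
    trials: Sequence[WheelTrial], config: ExtractionConfig
) -> Optional[FilterOutcome]:
    task = "wheel"
    if not trials:
        return _excluded(task, FilterReason.MISSING_TASK)
    completed = [tr for tr in trials if tr.completed]
    if len(completed) < config.wheel_min_completed_trials:
        return _excluded(task, FilterReason.FEWER_THAN_TWO_TRIALS)
    frames = [f for tr in trials for f in tr.face_frames]
    if frames:
        det = sum(f.face_detected for f in frames) / len(frames)
        if det <= config.wheel_face_detection_excl:
            return _excluded(task, FilterReason.FACE_DETECTION_AT_OR_BELOW_QUARTER)
    return None


def _frame_durations_s(t_ms: np.ndarray) -> np.ndarray:
    """Per-frame dwell times; the last frame gets the median inter-frame gap."""
    if t_ms.size == 1:
        return np.array([0.0])
    d = np.diff(t_ms) / 1000.0
    return np.append(d, np.median(d))


def wheel_looking(
    trials: Sequence[WheelTrial], config: ExtractionConfig = ExtractionConfig()
) -> tuple[Optional[float], FilterOutcome]:
    """Looking time summed over completed trials / max possible duration."""
    task = "wheel"
    bad = _wheel_filter(trials, config)
    if bad is not None:
        return None, bad
    completed = [tr for tr in trials if tr.completed]
    looking = 0.0
    max_total = 0.0
    for tr in completed:
        max_total += tr.max_duration_s
        if not tr.face_frames:
            continue
        t = np.array([f.t_ms for f in tr.face_frames], dtype=float)
        dur = _frame_durations_s(t)
        on = np.array([f.gaze_on_wheel for f in tr.face_frames], dtype=bool)
        looking += float(dur[on].sum())
    value = looking / max_total if max_total > 0 else None
    return value, _ok(task)


def wheel_face_distance(
    trials: Sequence[WheelTrial], config: ExtractionConfig = ExtractionConfig()
) -> tuple[Optional[tuple[float, float]], FilterOutcome]:
    """(min, max) face-screen distance in mm over face-detected frames."""
    task = "wheel"
    bad = _wheel_filter(trials, config)
    if bad is not None:
        return None, bad
    dists = [
        f.distance_mm
        for tr in trials
        if tr.completed
        for f in tr.face_frames
        if f.face_detected and f.distance_mm is not None
    ]
    if not dists:
        return None, _ok(task)
    return (float(min(dists)), float(max(dists))), _ok(task)


# ---------------------------------------------------------------------------
# motor domain


_DETREND_CACHE: dict[int, tuple[np.ndarray, float]] = {}


def linear_detrend(x: np.ndarray) -> np.ndarray:
    """Remove the least-squares straight line (equivalent to linear detrending)."""
    n = x.size
    cached = _DETREND_CACHE.get(n)
    if cached is None:
        tc = np.arange(n, dtype=float) - (n - 1) / 2.0
        cached = (tc, float(tc @ tc))
        if len(_DETREND_CACHE) < 32:
            _DETREND_CACHE[n] = cached
    tc, tt = cached
    slope = float(tc @ x) / tt
    return x - x.mean() - slope * tc


def _motor_trial_valid(trial: MotorTrial, config: ExtractionConfig) -> bool:
    if trial.touch.shape[0] < 2 or trial.target.shape[0] < 2:
        return False
    t0, t1 = trial.target[0, 0], trial.target[-1, 0]
    span = t1 - t0
    if span <= 0:
        return False
    lo = max(t0, trial.touch[0, 0])
    hi = min(t1, trial.touch[-1, 0])
    return (hi - lo) >= config.motor_overlap_min_frac * span


def _valid_motor_trials(
    trials: Sequence[MotorTrial], config: ExtractionConfig
) -> tuple[list[MotorTrial], Optional[FilterOutcome]]:
    task = "motor"
    if not trials:
        return [], _excluded(task, FilterReason.MISSING_TASK)
    valid = [tr for tr in trials if _motor_trial_valid(tr, config)]
    if len(valid) < config.motor_min_valid_trials:
        return [], _excluded(task, FilterReason.FEWER_THAN_TWO_TRIALS)
    return valid, None


def motor_rmse(trial: MotorTrial, config: ExtractionConfig = ExtractionConfig()) -> float:
    """Root-mean-square Euclidean target-finger distance for one trial.

    The finger trace is linearly interpolated onto the target timestamps
    within the overlapping time support.
    """
    tgt, tch = trial.target, trial.touch
    lo = max(tgt[0, 0], tch[0, 0])
    hi = min(tgt[-1, 0], tch[-1, 0])
    mask = (tgt[:, 0] >= lo) & (tgt[:, 0] <= hi)
    t = tgt[mask, 0]
    if t.size == 0:
        raise ValueError("no overlapping support between target and touch")
    x = np.interp(t, tch[:, 0], tch[:, 1])
    y = np.interp(t, tch[:, 0], tch[:, 2])
    d2 = (x - tgt[mask, 1]) ** 2 + (y - tgt[mask, 2]) ** 2
    return float(np.sqrt(d2.mean()))


def _resampled_pair(
    trial: MotorTrial, config: ExtractionConfig
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Target and touch resampled onto a uniform grid over the overlap."""
    tgt, tch = trial.target, trial.touch
    lo = max(tgt[0, 0], tch[0, 0])
    hi = min(tgt[-1, 0], tch[-1, 0])
    t = np.arange(lo, hi + 1e-9, config.resample_ms)
    T = np.column_stack(
        [np.interp(t, tgt[:, 0], tgt[:, 1]), np.interp(t, tgt[:, 0], tgt[:, 2])]
    )
    C = np.column_stack(
        [np.interp(t, tch[:, 0], tch[:, 1]), np.interp(t, tch[:, 0], tch[:, 2])]
    )
    return t, T, C


def motor_frequency_gain(
    trial: MotorTrial, axis: str, config: ExtractionConfig = ExtractionConfig()
) -> Optional[float]:
    """Band-limited, frequency-weighted spectral magnitude ratio child/target.

    Both series are resampled to a uniform grid, linearly detrended, and
    their one-sided magnitude spectra compared over ``fft_band_hz`` with
    weights w(f) = f.  The gain is 1 under perfect tracking and grows with
    child-added in-band motion; returns ``None`` when the target has no
    in-band power.
    """
    col = {"x": 0, "y": 1}[axis]
    t, T, C = _resampled_pair(trial, config)
    if t.size < 8:
        return None
    tgt = linear_detrend(T[:, col])
    tch = linear_detrend(C[:, col])
    f = np.fft.rfftfreq(t.size, d=config.resample_ms / 1000.0)
    lo, hi = config.fft_band_hz
    band = (f >= lo) & (f <= hi)
    w = f[band]
    denom = float((w * np.abs(np.fft.rfft(tgt))[band]).sum())
    if denom == 0.0:
        return None
    num = float((w * np.abs(np.fft.rfft(tch))[band]).sum())
    return num / denom


def motor_jerk(
    trial: MotorTrial, config: ExtractionConfig = ExtractionConfig()
) -> Optional[float]:
    """Dimensionless movement-smoothness index for one trial.

    Mean magnitude of the discrete third difference of the (uniformly
    resampled) finger trajectory divided by dt^3, normalised by
    screen diagonal x ``jerk_scale_s3``.
    """
    t, _T, C = _resampled_pair(trial, config)
    if t.size < 4:
        return None
    dt = config.resample_ms / 1000.0
    d3 = np.diff(C, n=3, axis=0)
    mag = np.sqrt((d3**2).sum(axis=1)).mean() / dt**3
    diag = math.hypot(*config.screen_px)
    return float(mag / (diag * config.jerk_scale_s3))


def _motor_features(
    trials: Sequence[MotorTrial], config: ExtractionConfig
) -> tuple[dict[str, Optional[float]], FilterOutcome]:
    valid, bad = _valid_motor_trials(trials, config)
    out: dict[str, Optional[float]] = {
        "motor_rmse": None,
        "fft_gain_x": None,
        "fft_gain_y": None,
        "jerk": None,
    }
    if bad is not None:
        return out, bad

    def _mean(vals: list[Optional[float]]) -> Optional[float]:
        xs = [v for v in vals if v is not None]
        return float(np.mean(xs)) if xs else None

    out["motor_rmse"] = _mean([motor_rmse(tr, config) for tr in valid])
    out["fft_gain_x"] = _mean([motor_frequency_gain(tr, "x", config) for tr in valid])
    out["fft_gain_y"] = _mean([motor_frequency_gain(tr, "y", config) for tr in valid])
    out["jerk"] = _mean([motor_jerk(tr, config) for tr in valid])
    return out, _ok("motor")


# ---------------------------------------------------------------------------
# bubble popping


def bubble_features(
    touches: Sequence[BubbleTouch], config: ExtractionConfig = ExtractionConfig()
) -> tuple[Optional[tuple[float, float, float]], FilterOutcome]:
    """(mean pressure, mean |dx|, mean |dy|) over popped bubbles."""
    task = "bubble"
    if not touches:
        return None, _excluded(task, FilterReason.MISSING_TASK)
    popped = [b for b in touches if b.popped]
    if not popped:
        return None, _excluded(task, FilterReason.NO_BUBBLES_POPPED)
    force = float(np.mean([b.pressure for b in popped]))
    dx = float(np.mean([abs(b.touch_point[0] - b.bubble_center[0]) for b in popped]))
    dy = float(np.mean([abs(b.touch_point[1] - b.bubble_center[1]) for b in popped]))
    return (force, dx, dy), _ok(task)


# ---------------------------------------------------------------------------
# colouring


def _polygon(session: ColouringSession) -> Polygon:
    return Polygon(session.figure_outline)


def _inside_flags(poly: Polygon, stroke: np.ndarray) -> np.ndarray:
    """Inside/outside per sample; points exactly on the outline count inside."""
    pts = shapely.points(stroke[:, 1], stroke[:, 2])
    return shapely.covers(poly, pts)


def colouring_crossings(
    sessions: Sequence[ColouringSession],
    config: ExtractionConfig = ExtractionConfig(),
) -> tuple[Optional[int], FilterOutcome]:
    """Total count of inside/outside flips between consecutive stroke samples.

    Stroke (and trial) boundaries never generate crossings; inclusion
    requires painted coverage of at least ``coverage_min``.
    """
    task = "colouring"
    if not sessions:
        return None, _excluded(task, FilterReason.MISSING_TASK)
    if not any(s.strokes for s in sessions):
        return None, _excluded(task, FilterReason.MISSING_TASK)
    cov = colouring_coverage(sessions, config)
    if cov < config.coverage_min:
        return None, _excluded(task, FilterReason.COVERAGE_BELOW_THRESHOLD)
    count = 0
    for sess in sessions:
        poly = _polygon(sess)
        for stroke in sess.strokes:
            if stroke.shape[0] < 2:
                continue
            inside = _inside_flags(poly, stroke)
            count += int(np.sum(inside[1:] != inside[:-1]))
    return count, _ok(task)


def colouring_coverage(
    sessions: Sequence[ColouringSession],
    config: ExtractionConfig = ExtractionConfig(),
) -> float:
    """Fraction of pixels within brush radius of any stroke sample.

    Computed on an integer pixel grid (optionally coarsened by
    ``coverage_grid_step``); the denominator is the whole screen or the
    figure interior depending on ``coverage_denominator``.
    """
    sessions = list(sessions)
    if not sessions:
        return 0.0
    w, h = sessions[0].screen_px
    step = max(1, int(config.coverage_grid_step))
    gw, gh = w // step, h // step
    painted = np.zeros((gh, gw), dtype=bool)
    for sess in sessions:
        r = sess.brush_radius_px / step
        ri = int(math.ceil(r))
        yy, xx = np.mgrid[-ri : ri + 1, -ri : ri + 1]
        disc = (xx**2 + yy**2) <= r**2
        for stroke in sess.strokes:
            cx = np.round(stroke[:, 1] / step).astype(int)
            cy = np.round(stroke[:, 2] / step).astype(int)
            for x, y in zip(cx, cy):
                x0, x1 = max(0, x - ri), min(gw, x + ri + 1)
                y0, y1 = max(0, y - ri), min(gh, y + ri + 1)
                if x0 >= x1 or y0 >= y1:
                    continue
                painted[y0:y1, x0:x1] |= disc[
                    y0 - (y - ri) : y1 - (y - ri), x0 - (x - ri) : x1 - (x - ri)
                ]
    if config.coverage_denominator == "screen":
        denom = gw * gh
        return float(painted.sum()) / denom
    if config.coverage_denominator == "figure":
        poly = _polygon(sessions[0])
        ys, xs = np.nonzero(painted)
        inside_painted = int(
            np.sum(shapely.covers(poly, shapely.points(xs * step, ys * step)))
        )
        denom = poly.area / step**2
        return min(1.0, inside_painted / denom) if denom > 0 else 0.0
    raise ValidationError(
        f"unknown coverage_denominator {config.coverage_denominator!r}"
    )


# ---------------------------------------------------------------------------
# parent/caregiver report and interaction


def questionnaire_score(resp: QuestionnaireResponse) -> int:
    """Sum of 14 binary items; reverse-coded items score 1 for 'no'."""
    if len(resp.items) != 14:
        raise ValidationError(f"{len(resp.items)} items, expected 14")
    rev = set(resp.reverse_coded)
    if len(rev) != 8:
        raise ValidationError("exactly 8 reverse-coded indices required")
    score = 0
    for i, yes in enumerate(resp.items):
        score += int(not yes) if i in rev else int(yes)
    return score


def pci_features(
    codings: Sequence[PCICoding], seed: int = 0
) -> Optional[tuple[float, float]]:
    """(child initiation, caregiver synchrony) proportions from one coder.

    When several coders coded the video, one is selected uniformly at
    random with the given seed.
    """
    codings = list(codings)
    if not codings:
        return None
    if len(codings) == 1:
        c = codings[0]
    else:
        rng = np.random.default_rng(seed)
        c = codings[int(rng.integers(len(codings)))]
    return (c.child_initiation_prop, c.caregiver_sync_prop)


# ---------------------------------------------------------------------------
# whole-record extraction


def extract_features(
    record: ChildRecord, config: ExtractionConfig = ExtractionConfig()
) -> tuple[FeatureVector, list[FilterOutcome]]:
    """Apply every task operation and filter to one record.

    Absent tasks yield missing slots with a ``missing_task`` outcome; the
    outcome list always covers all eight tasks.  The coder-selection seed
    for the interaction task is derived from ``config.pci_seed`` and the
    child id so re-extraction is deterministic.
    """
    fv = FeatureVector(record.child_id, record.group)
    outcomes: list[FilterOutcome] = []

    val, out = social_preference(record.tasks.get("preferential", []), config)
    fv["social_preference"] = val
    outcomes.append(out)

    val, out = button_social_choice(record.tasks.get("button", []), config)
    fv["social_choice"] = val
    outcomes.append(out)

    wl, out = wheel_looking(record.tasks.get("wheel", []), config)
    fv["wheel_looking"] = wl
    outcomes.append(out)
    wd, _ = wheel_face_distance(record.tasks.get("wheel", []), config)
    if wd is not None:
        fv["wheel_dist_min"], fv["wheel_dist_max"] = wd

    motor, out = _motor_features(record.tasks.get("motor", []), config)
    for k, v in motor.items():
        fv[k] = v
    outcomes.append(out)

    bub, out = bubble_features(record.tasks.get("bubble", []), config)
    if bub is not None:
        fv["pop_force"], fv["pop_dist_x"], fv["pop_dist_y"] = bub
    outcomes.append(out)

    cc, out = colouring_crossings(record.tasks.get("colouring", []), config)
    fv["colour_crossings"] = None if cc is None else float(cc)
    outcomes.append(out)

    codings = record.tasks.get("pci", [])
    child_seed = (
        config.pci_seed * 1_000_003 + zlib.crc32(record.child_id.encode())
    ) % (2**31)
    pci = pci_features(codings, seed=child_seed)
    if pci is None:
        outcomes.append(_excluded("pci", FilterReason.MISSING_TASK))
    else:
        fv["pci_child_init"], fv["pci_caregiver_sync"] = pci
        outcomes.append(_ok("pci"))

    q = record.tasks.get("questionnaire")
    if q is None:
        outcomes.append(_excluded("questionnaire", FilterReason.MISSING_TASK))
    else:
        fv["questionnaire_score"] = float(questionnaire_score(q))
        outcomes.append(_ok("questionnaire"))

    return fv, outcomes


def extract_cohort(
    cohort: Sequence[ChildRecord], config: ExtractionConfig = ExtractionConfig()
) -> tuple[list[FeatureVector], list[tuple[str, FilterOutcome]]]:
    """Extract every child; returns vectors plus tidy (child_id, outcome) rows."""
    vectors = []
    outcome_rows = []
    for rec in cohort:
        fv, outs = extract_features(rec, config)
        vectors.append(fv)
        outcome_rows.extend((rec.child_id, o) for o in outs)
    return vectors, outcome_rows
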