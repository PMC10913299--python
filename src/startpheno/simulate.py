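"""Synthetic three-group behavioural cohort generator.

Generates raw task streams (gaze frames, button choices, wheel watching,
butterfly-following finger traces, bubble touches, colouring strokes,
questionnaire answers, interaction codings) for TD/AS/ID children such
that the features extracted by :mod:`startpheno.features` follow
configured group-level target means/SDs, with per-task attrition and
filter-failure rates reproducing the study-like participant counts.

Calibration strategy
--------------------
Wherever a feature is a direct functional of a latent per-child parameter
(choice probabilities, looking ratios, interaction proportions, crossing
counts, face distances) the generator draws the latent parameter from a
moment-matched distribution — Beta for [0,1]-bounded features, gamma for
positive unbounded ones — deflating the latent variance by the exactly
known sampling variance the raw stream adds (binomial noise of frame or
trial counts, within-child pressure noise, finite-sample |offset| noise),
so the *extracted* features match the targets in both mean and SD.

The motor stream is signal-level: touch = target delayed by a reaction
lag, plus a constant per-child offset, plus band-limited tracking noise
(exact-DFT-bin sinusoids, 0.2-2 Hz) and a high-frequency tremor
(5.5-9.5 Hz).  Per-child feature targets (RMSE, spectral gains, jerk) are
drawn from moment-matched marginals joined by a Gaussian copula, and the
noise amplitudes are solved per trial: the expected frequency-weighted
magnitude spectrum of signal-plus-noise has a closed Rician form per DFT
bin, so the band-noise amplitude matching a target gain is found by 1-D
root finding; tremor amplitude likewise for jerk; the constant offset
absorbs the remaining RMSE budget exactly (a constant is annihilated by
the detrend step, so it moves RMSE without touching the spectral gains).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
from numpy.random import Generator, SeedSequence, default_rng
from scipy.optimize import brentq
from scipy.special import i0e, i1e

from .features import ExtractionConfig, linear_detrend
from .types import (
    TASK_NAMES,
    BubbleTouch,
    ButtonTrial,
    ChildRecord,
    ColouringSession,
    FaceFrame,
    GazeFrame,
    Gaze,
    Group,
    MotorTrial,
    PCICoding,
    PreferentialTrial,
    QuestionnaireResponse,
    WheelTrial,
)

__all__ = [
    "GroupProfile",
    "SimulationConfig",
    "default_profiles",
    "generate_butterfly_trajectory",
    "ButterflyTrajectory",
    "simulate_motor_trial",
    "simulate_gaze_stream",
    "simulate_child",
    "apply_attrition",
    "simulate_cohort",
    "REVERSE_ITEMS",
]

#: The 8 reverse-coded questionnaire item indices (an arbitrary fixed set;
#: which items are reverse-coded is a labelling choice with no effect on
#: the score distribution).
REVERSE_ITEMS: tuple[int, ...] = (6, 7, 8, 9, 10, 11, 12, 13)


@dataclass
class GroupProfile:
    """Feature-level targets and attrition rates for one group.

    ``targets`` maps every feature slot to its (mean, SD) target.
    ``questionnaire_item_p`` holds the 14 per-item endorsement
    probabilities (equal by default; their sum is the score mean).
    ``dropout`` is the per-task probability that the task is entirely
    absent (child refusal / app malfunction); ``filter_fail`` the
    probability that the task was administered but produced data failing
    its pre-set inclusion filter.
    """

    targets: dict[str, tuple[float, float]]
    questionnaire_item_p: np.ndarray
    dropout: dict[str, float] = field(default_factory=dict)
    filter_fail: dict[str, float] = field(default_factory=dict)


@dataclass(frozen=True)
class SimulationConfig:
    """Study-condition knobs of the simulator (defaults follow the field study)."""

    n_per_group: tuple[int, int, int] = (40, 48, 43)  # TD, AS, ID
    seed: int = 0
    fps: float = 20.0
    screen_px: tuple[int, int] = (2560, 1600)
    age_range: tuple[float, float] = (2.0, 7.99)
    female_p: tuple[float, float, float] = (19 / 40, 12 / 48, 9 / 43)
    # trial counts
    n_preferential_trials: int = 8
    n_button_trials: int = 8
    n_wheel_trials: int = 5
    n_motor_trials: int = 4
    n_bubble_trials: int = 6
    n_colouring_trials: int = 2
    # preferential looking
    preferential_trial_s: float = 7.5
    p_offscreen: float = 0.05
    p_undetected: float = 0.08
    p_elsewhere: float = 0.12
    # wheel
    wheel_trial_s: float = 15.0
    wheel_face_detect_p: float = 0.85
    wheel_fail_face_detect_p: float = 0.18
    # motor
    motor_trial_s: float = 30.0
    motor_lag_ms: float = 100.0
    velocity_range: tuple[float, float] = (60.0, 140.0)
    motor_noise_band_hz: tuple[float, float] = (0.2, 2.0)
    motor_tremor_band_hz: tuple[float, float] = (5.5, 9.5)
    motor_copula_rho: float = 0.6
    # bubble
    bubble_pop_p: float = 0.95
    pressure_within_sd: float = 0.01
    # colouring
    brush_radius_px: float = 60.0
    # interaction coding
    multi_coder_frac: float = 0.13
    n_coders: int = 3
    coder_noise_init: float = 0.15
    coder_noise_sync: float = 0.06
    # feature-layer conventions the generators invert
    extraction: ExtractionConfig = ExtractionConfig()


# ---------------------------------------------------------------------------
# moment-matching helpers


def _beta_params(mean: float, var: float) -> tuple[float, float]:
    vmax = mean * (1.0 - mean)
    var = min(max(var, 1e-8), 0.98 * vmax)
    r = vmax / var - 1.0
    return mean * r, (1.0 - mean) * r


def _gamma_params(mean: float, sd: float) -> tuple[float, float]:
    k = (mean / sd) ** 2
    return k, sd**2 / mean


def _deflated_var(mean: float, sd: float, sampling_var: float) -> float:
    """Latent variance so latent + sampling noise reproduces the target SD."""
    return max(sd**2 - sampling_var, 1e-8)


def _beta_draw(rng: Generator, mean: float, var: float) -> float:
    a, b = _beta_params(mean, var)
    return float(rng.beta(a, b))


# ---------------------------------------------------------------------------
# default profiles (feature targets + attrition tables)

# per-group feature targets: slot -> (TD, AS, ID) x (mean, sd)
_FEATURE_TARGETS: dict[str, tuple[tuple[float, float], ...]] = {
    "social_preference": ((0.59, 0.09), (0.52, 0.12), (0.53, 0.09)),
    "social_choice": ((0.47, 0.24), (0.52, 0.28), (0.52, 0.21)),
    "wheel_looking": ((0.46, 0.37), (0.73, 0.33), (0.66, 0.36)),
    # face-screen distances (mm) are not reported per group; plausible
    # seated-use values, identical across groups:
    "wheel_dist_min": ((260.0, 50.0), (255.0, 50.0), (258.0, 50.0)),
    "wheel_dist_max": ((480.0, 70.0), (475.0, 70.0), (478.0, 70.0)),
    "motor_rmse": ((203.80, 97.95), (591.27, 283.63), (404.70, 216.74)),
    "fft_gain_x": ((1.53, 0.40), (2.01, 0.76), (2.02, 0.72)),
    "fft_gain_y": ((10.33, 9.12), (25.28, 15.42), (20.27, 11.51)),
    "jerk": ((0.06, 0.13), (0.05, 0.13), (0.05, 0.13)),
    "pop_force": ((0.07, 0.01), (0.09, 0.02), (0.08, 0.02)),
    "pop_dist_x": ((45.20, 11.78), (88.97, 57.34), (66.81, 22.49)),
    "pop_dist_y": ((54.95, 13.59), (87.02, 43.17), (75.01, 25.03)),
    "colour_crossings": ((23.05, 16.98), (56.40, 29.43), (49.81, 28.31)),
    "pci_child_init": ((0.48, 0.24), (0.23, 0.24), (0.40, 0.23)),
    "pci_caregiver_sync": ((0.33, 0.22), (0.15, 0.11), (0.20, 0.14)),
    "questionnaire_score": ((1.03, 1.31), (5.06, 2.26), (3.09, 2.32)),
}

# data-availability counts per task: group n -> n with any data -> n passing
# the filter (from the per-task participant counts of the field study).
_ATTRITION = {
    # task: ((avail_td, avail_as, avail_id), (final_td, final_as, final_id))
    "preferential": ((40, 40, 38), (40, 40, 38)),
    "button": ((40, 37, 39), (39, 27, 38)),
    "wheel": ((40, 46, 39), (37, 41, 39)),
    "motor": ((40, 43, 37), (40, 40, 35)),
    "bubble": ((40, 41, 39), (40, 41, 39)),
    "colouring": ((40, 38, 35), (37, 29, 27)),
    "pci": ((32, 35, 33), (32, 35, 33)),
    "questionnaire": ((40, 48, 43), (40, 48, 43)),
}

_GROUP_N = {Group.TD: 40, Group.AS: 48, Group.ID: 43}
_GROUP_IDX = {Group.TD: 0, Group.AS: 1, Group.ID: 2}


def default_profiles() -> dict[Group, GroupProfile]:
    """Profiles calibrated to the printed group summary table and per-task ns."""
    out = {}
    for g in Group:
        gi = _GROUP_IDX[g]
        targets = {slot: _FEATURE_TARGETS[slot][gi] for slot in _FEATURE_TARGETS}
        q_mean = targets["questionnaire_score"][0]
        dropout = {}
        fail = {}
        for task, (avail, final) in _ATTRITION.items():
            n = _GROUP_N[g]
            dropout[task] = 1.0 - avail[gi] / n
            fail[task] = 1.0 - final[gi] / avail[gi] if avail[gi] else 0.0
        out[g] = GroupProfile(
            targets=targets,
            questionnaire_item_p=np.full(14, q_mean / 14.0),
            dropout=dropout,
            filter_fail=fail,
        )
    return out


# ---------------------------------------------------------------------------
# butterfly trajectory


@dataclass
class ButterflyTrajectory:
    """Piecewise-smooth random path with bounded speed, reflected at margins.

    ``samples`` is the (n, 3) array (t_ms, x_px, y_px) on the frame grid;
    ``eval(t_ms)`` interpolates the underlying fine-grid path, so the
    position at off-grid times (needed for reaction-lag simulation) is
    consistent with the samples.
    """

    samples: np.ndarray
    _fine_t: np.ndarray
    _fine_xy: np.ndarray

    def eval(self, t_ms: np.ndarray) -> np.ndarray:
        t = np.clip(np.asarray(t_ms, dtype=float), self._fine_t[0], self._fine_t[-1])
        x = np.interp(t, self._fine_t, self._fine_xy[:, 0])
        y = np.interp(t, self._fine_t, self._fine_xy[:, 1])
        return np.column_stack([x, y])


def _fold(p: np.ndarray, lo: float, hi: float) -> np.ndarray:
    L = hi - lo
    y = np.mod(p - lo, 2 * L)
    return lo + np.where(y <= L, y, 2 * L - y)


def generate_butterfly_trajectory(
    duration_s: float,
    velocity_range: tuple[float, float],
    seed: Union[int, SeedSequence],
    screen_px: tuple[int, int] = (2560, 1600),
    fps: float = 20.0,
    direction: int = 1,
) -> ButterflyTrajectory:
    """Random target path with speed inside ``velocity_range`` (px/s).

    Speed follows a slow sinusoidal profile spanning the configured range
    and the heading oscillates around horizontal with an amplitude
    proportional to the relative velocity spread, so a degenerate range
    (vmin == vmax == v) yields a straight horizontal path of length
    v x duration.  The path is reflected at the screen margins.
    """
    vmin, vmax = velocity_range
    if duration_s <= 0:
        raise ValueError("duration must be > 0")
    if vmin < 0 or vmax < vmin:
        raise ValueError(f"degenerate velocity range {velocity_range}")
    rng = default_rng(seed)
    w, h = screen_px
    margin = 150.0
    dt_fine = 0.02
    t = np.arange(0.0, duration_s + dt_fine / 2, dt_fine)

    f_speed = rng.uniform(0.15, 0.5)
    ph_speed = rng.uniform(0, 2 * math.pi)
    speed = vmin + (vmax - vmin) * 0.5 * (1.0 + np.sin(2 * math.pi * f_speed * t + ph_speed))

    v_mid = 0.5 * (vmin + vmax)
    theta_amp = 0.0 if v_mid == 0 else min(0.5, 0.6 * (vmax - vmin) / (vmax + vmin))
    f_head = rng.uniform(0.2, 0.6)
    ph_head = rng.uniform(0, 2 * math.pi)
    f_head2 = rng.uniform(0.2, 0.6)
    ph_head2 = rng.uniform(0, 2 * math.pi)
    theta = theta_amp * (
        0.7 * np.sin(2 * math.pi * f_head * t + ph_head)
        + 0.3 * np.sin(2 * math.pi * f_head2 * t + ph_head2)
    )

    vx = direction * speed * np.cos(theta)
    vy = speed * np.sin(theta)
    x0 = margin if direction > 0 else w - margin
    x = x0 + np.concatenate([[0.0], np.cumsum(0.5 * (vx[1:] + vx[:-1]) * dt_fine)])
    y = h / 2 + np.concatenate([[0.0], np.cumsum(0.5 * (vy[1:] + vy[:-1]) * dt_fine)])
    x = _fold(x, margin, w - margin)
    y = _fold(y, margin, h - margin)

    fine_t = t * 1000.0
    fine_xy = np.column_stack([x, y])
    step_ms = 1000.0 / fps
    t_ms = np.arange(0.0, duration_s * 1000.0 - step_ms / 2, step_ms)
    xi = np.interp(t_ms, fine_t, x)
    yi = np.interp(t_ms, fine_t, y)
    return ButterflyTrajectory(
        samples=np.column_stack([t_ms, xi, yi]), _fine_t=fine_t, _fine_xy=fine_xy
    )


# ---------------------------------------------------------------------------
# exact-bin band noise and the Rician gain/jerk solvers


def _band_bins(n: int, dt_s: float, band_hz: tuple[float, float]) -> np.ndarray:
    f = np.fft.rfftfreq(n, d=dt_s)
    return np.nonzero((f >= band_hz[0]) & (f <= band_hz[1]))[0]


def _bin_noise(rng: Generator, n: int, bins: np.ndarray, tau: float) -> np.ndarray:
    """Sum of exact-DFT-bin sinusoids with iid N(0, tau^2) quadrature coefs."""
    if tau == 0.0 or bins.size == 0:
        return np.zeros(n)
    a = rng.normal(0.0, tau, bins.size)
    b = rng.normal(0.0, tau, bins.size)
    Z = np.zeros(n // 2 + 1, dtype=complex)
    Z[bins] = (n / 2.0) * (a - 1j * b)
    return np.fft.irfft(Z, n)


def _rician_mean(s: np.ndarray, nu: float) -> np.ndarray:
    """E|s + CN| with complex-Gaussian noise of per-component sd ``nu``."""
    if nu == 0.0:
        return np.asarray(s, dtype=float)
    x = np.asarray(s, dtype=float) ** 2 / (2.0 * nu**2)
    L = (1.0 + x) * i0e(x / 2.0) + x * i1e(x / 2.0)
    return nu * math.sqrt(math.pi / 2.0) * L


def _expected_weighted_sum(
    S: np.ndarray, fw: np.ndarray, noise_bins: np.ndarray, tau: float, n: int
) -> float:
    E = S.astype(float).copy()
    if tau > 0.0 and noise_bins.size:
        E[noise_bins] = _rician_mean(S[noise_bins], (n / 2.0) * tau)
    return float((fw * E).sum())


def _solve_tau(
    S: np.ndarray, fw: np.ndarray, noise_bins: np.ndarray, target: float, n: int
) -> float:
    """Band-noise quadrature sd giving the target weighted-magnitude sum."""
    base = _expected_weighted_sum(S, fw, noise_bins, 0.0, n)
    if target <= base or noise_bins.size == 0:
        return 0.0
    hi = 1.0
    while _expected_weighted_sum(S, fw, noise_bins, hi, n) < target and hi < 1e7:
        hi *= 4.0
    return float(
        brentq(
            lambda tau: _expected_weighted_sum(S, fw, noise_bins, tau, n) - target,
            0.0,
            hi,
            xtol=1e-9,
            rtol=1e-12,
        )
    )


def _third_diff_gain(n: int, bins: np.ndarray) -> float:
    """Sum over bins of |H3(w)|^2 with H3 the third-difference filter."""
    w = 2.0 * math.pi * bins / n
    return float(((2.0 * np.sin(w / 2.0)) ** 6).sum())


def _expected_jerk_sum(d3_mag: np.ndarray, s2: float) -> float:
    """E sum_t |d3T(t) + 2D noise| for isotropic per-axis variance s2."""
    if s2 <= 0.0:
        return float(d3_mag.sum())
    return float(_rician_mean(d3_mag, math.sqrt(s2)).sum())


# ---------------------------------------------------------------------------
# task generators


def simulate_gaze_stream(
    p_social: float,
    duration_s: float,
    fps: float,
    p_offscreen: float,
    p_undetected: float,
    seed: Union[int, SeedSequence, Generator],
    p_elsewhere: float = 0.0,
    t0_ms: int = 0,
) -> list[GazeFrame]:
    """Frame-labelled gaze stream with the given marginal probabilities."""
    for p in (p_social, p_offscreen, p_undetected, p_elsewhere):
        if not 0.0 <= p <= 1.0:
            raise ValueError("probabilities must lie in [0, 1]")
    rng = seed if isinstance(seed, Generator) else default_rng(seed)
    n = int(round(duration_s * fps))
    step = int(round(1000.0 / fps))
    u = rng.random(n)
    v = rng.random(n)
    labels = np.where(
        u < p_undetected,
        0,
        np.where(
            u < p_undetected + p_offscreen,
            1,
            np.where(
                u < p_undetected + p_offscreen + p_elsewhere,
                2,
                np.where(v < p_social, 3, 4),
            ),
        ),
    )
    lut = (Gaze.UNDETECTED, Gaze.OFF, Gaze.ELSEWHERE, Gaze.SOCIAL, Gaze.NONSOCIAL)
    return [
        GazeFrame(t0_ms + i * step, lab != 0, lut[lab])
        for i, lab in enumerate(labels.tolist())
    ]


def _sim_preferential(
    rng: Generator, profile: GroupProfile, config: SimulationConfig, fail: bool
) -> list[PreferentialTrial]:
    m, sd = profile.targets["social_preference"]
    n_frames = config.n_preferential_trials * int(
        round(config.preferential_trial_s * config.fps)
    )
    p_stim = 1.0 - config.p_undetected - config.p_offscreen - config.p_elsewhere
    n_stim = max(1.0, n_frames * p_stim)
    var = _deflated_var(m, sd, m * (1.0 - m) / n_stim)
    p_child = _beta_draw(rng, m, var)
    p_und = 0.8 if fail else config.p_undetected
    trials = []
    for i in range(config.n_preferential_trials):
        frames = simulate_gaze_stream(
            p_child,
            config.preferential_trial_s,
            config.fps,
            config.p_offscreen,
            p_und,
            rng,
            p_elsewhere=config.p_elsewhere,
        )
        trials.append(PreferentialTrial(social_on_left=(i % 2 == 0), frames=frames))
    return trials


def _sim_button(
    rng: Generator, profile: GroupProfile, config: SimulationConfig, fail: bool
) -> list[ButtonTrial]:
    m, sd = profile.targets["social_choice"]
    nt = config.n_button_trials
    var = _deflated_var(m, sd, (m * (1.0 - m)) / nt)
    p_child = _beta_draw(rng, m, var)
    n_completed = (nt // 2 - 1) if fail else nt
    trials = []
    for i in range(nt):
        if i < n_completed:
            choice = "social" if rng.random() < p_child else "nonsocial"
            trials.append(ButtonTrial(completed=True, choice=choice))
        else:
            trials.append(ButtonTrial(completed=False, choice="none"))
    return trials


def _sim_wheel(
    rng: Generator, profile: GroupProfile, config: SimulationConfig, fail: bool
) -> list[WheelTrial]:
    m, sd = profile.targets["wheel_looking"]
    ratio = _beta_draw(rng, m, sd**2)
    dmin_m, dmin_sd = profile.targets["wheel_dist_min"]
    dmax_m, dmax_sd = profile.targets["wheel_dist_max"]
    dmin = rng.normal(dmin_m, dmin_sd)
    dmax = rng.normal(dmax_m, dmax_sd)
    dmin = max(50.0, dmin)
    dmax = max(dmin + 10.0, dmax)

    step = int(round(1000.0 / config.fps))
    frames_per_trial = int(round(config.wheel_trial_s * config.fps))
    n_total = config.n_wheel_trials * frames_per_trial
    look_total = int(round(ratio * n_total))
    detect_p = config.wheel_fail_face_detect_p if fail else config.wheel_face_detect_p

    # distance ramp over all detected frames realises (dmin, dmax) exactly
    detected = rng.random(n_total) < detect_p
    n_det = int(detected.sum())
    dists = np.linspace(dmin, dmax, max(n_det, 2))[:n_det] if n_det else np.array([])

    # pre-assign the ramp values to detected frame positions
    dist_by_idx = np.full(n_total, np.nan)
    dist_by_idx[np.nonzero(detected)[0]] = dists
    t_grid = [fi * step for fi in range(frames_per_trial)]

    trials = []
    remaining_look = look_total
    for ti in range(config.n_wheel_trials):
        k = min(remaining_look, frames_per_trial)
        remaining_look -= k
        sl = slice(ti * frames_per_trial, (ti + 1) * frames_per_trial)
        frames = [
            FaceFrame(
                t_ms=t_grid[fi],
                face_detected=det,
                distance_mm=(float(d) if det else None),
                gaze_on_wheel=fi < k,
            )
            for fi, (det, d) in enumerate(
                zip(detected[sl].tolist(), dist_by_idx[sl].tolist())
            )
        ]
        trials.append(
            WheelTrial(
                completed=True,
                play_duration_s=config.wheel_trial_s,
                face_frames=frames,
                max_duration_s=config.wheel_trial_s,
            )
        )
    return trials


def simulate_motor_trial(
    target: ButterflyTrajectory,
    lag_ms: float,
    noise_sd_px: float,
    seed: Union[int, SeedSequence, Generator],
    noise_band_hz: tuple[float, float] = (0.2, 2.0),
) -> MotorTrial:
    """Finger trace = target delayed by ``lag_ms`` + band-limited noise.

    The tracking noise is temporally smooth (band-limited below
    ``noise_band_hz[1]``) with time-domain RMS ``noise_sd_px`` per axis;
    expected RMSE grows monotonically with both lag and noise amplitude.
    """
    if lag_ms < 0 or noise_sd_px < 0:
        raise ValueError("lag and noise_sd must be >= 0")
    rng = seed if isinstance(seed, Generator) else default_rng(seed)
    t_ms = target.samples[:, 0]
    n = t_ms.size
    dt_s = (t_ms[1] - t_ms[0]) / 1000.0
    pos = target.eval(t_ms - lag_ms)
    bins = _band_bins(n, dt_s, noise_band_hz)
    tau = noise_sd_px / math.sqrt(bins.size) if bins.size else 0.0
    nx = _bin_noise(rng, n, bins, tau)
    ny = _bin_noise(rng, n, bins, tau)
    touch = np.column_stack(
        [t_ms, pos[:, 0] + nx, pos[:, 1] + ny, np.full(n, 0.5)]
    )
    return MotorTrial(target=target.samples.copy(), touch=touch)


def _draw_motor_targets(
    rng: Generator, profile: GroupProfile, rho: float
) -> tuple[float, float, float, float]:
    """(rmse, gain_x, gain_y, jerk) per-child targets; Gaussian copula on the
    first three (gains ride on 1 + gamma; jerk lognormal, independent)."""
    from scipy.stats import gamma as _gamma_dist, norm as _norm

    cov = np.full((3, 3), rho)
    np.fill_diagonal(cov, 1.0)
    z = np.linalg.cholesky(cov) @ rng.standard_normal(3)
    u = _norm.cdf(z)

    m, sd = profile.targets["motor_rmse"]
    k, th = _gamma_params(m, sd)
    rmse = float(_gamma_dist.ppf(u[0], k, scale=th))

    gx_m, gx_sd = profile.targets["fft_gain_x"]
    k, th = _gamma_params(max(gx_m - 1.0, 1e-3), gx_sd)
    gx = 1.0 + float(_gamma_dist.ppf(u[1], k, scale=th))

    gy_m, gy_sd = profile.targets["fft_gain_y"]
    k, th = _gamma_params(max(gy_m - 1.0, 1e-3), gy_sd)
    gy = 1.0 + float(_gamma_dist.ppf(u[2], k, scale=th))

    j_m, j_sd = profile.targets["jerk"]
    k, th = _gamma_params(j_m, j_sd)
    jerk = float(rng.gamma(k, th))
    return rmse, gx, gy, jerk


def _sim_motor_touch(
    rng: Generator,
    traj: ButterflyTrajectory,
    rmse_t: float,
    gx_t: float,
    gy_t: float,
    jerk_t: float,
    config: SimulationConfig,
) -> np.ndarray:
    """Synthesise one trial's touch stream realising the per-child targets."""
    ex = config.extraction
    t_ms = traj.samples[:, 0]
    n = t_ms.size
    dt_s = (t_ms[1] - t_ms[0]) / 1000.0
    f = np.fft.rfftfreq(n, d=dt_s)
    gain_band = (f >= ex.fft_band_hz[0]) & (f <= ex.fft_band_hz[1])
    fw = np.where(gain_band, f, 0.0)
    noise_bins = _band_bins(n, dt_s, config.motor_noise_band_hz)
    hf_bins = _band_bins(n, dt_s, config.motor_tremor_band_hz)

    lag = config.motor_lag_ms
    delayed = traj.eval(t_ms - lag)
    d_lag = delayed - traj.samples[:, 1:3]

    # per-axis detrended spectra of the deterministic child component
    Sx = np.abs(np.fft.rfft(linear_detrend(delayed[:, 0])))
    Sy = np.abs(np.fft.rfft(linear_detrend(delayed[:, 1])))
    Dx = float((fw * np.abs(np.fft.rfft(linear_detrend(traj.samples[:, 1])))).sum())
    Dy = float((fw * np.abs(np.fft.rfft(linear_detrend(traj.samples[:, 2])))).sum())

    tau_x = _solve_tau(Sx, fw, noise_bins, gx_t * Dx, n) if Dx > 0 else 0.0
    tau_y = _solve_tau(Sy, fw, noise_bins, gy_t * Dy, n) if Dy > 0 else 0.0
    sig_x2 = tau_x**2 * noise_bins.size
    sig_y2 = tau_y**2 * noise_bins.size

    # tremor amplitude from the jerk target
    dt3 = dt_s**3
    diag = math.hypot(*ex.screen_px)
    d3T = np.diff(delayed, n=3, axis=0)
    d3_mag = np.sqrt((d3T**2).sum(axis=1))
    h3_band = _third_diff_gain(n, noise_bins)
    h3_hf = _third_diff_gain(n, hf_bins)
    v3_band = 0.5 * (tau_x**2 + tau_y**2) * h3_band
    jerk_sum_target = jerk_t * (diag * ex.jerk_scale_s3) * dt3 * d3_mag.size

    def jerk_sum(tau_h: float) -> float:
        return _expected_jerk_sum(d3_mag, v3_band + tau_h**2 * h3_hf)

    if jerk_sum(0.0) >= jerk_sum_target or h3_hf == 0.0:
        tau_h = 0.0
    else:
        hi = 1.0
        while jerk_sum(hi) < jerk_sum_target and hi < 1e6:
            hi *= 4.0
        tau_h = float(
            brentq(lambda th: jerk_sum(th) - jerk_sum_target, 0.0, hi, xtol=1e-10)
        )
        # sanity guard only: tremor amplitude stays below 400 px RMS.  The
        # jerk target takes priority over the RMSE budget here; when both
        # cannot hold, the offset below is dropped and RMSE overshoots.
        cap2 = 400.0**2 / max(hf_bins.size, 1)
        tau_h = min(tau_h, math.sqrt(cap2))

    nx = _bin_noise(rng, n, noise_bins, tau_x)
    ny = _bin_noise(rng, n, noise_bins, tau_y)
    hx = _bin_noise(rng, n, hf_bins, tau_h)
    hy = _bin_noise(rng, n, hf_bins, tau_h)

    # constant per-child offset absorbs the remaining RMSE budget exactly;
    # a constant is removed by detrending, so the spectral gains are untouched
    err0 = d_lag + np.column_stack([nx + hx, ny + hy])
    c0 = float((err0**2).sum(axis=1).mean())
    mu = err0.mean(axis=0)
    ang = rng.uniform(0.0, 2.0 * math.pi)
    uhat = np.array([math.cos(ang), math.sin(ang)])
    p = float(uhat @ mu)
    disc = p**2 + rmse_t**2 - c0
    b = max(0.0, -p + math.sqrt(disc)) if disc > 0 else 0.0
    off = b * uhat

    touch = np.column_stack(
        [
            t_ms,
            delayed[:, 0] + nx + hx + off[0],
            delayed[:, 1] + ny + hy + off[1],
            np.full(n, 0.5),
        ]
    )
    return touch


def _sim_motor(
    rng: Generator, profile: GroupProfile, config: SimulationConfig, fail: bool
) -> list[MotorTrial]:
    rmse_t, gx_t, gy_t, jerk_t = _draw_motor_targets(
        rng, profile, config.motor_copula_rho
    )
    trials = []
    for i in range(config.n_motor_trials):
        traj = generate_butterfly_trajectory(
            config.motor_trial_s,
            config.velocity_range,
            rng,
            screen_px=config.screen_px,
            fps=config.fps,
            direction=1 if i % 2 == 0 else -1,
        )
        if fail and i > 0:
            trials.append(
                MotorTrial(target=traj.samples.copy(), touch=np.empty((0, 4)))
            )
            continue
        touch = _sim_motor_touch(rng, traj, rmse_t, gx_t, gy_t, jerk_t, config)
        trials.append(MotorTrial(target=traj.samples.copy(), touch=touch))
    return trials


def _sim_bubble(
    rng: Generator, profile: GroupProfile, config: SimulationConfig, fail: bool
) -> list[BubbleTouch]:
    del fail  # every child who produced data popped at least one bubble
    n_bubbles = config.n_bubble_trials * (config.n_bubble_trials + 1) // 2
    n_eff = max(2.0, n_bubbles * config.bubble_pop_p)

    fm, fsd = profile.targets["pop_force"]
    f_var = _deflated_var(fm, fsd, config.pressure_within_sd**2 / n_eff)
    mu_p = rng.normal(fm, math.sqrt(f_var))

    # mean |N(0,s)| over n pops has mean s*sqrt(2/pi) and relative sampling
    # variance c; deflate the latent spread so the extracted feature's SD
    # matches the target
    half_norm = math.sqrt(2.0 / math.pi)
    c = (1.0 - 2.0 / math.pi) / (n_eff * (2.0 / math.pi))

    def _axis_scale(slot: str) -> float:
        m, sd = profile.targets[slot]
        var_lat = max((sd**2 - m**2 * c) / (1.0 + c), 1e-8)
        k, th = _gamma_params(m, math.sqrt(var_lat))
        return float(rng.gamma(k, th)) / half_norm

    sx = _axis_scale("pop_dist_x")
    sy = _axis_scale("pop_dist_y")

    w, h = config.screen_px
    out = []
    for _ in range(n_bubbles):
        cx = rng.uniform(200, w - 200)
        cy = rng.uniform(300, h - 300)
        popped = bool(rng.random() < config.bubble_pop_p)
        dx = rng.normal(0.0, sx)
        dy = rng.normal(0.0, sy)
        pressure = float(np.clip(rng.normal(mu_p, config.pressure_within_sd), 0.0, 1.0))
        out.append(
            BubbleTouch(
                bubble_center=(cx, cy),
                touch_point=(cx + dx, cy + dy),
                pressure=pressure,
                popped=popped,
            )
        )
    if not any(b.popped for b in out):
        b0 = out[0]
        out[0] = BubbleTouch(b0.bubble_center, b0.touch_point, b0.pressure, True)
    return out


# colouring figure: a chamfered-rectangle outline centred on screen
def _colouring_polygon(screen_px: tuple[int, int]) -> np.ndarray:
    cx, cy = screen_px[0] / 2.0, screen_px[1] / 2.0
    hw, hh, ch = 750.0, 500.0, 200.0
    return np.array(
        [
            (cx - hw + ch, cy - hh),
            (cx + hw - ch, cy - hh),
            (cx + hw, cy - hh + ch),
            (cx + hw, cy + hh - ch),
            (cx + hw - ch, cy + hh),
            (cx - hw + ch, cy + hh),
            (cx - hw, cy + hh - ch),
            (cx - hw, cy - hh + ch),
        ]
    )


def _serpentine(
    rng: Generator,
    rows: np.ndarray,
    x_lo: float,
    x_hi: float,
    t0: int,
    step_px: float = 25.0,
    step_ms: int = 50,
    jitter: float = 5.0,
) -> tuple[np.ndarray, int]:
    pts = []
    for i, y in enumerate(rows):
        xs = np.arange(x_lo, x_hi + 1, step_px)
        if i % 2 == 1:
            xs = xs[::-1]
        for x in xs:
            pts.append((x, y))
        if i + 1 < rows.size:
            x_edge = xs[-1]
            for yv in np.arange(y + step_px, rows[i + 1], step_px):
                pts.append((x_edge, yv))
    pts = np.asarray(pts, dtype=float)
    pts += rng.uniform(-jitter, jitter, pts.shape)
    t = t0 + step_ms * np.arange(pts.shape[0])
    stroke = np.column_stack([t, pts[:, 0], pts[:, 1], np.full(pts.shape[0], 0.5)])
    return stroke, int(t[-1] + step_ms)


def _sim_colouring(
    rng: Generator, profile: GroupProfile, config: SimulationConfig, fail: bool
) -> list[ColouringSession]:
    m, sd = profile.targets["colour_crossings"]
    k, th = _gamma_params(m, sd)
    crossings = int(round(rng.gamma(k, th)))

    w, h = config.screen_px
    cx, cy = w / 2.0, h / 2.0
    outline = _colouring_polygon(config.screen_px)
    half_w, half_h = 640.0, 390.0

    if fail:
        rows = np.array([cy - 50.0, cy + 50.0])
    else:
        rows = np.linspace(cy - half_h, cy + half_h, 9)
    n_rows_first = max(1, rows.size // 2)

    sessions = []
    t0 = 0
    stroke1, t0 = _serpentine(rng, rows[:n_rows_first], cx - half_w, cx + half_w, t0)
    stroke2, t0 = _serpentine(rng, rows[n_rows_first:], cx - half_w, cx + half_w, t0)

    if not fail and crossings > 0:
        # weaving tail on the right edge: alternate inside/outside samples;
        # every consecutive in/out flip is one crossing
        y_site = cy
        x_in, x_out = cx + 720.0, cx + 790.0
        tail = [(cx + half_w + 30.0, y_site)]  # connector, inside
        pt_outside = True
        for _ in range(crossings):
            tail.append(((x_out if pt_outside else x_in), y_site))
            pt_outside = not pt_outside
        tail = np.asarray(tail, dtype=float)
        t = t0 + 50 * np.arange(tail.shape[0])
        t0 = int(t[-1] + 50)
        tail_stroke = np.column_stack(
            [t, tail[:, 0], tail[:, 1], np.full(tail.shape[0], 0.5)]
        )
        strokes2 = [stroke2, tail_stroke]
    else:
        strokes2 = [stroke2]

    sessions.append(
        ColouringSession(
            figure_outline=outline.copy(),
            screen_px=config.screen_px,
            strokes=[stroke1],
            brush_radius_px=config.brush_radius_px,
        )
    )
    sessions.append(
        ColouringSession(
            figure_outline=outline.copy(),
            screen_px=config.screen_px,
            strokes=strokes2,
            brush_radius_px=config.brush_radius_px,
        )
    )
    return sessions


def _sim_pci(
    rng: Generator, profile: GroupProfile, config: SimulationConfig, fail: bool
) -> list[PCICoding]:
    del fail
    multi = rng.random() < config.multi_coder_frac
    vals = {}
    for slot, noise in (
        ("pci_child_init", config.coder_noise_init),
        ("pci_caregiver_sync", config.coder_noise_sync),
    ):
        m, sd = profile.targets[slot]
        extra = config.multi_coder_frac * (2.0 / 3.0) * noise**2
        vals[slot] = _beta_draw(rng, m, _deflated_var(m, sd, extra))
    opportunities = int(rng.integers(10, 31))
    codings = [
        PCICoding(
            coder_id="coder_1",
            child_initiation_prop=vals["pci_child_init"],
            caregiver_sync_prop=vals["pci_caregiver_sync"],
            child_opportunities=opportunities,
            caregiver_opportunities=opportunities,
        )
    ]
    if multi:
        for ci in range(2, config.n_coders + 1):
            codings.append(
                PCICoding(
                    coder_id=f"coder_{ci}",
                    child_initiation_prop=float(
                        np.clip(
                            vals["pci_child_init"]
                            + rng.normal(0.0, config.coder_noise_init),
                            0.0,
                            1.0,
                        )
                    ),
                    caregiver_sync_prop=float(
                        np.clip(
                            vals["pci_caregiver_sync"]
                            + rng.normal(0.0, config.coder_noise_sync),
                            0.0,
                            1.0,
                        )
                    ),
                    child_opportunities=opportunities,
                    caregiver_opportunities=opportunities,
                )
            )
    return codings


def _sim_questionnaire(
    rng: Generator, profile: GroupProfile, config: SimulationConfig
) -> QuestionnaireResponse:
    del config
    m, sd = profile.targets["questionnaire_score"]
    mu = m / 14.0
    base_var = 14.0 * mu * (1.0 - mu)
    rho = max((sd**2 / base_var - 1.0) / 13.0, 1e-6)
    p_child = _beta_draw(rng, mu, rho * mu * (1.0 - mu))
    endorsed = rng.random(14) < p_child  # 1 = red-flag answer
    items = [
        bool(not e) if i in REVERSE_ITEMS else bool(e) for i, e in enumerate(endorsed)
    ]
    return QuestionnaireResponse(items=items, reverse_coded=REVERSE_ITEMS)


# ---------------------------------------------------------------------------
# child / cohort assembly

_TASK_SIMS = {
    "preferential": _sim_preferential,
    "button": _sim_button,
    "wheel": _sim_wheel,
    "motor": _sim_motor,
    "bubble": _sim_bubble,
    "colouring": _sim_colouring,
    "pci": _sim_pci,
}


def simulate_child(
    group: Group,
    profiles: dict[Group, GroupProfile],
    config: SimulationConfig,
    seed: Union[int, SeedSequence],
    child_id: Optional[str] = None,
) -> ChildRecord:
    """Generate one child's full eight-task raw record (before attrition).

    The seed is split deterministically per task, so regenerating with an
    extra task leaves the other streams untouched.
    """
    ss = seed if isinstance(seed, SeedSequence) else SeedSequence(seed)
    streams = ss.spawn(len(TASK_NAMES) + 1)
    admin = default_rng(streams[0])
    profile = profiles[group]

    age = admin.uniform(*config.age_range)
    sex = "F" if admin.random() < config.female_p[_GROUP_IDX[group]] else "M"
    fail_flags = {
        task: bool(admin.random() < profile.filter_fail.get(task, 0.0))
        for task in TASK_NAMES
    }

    tasks: dict = {}
    for ti, task in enumerate(TASK_NAMES):
        rng = default_rng(streams[ti + 1])
        if task == "questionnaire":
            tasks[task] = _sim_questionnaire(rng, profile, config)
        else:
            tasks[task] = _TASK_SIMS[task](rng, profile, config, fail_flags[task])

    return ChildRecord(
        child_id=child_id or f"{group.value}-{ss.entropy}",
        group=group,
        age_years=float(age),
        sex=sex,
        tasks=tasks,
    )


def apply_attrition(
    cohort: Sequence[ChildRecord],
    profiles: dict[Group, GroupProfile],
    seed: Union[int, SeedSequence],
) -> list[ChildRecord]:
    """Remove whole task sub-records per child with the group dropout rates.

    Pure removal: surviving sub-records are the identical objects.
    """
    rng = default_rng(seed)
    out = []
    for rec in cohort:
        dropout = profiles[rec.group].dropout
        tasks = {
            name: sub
            for name, sub in rec.tasks.items()
            if not (rng.random() < dropout.get(name, 0.0))
        }
        out.append(
            ChildRecord(
                child_id=rec.child_id,
                group=rec.group,
                age_years=rec.age_years,
                sex=rec.sex,
                tasks=tasks,
            )
        )
    return out


def simulate_cohort(
    config: SimulationConfig,
    profiles: Optional[dict[Group, GroupProfile]] = None,
) -> list[ChildRecord]:
    """Simulate the full three-group cohort (with attrition applied)."""
    profiles = profiles or default_profiles()
    master = SeedSequence(config.seed)
    n_total = sum(config.n_per_group)
    child_seeds = master.spawn(n_total + 1)
    attr_seed = child_seeds[-1]

    cohort = []
    idx = 0
    for g, n in zip((Group.TD, Group.AS, Group.ID), config.n_per_group):
        for j in range(n):
            cohort.append(
                simulate_child(
                    g,
                    profiles,
                    config,
                    child_seeds[idx],
                    child_id=f"{g.value}-{j + 1:03d}",
                )
            )
            idx += 1
    return apply_attrition(cohort, profiles, attr_seed)
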