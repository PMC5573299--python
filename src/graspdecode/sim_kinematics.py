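"""Synthetic reach-to-grasp trials with known kinematic ground truth.

The generator emulates a 140 Hz three-marker (wrist, thumb, index) recording
of a 30 cm reach-to-grasp movement performed under two intention conditions
(``social`` / ``individual``). Each trial is built from a set of *target
landmarks* — movement time, time/amplitude of the velocity peak, time of the
acceleration peak, amplitudes of the acceleration and deceleration peaks —
so condition effects, subject offsets and trial jitter can be injected
directly on the quantities the extraction pipeline measures.

The wrist speed profile is synthesised from two beta-shaped acceleration
lobes (a positive lobe peaking at the target acceleration peak, a negative
lobe for the deceleration phase). Lobe sharpness is solved numerically so the
integrated profile hits the target peak speed exactly, the areas match (the
speed returns to zero at movement end), and the extrema equal the configured
amplitudes. A symmetric minimum-jerk reach is the special case used for the
default individual-condition baseline: peak speed ``1.875 * D / MT`` at
``MT/2``, peak acceleration ``10 * D / (sqrt(3) * MT^2)`` at
``MT * (1/2 - 1/(2*sqrt(3)))``.

Grip aperture opens from a small initial value to its maximum (default 80 mm
at 60% of movement time) and closes onto the object (contact aperture
25 mm for the 20 mm sphere) along minimum-jerk segments, so the aperture
velocity has a single closing minimum and re-crosses the -5 mm/s detection
threshold within about one sample of the nominal contact time. (A faster
closing geometry would leave post-contact filter ripple of the same order as
the detection threshold, making the detected end unstable; the default keeps
that ripple below ~3 mm/s.)

With ``calibrate=True`` (the default) the profile is iteratively shifted —
first analytically, then against the actual filtered detection chain — so
the *detected* landmarks (which lag the physical movement start by the small
time the speed needs to climb through the 5 mm/s threshold) equal the
configured targets to within one sample period.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterator

import numpy as np
from scipy import integrate, optimize, special

from .errors import InvalidConfigError
from .kinematics import MarkerTrajectory

__all__ = [
    "KinSimConfig",
    "LandmarkTargets",
    "SpeedProfile",
    "minimum_jerk_landmarks",
    "simulate_reach_trial",
    "simulate_kinematics_dataset",
]

CONDITIONS = ("social", "individual")

#: landmarks that carry configurable condition effects (Table-1 style)
EFFECT_KEYS = ("mov_t", "t_peak_v", "amp_peak_v", "t_peak_a", "amp_peak_a", "amp_peak_d")

_SQRT3 = math.sqrt(3.0)


def minimum_jerk_landmarks(distance_mm: float, mov_t_ms: float) -> dict:
    """Closed-form landmark values of a symmetric minimum-jerk reach.

    ``v(t) = 30 D / T * tau^2 (1 - tau)^2`` with ``tau = t/T``: peak speed
    ``1.875 D/T`` at ``T/2``, acceleration extrema ``+-10 D/(sqrt(3) T^2)``
    at ``T (1/2 -+ 1/(2 sqrt(3)))``.
    """
    T = mov_t_ms / 1000.0
    return {
        "mov_t": mov_t_ms,
        "t_peak_v": mov_t_ms / 2.0,
        "amp_peak_v": 1.875 * distance_mm / T,
        "t_peak_a": mov_t_ms * (0.5 - 1.0 / (2.0 * _SQRT3)),
        "amp_peak_a": 10.0 * distance_mm / (_SQRT3 * T * T),
        "amp_peak_d": -10.0 * distance_mm / (_SQRT3 * T * T),
    }


@dataclass(frozen=True)
class LandmarkTargets:
    """Target landmark values (ms / mm/s / mm/s^2) for one trial."""

    mov_t: float
    t_peak_v: float
    amp_peak_v: float
    t_peak_a: float
    amp_peak_a: float
    amp_peak_d: float

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in EFFECT_KEYS}


def _bump_sharpness(m: float, c_target: float) -> float:
    """Solve the beta-bump sharpness ``s`` with peak position ``m`` such that
    area / (height * width) equals ``c_target``.

    The bump is ``g(u) = u^(m s) (1-u)^((1-m) s)`` on [0, 1]; its
    area/height ratio decreases monotonically from 1 (s -> 0) towards 0.
    """
    if not 0.0 < m < 1.0:
        raise InvalidConfigError(f"bump peak position {m:.3f} outside (0, 1)")
    if not 0.0 < c_target < 1.0:
        raise InvalidConfigError(
            f"infeasible landmark combination: area/height ratio {c_target:.3f} "
            "must lie in (0, 1)"
        )
    ent = m * math.log(m) + (1.0 - m) * math.log(1.0 - m)

    def log_ratio(s: float) -> float:
        return special.betaln(m * s + 1.0, (1.0 - m) * s + 1.0) - s * ent

    target = math.log(c_target)
    lo, hi = 1e-9, 8.0
    while log_ratio(hi) > target:
        hi *= 2.0
        if hi > 1e6:
            raise InvalidConfigError(
                f"landmark combination too peaked to realise (c={c_target:.4f})"
            )
    return float(optimize.brentq(lambda s: log_ratio(s) - target, lo, hi, xtol=1e-12))


@dataclass(frozen=True)
class SpeedProfile:
    """Analytic wrist-speed profile realising a set of landmark targets.

    Piecewise: ``v(t) = A_v * I(t/t_v; p1+1, q1+1)`` on the acceleration
    phase and ``A_v * (1 - I((t-t_v)/(T-t_v); p2+1, q2+1))`` on the
    deceleration phase, where ``I`` is the regularised incomplete beta
    function — i.e. the acceleration is a pair of scaled beta bumps.
    """

    T: float          # movement duration, s
    t_v: float        # time of peak speed, s
    amp_v: float      # peak speed, mm/s
    amp_a: float      # acceleration peak, mm/s^2
    amp_d: float      # deceleration peak (negative), mm/s^2
    p1: float
    q1: float
    p2: float
    q2: float

    @classmethod
    def from_landmarks(
        cls, lm: LandmarkTargets, decel_peak_frac: float = 1.0 / _SQRT3
    ) -> "SpeedProfile":
        T = lm.mov_t / 1000.0
        t_v = lm.t_peak_v / 1000.0
        t_a = lm.t_peak_a / 1000.0
        if not (T > 0 and 0 < t_a < t_v < T):
            raise InvalidConfigError(
                f"need 0 < t_peak_a < t_peak_v < mov_t, got "
                f"({lm.t_peak_a:.1f}, {lm.t_peak_v:.1f}, {lm.mov_t:.1f}) ms"
            )
        if not (lm.amp_peak_v > 0 and lm.amp_peak_a > 0 and lm.amp_peak_d < 0):
            raise InvalidConfigError(
                "need amp_peak_v > 0, amp_peak_a > 0, amp_peak_d < 0"
            )
        m1 = t_a / t_v
        c1 = lm.amp_peak_v / (lm.amp_peak_a * t_v)
        s1 = _bump_sharpness(m1, c1)
        m2 = decel_peak_frac
        c2 = lm.amp_peak_v / (abs(lm.amp_peak_d) * (T - t_v))
        s2 = _bump_sharpness(m2, c2)
        return cls(
            T=T, t_v=t_v, amp_v=lm.amp_peak_v, amp_a=lm.amp_peak_a,
            amp_d=lm.amp_peak_d,
            p1=m1 * s1, q1=(1.0 - m1) * s1, p2=m2 * s2, q2=(1.0 - m2) * s2,
        )

    def speed(self, t: np.ndarray) -> np.ndarray:
        """Tangential speed (mm/s) at times ``t`` seconds from movement start."""
        t = np.asarray(t, dtype=float)
        v = np.zeros_like(t)
        acc = (t >= 0) & (t <= self.t_v)
        dec = (t > self.t_v) & (t <= self.T)
        u = np.clip(t[acc] / self.t_v, 0.0, 1.0)
        v[acc] = self.amp_v * special.betainc(self.p1 + 1.0, self.q1 + 1.0, u)
        w = np.clip((t[dec] - self.t_v) / (self.T - self.t_v), 0.0, 1.0)
        v[dec] = self.amp_v * (1.0 - special.betainc(self.p2 + 1.0, self.q2 + 1.0, w))
        return v

    def threshold_crossings(self, threshold: float) -> tuple[float, float]:
        """Times at which the speed first exceeds / finally falls below
        ``threshold`` mm/s (closed form via the inverse incomplete beta)."""
        frac = threshold / self.amp_v
        if not 0.0 < frac < 1.0:
            raise ValueError("threshold outside the profile's speed range")
        u = special.betaincinv(self.p1 + 1.0, self.q1 + 1.0, frac)
        w = special.betaincinv(self.p2 + 1.0, self.q2 + 1.0, 1.0 - frac)
        return float(self.t_v * u), float(self.t_v + (self.T - self.t_v) * w)

    @property
    def distance(self) -> float:
        """Reach distance implied by the profile (mm)."""
        return float(integrate.quad(lambda x: float(self.speed(x)), 0.0, self.T,
                                    limit=200)[0])


def _aperture_series(
    t: np.ndarray, t0: float, T: float, peak_frac: float,
    a0: float, a_max: float, a_contact: float,
) -> np.ndarray:
    """Grip aperture (mm): quartic opening and closing segments.

    Both segments have zero velocity at the maximum but nonzero curvature
    (a genuine quadratic cap, so the detected aperture peak is stable under
    noise), and the closing segment meets the post-contact hold with zero
    velocity *and* acceleration, keeping filter ringing around the contact
    threshold negligible.
    """
    t_peak = t0 + peak_frac * T
    To, Tc = peak_frac * T, (1.0 - peak_frac) * T
    ap = np.full_like(t, a0, dtype=float)
    opening = (t >= t0) & (t < t_peak)
    closing = (t >= t_peak) & (t <= t0 + T)
    after = t > t0 + T
    u = (t[opening] - t0) / To
    ap[opening] = a0 + (a_max - a0) * u**3 * (4.0 - 3.0 * u)
    u = (t[closing] - t_peak) / Tc
    ap[closing] = a_contact + (a_max - a_contact) * (1.0 - u) ** 3 * (1.0 + 3.0 * u)
    ap[after] = a_contact
    return ap


def _aperture_end_lag(T: float, peak_frac: float, a_max: float, a_contact: float,
                      threshold: float) -> float:
    """Lag between nominal contact (t0+T) and the -|threshold| re-crossing of
    the closing aperture velocity (seconds, positive = earlier)."""
    Tc = (1.0 - peak_frac) * T
    dA = a_max - a_contact
    # closing speed magnitude: 12*dA/Tc * u (1-u)^2, peaked at u = 1/3
    def f(u: float) -> float:
        return 12.0 * dA / Tc * u * (1.0 - u) ** 2 - abs(threshold)
    if f(1.0 / 3.0) < 0:  # closing too slow ever to cross the threshold
        return 0.0
    u = optimize.brentq(f, 1.0 / 3.0, 1.0, xtol=1e-12)
    return Tc * (1.0 - u)


# plausibility bands for randomly drawn profile shapes. c1 is the
# area/height ratio of the acceleration lobe (minimum jerk: ~0.65): small
# values mean the speed rises so late that the detected onset lags the
# movement by >100 ms, so it is held near the physiological range. c2 (the
# deceleration lobe) only needs to stay clear of numerical degeneracy. m1 is
# the acceleration-peak position within the rise phase (minimum jerk: ~0.42).
_C1_BAND = (0.40, 0.92)
_C2_BAND = (0.22, 0.95)
_M1_BAND = (0.20, 0.70)


def _plausible_shape(lm: "LandmarkTargets", decel_peak_frac: float) -> bool:
    T = lm.mov_t / 1000.0
    t_v = lm.t_peak_v / 1000.0
    c1 = lm.amp_peak_v / (lm.amp_peak_a * t_v)
    c2 = lm.amp_peak_v / (abs(lm.amp_peak_d) * (T - t_v))
    m1 = lm.t_peak_a / lm.t_peak_v
    return (
        _C1_BAND[0] <= c1 <= _C1_BAND[1]
        and _C2_BAND[0] <= c2 <= _C2_BAND[1]
        and _M1_BAND[0] <= m1 <= _M1_BAND[1]
    )


@dataclass
class KinSimConfig:
    """Configuration of the kinematic simulator.

    Defaults reproduce the study conditions: 23 subjects, 12 trials per
    condition, 140 Hz sampling, a 300 mm reach, and social-minus-individual
    condition effects on the six tabulated landmarks (ms, mm/s, mm/s^2).

    Variability has three layers: ``between_subject_sd`` shifts a subject's
    baseline landmarks in both conditions (cancels in paired differences),
    ``effect_sd`` is subject-specific heterogeneity of the condition effect
    (applied to social trials only), and ``within_subject_sd`` is trial-level
    jitter. The effect/within defaults are set so the variance of the
    per-subject condition difference over 12-trial means,
    ``effect_sd^2 + 2 * within_sd^2 / 12``, matches the published
    standard-error-of-difference scale; between-subject SDs are plausible
    free choices.
    """

    n_subjects: int = 23
    trials_per_condition: int = 12
    sampling_rate: float = 140.0
    reach_distance: float = 300.0
    base_movement_time_individual: float = 700.0  # ms
    effects: dict = field(default_factory=lambda: {
        "mov_t": 84.13,
        "t_peak_v": 90.30,
        "amp_peak_v": -172.45,
        "t_peak_a": 77.00,
        "amp_peak_a": -1429.30,
        "amp_peak_d": -1054.74,
    })
    between_subject_sd: dict = field(default_factory=lambda: {
        "mov_t": 80.0, "t_peak_v": 60.0, "amp_peak_v": 120.0,
        "t_peak_a": 40.0, "amp_peak_a": 600.0, "amp_peak_d": 600.0,
    })
    within_subject_sd: dict = field(default_factory=lambda: {
        "mov_t": 30.0, "t_peak_v": 40.0, "amp_peak_v": 80.0,
        "t_peak_a": 35.0, "amp_peak_a": 350.0, "amp_peak_d": 350.0,
    })
    effect_sd: dict = field(default_factory=lambda: {
        "mov_t": 17.2, "t_peak_v": 34.7, "amp_peak_v": 71.1,
        "t_peak_a": 29.3, "amp_peak_a": 610.0, "amp_peak_d": 539.0,
    })
    marker_noise_sd: float = 0.05   # mm, per axis, after tracking
    pre_rest_ms: float = 1600.0
    post_rest_ms: float = 1200.0
    aperture_start: float = 10.0    # mm, fingers opposed
    aperture_max: float = 80.0      # mm
    aperture_contact: float = 25.0  # mm, on the 20 mm sphere
    aperture_peak_frac: float = 0.60
    decel_peak_frac: float = 1.0 / _SQRT3
    onset_threshold: float = 5.0    # mm/s, used only for calibration
    end_threshold: float = -5.0
    calibrate: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sampling_rate <= 0:
            raise InvalidConfigError("sampling_rate must be > 0")
        if self.trials_per_condition < 1:
            raise InvalidConfigError("trials_per_condition must be >= 1")
        if self.base_movement_time_individual <= 0:
            raise InvalidConfigError("base_movement_time_individual must be > 0")
        for name in ("between_subject_sd", "within_subject_sd", "effect_sd"):
            if any(v < 0 for v in getattr(self, name).values()):
                raise InvalidConfigError(f"{name} entries must be >= 0")
        if self.marker_noise_sd < 0:
            raise InvalidConfigError("marker_noise_sd must be >= 0")

    def base_landmarks(self) -> dict:
        """Individual-condition baseline: a minimum-jerk reach of the
        configured distance and movement time."""
        return minimum_jerk_landmarks(
            self.reach_distance, self.base_movement_time_individual
        )

    def targets_for(self, condition: str, offsets: dict | None = None) -> LandmarkTargets:
        """Landmark targets for one trial: baseline + condition effect
        (+ optional per-subject / per-trial offsets)."""
        if condition not in CONDITIONS:
            raise InvalidConfigError(f"condition must be one of {CONDITIONS}")
        values = self.base_landmarks()
        if condition == "social":
            for k in EFFECT_KEYS:
                values[k] += self.effects.get(k, 0.0)
        for k, v in (offsets or {}).items():
            values[k] += v
        if values["mov_t"] <= 0:
            raise InvalidConfigError(
                f"movement time {values['mov_t']:.1f} ms <= 0 after effects"
            )
        return LandmarkTargets(**{k: values[k] for k in EFFECT_KEYS})


def _calibrated_profile(
    targets: LandmarkTargets, cfg: KinSimConfig
) -> tuple[SpeedProfile, float]:
    """Build the speed profile; if ``cfg.calibrate``, shift the targets so
    the thresholded, dwell-gated detection recovers them.

    Returns ``(profile, t_on)`` where ``t_on`` is the onset-threshold
    crossing time within the profile (the detected onset lag).
    """
    lm = targets
    profile = SpeedProfile.from_landmarks(lm, cfg.decel_peak_frac)
    if not cfg.calibrate:
        t_on, _ = profile.threshold_crossings(cfg.onset_threshold)
        return profile, t_on
    end_lag = _aperture_end_lag(
        profile.T, cfg.aperture_peak_frac, cfg.aperture_max,
        cfg.aperture_contact, cfg.end_threshold,
    )
    t_on = 0.0
    for _ in range(4):  # fixed-point: corrections are ~10-20 ms and smooth
        t_on, _ = profile.threshold_crossings(cfg.onset_threshold)
        shifted = replace(
            lm,
            mov_t=lm.mov_t + (t_on + end_lag) * 1000.0,
            t_peak_v=lm.t_peak_v + t_on * 1000.0,
            t_peak_a=lm.t_peak_a + t_on * 1000.0,
        )
        profile = SpeedProfile.from_landmarks(shifted, cfg.decel_peak_frac)
        end_lag = _aperture_end_lag(
            profile.T, cfg.aperture_peak_frac, cfg.aperture_max,
            cfg.aperture_contact, cfg.end_threshold,
        )
    t_on, _ = profile.threshold_crossings(cfg.onset_threshold)
    return profile, t_on


_FINGER_OFFSET = np.array([25.0, 35.0, 0.0])  # hand geometry relative to wrist, mm


def _assemble_trial(
    cfg: KinSimConfig, profile: SpeedProfile, t_on: float
) -> MarkerTrajectory:
    """Lay out the noiseless trajectory for a given speed profile."""
    fs = cfg.sampling_rate
    n_pre = int(round(cfg.pre_rest_ms / 1000.0 * fs))
    n_move = int(math.ceil(profile.T * fs))
    n_post = int(round(cfg.post_rest_ms / 1000.0 * fs))
    n = n_pre + n_move + n_post
    time = np.arange(n) / fs
    t0 = n_pre / fs  # movement start, on the sample grid

    v = profile.speed(time - t0)
    displacement = integrate.cumulative_trapezoid(v, time, initial=0.0)
    direction = np.array([0.0, 1.0, 0.0])  # midsagittal reach
    wrist = np.array([0.0, 0.0, 50.0]) + displacement[:, None] * direction

    aperture = _aperture_series(
        time, t0, profile.T, cfg.aperture_peak_frac,
        cfg.aperture_start, cfg.aperture_max, cfg.aperture_contact,
    )
    half = np.column_stack([np.zeros(n), np.zeros(n), aperture / 2.0])
    thumb = wrist + _FINGER_OFFSET + half
    index = wrist + _FINGER_OFFSET - half

    meta = {
        "movement_start_s": t0,
        "detected_onset_nominal_s": t0 + t_on,
        "t_max_grip_apert_nominal_ms": (cfg.aperture_peak_frac * profile.T - t_on) * 1000.0,
    }
    return MarkerTrajectory(time=time, wrist=wrist, thumb=thumb, index=index, meta=meta)


def _trim_against_detection(
    targets: LandmarkTargets, cfg: KinSimConfig, max_iter: int = 4
) -> MarkerTrajectory:
    """Build the noiseless trial, nudging the time landmarks until the full
    filtered detection chain reproduces the targets to sub-sample accuracy.

    The analytic calibration accounts for the threshold-crossing lags of the
    continuous profile; the residual (filter smoothing, sample quantisation,
    post-contact ripple) is measured by actually running the extraction and
    subtracted. Detection failure on a candidate profile is reported as an
    invalid landmark combination so jittered draws can be retried.
    """
    from .kinematics import KinDetectConfig, extract_parameters

    det_cfg = KinDetectConfig(
        onset_threshold=cfg.onset_threshold, end_threshold=cfg.end_threshold
    )
    # half a sample (plus slack): detected landmarks are grid-quantised, so
    # the best achievable per-landmark error is +-0.5 samples
    tol_ms = 0.55 / cfg.sampling_rate * 1000.0
    shifted = targets
    profile, t_on = _calibrated_profile(shifted, cfg)
    trial = _assemble_trial(cfg, profile, t_on)
    for _ in range(max_iter):
        try:
            measured = extract_parameters(trial, det_cfg)
        except Exception as err:  # detection failed on this landmark set
            raise InvalidConfigError(
                f"landmark set not detectable by the extraction chain: {err}"
            ) from err
        errs = {
            k: getattr(measured, k) - getattr(targets, k)
            for k in ("mov_t", "t_peak_v", "t_peak_a")
        }
        if all(abs(e) <= tol_ms for e in errs.values()):
            break
        shifted = replace(
            shifted,
            mov_t=shifted.mov_t - errs["mov_t"],
            t_peak_v=shifted.t_peak_v - errs["t_peak_v"],
            t_peak_a=shifted.t_peak_a - errs["t_peak_a"],
        )
        profile, t_on = _calibrated_profile(shifted, cfg)
        trial = _assemble_trial(cfg, profile, t_on)
    else:
        try:
            measured = extract_parameters(trial, det_cfg)
        except Exception as err:
            raise InvalidConfigError(
                f"landmark set not detectable by the extraction chain: {err}"
            ) from err
        errs = {
            k: getattr(measured, k) - getattr(targets, k)
            for k in ("mov_t", "t_peak_v", "t_peak_a")
        }
        if any(abs(e) > 2.0 * 1000.0 / cfg.sampling_rate for e in errs.values()):
            raise InvalidConfigError(
                f"calibration did not converge for landmark set {targets}; "
                f"residuals {errs}"
            )
    return trial


def simulate_reach_trial(
    cfg: KinSimConfig,
    condition: str,
    rng: np.random.Generator,
    targets: LandmarkTargets | None = None,
) -> MarkerTrajectory:
    """Simulate one reach-to-grasp trial.

    The wrist travels along a straight sagittal path with the landmark-derived
    speed profile, flanked by rest periods; thumb and index straddle the wrist
    path so their distance equals the aperture schedule. Gaussian marker noise
    (``marker_noise_sd``) is added to every coordinate. Ground-truth targets
    are stored in ``meta["targets"]``.
    """
    if targets is None:
        targets = cfg.targets_for(condition)
    if cfg.calibrate:
        trial = _trim_against_detection(targets, cfg)
    else:
        profile, t_on = _calibrated_profile(targets, cfg)
        trial = _assemble_trial(cfg, profile, t_on)

    if cfg.marker_noise_sd > 0:
        trial.wrist += rng.normal(0.0, cfg.marker_noise_sd, trial.wrist.shape)
        trial.thumb += rng.normal(0.0, cfg.marker_noise_sd, trial.thumb.shape)
        trial.index += rng.normal(0.0, cfg.marker_noise_sd, trial.index.shape)
    trial.meta.update(condition=condition, targets=targets.as_dict())
    return trial


def _draw_targets(
    cfg: KinSimConfig, condition: str, subject_offsets: dict,
    rng: np.random.Generator, max_tries: int = 200,
) -> LandmarkTargets:
    """Draw per-trial jittered targets, redrawing until the landmark set is
    geometrically realisable (ordered times, feasible lobe shapes)."""
    for _ in range(max_tries):
        jitter = {
            k: rng.normal(0.0, cfg.within_subject_sd.get(k, 0.0))
            for k in EFFECT_KEYS
        }
        offsets = {k: subject_offsets.get(k, 0.0) + jitter[k] for k in EFFECT_KEYS}
        try:
            targets = cfg.targets_for(condition, offsets)
            SpeedProfile.from_landmarks(targets, cfg.decel_peak_frac)
        except InvalidConfigError:
            continue
        if not _plausible_shape(targets, cfg.decel_peak_frac):
            continue
        return targets
    raise InvalidConfigError(
        "could not draw a realisable landmark set; SDs too large relative to "
        "the baseline landmarks"
    )


def _draw_subject_offsets(
    cfg: KinSimConfig, rng: np.random.Generator, max_tries: int = 100
) -> tuple[dict, dict]:
    """Draw a subject's baseline offsets (both conditions) and condition-effect
    heterogeneity (social only), redrawing until the subject's jitter-free
    landmark sets are realisable in both conditions."""
    for _ in range(max_tries):
        base = {
            k: rng.normal(0.0, cfg.between_subject_sd.get(k, 0.0))
            for k in EFFECT_KEYS
        }
        effect = {
            k: rng.normal(0.0, cfg.effect_sd.get(k, 0.0)) for k in EFFECT_KEYS
        }
        try:
            ok = True
            for condition in CONDITIONS:
                offsets = dict(base)
                if condition == "social":
                    offsets = {k: base[k] + effect[k] for k in EFFECT_KEYS}
                targets = cfg.targets_for(condition, offsets)
                SpeedProfile.from_landmarks(targets, cfg.decel_peak_frac)
                ok = ok and _plausible_shape(targets, cfg.decel_peak_frac)
        except InvalidConfigError:
            continue
        if ok:
            return base, effect
    raise InvalidConfigError(
        "could not draw realisable subject offsets; between/effect SDs too "
        "large relative to the baseline landmarks"
    )


def simulate_kinematics_dataset(cfg: KinSimConfig) -> list[MarkerTrajectory]:
    """Simulate the full design: ``n_subjects x 2 conditions x
    trials_per_condition`` trials.

    Subject-level landmark offsets (``between_subject_sd``) are shared across
    all of a subject's trials; subject-specific effect heterogeneity
    (``effect_sd``) shifts the social condition only; per-trial jitter uses
    ``within_subject_sd``. Deterministic given ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    trials: list[MarkerTrajectory] = []
    for subject in range(1, cfg.n_subjects + 1):
        base_offsets, effect_offsets = _draw_subject_offsets(cfg, rng)
        for condition in CONDITIONS:
            subject_offsets = dict(base_offsets)
            if condition == "social":
                for k in EFFECT_KEYS:
                    subject_offsets[k] += effect_offsets[k]
            for trial in range(1, cfg.trials_per_condition + 1):
                for _ in range(50):
                    targets = _draw_targets(cfg, condition, subject_offsets, rng)
                    try:
                        traj = simulate_reach_trial(cfg, condition, rng, targets=targets)
                        break
                    except InvalidConfigError:
                        continue
                else:
                    raise InvalidConfigError(
                        "no detectable trial could be drawn; check SDs/landmarks"
                    )
                traj.meta.update(subject=subject, trial=trial)
                trials.append(traj)
    return trials


def iter_by_subject(trials: list[MarkerTrajectory]) -> Iterator[tuple[int, list]]:
    """Group a trial list by subject id (in first-seen order)."""
    seen: dict = {}
    for traj in trials:
        seen.setdefault(traj.meta["subject"], []).append(traj)
    yield from seen.items()
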