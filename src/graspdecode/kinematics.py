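"""Reach-to-grasp kinematics: filtering, landmark detection, parameter extraction.

The processing chain mirrors standard optoelectronic motion-capture practice:
marker trajectories (wrist, thumb, index at 140 Hz) are low-pass filtered with
a zero-phase FIR filter, the wrist tangential velocity and the thumb-index
grip aperture are derived, movement onset/end are detected with velocity
thresholds plus a dwell rule, and eight per-trial parameters are extracted:

========================  =====================================================
Mov_T                     movement time (onset to object contact), ms
T_peak_V / Amp_peak_V     time / amplitude of the wrist tangential-velocity peak
T_peak_A / Amp_peak_A     time / amplitude of the wrist acceleration peak
T_peak_D / Amp_peak_D     time / amplitude of the wrist deceleration peak (< 0)
T_max_grip_apert          time of the maximum thumb-index aperture
========================  =====================================================

All times except the absolute onset/end are reported relative to movement
onset. Acceleration is the derivative of the scalar wrist speed (not the norm
of the 3-D acceleration vector), so the deceleration peak is a negative
number.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import signal

from .errors import EndNotFoundError, InvalidConfigError, OnsetNotFoundError

__all__ = [
    "MarkerTrajectory",
    "KinDetectConfig",
    "TrialKinematics",
    "PARAMETER_NAMES",
    "lowpass_filter",
    "tangential_velocity",
    "grip_aperture",
    "aperture_velocity",
    "detect_movement_onset",
    "detect_movement_end",
    "extract_parameters",
    "extract_table",
]

MARKERS = ("wrist", "thumb", "index")

#: the eight extracted parameters, in report order
PARAMETER_NAMES = (
    "mov_t",
    "t_peak_v",
    "amp_peak_v",
    "t_peak_a",
    "amp_peak_a",
    "t_peak_d",
    "amp_peak_d",
    "t_max_grip_apert",
)


@dataclass
class MarkerTrajectory:
    """Time-indexed 3-D positions of the three hand markers for one trial.

    Attributes
    ----------
    time : (n,) array, seconds, uniform grid
    wrist, thumb, index : (n, 3) arrays, millimetres
    meta : free-form trial metadata (subject, condition, trial index, ...)
    """

    time: np.ndarray
    wrist: np.ndarray
    thumb: np.ndarray
    index: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        for name in MARKERS:
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (self.time.size, 3):
                raise ValueError(
                    f"marker '{name}' has shape {arr.shape}, "
                    f"expected {(self.time.size, 3)}"
                )
            setattr(self, name, arr)
        dt = np.diff(self.time)
        if self.time.size < 2 or np.any(dt <= 0):
            raise ValueError("time grid must be strictly increasing")
        if np.any(np.abs(dt - dt.mean()) > 0.01 * dt.mean()):
            raise ValueError("time grid must be uniform (within 1%)")

    @property
    def fs(self) -> float:
        """Sampling rate in Hz."""
        return 1.0 / float(np.mean(np.diff(self.time)))

    def marker(self, name: str) -> np.ndarray:
        if name not in MARKERS:
            raise KeyError(f"unknown marker {name!r}; expected one of {MARKERS}")
        return getattr(self, name)


@dataclass(frozen=True)
class KinDetectConfig:
    """Thresholds and filter settings for landmark detection.

    onset_threshold
        wrist tangential speed (mm/s) that must be exceeded at movement onset.
    end_threshold
        aperture velocity (mm/s) that must be re-crossed after the closing
        minimum to mark object contact.
    dwell_ms
        minimum time the threshold condition must hold (dwell rule).
    cutoff_hz, transition_hz
        low-pass FIR design: cutoff frequency and transition-band width.
    """

    onset_threshold: float = 5.0
    end_threshold: float = -5.0
    dwell_ms: float = 500.0
    cutoff_hz: float = 10.0
    transition_hz: float = 1.0
    ripple_db: float = 50.0

    def __post_init__(self) -> None:
        if self.dwell_ms <= 0:
            raise InvalidConfigError("dwell_ms must be > 0")
        if not (self.cutoff_hz > self.transition_hz > 0):
            raise InvalidConfigError("need cutoff_hz > transition_hz > 0")

    def design_taps(self, fs: float) -> np.ndarray:
        """Design the zero-phase low-pass FIR (Kaiser window method).

        Unit DC gain, ~0.3% passband ripple / 50 dB stopband by default; the
        transition band is centred on the cutoff. The ripple budget keeps
        filter ringing well below the 5 mm/s detection thresholds.
        """
        numtaps, beta = signal.kaiserord(self.ripple_db, self.transition_hz / (fs / 2))
        numtaps += 1 - numtaps % 2  # odd length -> integer group delay
        return signal.firwin(
            numtaps, self.cutoff_hz, window=("kaiser", beta), fs=fs
        )

    def dwell_samples(self, fs: float) -> int:
        """Dwell rule expressed in samples (>= , not >, at one-sample resolution)."""
        return int(round(self.dwell_ms / 1000.0 * fs))


def lowpass_filter(traj: MarkerTrajectory, cfg: KinDetectConfig | None = None) -> MarkerTrajectory:
    """Zero-phase low-pass filter every coordinate series of a trajectory.

    A symmetric (linear-phase) FIR kernel is applied by reflect-padded
    convolution, which cancels the group delay exactly; the time grid is
    unchanged.
    """
    cfg = cfg or KinDetectConfig()
    taps = cfg.design_taps(traj.fs)
    n = traj.time.size
    if n <= taps.size:
        raise ValueError(
            f"trajectory has {n} samples but the filter needs more than "
            f"{taps.size}; record at least {(taps.size + 1) / traj.fs:.2f} s"
        )
    half = taps.size // 2

    def _apply(series: np.ndarray) -> np.ndarray:
        out = np.empty_like(series)
        for j in range(series.shape[1]):
            padded = np.pad(series[:, j], half, mode="reflect")
            out[:, j] = np.convolve(padded, taps, mode="valid")
        return out

    return MarkerTrajectory(
        time=traj.time.copy(),
        wrist=_apply(traj.wrist),
        thumb=_apply(traj.thumb),
        index=_apply(traj.index),
        meta=dict(traj.meta),
    )


def tangential_velocity(traj: MarkerTrajectory, marker: str = "wrist") -> np.ndarray:
    """Tangential (scalar) velocity of a marker in mm/s.

    Euclidean norm of the 3-D first derivative, central differences in the
    interior and one-sided differences at the endpoints.
    """
    pos = traj.marker(marker)
    vel = np.gradient(pos, traj.time, axis=0)
    return np.linalg.norm(vel, axis=1)


def grip_aperture(traj: MarkerTrajectory) -> np.ndarray:
    """Thumb-index 3-D Euclidean distance (mm) at each sample."""
    return np.linalg.norm(traj.thumb - traj.index, axis=1)


def aperture_velocity(aperture: np.ndarray, time: np.ndarray) -> np.ndarray:
    """First derivative of the grip aperture (mm/s); positive = opening."""
    return np.gradient(np.asarray(aperture, float), time)


def _first_dwelling_index(mask: np.ndarray, n_dwell: int) -> int | None:
    """First index i such that mask[i:i+n_dwell] is all True, else None."""
    if mask.size < n_dwell:
        return None
    counts = np.convolve(mask.astype(int), np.ones(n_dwell, dtype=int), mode="valid")
    hits = np.nonzero(counts == n_dwell)[0]
    return int(hits[0]) if hits.size else None


def detect_movement_onset(
    wrist_speed: np.ndarray, time: np.ndarray, cfg: KinDetectConfig | None = None
) -> float:
    """Movement onset: first sample where the wrist speed exceeds the
    threshold and remains above it for the full dwell period.

    Returns the onset time in seconds (on the recording clock).
    """
    cfg = cfg or KinDetectConfig()
    fs = 1.0 / float(np.mean(np.diff(time)))
    n_dwell = cfg.dwell_samples(fs)
    idx = _first_dwelling_index(np.asarray(wrist_speed) > cfg.onset_threshold, n_dwell)
    if idx is None:
        raise OnsetNotFoundError(
            f"no wrist-speed sample > {cfg.onset_threshold} mm/s sustained for "
            f"{cfg.dwell_ms} ms"
        )
    return float(time[idx])


def detect_movement_end(
    ap_velocity: np.ndarray,
    time: np.ndarray,
    onset: float,
    cfg: KinDetectConfig | None = None,
) -> float:
    """Object-contact time: after the global minimum of the aperture velocity
    (the grip-closing peak) following onset, the first sample whose aperture
    velocity re-crosses the end threshold and stays above it for the dwell
    period.
    """
    cfg = cfg or KinDetectConfig()
    ap_velocity = np.asarray(ap_velocity, float)
    fs = 1.0 / float(np.mean(np.diff(time)))
    n_dwell = cfg.dwell_samples(fs)
    after = np.nonzero(time > onset)[0]
    if after.size == 0:
        raise EndNotFoundError("no samples after onset")
    i0 = after[0]
    i_min = i0 + int(np.argmin(ap_velocity[i0:]))
    if ap_velocity[i_min] >= cfg.end_threshold:
        raise EndNotFoundError(
            f"aperture velocity never fell below {cfg.end_threshold} mm/s after "
            "onset (no closing phase)"
        )
    rel = _first_dwelling_index(ap_velocity[i_min:] > cfg.end_threshold, n_dwell)
    if rel is None:
        raise EndNotFoundError(
            f"no aperture-velocity crossing above {cfg.end_threshold} mm/s "
            f"sustained for {cfg.dwell_ms} ms after the closing minimum"
        )
    return float(time[i_min + rel])


@dataclass(frozen=True)
class TrialKinematics:
    """The eight extracted parameters plus detected onset/end for one trial.

    Times are milliseconds; ``onset_ms``/``end_ms`` are on the recording
    clock, every other time parameter is relative to onset.
    """

    onset_ms: float
    end_ms: float
    mov_t: float
    t_peak_v: float
    amp_peak_v: float
    t_peak_a: float
    amp_peak_a: float
    t_peak_d: float
    amp_peak_d: float
    t_max_grip_apert: float

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in ("onset_ms", "end_ms") + PARAMETER_NAMES}


def extract_parameters(
    traj: MarkerTrajectory,
    cfg: KinDetectConfig | None = None,
    *,
    prefiltered: bool = False,
) -> TrialKinematics:
    """Run the full per-trial chain: filter, detect onset/end, extract the
    eight parameters.

    Ties at extrema resolve to the earliest sample. Detection failures raise
    :class:`~graspdecode.errors.DetectionError` subclasses; callers that
    aggregate over trials should catch these and flag the trial.
    """
    cfg = cfg or KinDetectConfig()
    filt = traj if prefiltered else lowpass_filter(traj, cfg)
    t = filt.time
    speed = tangential_velocity(filt, "wrist")
    aperture = grip_aperture(filt)
    ap_vel = aperture_velocity(aperture, t)

    onset = detect_movement_onset(speed, t, cfg)
    end = detect_movement_end(ap_vel, t, onset, cfg)

    sel = (t >= onset) & (t <= end)
    idx = np.nonzero(sel)[0]
    t_rel = (t[idx] - onset) * 1000.0

    accel = np.gradient(speed, t)

    i_pv = int(np.argmax(speed[idx]))
    i_pa = int(np.argmax(accel[idx]))
    i_pd = int(np.argmin(accel[idx]))
    i_ap = int(np.argmax(aperture[idx]))

    return TrialKinematics(
        onset_ms=onset * 1000.0,
        end_ms=end * 1000.0,
        mov_t=(end - onset) * 1000.0,
        t_peak_v=float(t_rel[i_pv]),
        amp_peak_v=float(speed[idx][i_pv]),
        t_peak_a=float(t_rel[i_pa]),
        amp_peak_a=float(accel[idx][i_pa]),
        t_peak_d=float(t_rel[i_pd]),
        amp_peak_d=float(accel[idx][i_pd]),
        t_max_grip_apert=float(t_rel[i_ap]),
    )


def extract_table(
    trials: Iterable[MarkerTrajectory], cfg: KinDetectConfig | None = None
) -> pd.DataFrame:
    """Extract parameters for a collection of trials into a tidy table.

    One row per trial with subject/condition/trial metadata, the eight
    parameters, onset/end, and a ``qc_flag`` column: ``"ok"`` or the name of
    the detection error. Failed trials keep NaN parameters and are meant to be
    excluded from aggregation.
    """
    cfg = cfg or KinDetectConfig()
    rows = []
    for traj in trials:
        row = {
            "subject": traj.meta.get("subject"),
            "condition": traj.meta.get("condition"),
            "trial": traj.meta.get("trial"),
        }
        try:
            row.update(extract_parameters(traj, cfg).as_dict())
            row["qc_flag"] = "ok"
        except (OnsetNotFoundError, EndNotFoundError) as err:
            row.update({k: np.nan for k in ("onset_ms", "end_ms") + PARAMETER_NAMES})
            row["qc_flag"] = type(err).__name__
        rows.append(row)
    return pd.DataFrame(rows)
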