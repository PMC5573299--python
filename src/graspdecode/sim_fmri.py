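"""Event-related ROI time-series simulation with known multivariate structure.

Emulates the study's acquisition: per subject, 2 runs of 165 volumes at
TR = 3 s, 25 trials per condition per run in randomised order, inter-stimulus
intervals drawn from a 3-8 s shifted, truncated ("long") exponential. Each
ROI voxel's series is

    baseline + linear drift + slow sinusoid
    + sum_trials hrf(t - onset) * (common_evoked + label * amplitude * w_v)
    + Gaussian noise,

where ``w_v`` is a per-voxel condition-pattern weight drawn once per
subject x ROI (so the multivariate pattern is stable across runs — the
property the decoder exploits) and ``label`` is +1 for social, -1 for
individual trials. Control ROIs use amplitude 0: their series are
statistically independent of the condition labels, which pins decoding at
chance.

Per-subject amplitude scaling (lognormal) makes some subjects more decodable
than others; designating two ROIs to share their subject factor induces a
positive across-subject correlation between their decoding accuracies, the
structure behind correlated region pairs in group analyses.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

from .errors import InvalidConfigError, SchedulingError
from .mvpa import RoiRunSeries

__all__ = [
    "FmriSimConfig",
    "RunEvents",
    "SubjectFmri",
    "FmriDataset",
    "hrf",
    "simulate_event_schedule",
    "simulate_roi_run",
    "simulate_subject",
    "simulate_fmri_dataset",
]

SOCIAL, INDIVIDUAL = 1, -1


@dataclass
class RunEvents:
    """Ordered trial onsets (s from run start) and +-1 condition labels for
    one run."""

    run: int
    onsets: np.ndarray
    labels: np.ndarray
    trial_duration: float = 4.0

    def __post_init__(self) -> None:
        self.onsets = np.asarray(self.onsets, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.onsets.shape != self.labels.shape:
            raise ValueError("onsets and labels must align")
        if np.any(np.diff(self.onsets) <= 0):
            raise ValueError("onsets must be strictly increasing")
        if not np.isin(self.labels, (SOCIAL, INDIVIDUAL)).all():
            raise ValueError("labels must be +-1")


@dataclass
class FmriSimConfig:
    """Configuration of the event-related ROI simulator.

    Defaults reproduce the study's acquisition geometry (2 runs x 165
    volumes, TR 3 s, 25 trials/condition/run, ISI 3-8 s) for 23 subjects.
    ``signal_amplitude`` scales the condition-dependent per-voxel response of
    the task ROIs relative to unit noise SD; control ROIs are fixed at 0.
    """

    n_subjects: int = 23
    runs: int = 2
    volumes_per_run: int = 165
    tr: float = 3.0
    trials_per_condition_per_run: int = 25
    isi_min: float = 3.0
    isi_max: float = 8.0
    isi_rate: float = 0.5          # 1/s, rate of the shifted exponential
    trial_duration: float = 4.0    # s occupied by the trial itself
    n_voxels_per_roi: int = 200
    task_rois: tuple = ("IFG", "IPL", "MTG", "mPFC")
    control_rois: tuple = ("PCC", "ventricle", "outside_skull")
    bilateral_rois: tuple = ("IFG", "IPL", "MTG", "mPFC", "PCC")
    signal_amplitude: float = 0.06
    roi_amplitudes: dict = field(default_factory=dict)
    coupled_rois: tuple = ("IFG", "mPFC")
    subject_amplitude_sd: float = 0.4
    common_evoked: float = 1.0
    noise_sd: float = 1.0
    baseline: float = 100.0
    drift_slope: float = 0.02          # signal units per second
    drift_sin_amplitude: float = 0.5
    drift_sin_period: float = 128.0    # s
    hrf_peak_delay: float = 6.0
    hrf_undershoot_delay: float = 16.0
    hrf_undershoot_ratio: float = 1.0 / 6.0
    hrf_dispersion: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.isi_min < self.isi_max:
            raise InvalidConfigError("need isi_min < isi_max")
        if self.isi_rate <= 0 or self.tr <= 0:
            raise InvalidConfigError("isi_rate and tr must be > 0")
        if self.signal_amplitude < 0 or any(v < 0 for v in self.roi_amplitudes.values()):
            raise InvalidConfigError("signal amplitudes must be >= 0")
        if self.n_voxels_per_roi < 2:
            raise InvalidConfigError("need at least 2 voxels per ROI")

    @property
    def rois(self) -> tuple:
        return tuple(self.task_rois) + tuple(self.control_rois)

    def amplitude_for(self, roi: str) -> float:
        if roi in self.roi_amplitudes:
            return self.roi_amplitudes[roi]
        return self.signal_amplitude if roi in self.task_rois else 0.0

    @property
    def run_duration(self) -> float:
        return self.volumes_per_run * self.tr

    def hrf_params(self) -> tuple:
        return (
            self.hrf_peak_delay, self.hrf_undershoot_delay,
            self.hrf_undershoot_ratio, self.hrf_dispersion,
        )


def _double_gamma(t: np.ndarray, peak: float, under: float, ratio: float,
                  disp: float) -> np.ndarray:
    from scipy.stats import gamma
    t = np.asarray(t, dtype=float)
    out = gamma.pdf(t, peak / disp, scale=disp) - ratio * gamma.pdf(
        t, under / disp, scale=disp
    )
    return np.where(t > 0, out, 0.0)


@lru_cache(maxsize=8)
def _hrf_peak_value(params: tuple) -> float:
    grid = np.linspace(0.0, 30.0, 3001)
    return float(_double_gamma(grid, *params).max())


def hrf(
    t,
    peak_delay: float = 6.0,
    undershoot_delay: float = 16.0,
    undershoot_ratio: float = 1.0 / 6.0,
    dispersion: float = 1.0,
):
    """Canonical double-gamma haemodynamic response, normalised to peak 1.

    Zero at t <= 0, positive peak near 5 s, a small late undershoot, and
    negligible (<1e-3) beyond 30 s with the default shape constants.
    """
    params = (peak_delay, undershoot_delay, undershoot_ratio, dispersion)
    return _double_gamma(t, *params) / _hrf_peak_value(params)


def _truncated_exp(rng: np.random.Generator, rate: float, span: float,
                   size: int) -> np.ndarray:
    """Exponential(rate) truncated to [0, span], by inverse CDF."""
    u = rng.random(size)
    return -np.log1p(-u * (1.0 - math.exp(-rate * span))) / rate


def simulate_event_schedule(
    cfg: FmriSimConfig, rng: np.random.Generator
) -> list[RunEvents]:
    """Randomised balanced trial order per run with 3-8 s "long exponential"
    inter-stimulus intervals.

    Each gap is ``trial_duration + isi`` with ``isi = isi_min +
    Exp(isi_rate)`` truncated at ``isi_max`` — a right-skewed distribution
    with most mass near the minimum. Raises
    :class:`~graspdecode.errors.SchedulingError` if the last trial onset
    plus the 6 s decoding-window end exceeds the run duration.
    """
    k = cfg.trials_per_condition_per_run
    schedule = []
    for run in range(1, cfg.runs + 1):
        labels = rng.permutation(np.repeat([SOCIAL, INDIVIDUAL], k))
        isi = cfg.isi_min + _truncated_exp(
            rng, cfg.isi_rate, cfg.isi_max - cfg.isi_min, 2 * k
        )
        gaps = isi + cfg.trial_duration
        onsets = np.concatenate([[isi[0]], isi[0] + np.cumsum(gaps[1:])])
        if onsets[-1] + 6.0 > cfg.run_duration:
            raise SchedulingError(
                f"run {run}: last onset {onsets[-1]:.1f} s + 6 s exceeds the "
                f"{cfg.run_duration:.0f} s run"
            )
        schedule.append(RunEvents(run=run, onsets=onsets, labels=labels,
                                  trial_duration=cfg.trial_duration))
    return schedule


def simulate_roi_run(
    cfg: FmriSimConfig,
    events: RunEvents,
    pattern: np.ndarray,
    amplitude: float,
    rng: np.random.Generator,
    roi: str = "ROI",
    hemisphere: str | None = None,
) -> RoiRunSeries:
    """Simulate one run's voxel x volume matrix for one ROI.

    ``pattern`` holds the per-voxel condition weights ``w_v``; the
    condition-dependent evoked term is ``amplitude * label * w_v`` per trial,
    added to a condition-independent common response, drift and noise.
    """
    pattern = np.asarray(pattern, dtype=float)
    t = np.arange(cfg.volumes_per_run) * cfg.tr
    lags = t[:, None] - events.onsets[None, :]            # (V, J)
    R = hrf(lags, *cfg.hrf_params())
    shared = (
        cfg.baseline
        + cfg.drift_slope * t
        + cfg.drift_sin_amplitude * np.sin(2.0 * np.pi * t / cfg.drift_sin_period)
        + cfg.common_evoked * R.sum(axis=1)
    )
    cond = R @ events.labels                              # (V,)
    data = (
        shared[None, :]
        + amplitude * np.outer(pattern, cond)
        + rng.normal(0.0, cfg.noise_sd, (pattern.size, t.size))
    )
    return RoiRunSeries(roi=roi, run=events.run, data=data, tr=cfg.tr,
                        hemisphere=hemisphere)


@dataclass
class SubjectFmri:
    """One subject's schedule and per-ROI (x hemisphere) run series."""

    subject: int
    schedule: list
    series: dict      # (roi, hemisphere|None) -> list[RoiRunSeries]


@dataclass
class FmriDataset:
    config: FmriSimConfig
    subjects: list


def _roi_units(cfg: FmriSimConfig) -> list[tuple[str, str | None, int]]:
    """(roi, hemisphere, n_voxels) decomposition of the configured ROIs."""
    units = []
    for roi in cfg.rois:
        if roi in cfg.bilateral_rois:
            half = cfg.n_voxels_per_roi // 2
            units += [(roi, "L", half), (roi, "R", cfg.n_voxels_per_roi - half)]
        else:
            units.append((roi, None, cfg.n_voxels_per_roi))
    return units


def simulate_subject(
    cfg: FmriSimConfig, subject: int, rng: np.random.Generator
) -> SubjectFmri:
    """Simulate one subject: schedule, patterns, and all ROI run series."""
    schedule = simulate_event_schedule(cfg, rng)
    shared_factor = math.exp(rng.normal(0.0, cfg.subject_amplitude_sd))
    factors = {}
    for roi in cfg.rois:
        if roi in cfg.coupled_rois:
            factors[roi] = shared_factor
        else:
            factors[roi] = math.exp(rng.normal(0.0, cfg.subject_amplitude_sd))
    series: dict = {}
    for roi, hemi, n_vox in _roi_units(cfg):
        pattern = rng.standard_normal(n_vox)
        amplitude = cfg.amplitude_for(roi) * factors[roi]
        series[(roi, hemi)] = [
            simulate_roi_run(cfg, ev, pattern, amplitude, rng, roi=roi,
                             hemisphere=hemi)
            for ev in schedule
        ]
    return SubjectFmri(subject=subject, schedule=schedule, series=series)


def simulate_fmri_dataset(cfg: FmriSimConfig) -> FmriDataset:
    """Simulate the full cohort, deterministically from ``cfg.seed``."""
    rng = np.random.default_rng(cfg.seed)
    subjects = [
        simulate_subject(cfg, s, rng) for s in range(1, cfg.n_subjects + 1)
    ]
    return FmriDataset(config=cfg, subjects=subjects)
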