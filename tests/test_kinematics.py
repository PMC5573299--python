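"""Filtering, derivative channels, landmark detection and extraction."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from graspdecode.errors import EndNotFoundError, OnsetNotFoundError
from graspdecode.kinematics import (
    KinDetectConfig,
    MarkerTrajectory,
    aperture_velocity,
    detect_movement_end,
    detect_movement_onset,
    extract_parameters,
    grip_aperture,
    lowpass_filter,
    tangential_velocity,
)

FS = 140.0


def _flat_traj(n, fs=FS, pos=(0.0, 0.0, 0.0)):
    t = np.arange(n) / fs
    p = np.tile(np.asarray(pos, float), (n, 1))
    return MarkerTrajectory(time=t, wrist=p.copy(), thumb=p.copy(), index=p.copy())


def _sine_traj(freq, n=900, amp=10.0):
    t = np.arange(n) / FS
    x = amp * np.sin(2 * np.pi * freq * t)
    p = np.column_stack([x, np.zeros(n), np.zeros(n)])
    return MarkerTrajectory(time=t, wrist=p, thumb=p.copy(), index=p.copy()), t


class TestLowpassFilter:
    def test_dc_preserved(self):
        traj = _flat_traj(900, pos=(5.0, -3.0, 7.0))
        out = lowpass_filter(traj)
        np.testing.assert_allclose(out.wrist, traj.wrist, atol=1e-8)

    @pytest.mark.parametrize("freq, lo, hi", [(2.0, 0.99, 1.01), (20.0, 0.0, 0.05)])
    def test_passband_and_stopband(self, freq, lo, hi):
        traj, t = _sine_traj(freq)
        out = lowpass_filter(traj)
        core = slice(250, 650)  # away from the reflect-padded edges
        ratio = out.wrist[core, 0].std() / traj.wrist[core, 0].std()
        assert lo <= ratio <= hi

    def test_too_short_series_names_minimum(self):
        with pytest.raises(ValueError, match="at least"):
            lowpass_filter(_flat_traj(100))

    def test_time_grid_unchanged(self):
        traj, _ = _sine_traj(2.0)
        out = lowpass_filter(traj)
        np.testing.assert_array_equal(out.time, traj.time)


class TestVelocityChannels:
    def test_stationary_marker_zero_speed(self):
        traj = _flat_traj(300)
        assert np.all(tangential_velocity(traj) == 0)

    def test_uniform_motion_closed_form(self):
        # (3, 4, 0) mm per frame at 140 Hz -> |v| = 5 mm * 140 = 700 mm/s
        n = 200
        t = np.arange(n) / FS
        p = np.column_stack([3.0 * np.arange(n), 4.0 * np.arange(n), np.zeros(n)])
        traj = MarkerTrajectory(time=t, wrist=p, thumb=p.copy(), index=p.copy())
        np.testing.assert_allclose(tangential_velocity(traj), 700.0, rtol=1e-9)

    def test_unknown_marker(self):
        with pytest.raises(KeyError):
            tangential_velocity(_flat_traj(100), "elbow")

    def test_minjerk_peak_speed(self, minjerk_trial):
        # closed form: 1.875 * D / MT = 937.5 mm/s at t = MT/2 from movement start
        _, traj = minjerk_trial
        filt = lowpass_filter(traj)
        speed = tangential_velocity(filt)
        i = int(np.argmax(speed))
        assert speed[i] == pytest.approx(937.5, rel=0.01)
        t_peak = traj.time[i] - traj.meta["movement_start_s"]
        assert t_peak == pytest.approx(0.300, abs=1.0 / FS)

    def test_aperture_zero_and_linear(self):
        n = 300
        t = np.arange(n) / FS
        base = np.zeros((n, 3))
        traj = MarkerTrajectory(time=t, wrist=base, thumb=base.copy(),
                                index=base.copy())
        assert np.all(grip_aperture(traj) == 0)
        # aperture opening 10 mm per 100 ms -> velocity 100 mm/s
        ap = 100.0 * t
        vel = aperture_velocity(ap, t)
        np.testing.assert_allclose(vel, 100.0, rtol=1e-9)
        np.testing.assert_allclose(aperture_velocity(np.full(n, 40.0), t), 0.0,
                                   atol=1e-9)


def _brute_force_onset(speed, time, thr, n_dwell):
    for i in range(len(speed)):
        if i + n_dwell <= len(speed) and np.all(speed[i:i + n_dwell] > thr):
            return time[i]
    return None


class TestOnsetDetection:
    def test_zero_speed_raises(self):
        t = np.arange(500) / FS
        with pytest.raises(OnsetNotFoundError):
            detect_movement_onset(np.zeros(500), t)

    def test_step_onset(self):
        t = np.arange(280) / FS
        speed = np.where(t >= 1.0, 100.0, 0.0)
        assert detect_movement_onset(speed, t) == pytest.approx(1.0)

    def test_short_blip_rejected_by_dwell(self):
        t = np.arange(560) / FS
        speed = np.zeros_like(t)
        speed[(t >= 0.5) & (t < 0.8)] = 50.0        # 300 ms blip: fails dwell
        speed[t >= 1.2] = 100.0                     # sustained rise
        onset = detect_movement_onset(speed, t)
        assert onset == pytest.approx(1.2, abs=1e-9)
        assert onset == _brute_force_onset(speed, t, 5.0, 70)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_matches_exhaustive_scan(self, seed):
        """The vectorised dwell scan agrees with brute force on arbitrary
        piecewise speed series."""
        rng = np.random.default_rng(seed)
        n = 250
        t = np.arange(n) / FS
        # blocky random series to exercise runs of every length
        speed = np.repeat(rng.uniform(0, 12, size=n // 10 + 1), 10)[:n]
        expected = _brute_force_onset(speed, t, 5.0, 70)
        if expected is None:
            with pytest.raises(OnsetNotFoundError):
                detect_movement_onset(speed, t)
        else:
            assert detect_movement_onset(speed, t) == expected


class TestEndDetection:
    def test_no_closing_phase_raises(self):
        t = np.arange(560) / FS
        with pytest.raises(EndNotFoundError):
            detect_movement_end(np.zeros_like(t), t, onset=0.5)

    def test_recross_after_minimum(self):
        t = np.arange(560) / FS
        apv = np.zeros_like(t)
        closing = (t >= 1.3) & (t < 1.62)
        apv[closing] = -200.0 * np.sin(
            np.pi * (t[closing] - 1.3) / 0.34
        )  # min near 1.47, back above -5 from ~1.62
        end = detect_movement_end(apv, t, onset=0.5)
        assert end == pytest.approx(1.6214, abs=1.5 / FS)

    def test_simulated_contact_time(self, noiseless_pair):
        cfg, trials = noiseless_pair
        k = extract_parameters(trials["individual"])
        assert k.mov_t == pytest.approx(
            trials["individual"].meta["targets"]["mov_t"], abs=1000.0 / FS
        )


class TestExtraction:
    def test_symmetric_minjerk_landmarks(self, minjerk_trial):
        _, traj = minjerk_trial
        k = extract_parameters(traj)
        # extremum ordering for a single-peaked profile
        assert k.t_peak_a < k.t_peak_v < k.t_peak_d
        assert 0 < k.t_peak_a and k.t_peak_d < k.mov_t
        # symmetric profile: acceleration and deceleration peaks mirror
        assert k.amp_peak_a == pytest.approx(-k.amp_peak_d, rel=0.02)
        assert k.amp_peak_v > 0 and k.amp_peak_a > 0 and k.amp_peak_d < 0

    def test_times_relative_to_onset_within_movement(self, noiseless_pair):
        _, trials = noiseless_pair
        for traj in trials.values():
            k = extract_parameters(traj)
            for name in ("t_peak_v", "t_peak_a", "t_peak_d", "t_max_grip_apert"):
                assert 0 <= getattr(k, name) <= k.mov_t
            assert k.mov_t == pytest.approx(k.end_ms - k.onset_ms)

    def test_aperture_plateau_tie_resolves_to_first_sample(self, noiseless_pair):
        _, trials = noiseless_pair
        traj = trials["individual"]
        filt = lowpass_filter(traj)
        ap = grip_aperture(filt)
        i_max = int(np.argmax(ap))
        plateau = ap[i_max] + 1.0
        ap_mod = ap.copy()
        ap_mod[i_max:i_max + 7] = plateau   # 50 ms flat top
        # rebuild thumb/index so |thumb - index| equals the modified aperture
        half = np.zeros((len(ap), 3))
        half[:, 2] = ap_mod / 2.0
        mod = MarkerTrajectory(
            time=filt.time, wrist=filt.wrist,
            thumb=filt.wrist + half, index=filt.wrist - half,
            meta=filt.meta,
        )
        k = extract_parameters(mod, prefiltered=True)
        onset_idx = int(round(k.onset_ms / 1000.0 * FS))
        t_expected = (filt.time[i_max] - filt.time[onset_idx]) * 1000.0
        assert k.t_max_grip_apert == pytest.approx(t_expected, abs=1e-9)

    def test_scale_equivariance(self, noiseless_pair):
        """Scaling positions by k scales amplitudes by k and leaves times
        unchanged (thresholds scaled accordingly)."""
        _, trials = noiseless_pair
        traj = trials["individual"]
        k1 = extract_parameters(traj)
        scale = 2.5
        scaled = MarkerTrajectory(
            time=traj.time, wrist=traj.wrist * scale,
            thumb=traj.thumb * scale, index=traj.index * scale, meta=traj.meta,
        )
        cfg = KinDetectConfig(onset_threshold=5.0 * scale,
                              end_threshold=-5.0 * scale)
        k2 = extract_parameters(scaled, cfg)
        for name in ("mov_t", "t_peak_v", "t_peak_a", "t_peak_d",
                     "t_max_grip_apert"):
            assert getattr(k2, name) == pytest.approx(getattr(k1, name))
        for name in ("amp_peak_v", "amp_peak_a", "amp_peak_d"):
            assert getattr(k2, name) == pytest.approx(scale * getattr(k1, name))
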