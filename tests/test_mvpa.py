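"""Run conditioning, pattern extraction, and balanced leave-pair-out CV."""

import numpy as np
import pytest
from sklearn.svm import SVC

from graspdecode.errors import PreprocessingError
from graspdecode.mvpa import (
    PatternSet,
    RoiRunSeries,
    SvmConfig,
    balanced_loocv,
    extract_patterns,
    pool_patterns,
    preprocess_run,
)
from graspdecode.mvpa import _fold_plan
from graspdecode.sim_fmri import FmriSimConfig, simulate_event_schedule, \
    simulate_roi_run


def _series(data, tr=3.0, run=1):
    return RoiRunSeries(roi="ROI", run=run, data=np.asarray(data, float), tr=tr)


class TestPreprocess:
    def test_zero_mean_unit_sd(self):
        rng = np.random.default_rng(0)
        out = preprocess_run(_series(rng.normal(10, 3, (8, 165))))
        np.testing.assert_allclose(out.data.mean(axis=1), 0.0, atol=1e-10)
        np.testing.assert_allclose(out.data.std(axis=1), 1.0, atol=1e-10)

    def test_pure_linear_ramp_raises(self):
        t = np.arange(165, dtype=float)
        data = np.vstack([2.0 * t + 5.0, np.random.default_rng(1).normal(size=165)])
        with pytest.raises(PreprocessingError, match="0"):
            preprocess_run(_series(data))

    def test_highpass_removes_slow_keeps_fast(self):
        """A sub-cutoff sinusoid (495 s period) is removed; a 30 s-period
        component survives nearly unchanged."""
        t = np.arange(165) * 3.0
        slow = np.sin(2 * np.pi * t / 495.0)
        fast = np.sin(2 * np.pi * t / 30.0)
        noise = np.random.default_rng(2).normal(0, 1e-3, 165)
        out = preprocess_run(_series(np.vstack([slow + fast, noise])))
        zfast = (fast - fast.mean()) / fast.std()
        r = np.corrcoef(out.data[0], zfast)[0, 1]
        assert r > 0.99

    def test_butter_method_also_standardises(self):
        rng = np.random.default_rng(3)
        out = preprocess_run(_series(rng.normal(0, 1, (4, 165))), method="butter")
        np.testing.assert_allclose(out.data.std(axis=1), 1.0, atol=1e-10)


class TestExtractPatterns:
    @staticmethod
    def _events(onsets, labels, run=1):
        from graspdecode.sim_fmri import RunEvents
        return RunEvents(run=run, onsets=np.array(onsets, float),
                         labels=np.array(labels))

    def test_half_open_window_picks_single_volume(self):
        # TR = 3 s, onset on a volume time t0: only the volume at t0+3
        # falls in [t0+3, t0+6)
        data = np.tile(np.arange(20, dtype=float), (3, 1))  # voxel value = index
        s = _series(data)
        ps = extract_patterns([s], [self._events([9.0], [1])])
        np.testing.assert_array_equal(ps.X, [[4.0, 4.0, 4.0]])

    def test_jittered_onset_averages_two_volumes(self):
        data = np.tile(np.arange(20, dtype=float), (2, 1))
        s = _series(data)
        # onset 7.5: window [10.5, 13.5) contains volumes at 12 only? no:
        # volume times 0,3,..: 12 in window, 10.5<=12<13.5 -> index 4
        ps = extract_patterns([s], [self._events([7.5], [-1])])
        np.testing.assert_array_equal(ps.X, [[4.0, 4.0]])
        # onset 6.5: window [9.5, 12.5) contains 12: index 4... and not 9
        ps2 = extract_patterns([s], [self._events([8.0], [1])])
        # window [11, 14): volume 12 -> index 4
        np.testing.assert_array_equal(ps2.X, [[4.0, 4.0]])

    def test_constant_series_identical_features(self):
        s = _series(np.full((4, 30), 7.0))
        ps = extract_patterns([s], [self._events([3.0, 12.0, 21.0, 30.0],
                                                 [1, -1, 1, -1])])
        assert np.all(ps.X == 7.0)

    def test_full_design_yields_100_trials(self):
        cfg = FmriSimConfig(n_voxels_per_roi=5, seed=0)
        sched = simulate_event_schedule(cfg, np.random.default_rng(0))
        runs = [
            simulate_roi_run(cfg, ev, np.zeros(5), 0.0,
                             np.random.default_rng(i))
            for i, ev in enumerate(sched)
        ]
        ps = extract_patterns([preprocess_run(r) for r in runs], sched)
        assert ps.n_trials == 100
        assert ps.is_balanced()

    def test_trial_without_volume_raises(self):
        s = _series(np.zeros((2, 4)))  # volumes at 0, 3, 6, 9 s
        with pytest.raises(ValueError, match="no volume"):
            extract_patterns([s], [self._events([9.0], [1])])

    def test_pool_patterns_concatenates_features(self):
        s = _series(np.random.default_rng(0).normal(size=(3, 30)))
        ev = [self._events([3.0, 12.0], [1, -1])]
        a = extract_patterns([s], ev)
        b = extract_patterns([s], ev)
        pooled = pool_patterns(a, b)
        assert pooled.X.shape == (2, 6)
        np.testing.assert_array_equal(pooled.y, a.y)


def _gaussian_patterns(n_per_class=10, n_vox=6, sep=0.0, seed=0):
    rng = np.random.default_rng(seed)
    X = rng.normal(0, 1, (2 * n_per_class, n_vox))
    y = np.array([1, -1] * n_per_class)
    X[y == 1] += sep
    return PatternSet(X=X, y=y, runs=np.ones(2 * n_per_class, int),
                      onsets=np.arange(2 * n_per_class, dtype=float))


class TestBalancedLoocv:
    def test_separable_clouds_perfect_accuracy(self):
        ps = _gaussian_patterns(n_per_class=50, sep=20.0)
        res = balanced_loocv(ps)
        assert res.accuracy == 1.0
        assert res.n_folds == 50

    def test_fold_count_and_training_balance(self):
        ps = _gaussian_patterns(n_per_class=50, sep=0.5)
        folds = _fold_plan(ps, "ordered", None)
        assert len(folds) == 50
        all_idx = np.arange(100)
        for pos, neg in folds:
            assert ps.y[pos] == 1 and ps.y[neg] == -1
            train = np.setdiff1d(all_idx, [pos, neg])
            assert (ps.y[train] == 1).sum() == 49
            assert (ps.y[train] == -1).sum() == 49

    def test_every_trial_held_out_exactly_once(self):
        ps = _gaussian_patterns(n_per_class=8)
        folds = _fold_plan(ps, "ordered", None)
        held = sorted(i for pair in folds for i in pair)
        assert held == list(range(16))

    def test_unbalanced_and_tiny_inputs_raise(self):
        ps = _gaussian_patterns(n_per_class=3)
        bad = PatternSet(X=ps.X[:5], y=ps.y[:5], runs=ps.runs[:5],
                         onsets=ps.onsets[:5])
        with pytest.raises(ValueError, match="unbalanced"):
            balanced_loocv(bad)
        tiny = PatternSet(X=ps.X[:2], y=ps.y[:2], runs=ps.runs[:2],
                          onsets=ps.onsets[:2])
        with pytest.raises(ValueError, match="at least"):
            balanced_loocv(tiny)

    def test_matches_exhaustive_oracle_on_toy_set(self):
        """Fold membership and accuracy agree with an explicitly enumerated
        cross-validation on an N = 8 set."""
        ps = _gaussian_patterns(n_per_class=4, sep=1.0, seed=3)
        res = balanced_loocv(ps)
        pos = [i for i in range(8) if ps.y[i] == 1]
        neg = [i for i in range(8) if ps.y[i] == -1]
        correct = []
        for p, q in zip(pos, neg):
            train = [i for i in range(8) if i not in (p, q)]
            clf = SVC(kernel="linear", C=1.0)
            clf.fit(ps.X[train], ps.y[train])
            for i in (p, q):
                f = clf.decision_function(ps.X[[i]])[0]
                correct.append((f > 0 and ps.y[i] == 1)
                               or (f < 0 and ps.y[i] == -1))
        assert res.accuracy == pytest.approx(np.mean(correct))
        assert res.n_folds == 4

    def test_voxel_permutation_and_label_swap_invariance(self):
        ps = _gaussian_patterns(n_per_class=10, sep=0.8, seed=4)
        base = balanced_loocv(ps).accuracy
        rng = np.random.default_rng(0)
        perm = rng.permutation(ps.X.shape[1])
        shuffled = PatternSet(X=ps.X[:, perm], y=ps.y, runs=ps.runs,
                              onsets=ps.onsets)
        assert balanced_loocv(shuffled).accuracy == base
        swapped = PatternSet(X=ps.X, y=-ps.y, runs=ps.runs, onsets=ps.onsets)
        assert balanced_loocv(swapped).accuracy == pytest.approx(base)

    def test_random_pairing_is_seeded_and_valid(self):
        ps = _gaussian_patterns(n_per_class=10, sep=0.5, seed=5)
        r1 = balanced_loocv(ps, pairing="random", rng=np.random.default_rng(1))
        r2 = balanced_loocv(ps, pairing="random", rng=np.random.default_rng(1))
        assert r1.accuracy == r2.accuracy
        with pytest.raises(ValueError):
            balanced_loocv(ps, pairing="random")

    def test_invalid_svm_config(self):
        with pytest.raises(Exception):
            SvmConfig(C=0.0)


class TestDecodability:
    def test_chance_level_on_signal_free_patterns(self):
        """23 simulated subjects with no condition signal decode at chance:
        the group mean stays within 0.5 +- 0.02."""
        from graspdecode.pipeline import decode_dataset
        from graspdecode.sim_fmri import simulate_fmri_dataset
        cfg = FmriSimConfig(
            n_subjects=23, n_voxels_per_roi=30,
            task_rois=(), control_rois=("ventricle",), bilateral_rois=(),
            seed=21,
        )
        acc = decode_dataset(simulate_fmri_dataset(cfg))
        assert len(acc) == 23
        assert abs(acc.accuracy.mean() - 0.5) <= 0.02

    def test_accuracy_monotone_in_signal_amplitude(self):
        """Mean accuracy increases with the injected condition amplitude
        (rank correlation > 0 across seeded replicates)."""
        from scipy.stats import spearmanr
        from graspdecode.pipeline import decode_dataset
        from graspdecode.sim_fmri import simulate_fmri_dataset
        amps, means = [], []
        for amp in (0.0, 0.08, 0.25):
            for seed in range(7):
                cfg = FmriSimConfig(
                    n_subjects=1, n_voxels_per_roi=24,
                    volumes_per_run=84, trials_per_condition_per_run=12,
                    task_rois=("IFG",), control_rois=(), bilateral_rois=(),
                    signal_amplitude=amp, subject_amplitude_sd=0.0,
                    seed=100 + seed,
                )
                acc = decode_dataset(simulate_fmri_dataset(cfg),
                                     hemispheres=False)
                amps.append(amp)
                means.append(acc.accuracy.mean())
        rho = spearmanr(amps, means).statistic
        assert rho > 0
        # and the extremes separate decisively
        lo = np.mean([m for a, m in zip(amps, means) if a == 0.0])
        hi = np.mean([m for a, m in zip(amps, means) if a == 0.25])
        assert hi > lo + 0.1
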