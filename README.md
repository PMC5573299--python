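# graspdecode

Tools for asking whether a *social* intention leaves measurable traces in a
reach-to-grasp movement — in the hand's kinematics and in the multivoxel
pattern of brain activity while the movement is executed.

The experimental paradigm is a prehensile action toward the same object at
the same location performed with two intentions: **individual** (grasp the
object and place it on a concave base) and **social** (grasp it and pass it
to a partner). The package implements the two analysis arms of such a study
as a tested, fully simulatable pipeline:

* **Behavioral arm** — 140 Hz three-marker (wrist, thumb, index) motion
  capture of the reach-to-grasp phase. Trajectories are low-pass filtered
  (zero-phase FIR, 10 Hz cutoff, 1 Hz transition); movement onset is the
  first wrist tangential-velocity sample above 5 mm/s sustained ≥ 500 ms and
  movement end the first aperture-velocity sample back above −5 mm/s after
  the grip-closing minimum, sustained ≥ 500 ms. Eight parameters per trial:
  movement time (Mov_T), time and amplitude of the wrist velocity peak
  (T_peak_V, Amp_peak_V), acceleration and deceleration peaks (T_peak_A,
  Amp_peak_A, T_peak_D, Amp_peak_D < 0), and the time of maximum grip
  aperture (T_max_grip_apert). Per-subject condition means are compared with
  a Shapiro–Wilk-gated paired Student t / Wilcoxon signed-rank test with
  Cohen's d_z and 95% CIs.

* **Decoding arm** — event-related ROI voxel time series (2 runs × 165
  volumes, TR = 3 s, 25 trials/condition/run, 3–8 s "long-exponential"
  ISIs). Each run is conditioned independently (linear detrend, 0.01 Hz
  discrete-cosine high-pass, per-voxel z-scoring); per-trial patterns are the
  mean of volumes acquired in the half-open window [onset + 3 s, onset + 6 s);
  a linear SVM (C = 1, labels +1 social / −1 individual) is evaluated with
  **balanced leave-one-pair-out cross-validation** — each of the N/2 folds
  holds out one trial per condition so training sets stay exactly balanced.
  Group inference: upper-tailed t-tests against the 50% chance level,
  left-vs-right paired comparisons, a Greenhouse–Geisser-corrected
  repeated-measures ANOVA across ROIs, and Benjamini–Hochberg-corrected
  Pearson correlations between ROI accuracies.

Both arms come with synthetic-data generators (`sim_kinematics`,
`sim_fmri`) that reproduce the design geometry and inject known condition
effects, so every stage runs — and is tested — with no external data.

## Worked example

Simulate one social reach and extract its kinematics:

```python
import numpy as np
from graspdecode import KinSimConfig, simulate_reach_trial, extract_parameters

cfg = KinSimConfig(seed=1)
trial = simulate_reach_trial(cfg, "social", np.random.default_rng(0))
k = extract_parameters(trial)
```

prints (via `k.as_dict()`), in ms / mm/s / mm/s²:

```
mov_t                  792.86
t_peak_v               478.57
amp_peak_v             631.93
t_peak_a               228.57
amp_peak_a            2176.21
t_peak_d               650.00
amp_peak_d           -4592.81
t_max_grip_apert       471.43
```

The social reach is ~85 ms slower than the 700 ms individual baseline, with
a later, lower velocity peak — exactly the injected condition effects, which
the detection chain recovers to within one sample (7.14 ms).

Decode a simulated 10-subject cohort and run the group statistics:

```python
from graspdecode import (FmriSimConfig, simulate_fmri_dataset,
                         decode_dataset, group_report)

cfg = FmriSimConfig(n_subjects=10, seed=11)
acc = decode_dataset(simulate_fmri_dataset(cfg), hemispheres=False)
rep = group_report(acc[acc.roi.isin(cfg.task_rois)])
print(rep["chance"][["mean_accuracy", "t", "p"]].round(3))
```

```
      mean_accuracy      t      p
roi
IFG           0.574  2.757  0.011
IPL           0.588  5.583  0.000
MTG           0.620  7.006  0.000
mPFC          0.627  4.762  0.001
```

All four task regions decode the intention above chance in the upper-50s /
low-60s accuracy range, while the signal-free control regions (PCC,
ventricle, outside-skull) stay at ~0.50. The ROI ANOVA is non-significant
(F(2.34, 21.09) = 1.62, p = .22, Greenhouse–Geisser corrected): the regions
carry similar amounts of intention information. The coupled IFG–mPFC pair
shows the largest accuracy correlation (r = .52 at this small n), the
structure the simulator's shared per-subject amplitude factor creates.

## Command line

```bash
graspdecode simulate-kin  --config kin.yaml  --out-dir data/kin
graspdecode extract-kin   --data-dir data/kin --out-dir out/kin
graspdecode kin-stats     --table out/kin/trial_kinematics.csv --out-dir out/stats
graspdecode decode        --config fmri.yaml --out-dir out/decode
graspdecode group-stats   --accuracies out/decode/accuracies.csv --out-dir out/group
```

Configs are flat YAML files (`seed` mandatory, unknown keys rejected); every
command writes a `log.json` with the config hash and seed so outputs can be
re-derived.

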