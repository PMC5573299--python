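"""End-to-end pipelines tying the simulators to the two analysis arms."""

from __future__ import annotations

import pandas as pd

from .group_stats import group_report
from .kin_stats import behavioral_report, subject_parameter_table
from .kinematics import KinDetectConfig, extract_table
from .mvpa import PatternSet, SvmConfig, balanced_loocv, extract_patterns, \
    pool_patterns, preprocess_run
from .sim_fmri import FmriDataset, FmriSimConfig, SubjectFmri, simulate_fmri_dataset
from .sim_kinematics import KinSimConfig, simulate_kinematics_dataset

__all__ = [
    "behavioral_pipeline",
    "subject_pattern_sets",
    "decode_dataset",
    "decoding_pipeline",
]


def behavioral_pipeline(
    cfg: KinSimConfig, det_cfg: KinDetectConfig | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate the kinematic design, extract all trials, and produce the
    paired-statistics report.

    Returns ``(trial_table, report)``.
    """
    trials = simulate_kinematics_dataset(cfg)
    table = extract_table(trials, det_cfg)
    report = behavioral_report(subject_parameter_table(table))
    return table, report


def subject_pattern_sets(
    subject: SubjectFmri,
    window: tuple[float, float] = (3.0, 6.0),
    highpass_cutoff: float = 0.01,
) -> dict:
    """Preprocess every run and extract patterns per ROI for one subject.

    Bilateral ROIs yield "L", "R" and pooled "both" entries (hemisphere
    pooling = feature concatenation of the per-hemisphere patterns);
    unilateral ROIs yield a single "both" entry. Keys are
    ``(roi, hemisphere_label)``.
    """
    by_roi: dict = {}
    for (roi, hemi), runs in subject.series.items():
        processed = [preprocess_run(s, highpass_cutoff) for s in runs]
        ps = extract_patterns(processed, subject.schedule, window)
        by_roi.setdefault(roi, {})[hemi] = ps
    out: dict = {}
    for roi, parts in by_roi.items():
        if None in parts:
            out[(roi, "both")] = parts[None]
        else:
            for hemi, ps in parts.items():
                out[(roi, hemi)] = ps
            out[(roi, "both")] = pool_patterns(
                *[parts[h] for h in sorted(parts)]
            )
    return out


def decode_dataset(
    dataset: FmriDataset,
    svm: SvmConfig | None = None,
    window: tuple[float, float] = (3.0, 6.0),
    hemispheres: bool = True,
) -> pd.DataFrame:
    """Run the full decoding arm on a simulated (or loaded) dataset.

    Returns a tidy table (subject, roi, hemisphere, accuracy, n_folds); the
    pooled bilateral entry is labelled "both". Set ``hemispheres=False`` to
    skip per-hemisphere decoding and roughly halve the runtime.
    """
    rows = []
    for subj in dataset.subjects:
        for (roi, hemi), ps in subject_pattern_sets(subj).items():
            if hemi != "both" and not hemispheres:
                continue
            res = balanced_loocv(ps, svm)
            rows.append({
                "subject": subj.subject, "roi": roi, "hemisphere": hemi,
                "accuracy": res.accuracy, "n_folds": res.n_folds,
            })
    return pd.DataFrame(rows)


def decoding_pipeline(
    cfg: FmriSimConfig,
    svm: SvmConfig | None = None,
    hemispheres: bool = True,
) -> tuple[pd.DataFrame, dict]:
    """Simulate the cohort, decode every subject x ROI, and run the group
    analyses.

    Returns ``(accuracy_table, group_report)``.
    """
    dataset = simulate_fmri_dataset(cfg)
    acc = decode_dataset(dataset, svm, hemispheres=hemispheres)
    return acc, group_report(acc)
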