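"""Paired behavioral statistics on per-subject kinematic parameter means.

For each of the eight reach-to-grasp parameters, the per-subject means of the
two intention conditions are compared with a paired test. A Shapiro-Wilk
gate on the paired differences chooses between the paired Student t-test and
the Wilcoxon signed-rank test; both report the social-minus-individual mean
difference, its standard error, Cohen's d_z (mean difference / SD of the
differences), and a t-based 95% confidence interval.

Conventions
-----------
* The Shapiro-Wilk gate is applied to the paired differences — the quantity
  whose normality the paired t-test actually assumes.
* The Wilcoxon statistic W is the sum of the ranks of the *positive*
  differences (zero differences dropped, average ranks for ties); with n
  pairs and no zeros/ties it ranges over [0, n(n+1)/2], reaching the upper
  bound when every difference is positive.
* All p-values are two-sided.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .kinematics import PARAMETER_NAMES

__all__ = [
    "PairedTestResult",
    "subject_parameter_table",
    "normality_gate",
    "paired_test",
    "behavioral_report",
]


@dataclass(frozen=True)
class PairedTestResult:
    """Outcome of one paired comparison (social vs. individual)."""

    parameter: str
    kind: str                 # "t" | "wilcoxon"
    statistic: float          # t value, or Wilcoxon W (rank sum of positives)
    df: float | None          # t only
    p: float                  # two-sided
    mean_difference: float    # social - individual, parameter units
    se_difference: float
    cohen_dz: float
    ci_low: float
    ci_high: float
    n: int

    def as_dict(self) -> dict:
        d = self.__dict__.copy()
        return d


def subject_parameter_table(trial_table: pd.DataFrame) -> pd.DataFrame:
    """Collapse a tidy per-trial parameter table to per-subject condition means.

    Trials whose ``qc_flag`` is not ``"ok"`` are excluded before averaging.
    Returns a table indexed by (subject, condition) with one column per
    parameter.
    """
    df = trial_table
    if "qc_flag" in df.columns:
        df = df[df["qc_flag"] == "ok"]
    cols = [c for c in PARAMETER_NAMES if c in df.columns]
    return df.groupby(["subject", "condition"])[cols].mean()


def normality_gate(differences: np.ndarray, alpha: float = 0.05) -> str:
    """Choose the paired test from a Shapiro-Wilk test on the differences.

    Returns ``"t"`` when the Shapiro-Wilk p-value is >= ``alpha`` (normality
    not rejected), ``"wilcoxon"`` otherwise. Degenerate all-equal samples
    cannot be tested for normality and are routed to the rank test with a
    warning. ``alpha = 0`` always selects the t-test.
    """
    d = np.asarray(differences, dtype=float)
    if d.size < 3:
        raise ValueError("need at least 3 paired differences")
    if alpha == 0:
        return "t"
    if np.ptp(d) == 0:
        warnings.warn("all paired differences identical; using Wilcoxon",
                      stacklevel=2)
        return "wilcoxon"
    p = stats.shapiro(d).pvalue
    return "t" if p >= alpha else "wilcoxon"


def _signed_rank_sum(d: np.ndarray) -> float:
    """Wilcoxon W: rank sum of positive differences (zeros dropped,
    average ranks for ties in |d|)."""
    d = d[d != 0]
    ranks = stats.rankdata(np.abs(d))
    return float(ranks[d > 0].sum())


def paired_test(
    social: np.ndarray,
    individual: np.ndarray,
    kind: str,
    parameter: str = "",
    ci_level: float = 0.95,
) -> PairedTestResult:
    """Paired comparison of two equally long, subject-matched vectors.

    ``kind="t"``: paired Student t-test. ``kind="wilcoxon"``: signed-rank
    test with an exact null distribution when there are no zeros or ties
    (scipy falls back to the normal approximation otherwise). The reported
    mean difference, SE, d_z and CI are the same descriptive quantities for
    both kinds.
    """
    social = np.asarray(social, dtype=float)
    individual = np.asarray(individual, dtype=float)
    if social.shape != individual.shape or social.ndim != 1:
        raise ValueError("social and individual must be equal-length 1-D vectors")
    n = social.size
    if n < 2:
        raise ValueError("need at least 2 pairs")
    d = social - individual
    sd = d.std(ddof=1)
    mean = d.mean()
    se = sd / np.sqrt(n)

    if kind == "t":
        if sd == 0:
            raise ZeroDivisionError(
                "paired t statistic undefined: zero variance of differences"
            )
        res = stats.ttest_rel(social, individual)
        statistic, p, df = float(res.statistic), float(res.pvalue), float(n - 1)
    elif kind == "wilcoxon":
        statistic = _signed_rank_sum(d)
        nz = d[d != 0]
        if nz.size == 0:
            raise ZeroDivisionError("all paired differences are zero")
        p = float(stats.wilcoxon(nz, method="auto").pvalue)
        df = None
    else:
        raise ValueError(f"unknown test kind {kind!r}")

    dz = mean / sd if sd > 0 else np.nan
    tcrit = stats.t.ppf(0.5 + ci_level / 2.0, n - 1)
    return PairedTestResult(
        parameter=parameter, kind=kind, statistic=statistic, df=df, p=p,
        mean_difference=float(mean), se_difference=float(se),
        cohen_dz=float(dz), ci_low=float(mean - tcrit * se),
        ci_high=float(mean + tcrit * se), n=n,
    )


def behavioral_report(
    subject_table: pd.DataFrame, alpha: float = 0.05
) -> pd.DataFrame:
    """Run the normality gate and the chosen paired test for every parameter.

    ``subject_table`` is the (subject, condition)-indexed table from
    :func:`subject_parameter_table`; it must contain both conditions for every
    subject. Returns one row per parameter in the shape of the published
    kinematics table.
    """
    wide = subject_table.unstack("condition")
    missing = [
        (param, cond)
        for param in subject_table.columns
        for cond in ("social", "individual")
        if (param, cond) not in wide.columns or wide[(param, cond)].isna().any()
    ]
    if missing:
        raise ValueError(f"missing subject/condition cells: {missing}")

    rows = []
    for param in subject_table.columns:
        soc = wide[(param, "social")].to_numpy()
        ind = wide[(param, "individual")].to_numpy()
        kind = normality_gate(soc - ind, alpha=alpha)
        rows.append(paired_test(soc, ind, kind, parameter=param).as_dict())
    return pd.DataFrame(rows).set_index("parameter")
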