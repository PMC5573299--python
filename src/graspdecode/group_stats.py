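"""Group-level inference on decoding accuracies.

Four analyses over the subjects x ROI accuracy grid:

* one-tailed one-sample t-tests of each ROI's accuracy against the 50%
  chance level (the only meaningful direction for a binary classifier);
* two-sided paired t-tests between left- and right-hemisphere accuracies of
  each bilateral ROI;
* a one-way repeated-measures ANOVA with ROI as the within-subject factor,
  Greenhouse-Geisser corrected for sphericity violation;
* Pearson correlations between all ROI accuracy pairs with Benjamini-
  Hochberg FDR adjustment (two-sided p-values before correction).
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd
import pingouin as pg
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ttest_vs_chance",
    "chance_level_table",
    "hemisphere_comparison",
    "rm_anova_roi",
    "correlate_accuracies",
    "group_report",
]


def _acc_matrix(acc: pd.DataFrame, hemisphere: str = "both") -> pd.DataFrame:
    """Pivot a tidy accuracy table to a complete subjects x ROI grid."""
    df = acc
    if "hemisphere" in df.columns:
        df = df[df["hemisphere"] == hemisphere]
    wide = df.pivot(index="subject", columns="roi", values="accuracy")
    if wide.isna().any().any():
        missing = [
            (s, r) for s in wide.index for r in wide.columns
            if pd.isna(wide.loc[s, r])
        ]
        raise ValueError(f"incomplete accuracy grid: missing {missing}")
    return wide


def ttest_vs_chance(accuracies: np.ndarray, chance: float = 0.5) -> dict:
    """Upper-tailed one-sample t-test of a per-subject accuracy vector
    against chance.

    Returns mean accuracy, mean difference from chance, SE, t, df, one-tailed
    p, Cohen's d (mean difference / SD) and the one-sided 95% CI lower bound
    (upper bound is 1 by construction of the one-tailed test).
    """
    a = np.asarray(accuracies, dtype=float)
    n = a.size
    if n < 2:
        raise ValueError("need at least 2 subjects")
    d = a - chance
    sd = d.std(ddof=1)
    if sd == 0:
        raise ZeroDivisionError("zero variance of accuracies: t undefined")
    se = sd / np.sqrt(n)
    t = d.mean() / se
    p = float(stats.t.sf(t, n - 1))
    tcrit = stats.t.ppf(0.95, n - 1)
    return {
        "mean_accuracy": float(a.mean()),
        "mean_difference": float(d.mean()),
        "se": float(se),
        "t": float(t),
        "df": n - 1,
        "p": p,
        "cohen_d": float(d.mean() / sd),
        "ci_lower": float(a.mean() - tcrit * se),
    }


def chance_level_table(acc: pd.DataFrame, chance: float = 0.5,
                       hemisphere: str = "both") -> pd.DataFrame:
    """One row of :func:`ttest_vs_chance` per ROI."""
    wide = _acc_matrix(acc, hemisphere)
    return pd.DataFrame(
        {roi: ttest_vs_chance(wide[roi].to_numpy(), chance) for roi in wide.columns}
    ).T.rename_axis("roi")


def hemisphere_comparison(acc: pd.DataFrame, ci_level: float = 0.95) -> pd.DataFrame:
    """Two-sided paired t-test (left vs right) per bilateral ROI.

    Expects a tidy table with hemisphere values "L" and "R"; ROIs lacking
    either hemisphere raise.
    """
    left = _acc_matrix(acc, "L")
    right = _acc_matrix(acc, "R")
    if set(left.columns) != set(right.columns):
        raise ValueError(
            f"hemisphere mismatch: L={sorted(left.columns)} R={sorted(right.columns)}"
        )
    rows = {}
    for roi in left.columns:
        d = left[roi].to_numpy() - right[roi].to_numpy()
        n = d.size
        sd = d.std(ddof=1)
        if sd == 0:
            raise ZeroDivisionError(f"zero variance of L-R differences in {roi}")
        se = sd / np.sqrt(n)
        res = stats.ttest_rel(left[roi], right[roi])
        tcrit = stats.t.ppf(0.5 + ci_level / 2, n - 1)
        rows[roi] = {
            "t": float(res.statistic), "df": n - 1, "p": float(res.pvalue),
            "mean_difference": float(d.mean()), "se": float(se),
            "cohen_dz": float(d.mean() / sd),
            "ci_low": float(d.mean() - tcrit * se),
            "ci_high": float(d.mean() + tcrit * se),
        }
    return pd.DataFrame(rows).T.rename_axis("roi")


def rm_anova_roi(acc: pd.DataFrame, hemisphere: str = "both") -> dict:
    """One-way repeated-measures ANOVA on accuracies, ROI within-subject.

    The Greenhouse-Geisser epsilon is always applied: both degrees of freedom
    are multiplied by epsilon and the p-value is evaluated on the corrected
    distribution.
    """
    wide = _acc_matrix(acc, hemisphere)
    k, n = wide.shape[1], wide.shape[0]
    centred = wide.sub(wide.mean(axis=1), axis=0)
    if np.allclose(centred.to_numpy(), 0.0):
        # no within-subject ROI variation at all: F degenerates to 0
        return {"F": 0.0, "df1": float(k - 1), "df2": float((k - 1) * (n - 1)),
                "p_gg": 1.0, "eps": 1.0, "p_uncorrected": 1.0}
    long = wide.reset_index().melt(
        id_vars="subject", var_name="roi", value_name="accuracy"
    )
    res = pg.rm_anova(
        data=long, dv="accuracy", within="roi", subject="subject",
        correction=True, detailed=True,
    ).set_index("Source")
    eps = float(res.loc["roi", "eps"])
    p_gg = res.loc["roi", "p_GG_corr"] if "p_GG_corr" in res.columns else np.nan
    if np.isnan(p_gg):  # k = 2 or exact sphericity: correction is a no-op
        p_gg = res.loc["roi", "p_unc"]
    return {
        "F": float(res.loc["roi", "F"]),
        "df1": eps * (k - 1),
        "df2": eps * (k - 1) * (n - 1),
        "p_gg": float(p_gg),
        "eps": eps,
        "p_uncorrected": float(res.loc["roi", "p_unc"]),
    }


def correlate_accuracies(acc: pd.DataFrame, hemisphere: str = "both") -> pd.DataFrame:
    """Pearson correlation of every ROI accuracy pair, BH-FDR adjusted.

    Two-sided p-values enter a Benjamini-Hochberg step-up adjustment across
    all pairs. The report is invariant to ROI ordering (pairs are listed in
    sorted-name order).
    """
    wide = _acc_matrix(acc, hemisphere)
    if wide.shape[0] < 3:
        raise ValueError("need at least 3 subjects for correlations")
    zero_var = [roi for roi in wide.columns if wide[roi].std(ddof=1) < 1e-12]
    if zero_var:
        raise ZeroDivisionError(f"zero-variance accuracy column(s): {zero_var}")
    rows = []
    for a, b in combinations(sorted(wide.columns), 2):
        r, p = stats.pearsonr(wide[a], wide[b])
        rows.append({"roi_a": a, "roi_b": b, "r": float(r), "p": float(p)})
    out = pd.DataFrame(rows)
    out["p_fdr"] = multipletests(out["p"], method="fdr_bh")[1]
    return out


def group_report(acc: pd.DataFrame, chance: float = 0.5) -> dict:
    """Bundle all group analyses available for a tidy accuracy table.

    Hemisphere-resolved analyses are included only when the table carries
    "L"/"R" rows.
    """
    report = {
        "chance": chance_level_table(acc, chance),
        "anova": rm_anova_roi(acc),
        "correlations": correlate_accuracies(acc),
    }
    if "hemisphere" in acc.columns and {"L", "R"} <= set(acc["hemisphere"]):
        hemi = acc[acc["hemisphere"].isin(["L", "R"])]
        report["hemispheres"] = hemisphere_comparison(hemi)
    return report
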