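"""Per-peak class-comparison statistics (differential peak discovery).

For every consensus peak, the class-conditional mean ± SD of the peak area is
compared between mutation-positive and wild-type samples with Welch's t-test
(primary, used for ranking) and the Wilcoxon rank-sum test; Benjamini-Hochberg
adjusted p-values are reported alongside, but the significant set is defined
on the raw Welch p at ``alpha`` to match the study design this reimplements.
Invalid samples are excluded listwise.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sp_stats
from statsmodels.stats.multitest import multipletests

from serumpep.preprocess import FeatureMatrix
from serumpep.simulate import MUTANT, WILD

UP = "up_in_mutant"
DOWN = "down_in_mutant"


def differential_peaks(matrix: FeatureMatrix, labels, alpha: float = 0.05) -> pd.DataFrame:
    """Rank consensus peaks by class difference.

    Parameters
    ----------
    matrix:
        The cohort feature matrix.
    labels:
        Per-sample true class, aligned with ``matrix.sample_ids``;
        values ``"mutant"`` / ``"wild"``.
    alpha:
        Raw-p significance cut for the ``significant`` column.

    Returns a table with one row per peak, sorted by ascending Welch p:
    columns ``centroid, mean_wild, sd_wild, mean_mutant, sd_mutant, p_welch,
    p_ranksum, p_welch_bh, direction, significant``.
    """
    labels = np.asarray(labels)
    valid = matrix.valid_mask()
    keep_m = valid & (labels == MUTANT)
    keep_w = valid & (labels == WILD)
    classes = set(labels[valid])
    if classes - {MUTANT, WILD}:
        raise ValueError(f"unknown class labels: {classes - {MUTANT, WILD}}")
    if keep_m.sum() < 3 or keep_w.sum() < 3:
        raise ValueError("need >= 3 valid samples per class")

    rows = []
    for j, peak in enumerate(matrix.peak_definitions):
        xm = matrix.areas[keep_m, j]
        xw = matrix.areas[keep_w, j]
        if np.std(xm) == 0 and np.std(xw) == 0 and np.mean(xm) == np.mean(xw):
            p_w, p_r = 1.0, 1.0
        else:
            p_w = float(sp_stats.ttest_ind(xm, xw, equal_var=False).pvalue)
            p_r = float(sp_stats.mannwhitneyu(xm, xw, alternative="two-sided",
                                              method="auto").pvalue)
        rows.append({
            "centroid": peak.centroid,
            "mean_wild": float(np.mean(xw)), "sd_wild": float(np.std(xw, ddof=1)),
            "mean_mutant": float(np.mean(xm)), "sd_mutant": float(np.std(xm, ddof=1)),
            "p_welch": p_w, "p_ranksum": p_r,
            "direction": UP if np.mean(xm) >= np.mean(xw) else DOWN,
        })
    df = pd.DataFrame(rows)
    df["p_welch_bh"] = multipletests(df["p_welch"], method="fdr_bh")[1]
    df["significant"] = df["p_welch"] < alpha
    return df.sort_values("p_welch", kind="mergesort").reset_index(drop=True)


def welch_t(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Welch's t statistic, degrees of freedom and two-sided p (convenience)."""
    res = sp_stats.ttest_ind(x, y, equal_var=False)
    nx, ny = len(x), len(y)
    vx, vy = np.var(x, ddof=1) / nx, np.var(y, ddof=1) / ny
    dof = (vx + vy) ** 2 / (vx**2 / (nx - 1) + vy**2 / (ny - 1))
    return float(res.statistic), float(dof), float(res.pvalue)
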