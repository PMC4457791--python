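"""Blinded-test concordance and clinical-outcome evaluation.

Concordance between the serum classifier and the tissue assay uses the
conventions of the study this pipeline reimplements: unclassifiable
(invalid-spectrum) samples count against sensitivity, specificity and
accuracy — the classifier gets no credit for declining — but are excluded
from Cohen's kappa, which is defined on the 2x2 table of actual calls.

Outcome analysis links predicted labels to RECIST response (objective
response rate = CR+PR, disease control rate = CR+PR+SD; chi-squared without
continuity correction and Fisher's exact test) and to right-censored
progression-free/overall survival (Kaplan-Meier curves via lifelines, with
log(-log)-transformed median confidence intervals, and the two-group
log-rank test).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sp_stats
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from lifelines.utils import median_survival_times

from serumpep.simulate import MUTANT, WILD

RESPONSE_CATEGORIES = ("CR", "PR", "SD", "PD")
OBJECTIVE = ("CR", "PR")
CONTROLLED = ("CR", "PR", "SD")


@dataclass
class ConfusionSummary:
    """Concordance of predicted vs tissue-assay mutation status."""

    tp: int
    fn: int
    fp: int
    tn: int
    invalid_mutant: int
    invalid_wild: int
    sensitivity_pct: float
    specificity_pct: float
    accuracy_pct: float
    kappa: float  # NaN when undefined
    kappa_p: float

    @property
    def total(self) -> int:
        return (self.tp + self.fn + self.fp + self.tn
                + self.invalid_mutant + self.invalid_wild)


def cohen_kappa(table) -> tuple[float, float]:
    """Cohen's kappa for a 2x2 agreement table, with a large-sample z-test
    of kappa = 0.

    ``table[i][j]`` counts truth class i (mutant, wild) against predicted
    class j. Returns ``(nan, nan)`` when chance agreement is 1 (degenerate
    margins), in which case kappa is undefined.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or np.any(t < 0) or np.any(t != np.round(t)):
        raise ValueError("expected a 2x2 nonnegative integer table")
    n = t.sum()
    if n == 0:
        raise ValueError("empty table")
    p = t / n
    po = float(np.trace(p))
    row, col = p.sum(axis=1), p.sum(axis=0)
    pe = float(row @ col)
    if pe >= 1.0 - 1e-15:
        return float("nan"), float("nan")
    kappa = (po - pe) / (1.0 - pe)
    # null-hypothesis standard error of kappa (Fleiss, Cohen & Everitt)
    se0_sq = (pe + pe**2 - float(sum(row[i] * col[i] * (row[i] + col[i])
                                     for i in range(2))))
    se0 = math.sqrt(max(se0_sq, 0.0)) / ((1.0 - pe) * math.sqrt(n))
    if se0 == 0:
        return float(kappa), float("nan")
    z = kappa / se0
    pval = 2.0 * (1.0 - sp_stats.norm.cdf(abs(z)))
    return float(kappa), float(pval)


def confusion_summary(records: pd.DataFrame) -> ConfusionSummary:
    """Score predicted labels against the tissue-assay truth.

    ``records`` needs columns ``truth`` (mutant/wild) and ``predicted``
    (mutant/wild/unclassifiable).
    """
    if len(records) == 0:
        raise ValueError("no records")
    truth = records["truth"].to_numpy()
    pred = records["predicted"].to_numpy()
    tp = int(((truth == MUTANT) & (pred == MUTANT)).sum())
    fn = int(((truth == MUTANT) & (pred == WILD)).sum())
    fp = int(((truth == WILD) & (pred == MUTANT)).sum())
    tn = int(((truth == WILD) & (pred == WILD)).sum())
    inv_m = int(((truth == MUTANT) & (pred == "unclassifiable")).sum())
    inv_w = int(((truth == WILD) & (pred == "unclassifiable")).sum())

    def pct(num, den):
        return 100.0 * num / den if den else 0.0

    sens = pct(tp, tp + fn + inv_m)
    spec = pct(tn, tn + fp + inv_w)
    acc = pct(tp + tn, tp + fn + fp + tn + inv_m + inv_w)
    if tp + fn + fp + tn > 0:
        kappa, kp = cohen_kappa([[tp, fn], [fp, tn]])
    else:
        kappa, kp = float("nan"), float("nan")
    return ConfusionSummary(tp=tp, fn=fn, fp=fp, tn=tn,
                            invalid_mutant=inv_m, invalid_wild=inv_w,
                            sensitivity_pct=sens, specificity_pct=spec,
                            accuracy_pct=acc, kappa=kappa, kappa_p=kp)


@dataclass
class ResponseTable:
    """Per-predicted-label RECIST summary plus association tests."""

    table: pd.DataFrame  # rows per label: counts, ORR %, DCR %
    orr_chi2_p: float
    orr_fisher_p: float
    dcr_chi2_p: float
    dcr_fisher_p: float
    warnings: list = field(default_factory=list)


def response_table(records: pd.DataFrame) -> ResponseTable:
    """Objective-response and disease-control rates by predicted label.

    Only TKI-treated patients with a recorded response and a definite
    predicted label enter; a label with zero patients is omitted with a
    warning. The chi-squared test is computed without continuity correction;
    Fisher's exact test is reported alongside.
    """
    df = records.copy()
    if "tki_treated" in df.columns:
        df = df[df["tki_treated"].astype(bool)]
    df = df[df["predicted"].isin([MUTANT, WILD])
            & df["response"].isin(RESPONSE_CATEGORIES)]
    warns = []
    rows = []
    counts = {}
    for label in (MUTANT, WILD):
        sub = df[df["predicted"] == label]
        if len(sub) == 0:
            warns.append(f"no evaluable patients labeled {label}; omitted")
            continue
        c = {cat: int((sub["response"] == cat).sum()) for cat in RESPONSE_CATEGORIES}
        n = len(sub)
        n_obj = sum(c[cat] for cat in OBJECTIVE)
        n_ctrl = sum(c[cat] for cat in CONTROLLED)
        counts[label] = (n_obj, n_ctrl, n)
        rows.append({"predicted": label, **c, "n": n,
                     "orr_pct": 100.0 * n_obj / n, "dcr_pct": 100.0 * n_ctrl / n})
    table = pd.DataFrame(rows)

    def tests(idx):
        if len(counts) < 2:
            return float("nan"), float("nan")
        a_m = counts[MUTANT][idx]
        a_w = counts[WILD][idx]
        t = np.array([[a_m, counts[MUTANT][2] - a_m],
                      [a_w, counts[WILD][2] - a_w]])
        if t.sum(axis=0).min() == 0 or t.sum(axis=1).min() == 0:
            chi_p = 1.0
        else:
            chi_p = float(sp_stats.chi2_contingency(t, correction=False)[1])
        fisher_p = float(sp_stats.fisher_exact(t, alternative="two-sided")[1])
        return chi_p, fisher_p

    orr_chi, orr_fish = tests(0)
    dcr_chi, dcr_fish = tests(1)
    return ResponseTable(table=table, orr_chi2_p=orr_chi, orr_fisher_p=orr_fish,
                         dcr_chi2_p=dcr_chi, dcr_fisher_p=dcr_fish, warnings=warns)


@dataclass
class KMResult:
    """A Kaplan-Meier fit: step curve, median and its 95% CI (inf = not reached)."""

    curve: pd.DataFrame  # columns: time, survival
    median: float
    median_ci: tuple


def km_estimate(times, events) -> KMResult:
    """Product-limit survival estimate with median and 95% CI.

    The median is the earliest time where S(t) <= 0.5; confidence limits come
    from the log(-log)-transformed (exponential Greenwood) pointwise bands.
    ``inf`` encodes "not reached".
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events).astype(bool)
    if np.any(times < 0):
        raise ValueError("negative survival time")
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    curve = kmf.survival_function_.reset_index()
    curve.columns = ["time", "survival"]
    median = float(kmf.median_survival_time_)
    ci_df = median_survival_times(kmf.confidence_interval_)
    lo, hi = float(ci_df.iloc[0, 0]), float(ci_df.iloc[0, 1])
    return KMResult(curve=curve, median=median, median_ci=(lo, hi))


def logrank(times_a, events_a, times_b, events_b) -> tuple[float, float]:
    """Two-group log-rank test (1 df). Returns ``(chi2, p)``;
    ``(nan, nan)`` when there are no events in either group."""
    ta, tb = np.asarray(times_a, float), np.asarray(times_b, float)
    ea = np.asarray(events_a).astype(bool)
    eb = np.asarray(events_b).astype(bool)
    if len(ta) == 0 or len(tb) == 0:
        raise ValueError("both groups must be non-empty")
    if ea.sum() + eb.sum() == 0:
        return float("nan"), float("nan")
    res = _ll_logrank(ta, tb, event_observed_A=ea, event_observed_B=eb)
    return float(res.test_statistic), float(res.p_value)
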