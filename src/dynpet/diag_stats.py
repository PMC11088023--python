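"""Diagnostic statistics: group comparisons, ROC cut-offs, cohort reports.

The clinical workflow this layer reproduces: for each metabolic parameter
(SUVmax, K1, k2, k3, Ki) compare two groups with a normality-gated test
(Shapiro-Wilk on each group; Welch t-test with mean +/- SD summaries when
both pass, Wilcoxon rank-sum with median [IQR] summaries otherwise), then
build an ROC curve, select the Youden-optimal cut-off and report
sensitivity/specificity/AUC with a bootstrap confidence interval.

No multiple-testing correction is applied (per-comparison alpha = 0.05),
matching common practice in this literature.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score

from .framing import ValidationError

__all__ = [
    "GroupComparison",
    "ROCResult",
    "compare_groups",
    "roc_analysis",
    "classify_at_cutoff",
    "cohort_report",
    "PARAMETERS",
]

PARAMETERS = ["suv_max", "k1", "k2", "k3", "ki"]

_POSITIVE_CLASS = {"malignancy": "malignant", "histology": "SCC", "egfr": "positive"}
_MISSING_LABEL = {"malignancy": {}, "histology": {"none", "other"}, "egfr": {"untested"}}


@dataclass
class GroupComparison:
    """Two-group test result with summaries matching the test used."""

    parameter: str
    n_a: int
    n_b: int
    test: str  # "t_test" | "wilcoxon"
    statistic: float
    p_value: float
    summary_a: dict
    summary_b: dict

    def format_summary(self, which: str = "a") -> str:
        s = self.summary_a if which == "a" else self.summary_b
        if self.test == "t_test":
            return f"{s['mean']:.4g} (±{s['sd']:.4g})"
        return f"{s['median']:.4g} [{s['q1']:.4g};{s['q3']:.4g}]"


@dataclass
class ROCResult:
    auc: float
    ci: tuple[float, float]
    cutoff: float
    sensitivity: float
    specificity: float
    direction: str  # "higher" | "lower": which side of the cutoff is test-positive


def _summaries(x: np.ndarray) -> dict:
    q1, med, q3 = np.percentile(x, [25, 50, 75])
    return {
        "mean": float(np.mean(x)),
        "sd": float(np.std(x, ddof=1)),
        "median": float(med),
        "q1": float(q1),
        "q3": float(q3),
        "n": int(x.size),
    }


def compare_groups(
    values_a, values_b, alpha: float = 0.05, parameter: str = "", test: str = "auto"
) -> GroupComparison:
    """Normality-gated two-group comparison.

    Shapiro-Wilk on each group at ``alpha``; if both look normal, Welch's
    unequal-variance t-test (summaries mean +/- SD), otherwise the Wilcoxon
    rank-sum (Mann-Whitney U, two-sided, summaries median [IQR]).  ``test``
    may force a branch ('t_test' | 'wilcoxon') instead of gating.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 3 or b.size < 3:
        raise ValidationError("each group needs n >= 3 for the normality gate")
    if test not in ("auto", "t_test", "wilcoxon"):
        raise ValidationError("test must be 'auto', 't_test' or 'wilcoxon'")
    if test == "auto":
        # Shapiro is undefined for constant samples; treat those as non-normal
        normal = True
        for x in (a, b):
            if np.ptp(x) == 0:
                normal = False
                break
            if stats.shapiro(x).pvalue <= alpha:
                normal = False
                break
    else:
        normal = test == "t_test"
    if normal:
        res = stats.ttest_ind(a, b, equal_var=False)
        test = "t_test"
    else:
        res = stats.mannwhitneyu(a, b, alternative="two-sided")
        test = "wilcoxon"
    return GroupComparison(
        parameter=parameter,
        n_a=a.size,
        n_b=b.size,
        test=test,
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        summary_a=_summaries(a),
        summary_b=_summaries(b),
    )


def _sens_spec(scores, y, cutoff, direction):
    pos_test = scores > cutoff if direction == "higher" else scores < cutoff
    tp = int(np.sum(pos_test & (y == 1)))
    fn = int(np.sum(~pos_test & (y == 1)))
    tn = int(np.sum(~pos_test & (y == 0)))
    fp = int(np.sum(pos_test & (y == 0)))
    sens = tp / (tp + fn) if tp + fn else 0.0
    spec = tn / (tn + fp) if tn + fp else 0.0
    return sens, spec, {"tp": tp, "fn": fn, "tn": tn, "fp": fp}


def roc_analysis(
    scores, labels, n_boot: int = 2000, seed: int = 0
) -> ROCResult:
    """ROC with Youden-optimal cut-off and stratified bootstrap AUC CI.

    The orientation is chosen automatically so AUC >= 0.5 and recorded in
    ``direction``.  AUC uses the midrank Mann-Whitney formulation (ties get
    half credit).  Candidate cut-offs are midpoints between adjacent
    observed unique scores plus +/-inf; Youden ties resolve to the lowest
    cut-off.  The percentile CI comes from ``n_boot`` class-stratified
    resamples under ``seed``.
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    if y.dtype.kind in "USO":
        raise ValidationError("labels must be binary 0/1 integers or booleans")
    y = y.astype(int)
    if set(np.unique(y)) != {0, 1}:
        raise ValidationError("both classes must be present in labels")
    if n_boot < 100:
        raise ValidationError("n_boot must be >= 100")
    auc = float(roc_auc_score(y, scores))
    direction = "higher"
    if auc < 0.5:
        direction = "lower"
        auc = 1.0 - auc
    oriented = scores if direction == "higher" else -scores

    uniq = np.unique(scores)
    if uniq.size > 1:
        mids = (uniq[:-1] + uniq[1:]) / 2.0
        cand = np.concatenate([[-np.inf], mids, [np.inf]])
    else:
        cand = np.array([-np.inf, np.inf])
    best_j, best_cut, best = -np.inf, -np.inf, (0.0, 0.0)
    for cut in cand:
        sens, spec, _ = _sens_spec(scores, y, cut, direction)
        j = sens + spec - 1.0
        if j > best_j + 1e-12:
            best_j, best_cut, best = j, cut, (sens, spec)

    rng = np.random.default_rng(seed)
    pos = np.where(y == 1)[0]
    neg = np.where(y == 0)[0]
    boots = np.empty(n_boot)
    for i in range(n_boot):
        idx = np.concatenate(
            [rng.choice(pos, pos.size, replace=True), rng.choice(neg, neg.size, replace=True)]
        )
        boots[i] = roc_auc_score(y[idx], oriented[idx])
    lo, hi = np.percentile(boots, [2.5, 97.5])
    ci = (min(float(lo), auc), max(float(hi), auc))
    return ROCResult(
        auc=auc, ci=ci, cutoff=float(best_cut),
        sensitivity=best[0], specificity=best[1], direction=direction,
    )


def classify_at_cutoff(
    scores, labels, cutoff: float, direction: str = "higher"
) -> tuple[float, float, dict]:
    """Sensitivity/specificity of the threshold rule at a fixed cut-off.

    "Test positive" means score strictly above the cut-off when
    ``direction='higher'`` (strictly below for ``'lower'``).
    """
    if direction not in ("higher", "lower"):
        raise ValidationError("direction must be 'higher' or 'lower'")
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(int)
    if set(np.unique(y)) != {0, 1}:
        raise ValidationError("both classes must be present in labels")
    return _sens_spec(scores, y, cutoff, direction)


def cohort_report(
    cohort: pd.DataFrame,
    grouping: str = "malignancy",
    *,
    seed: int = 0,
    n_boot: int = 2000,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-parameter comparison + ROC block for a binary grouping.

    One row per metabolic parameter with the group summaries, the gated
    test and its p-value, and the ROC quantities (sensitivity, specificity,
    cut-off, AUC with CI).  Rows whose grouping label is missing (e.g.
    EGFR 'untested' under the egfr grouping) raise an error listing the
    offending lesion ids.
    """
    if grouping not in _POSITIVE_CLASS:
        raise ValidationError(f"grouping must be one of {sorted(_POSITIVE_CLASS)}")
    if grouping not in cohort.columns:
        raise ValidationError(f"cohort lacks a {grouping!r} column")
    missing_vals = _MISSING_LABEL[grouping]
    bad = cohort[cohort[grouping].isna() | cohort[grouping].isin(missing_vals)]
    if len(bad):
        raise ValidationError(
            f"lesions without a usable {grouping!r} label: {', '.join(bad['lesion_id'].astype(str))}"
        )
    classes = sorted(cohort[grouping].unique())
    if len(classes) != 2:
        raise ValidationError(f"grouping {grouping!r} must be binary, found {classes}")
    pos_label = _POSITIVE_CLASS[grouping]
    neg_label = next(c for c in classes if c != pos_label)
    a = cohort[cohort[grouping] == neg_label]
    b = cohort[cohort[grouping] == pos_label]

    rows = []
    for j, param in enumerate(PARAMETERS):
        cmp_res = compare_groups(a[param], b[param], alpha=alpha, parameter=param)
        y = (cohort[grouping] == pos_label).to_numpy().astype(int)
        roc = roc_analysis(
            cohort[param].to_numpy(), y, n_boot=n_boot, seed=seed + j
        )
        rows.append(
            {
                "parameter": param,
                "group_a": neg_label,
                "group_b": pos_label,
                "summary_a": cmp_res.format_summary("a"),
                "summary_b": cmp_res.format_summary("b"),
                "test": cmp_res.test,
                "p_value": cmp_res.p_value,
                "sensitivity": roc.sensitivity,
                "specificity": roc.specificity,
                "cutoff": roc.cutoff,
                "auc": roc.auc,
                "ci_low": roc.ci[0],
                "ci_high": roc.ci[1],
            }
        )
    return pd.DataFrame(rows)
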