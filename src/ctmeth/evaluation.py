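"""Diagnostic evaluation of cumulative-methylation scores.

Covers the statistics used to characterize a binary ctDNA methylation
classifier: nonparametric group comparison (Mann-Whitney U with an exact
small-sample path), ROC analysis with pair-counting AUC and a DeLong
confidence interval, Youden threshold selection, confusion-matrix metrics
with Wilson score intervals and the positive likelihood ratio, Spearman rank
concordance for duplicate/interplatform measurements, and descriptive
summaries of longitudinal score trajectories.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

from .core_model import DEFAULT_CONSTANTS, AlgorithmConstants, InputError

#: largest pooled sample size for which the exact Mann-Whitney null is enumerated
EXACT_MW_LIMIT = 12


@dataclass(frozen=True)
class MannWhitneyResult:
    u: float
    p_value: float
    method: str  # "exact" or "asymptotic"


@dataclass(frozen=True)
class RocResult:
    thresholds: tuple[float, ...]
    sensitivity: tuple[float, ...]
    specificity: tuple[float, ...]
    auc: float
    auc_se: float
    auc_ci: tuple[float, float]
    best_threshold: float


@dataclass(frozen=True)
class ConfusionMetrics:
    tp: int
    fn: int
    tn: int
    fp: int
    threshold: float
    sensitivity: float
    specificity: float
    accuracy: float
    sensitivity_ci: tuple[float, float]
    specificity_ci: tuple[float, float]
    accuracy_ci: tuple[float, float]
    positive_likelihood_ratio: Optional[float]  # None when specificity == 1


@dataclass(frozen=True)
class GroupDescriptives:
    n: int
    minimum: float
    q25: float
    median: float
    q75: float
    maximum: float
    mean: float
    mean_ci: tuple[float, float]


@dataclass(frozen=True)
class EvaluationReport:
    n_cancer: int
    n_control: int
    descriptives: dict[str, GroupDescriptives]
    mann_whitney: MannWhitneyResult
    roc: RocResult
    confusion: ConfusionMetrics
    threshold: float
    threshold_derived: bool


@dataclass(frozen=True)
class TrajectorySummary:
    subject_id: str
    days: tuple[int, ...]
    cm: tuple[float, ...]
    baseline_cm: float
    delta_from_baseline: tuple[float, ...]
    directions: tuple[str, ...]  # per interval: "rise" | "fall" | "flat"


def _as_float_array(values, name: str) -> np.ndarray:
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise InputError(f"{name} must contain at least one value")
    return arr


def _exact_mw_p(a: np.ndarray, b: np.ndarray, u1: float) -> float:
    """Exact two-sided p by enumerating all assignments of pooled ranks.

    Only called for tie-free pooled samples of total size <= EXACT_MW_LIMIT;
    the two-sided p doubles the smaller tail, capped at 1.
    """
    n1 = a.size
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    offset = n1 * (n1 + 1) / 2.0
    us = [
        sum(combo) - offset
        for combo in itertools.combinations(ranks, n1)
    ]
    us = np.asarray(us)
    total = us.size
    p_le = np.count_nonzero(us <= u1) / total
    p_ge = np.count_nonzero(us >= u1) / total
    return min(1.0, 2.0 * min(p_le, p_ge))


def mann_whitney_test(group_a, group_b) -> MannWhitneyResult:
    """Mann-Whitney U test (two-sided) between two score groups.

    U is computed with average ranks for ties.  For tie-free pooled samples of
    at most 12 observations the two-sided p is exact by enumeration; otherwise
    a normal approximation with tie correction and continuity correction is
    used.  All-tied degenerate input yields p = 1.
    """
    a = _as_float_array(group_a, "group_a")
    b = _as_float_array(group_b, "group_b")
    n1, n2 = a.size, b.size
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    u1 = float(ranks[:n1].sum() - n1 * (n1 + 1) / 2.0)
    has_ties = np.unique(pooled).size < pooled.size
    if n1 + n2 <= EXACT_MW_LIMIT and not has_ties:
        return MannWhitneyResult(u=u1, p_value=_exact_mw_p(a, b, u1), method="exact")
    n = n1 + n2
    mu = n1 * n2 / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts)).sum())
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0.0:
        return MannWhitneyResult(u=u1, p_value=1.0, method="asymptotic")
    # continuity correction shrinks |U - mu| by 0.5 toward the mean
    z = (abs(u1 - mu) - 0.5) / math.sqrt(var)
    z = max(z, 0.0)
    p = min(1.0, 2.0 * stats.norm.sf(z))
    return MannWhitneyResult(u=u1, p_value=p, method="asymptotic")


def _delong_se(case_scores: np.ndarray, control_scores: np.ndarray) -> float:
    """DeLong standard error of the pair-counting AUC (ties weighted 1/2)."""
    psi = (case_scores[:, None] > control_scores[None, :]).astype(float)
    psi += 0.5 * (case_scores[:, None] == control_scores[None, :])
    v10 = psi.mean(axis=1)  # per-case placement
    v01 = psi.mean(axis=0)  # per-control placement
    m, n = case_scores.size, control_scores.size
    s10 = float(np.var(v10, ddof=1)) if m > 1 else 0.0
    s01 = float(np.var(v01, ddof=1)) if n > 1 else 0.0
    return math.sqrt(s10 / m + s01 / n)


def roc_auc(scores, labels) -> RocResult:
    """ROC analysis of *scores* against boolean *labels* (True = case).

    The AUC is the concordant-pair fraction with ties counted 1/2 (equal to
    U / (n1 * n0)).  Candidate thresholds sit at midpoints between consecutive
    distinct pooled scores, with -inf/+inf endpoints; a positive call is score
    strictly greater than the threshold.  ``best_threshold`` maximizes
    sensitivity + specificity (Youden), ties broken toward higher specificity.
    The AUC confidence interval is DeLong's, clipped to [0, 1].
    """
    scores = _as_float_array(scores, "scores")
    labels = np.asarray(list(labels), dtype=bool)
    if scores.size != labels.size:
        raise InputError("scores and labels must have the same length")
    cases = scores[labels]
    controls = scores[~labels]
    if cases.size == 0 or controls.size == 0:
        raise InputError("both classes must be present for ROC analysis")

    ranks = stats.rankdata(scores)
    m, n = cases.size, controls.size
    auc = float((ranks[labels].sum() - m * (m + 1) / 2.0) / (m * n))

    distinct = np.unique(scores)
    mids = (distinct[:-1] + distinct[1:]) / 2.0
    thresholds = np.concatenate([[-np.inf], mids, [np.inf]])
    sens = np.array([(cases > t).mean() for t in thresholds])
    spec = np.array([(controls <= t).mean() for t in thresholds])

    youden = sens + spec
    best_j = youden.max()
    candidates = np.flatnonzero(np.isclose(youden, best_j))
    # among Youden-optimal thresholds prefer higher specificity, then the
    # larger (more conservative) threshold
    best_spec = spec[candidates].max()
    candidates = candidates[np.isclose(spec[candidates], best_spec)]
    best_threshold = float(thresholds[candidates].max())

    se = _delong_se(cases, controls)
    half = 1.959963984540054 * se
    ci = (max(0.0, auc - half), min(1.0, auc + half))
    return RocResult(
        thresholds=tuple(float(t) for t in thresholds),
        sensitivity=tuple(float(s) for s in sens),
        specificity=tuple(float(s) for s in spec),
        auc=auc,
        auc_se=se,
        auc_ci=ci,
        best_threshold=best_threshold,
    )


def _wilson(count: int, nobs: int) -> tuple[float, float]:
    if nobs == 0:
        return (float("nan"), float("nan"))
    lo, hi = proportion_confint(count, nobs, alpha=0.05, method="wilson")
    return (float(lo), float(hi))


def confusion_metrics(
    scores,
    labels,
    threshold: float,
    constants: AlgorithmConstants = DEFAULT_CONSTANTS,
) -> ConfusionMetrics:
    """Confusion-matrix metrics at a fixed CM threshold.

    A sample is called positive iff its score is strictly greater than the
    threshold; a score exactly on the cutoff is a negative call.  Sensitivity,
    specificity and accuracy carry Wilson 95% intervals; LR+ = sensitivity /
    (1 - specificity) is None (undefined) when specificity is exactly 1.
    """
    threshold = float(threshold)
    if not math.isfinite(threshold):
        raise InputError("threshold must be finite")
    scores = _as_float_array(scores, "scores")
    labels = np.asarray(list(labels), dtype=bool)
    if scores.size != labels.size:
        raise InputError("scores and labels must have the same length")
    positive = scores > threshold
    tp = int(np.count_nonzero(positive & labels))
    fn = int(np.count_nonzero(~positive & labels))
    fp = int(np.count_nonzero(positive & ~labels))
    tn = int(np.count_nonzero(~positive & ~labels))
    n_pos, n_neg, n = tp + fn, tn + fp, tp + fn + tn + fp
    sens = tp / n_pos if n_pos else float("nan")
    spec = tn / n_neg if n_neg else float("nan")
    acc = (tp + tn) / n
    if spec == 1.0:
        lr = None
    elif math.isnan(spec):
        lr = None
    else:
        lr = sens / (1.0 - spec)
    return ConfusionMetrics(
        tp=tp,
        fn=fn,
        tn=tn,
        fp=fp,
        threshold=threshold,
        sensitivity=sens,
        specificity=spec,
        accuracy=acc,
        sensitivity_ci=_wilson(tp, n_pos),
        specificity_ci=_wilson(tn, n_neg),
        accuracy_ci=_wilson(tp + tn, n),
        positive_likelihood_ratio=lr,
    )


def spearman_concordance(x, y) -> tuple[float, float]:
    """Spearman rank correlation (average ranks for ties) with two-sided p.

    The p-value uses the t-distribution approximation; requires paired inputs
    of equal length n >= 3.
    """
    x = _as_float_array(x, "x")
    y = _as_float_array(y, "y")
    if x.size != y.size:
        raise InputError("x and y must be paired (equal length)")
    if x.size < 3:
        raise InputError("Spearman concordance requires n >= 3 pairs")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


def _describe(values: np.ndarray) -> GroupDescriptives:
    n = values.size
    mean = float(values.mean())
    if n > 1 and values.std(ddof=1) > 0:
        half = float(stats.t.ppf(0.975, n - 1) * values.std(ddof=1) / math.sqrt(n))
    else:
        half = 0.0
    return GroupDescriptives(
        n=n,
        minimum=float(values.min()),
        q25=float(np.percentile(values, 25)),
        median=float(np.median(values)),
        q75=float(np.percentile(values, 75)),
        maximum=float(values.max()),
        mean=mean,
        mean_ci=(mean - half, mean + half),
    )


def evaluate_cohort(
    cm_values,
    group_labels: Sequence[str],
    threshold: Union[float, str] = "derive",
    constants: AlgorithmConstants = DEFAULT_CONSTANTS,
) -> EvaluationReport:
    """Full cohort evaluation of CM scores against cancer vs. benign/normal labels.

    Benign and normal samples are pooled into a single control class.  With
    ``threshold="derive"`` the Youden-optimal threshold is derived from this
    cohort (training mode); passing a number evaluates at that locked cutoff
    (test mode).
    """
    cm = _as_float_array(cm_values, "cm_values")
    labels = [str(l) for l in group_labels]
    if len(labels) != cm.size:
        raise InputError("cm_values and group_labels must have the same length")
    known = {"cancer", "benign", "normal"}
    unknown = sorted(set(labels) - known)
    if unknown:
        raise InputError(f"unknown group labels {unknown}; expected one of {sorted(known)}")
    is_case = np.array([l == "cancer" for l in labels], dtype=bool)
    n_cancer = int(is_case.sum())
    n_control = int((~is_case).sum())
    if n_cancer < 2 or n_control < 2:
        raise InputError("need at least 2 samples per class")

    mw = mann_whitney_test(cm[is_case], cm[~is_case])
    roc = roc_auc(cm, is_case)
    if isinstance(threshold, str):
        if threshold != "derive":
            raise InputError("threshold must be a number or the string 'derive'")
        thr, derived = roc.best_threshold, True
    else:
        thr, derived = float(threshold), False
    confusion = confusion_metrics(cm, is_case, thr, constants)
    descriptives = {
        "cancer": _describe(cm[is_case]),
        "control": _describe(cm[~is_case]),
    }
    return EvaluationReport(
        n_cancer=n_cancer,
        n_control=n_control,
        descriptives=descriptives,
        mann_whitney=mw,
        roc=roc,
        confusion=confusion,
        threshold=thr,
        threshold_derived=derived,
    )


def summarize_trajectory(
    subject_id: str,
    points: Sequence[tuple[int, float]],
    flat_tolerance: float = 5.0,
) -> TrajectorySummary:
    """Describe a subject's serial CM draws relative to baseline.

    *points* are (draw_day, CM) pairs; they are sorted by day and the earliest
    draw is taken as baseline.  Each consecutive interval is labelled "rise",
    "fall" or "flat" using ``flat_tolerance`` (CM units) as the dead band; the
    labels are descriptive only, not a formal progression rule.
    """
    pts = sorted((int(d), float(c)) for d, c in points)
    if len(pts) < 2:
        raise InputError("trajectory summary requires at least 2 draws")
    days = tuple(d for d, _ in pts)
    if len(set(days)) != len(days):
        raise InputError(f"subject {subject_id!r}: duplicate draw days")
    cm = tuple(c for _, c in pts)
    baseline = cm[0]
    deltas = tuple(c - baseline for c in cm)
    directions = []
    for prev, curr in zip(cm, cm[1:]):
        change = curr - prev
        if change > flat_tolerance:
            directions.append("rise")
        elif change < -flat_tolerance:
            directions.append("fall")
        else:
            directions.append("flat")
    return TrajectorySummary(
        subject_id=subject_id,
        days=days,
        cm=cm,
        baseline_cm=baseline,
        delta_from_baseline=deltas,
        directions=tuple(directions),
    )
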