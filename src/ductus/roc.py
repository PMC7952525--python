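"""Empirical ROC curves, Youden cut-offs and 2x2 diagnostic performance.

Operating points are taken at the midpoints between adjacent distinct score
values (plus -inf/+inf sentinels), so integer staging scores yield half-point
cut-offs such as 4.5.  The trapezoidal area under the resulting curve is, by
construction, identical to the Mann-Whitney estimator
P(score_pos > score_neg) + 0.5 P(tie); both are exposed and tested against
each other.

Orientation: the *positive* class is the treated (hemodynamically
significant) group, and test-positive means a score **above** the cut-off.
This is the orientation under which the 2x2 sensitivity/specificity/PPV/NPV
are jointly consistent; a score below the cut-off therefore predicts early
spontaneous closure.  Proportion confidence intervals use the Wilson score
method.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from statsmodels.stats.proportion import proportion_confint

from .errors import DegenerateInputError, InvalidInputError
from .staging import StagingScheme

__all__ = [
    "ROCResult",
    "Proportion",
    "DiagnosticPerformance",
    "roc_curve",
    "auc_mann_whitney",
    "youden_cutoff",
    "diagnostic_performance",
    "predictive_values_from_rates",
    "compare_schemes",
]


def _check_scores_labels(scores, labels) -> Tuple[np.ndarray, np.ndarray]:
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    if y.dtype == bool:
        y = y.astype(int)
    y = y.astype(float)
    if s.shape != y.shape or s.ndim != 1:
        raise InvalidInputError("scores and labels must be equal-length 1-d arrays")
    if np.isnan(s).any():
        raise InvalidInputError("scores contain missing values")
    if not np.isin(y, (0.0, 1.0)).all():
        raise InvalidInputError("labels must be binary 0/1")
    if y.min() == y.max():
        raise DegenerateInputError("both classes must be present")
    return s, y.astype(int)


@dataclass
class ROCResult:
    """Threshold sweep: sensitivity/specificity per candidate cut-off."""

    thresholds: np.ndarray  # ascending, with -inf/+inf sentinels
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    positive_high: bool = True

    @property
    def fpr(self) -> np.ndarray:
        return 1.0 - self.specificity

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "threshold": self.thresholds,
                "sensitivity": self.sensitivity,
                "specificity": self.specificity,
            }
        )


def roc_curve(scores, labels, positive_high: bool = True) -> ROCResult:
    """Empirical ROC over midpoint thresholds; AUC by the trapezoidal rule."""
    s, y = _check_scores_labels(scores, labels)
    work = s if positive_high else -s
    distinct = np.unique(work)
    mids = (distinct[:-1] + distinct[1:]) / 2.0
    thresholds = np.concatenate(([-np.inf], mids, [np.inf]))
    n_pos = int(y.sum())
    n_neg = len(y) - n_pos
    sens = np.empty(len(thresholds))
    spec = np.empty(len(thresholds))
    for i, t in enumerate(thresholds):
        pred_pos = work > t
        sens[i] = np.sum(pred_pos & (y == 1)) / n_pos
        spec[i] = np.sum(~pred_pos & (y == 0)) / n_neg
    # thresholds ascend, so the (FPR, TPR) staircase is traversed from (1,1)
    # down to (0,0); integrate in reverse threshold order to keep vertical
    # segments (duplicate FPR) from being reordered
    auc = float(np.trapezoid(sens[::-1], (1.0 - spec)[::-1]))
    if not positive_high:
        thresholds = -thresholds  # back to the original score scale (descending)
    return ROCResult(
        thresholds=thresholds,
        sensitivity=sens,
        specificity=spec,
        auc=auc,
        positive_high=positive_high,
    )


def auc_mann_whitney(scores, labels, positive_high: bool = True) -> float:
    """AUC as P(score_pos > score_neg) + 0.5 P(tie) via midranks."""
    s, y = _check_scores_labels(scores, labels)
    if not positive_high:
        s = -s
    n_pos = int(y.sum())
    n_neg = len(y) - n_pos
    ranks = rankdata(s)  # midranks for ties
    rank_sum_pos = ranks[y == 1].sum()
    u = rank_sum_pos - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def youden_cutoff(roc: ROCResult) -> Tuple[float, float]:
    """Threshold maximising J = sensitivity + specificity - 1.

    Ties go to the operating point with higher sensitivity, then (on the
    positive-high scale) the lower threshold.
    """
    j = roc.sensitivity + roc.specificity - 1.0
    work = roc.thresholds if roc.positive_high else -roc.thresholds
    best = None
    for t, s, jj in zip(work, roc.sensitivity, j):
        if not math.isfinite(t):
            continue
        key = (jj, s, -t)
        if best is None or key > best[0]:
            best = (key, t, jj)
    if best is None:  # no finite threshold (all scores identical)
        raise DegenerateInputError("no finite threshold available (single score value)")
    t = best[1] if roc.positive_high else -best[1]
    return float(t), float(best[2])


@dataclass(frozen=True)
class Proportion:
    """A binomial proportion with its Wilson confidence interval.

    ``defined`` is False when the denominator is empty (e.g. PPV with no
    test-positives); the estimate is then NaN rather than a silent 0.
    """

    numerator: int
    denominator: int
    estimate: float
    ci_low: float
    ci_high: float
    defined: bool = True


def _wilson(numerator: int, denominator: int, confidence: float) -> Proportion:
    if denominator == 0:
        return Proportion(numerator, 0, float("nan"), float("nan"), float("nan"), False)
    low, high = proportion_confint(
        numerator, denominator, alpha=1 - confidence, method="wilson"
    )
    return Proportion(
        numerator, denominator, numerator / denominator, float(low), float(high)
    )


@dataclass(frozen=True)
class DiagnosticPerformance:
    tp: int
    fp: int
    fn: int
    tn: int
    sensitivity: Proportion
    specificity: Proportion
    ppv: Proportion
    npv: Proportion
    cutoff: Optional[float] = None


def performance_from_counts(
    tp: int, fp: int, fn: int, tn: int, confidence: float = 0.95, cutoff=None
) -> DiagnosticPerformance:
    """Sens/spec/PPV/NPV (Wilson CIs) from a 2x2 table of counts."""
    for name, v in (("tp", tp), ("fp", fp), ("fn", fn), ("tn", tn)):
        if int(v) != v or v < 0:
            raise InvalidInputError(f"{name} must be a non-negative integer")
    return DiagnosticPerformance(
        tp=tp,
        fp=fp,
        fn=fn,
        tn=tn,
        sensitivity=_wilson(tp, tp + fn, confidence),
        specificity=_wilson(tn, tn + fp, confidence),
        ppv=_wilson(tp, tp + fp, confidence),
        npv=_wilson(tn, tn + fn, confidence),
        cutoff=cutoff,
    )


def diagnostic_performance(
    scores,
    labels,
    cutoff: float,
    positive_high: bool = True,
    confidence: float = 0.95,
) -> DiagnosticPerformance:
    """2x2 performance at a cut-off (test-positive = score above it)."""
    s, y = _check_scores_labels(scores, labels)
    pred = s > cutoff if positive_high else s < cutoff
    tp = int(np.sum(pred & (y == 1)))
    fp = int(np.sum(pred & (y == 0)))
    fn = int(np.sum(~pred & (y == 1)))
    tn = int(np.sum(~pred & (y == 0)))
    return performance_from_counts(tp, fp, fn, tn, confidence, cutoff=cutoff)


def predictive_values_from_rates(
    sensitivity: float, specificity: float, prevalence: float
) -> Tuple[float, float]:
    """PPV/NPV implied by sensitivity, specificity and prevalence (Bayes).

    A consistency check tying the four reported metrics together; returns NaN
    (not 0) for an undefined value when a denominator vanishes.
    """
    for name, v in (
        ("sensitivity", sensitivity),
        ("specificity", specificity),
        ("prevalence", prevalence),
    ):
        if not 0 <= v <= 1:
            raise InvalidInputError(f"{name} must be in [0, 1], got {v}")
    ppv_den = sensitivity * prevalence + (1 - specificity) * (1 - prevalence)
    npv_den = specificity * (1 - prevalence) + (1 - sensitivity) * prevalence
    ppv = sensitivity * prevalence / ppv_den if ppv_den > 0 else float("nan")
    npv = specificity * (1 - prevalence) / npv_den if npv_den > 0 else float("nan")
    return ppv, npv


def compare_schemes(
    cohort: pd.DataFrame,
    schemes: Sequence[StagingScheme],
    confidence: float = 0.95,
) -> pd.DataFrame:
    """Score a cohort under each scheme and tabulate AUC/cut-off/performance.

    One row per scheme, shaped like a score-model comparison table: AUC,
    Youden cut-off, and sens/spec/PPV/NPV at that cut-off.  The positive
    class is the treated (``IBT``) group.
    """
    from .io import score_cohort  # local import to avoid a cycle

    if not schemes:
        raise InvalidInputError("at least one scheme is required")
    labels = (cohort["group"] == "IBT").to_numpy()
    rows = []
    for scheme in schemes:
        scored = score_cohort(cohort, scheme, overwrite=True)
        scores = scored["pda_score"].to_numpy(dtype=float)
        roc = roc_curve(scores, labels)
        cutoff, j = youden_cutoff(roc)
        perf = diagnostic_performance(scores, labels, cutoff, confidence=confidence)
        rows.append(
            {
                "scheme": scheme.name,
                "auc": roc.auc,
                "cutoff": cutoff,
                "youden_j": j,
                "sensitivity": perf.sensitivity.estimate,
                "specificity": perf.specificity.estimate,
                "ppv": perf.ppv.estimate,
                "npv": perf.npv.estimate,
            }
        )
    return pd.DataFrame(rows)
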