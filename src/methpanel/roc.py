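"""Empirical ROC analysis, locked thresholds, and prevalence-adjusted metrics.

The classification score is the panel CMI (or a single gene's %M); a sample
is called carcinoma when ``score >= threshold``.  Candidate thresholds are
the midpoints between consecutive distinct observed scores plus +/-inf
sentinels — on data quantized to integers or one decimal this yields
thresholds ending in .0 or .5.

The operating threshold is chosen on *training* data only: among candidates
whose training specificity meets a floor (default 90%), pick the one
maximizing sensitivity, breaking ties toward the largest (most conservative)
cutoff.  The resulting :class:`LockedThreshold` is immutable and is applied
unchanged to test data.

Diagnostic predictive values are prevalence-adjusted:

    %PPV = 100 * se*pi / (se*pi + (1-sp)*(1-pi))
    %NPV = 100 * sp*(1-pi) / ((1-se)*pi + sp*(1-pi))
    %Accuracy = 100 * (se*pi + sp*(1-pi))

with se = sensitivity, sp = specificity, pi = prevalence (default 0.01).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.stats import beta as beta_dist
from scipy.stats import norm, rankdata

from .core import ValidationError

DEFAULT_SPECIFICITY_FLOOR = 0.90
DEFAULT_PREVALENCE = 0.01


# ROC curve -------------------------------------------------------------------


@dataclass(frozen=True)
class RocCurve:
    """Empirical ROC: thresholds descending, positive call = score >= t."""

    thresholds: np.ndarray  # descending; +inf first, -inf last
    sensitivity: np.ndarray
    specificity: np.ndarray
    n_pos: int
    n_neg: int

    def auc(self) -> float:
        """Trapezoidal area under sensitivity vs (1 - specificity)."""
        fpr = 1.0 - self.specificity
        order = np.argsort(fpr, kind="stable")
        return float(np.trapezoid(self.sensitivity[order], fpr[order]))


def _check_groups(scores_pos: Sequence[float], scores_neg: Sequence[float]):
    pos = np.asarray(scores_pos, dtype=float)
    neg = np.asarray(scores_neg, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise ValidationError("ROC needs nonempty positive and negative groups")
    if np.isnan(pos).any() or np.isnan(neg).any():
        raise ValidationError("ROC scores contain NaN")
    return pos, neg


def candidate_thresholds(scores_pos, scores_neg) -> np.ndarray:
    """Midpoints between consecutive distinct pooled scores, +/-inf sentinels."""
    pos, neg = _check_groups(scores_pos, scores_neg)
    distinct = np.unique(np.concatenate([pos, neg]))
    mids = (distinct[:-1] + distinct[1:]) / 2.0
    return np.concatenate([[np.inf], mids[::-1], [-np.inf]])


def roc_curve(scores_pos, scores_neg) -> RocCurve:
    pos, neg = _check_groups(scores_pos, scores_neg)
    thr = candidate_thresholds(pos, neg)
    sens = np.array([(pos >= t).mean() for t in thr])
    spec = np.array([(neg < t).mean() for t in thr])
    return RocCurve(thr, sens, spec, pos.size, neg.size)


def auc(scores_pos, scores_neg) -> float:
    """Empirical AUC; equals the Mann-Whitney U / (n1*n2) identity."""
    return roc_curve(scores_pos, scores_neg).auc()


# Locked threshold ------------------------------------------------------------


@dataclass(frozen=True)
class LockedThreshold:
    """A CMI cutoff fixed on training data; immutable once created."""

    value: float
    specificity_floor: float
    training_sensitivity: float
    training_specificity: float
    provenance: str = ""


def lock_threshold(
    scores_pos,
    scores_neg,
    specificity_floor: float = DEFAULT_SPECIFICITY_FLOOR,
    provenance: str = "",
) -> LockedThreshold:
    """Maximize training sensitivity subject to specificity >= floor.

    The +inf sentinel (specificity 1, sensitivity 0) guarantees feasibility.
    Among equally sensitive feasible thresholds the largest is returned.
    """
    if not 0.0 <= specificity_floor <= 1.0:
        raise ValidationError("specificity_floor must be in [0, 1]")
    curve = roc_curve(scores_pos, scores_neg)
    feasible = curve.specificity >= specificity_floor
    sens = np.where(feasible, curve.sensitivity, -1.0)
    best_sens = sens.max()
    # thresholds are descending; first index attaining best_sens is largest t
    i = int(np.argmax(sens == best_sens))
    return LockedThreshold(
        value=float(curve.thresholds[i]),
        specificity_floor=float(specificity_floor),
        training_sensitivity=float(curve.sensitivity[i]),
        training_specificity=float(curve.specificity[i]),
        provenance=provenance,
    )


# Confusion counts and predictive values --------------------------------------


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int


def confusion_at(scores_pos, scores_neg, threshold: float) -> ConfusionCounts:
    pos, neg = _check_groups(scores_pos, scores_neg)
    tp = int((pos >= threshold).sum())
    fp = int((neg >= threshold).sum())
    return ConfusionCounts(tp=tp, fp=fp, tn=neg.size - fp, fn=pos.size - tp)


@dataclass(frozen=True)
class PredictiveValues:
    """PPV/NPV/accuracy in percent at a stated prevalence.

    ``ppv``/``npv`` are NaN with the matching ``*_defined`` flag False when
    the defining ratio is 0/0 (e.g. PPV at sensitivity 0, specificity 1).
    """

    ppv: float
    npv: float
    accuracy: float
    prevalence: float
    ppv_defined: bool = True
    npv_defined: bool = True


def predictive_values(
    sensitivity: float, specificity: float, prevalence: float = DEFAULT_PREVALENCE
) -> PredictiveValues:
    for name, v in (("sensitivity", sensitivity), ("specificity", specificity),
                    ("prevalence", prevalence)):
        if not 0.0 <= v <= 1.0:
            raise ValidationError(f"{name} must be in [0, 1], got {v}")
    se, sp, pi = sensitivity, specificity, prevalence
    ppv_num = se * pi
    ppv_den = se * pi + (1.0 - sp) * (1.0 - pi)
    npv_num = sp * (1.0 - pi)
    npv_den = (1.0 - se) * pi + sp * (1.0 - pi)
    ppv_defined = ppv_den > 0.0
    npv_defined = npv_den > 0.0
    return PredictiveValues(
        ppv=100.0 * ppv_num / ppv_den if ppv_defined else float("nan"),
        npv=100.0 * npv_num / npv_den if npv_defined else float("nan"),
        accuracy=100.0 * (se * pi + sp * (1.0 - pi)),
        prevalence=pi,
        ppv_defined=ppv_defined,
        npv_defined=npv_defined,
    )


# Confidence intervals --------------------------------------------------------


def clopper_pearson(k: int, n: int, confidence: float = 0.95) -> tuple[float, float]:
    """Exact binomial (Clopper-Pearson) two-sided CI for a proportion."""
    if not 0 <= k <= n or n == 0:
        raise ValidationError(f"invalid counts k={k}, n={n}")
    a = 1.0 - confidence
    lo = 0.0 if k == 0 else float(beta_dist.ppf(a / 2.0, k, n - k + 1))
    hi = 1.0 if k == n else float(beta_dist.ppf(1.0 - a / 2.0, k + 1, n - k))
    return lo, hi


def _midrank_placements(x: np.ndarray, pooled: np.ndarray) -> np.ndarray:
    # placement of each x among pooled, with ties counted half
    all_ranks = rankdata(np.concatenate([x, pooled]))[: x.size]
    own_ranks = rankdata(x)
    return all_ranks - own_ranks


def delong_auc_ci(
    scores_pos, scores_neg, confidence: float = 0.95
) -> tuple[float, tuple[float, float]]:
    """AUC with DeLong asymptotic CI (degenerate variance collapses the CI)."""
    pos, neg = _check_groups(scores_pos, scores_neg)
    m, n = pos.size, neg.size
    v10 = _midrank_placements(pos, neg) / n        # P(neg < pos_i)
    v01 = 1.0 - _midrank_placements(neg, pos) / m  # P(neg_j < pos)
    a = float(np.mean(v10))
    var = (np.var(v10, ddof=1) / m if m > 1 else 0.0) + (
        np.var(v01, ddof=1) / n if n > 1 else 0.0
    )
    if var <= 0:
        return a, (a, a)
    z = float(norm.ppf(0.5 + confidence / 2.0))
    half = z * math.sqrt(var)
    return a, (max(0.0, a - half), min(1.0, a + half))


def bootstrap_auc_ci(
    scores_pos, scores_neg, confidence: float = 0.95,
    n_boot: int = 2000, seed: int = 0,
) -> tuple[float, tuple[float, float]]:
    """Stratified bootstrap percentile CI for the AUC (seeded)."""
    pos, neg = _check_groups(scores_pos, scores_neg)
    rng = np.random.default_rng(seed)
    a = auc(pos, neg)
    stats = np.empty(n_boot)
    for i in range(n_boot):
        bp = rng.choice(pos, pos.size, replace=True)
        bn = rng.choice(neg, neg.size, replace=True)
        stats[i] = auc(bp, bn)
    alpha = 1.0 - confidence
    lo, hi = np.quantile(stats, [alpha / 2.0, 1.0 - alpha / 2.0])
    return a, (float(lo), float(hi))


# Locked evaluation -----------------------------------------------------------


@dataclass(frozen=True)
class PerformanceReport:
    sensitivity: float
    sensitivity_ci: tuple[float, float]
    specificity: float
    specificity_ci: tuple[float, float]
    auc: float
    auc_ci: tuple[float, float]
    ppv: float
    npv: float
    accuracy: float
    prevalence: float
    threshold: float
    confusion: ConfusionCounts
    n_pos: int
    n_neg: int
    ppv_defined: bool = True
    npv_defined: bool = True

    def to_dict(self) -> dict:
        return {
            "threshold": self.threshold,
            "n_pos": self.n_pos,
            "n_neg": self.n_neg,
            "confusion": {"tp": self.confusion.tp, "fp": self.confusion.fp,
                          "tn": self.confusion.tn, "fn": self.confusion.fn},
            "sensitivity": self.sensitivity,
            "sensitivity_ci": list(self.sensitivity_ci),
            "specificity": self.specificity,
            "specificity_ci": list(self.specificity_ci),
            "auc": self.auc,
            "auc_ci": list(self.auc_ci),
            "ppv_percent": self.ppv,
            "npv_percent": self.npv,
            "accuracy_percent": self.accuracy,
            "prevalence": self.prevalence,
            "ppv_defined": self.ppv_defined,
            "npv_defined": self.npv_defined,
        }


def evaluate_locked(
    scores_pos,
    scores_neg,
    locked: LockedThreshold,
    prevalence: float = DEFAULT_PREVALENCE,
    auc_ci_method: str = "delong",
    seed: int = 0,
) -> PerformanceReport:
    """Apply a locked threshold to (test) scores and report performance.

    The threshold is used exactly as locked; test data never re-optimize it.
    """
    if not 0.0 < prevalence < 1.0:
        raise ValidationError("prevalence must be in (0, 1)")
    cc = confusion_at(scores_pos, scores_neg, locked.value)
    sens = cc.tp / (cc.tp + cc.fn)
    spec = cc.tn / (cc.tn + cc.fp)
    if auc_ci_method == "delong":
        a, a_ci = delong_auc_ci(scores_pos, scores_neg)
    elif auc_ci_method == "bootstrap":
        a, a_ci = bootstrap_auc_ci(scores_pos, scores_neg, seed=seed)
    else:
        raise ValidationError(f"unknown auc_ci_method {auc_ci_method!r}")
    pv = predictive_values(sens, spec, prevalence)
    return PerformanceReport(
        sensitivity=sens,
        sensitivity_ci=clopper_pearson(cc.tp, cc.tp + cc.fn),
        specificity=spec,
        specificity_ci=clopper_pearson(cc.tn, cc.tn + cc.fp),
        auc=a,
        auc_ci=a_ci,
        ppv=pv.ppv,
        npv=pv.npv,
        accuracy=pv.accuracy,
        prevalence=prevalence,
        threshold=locked.value,
        confusion=cc,
        n_pos=cc.tp + cc.fn,
        n_neg=cc.tn + cc.fp,
        ppv_defined=pv.ppv_defined,
        npv_defined=pv.npv_defined,
    )
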