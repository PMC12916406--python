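"""Threshold-independent evaluation: ROC, DeLong inference, Youden calibration.

The AUC is the Mann–Whitney probability that a pathogenic variant scores
more damaging than a benign one (ties count ½). Its variance follows
DeLong's nonparametric estimator from per-observation placement values:
with ψ(x, y) = 1 if x is more damaging, ½ if tied, 0 otherwise,

    V10_i = mean_j ψ(pos_i, neg_j),   V01_j = mean_i ψ(pos_i, neg_j),
    var(AUC) = S10/m + S01/n,

where S10, S01 are the sample variances of the placements and m, n the
class sizes. The Wald 95% CI is truncated to [0, 1]; the p-value against
AUC = 0.5 is the two-sided normal test.

Gene-specific threshold calibration maximizes Youden's J = sens + spec − 1
over candidate thresholds — midpoints of consecutive distinct score values
plus sentinel extremes (configurable to observed values). All computation
happens on the oriented ("larger = more damaging") scale; reported
thresholds are mapped back to each tool's raw scale.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .metrics import ConfusionMatrix, MetricsSet, metrics
from .registry import HIGHER_DAMAGING, ToolSpec

logger = logging.getLogger(__name__)

MIDPOINT = "midpoint"
OBSERVED = "observed"


class RocError(ValueError):
    pass


def _validate(pos: np.ndarray, neg: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    pos = np.asarray(pos, dtype=float)
    neg = np.asarray(neg, dtype=float)
    pos = pos[~np.isnan(pos)]
    neg = neg[~np.isnan(neg)]
    if len(pos) == 0 or len(neg) == 0:
        raise RocError("need at least one score in each class")
    return pos, neg


@dataclass(frozen=True)
class RocCurve:
    """Operating points indexed by candidate threshold (oriented scale).

    A variant is called deleterious iff its oriented score >= threshold, so
    thresholds are listed descending: the first sentinel (+inf) calls
    nothing deleterious (sens 0, spec 1) and the last (-inf) calls
    everything (sens 1, spec 0).
    """

    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    n_pos: int
    n_neg: int

    def __len__(self) -> int:
        return len(self.thresholds)


@dataclass(frozen=True)
class AucResult:
    auc: float
    variance: float
    ci_low: float
    ci_high: float
    p_vs_half: float
    n_pos: int
    n_neg: int
    degenerate: bool = False  # zero variance with AUC at 0 or 1

    def to_dict(self) -> dict:
        return {
            "auc": self.auc,
            "variance": self.variance,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "p_vs_half": self.p_vs_half,
            "n_pos": self.n_pos,
            "n_neg": self.n_neg,
            "degenerate": self.degenerate,
        }


@dataclass(frozen=True)
class ThresholdReport:
    best_threshold: float  # raw score scale of the tool
    youden_j: float
    metrics_at_best: MetricsSet
    confusion_at_best: ConfusionMatrix
    ties: tuple[float, ...] = ()

    def to_dict(self) -> dict:
        return {
            "best_threshold": self.best_threshold,
            "youden_j": self.youden_j,
            "metrics_at_best": self.metrics_at_best.to_dict(),
            "confusion_at_best": {
                "tp": self.confusion_at_best.tp,
                "fp": self.confusion_at_best.fp,
                "tn": self.confusion_at_best.tn,
                "fn": self.confusion_at_best.fn,
            },
            "ties": list(self.ties),
        }


def _candidate_thresholds(
    pos: np.ndarray, neg: np.ndarray, convention: str
) -> np.ndarray:
    values = np.unique(np.concatenate([pos, neg]))  # ascending
    if convention == MIDPOINT:
        inner = (values[1:] + values[:-1]) / 2 if len(values) > 1 else np.empty(0)
    elif convention == OBSERVED:
        inner = values
    else:
        raise RocError(f"unknown threshold convention {convention!r}")
    return np.concatenate([[np.inf], inner[::-1], [-np.inf]])


def build_roc(
    pos_scores: Sequence[float],
    neg_scores: Sequence[float],
    convention: str = MIDPOINT,
) -> RocCurve:
    """ROC operating points over oriented scores (larger = more damaging)."""
    pos, neg = _validate(pos_scores, neg_scores)
    thresholds = _candidate_thresholds(pos, neg, convention)
    sens = np.array([(pos >= t).mean() for t in thresholds])
    spec = np.array([(neg < t).mean() for t in thresholds])
    return RocCurve(
        thresholds=thresholds,
        sensitivity=sens,
        specificity=spec,
        n_pos=len(pos),
        n_neg=len(neg),
    )


def _placements(pos: np.ndarray, neg: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Midrank-based placement values (ψ row/column means), O(N log N)."""
    m, n = len(pos), len(neg)
    combined = np.concatenate([pos, neg])
    ranks = stats.rankdata(combined)  # midranks
    pos_ranks = stats.rankdata(pos)
    neg_ranks = stats.rankdata(neg)
    v10 = (ranks[:m] - pos_ranks) / n
    v01 = 1.0 - (ranks[m:] - neg_ranks) / m
    return v10, v01


def auc(pos_scores: Sequence[float], neg_scores: Sequence[float]) -> float:
    """Mann–Whitney AUC: mean over all (pos, neg) pairs of ψ."""
    pos, neg = _validate(pos_scores, neg_scores)
    v10, _ = _placements(pos, neg)
    return float(v10.mean())


def delong_inference(
    pos_scores: Sequence[float],
    neg_scores: Sequence[float],
    level: float = 0.95,
) -> AucResult:
    """AUC with DeLong variance, Wald CI and two-sided p versus 0.5."""
    pos, neg = _validate(pos_scores, neg_scores)
    if len(pos) < 2 or len(neg) < 2:
        raise RocError("need >= 2 scores per class for a finite DeLong variance")
    if not 0 < level < 1:
        raise RocError(f"confidence level must be in (0, 1), got {level}")
    v10, v01 = _placements(pos, neg)
    a = float(v10.mean())
    var = float(np.var(v10, ddof=1) / len(pos) + np.var(v01, ddof=1) / len(neg))
    z = stats.norm.ppf(0.5 + level / 2)
    degenerate = var <= 0.0
    if degenerate:
        ci_low = ci_high = a
        p = 0.0 if a != 0.5 else 1.0
    else:
        se = math.sqrt(var)
        ci_low = max(0.0, a - z * se)
        ci_high = min(1.0, a + z * se)
        p = float(2 * stats.norm.sf(abs(a - 0.5) / se))
    return AucResult(
        auc=a,
        variance=var,
        ci_low=ci_low,
        ci_high=ci_high,
        p_vs_half=p,
        n_pos=len(pos),
        n_neg=len(neg),
        degenerate=degenerate,
    )


def youden_best(roc: RocCurve, orientation: str = HIGHER_DAMAGING) -> ThresholdReport:
    """Youden-optimal operating point with the full metric suite.

    Ties in J break toward higher specificity, then the stricter (larger
    oriented) threshold; every tied threshold is reported. Sentinel
    thresholds are eligible (they win only for pathological score sets).
    The reported threshold is mapped back to the raw scale for
    lower-damaging tools (raw = −oriented).
    """
    j = roc.sensitivity + roc.specificity - 1.0
    best_j = j.max()
    tied = np.flatnonzero(np.isclose(j, best_j, rtol=0, atol=1e-12))
    # higher specificity first, then the lower threshold
    order = sorted(
        tied, key=lambda i: (-roc.specificity[i], roc.thresholds[i])
    )
    win = order[0]
    t_oriented = roc.thresholds[win]
    sens, spec = roc.sensitivity[win], roc.specificity[win]
    tp = round(sens * roc.n_pos)
    fn = roc.n_pos - tp
    tn = round(spec * roc.n_neg)
    fp = roc.n_neg - tn
    cm = ConfusionMatrix(tp=tp, fp=fp, tn=tn, fn=fn)
    sign = 1.0 if orientation == HIGHER_DAMAGING else -1.0
    return ThresholdReport(
        best_threshold=float(sign * t_oriented),
        youden_j=float(best_j),
        metrics_at_best=metrics(cm),
        confusion_at_best=cm,
        ties=tuple(float(sign * roc.thresholds[i]) for i in order),
    )


@dataclass
class ToolEvaluation:
    tool: str
    n_pos: int
    n_neg: int
    auc: AucResult | None = None
    calibration: ThresholdReport | None = None
    default_metrics: MetricsSet | None = None
    default_confusion: ConfusionMatrix | None = None
    comparison_p: float | None = None
    skipped_reason: str | None = None


def evaluate_tool(
    tool: ToolSpec,
    pos_scores: Sequence[float],
    neg_scores: Sequence[float],
    level: float = 0.95,
    convention: str = MIDPOINT,
) -> ToolEvaluation:
    """DeLong inference + Youden calibration + default-threshold metrics for
    one tool's raw scores (orientation applied internally)."""
    from .registry import oriented

    pos, neg = _validate(pos_scores, neg_scores)
    opos, oneg = oriented(pos, tool), oriented(neg, tool)
    result = ToolEvaluation(tool=tool.name, n_pos=len(pos), n_neg=len(neg))
    result.auc = delong_inference(opos, oneg, level=level)
    roc = build_roc(opos, oneg, convention=convention)
    result.calibration = youden_best(roc, orientation=tool.orientation)
    if tool.recommended_threshold is not None:
        from .metrics import confusion
        from .registry import classify_at_threshold

        calls = [classify_at_threshold(s, tool) for s in np.concatenate([pos, neg])]
        labels = ["pathogenic"] * len(pos) + ["benign"] * len(neg)
        cm = confusion(calls, labels)
        result.default_confusion = cm
        result.default_metrics = metrics(cm)
    return result


def evaluate_all_tools(
    pm,
    variant_labels: dict[str, str],
    alpha: float = 0.05,
    level: float = 0.95,
    convention: str = MIDPOINT,
    comparison_policy: str = "auto",
) -> tuple[list[ToolEvaluation], dict]:
    """Run the full threshold-independent benchmark over a PredictionMatrix.

    Per the study design, each tool's score distributions are first compared
    between classes; tools whose comparison is not significant at ``alpha``
    are excluded from ROC analysis and flagged (never silently dropped).
    Returns per-tool evaluations plus summary statistics (AUC min/median/max).
    """
    from .score_statistics import compare_scores

    evaluations: list[ToolEvaluation] = []
    for tool in pm.tools:
        if not tool.has_continuous:
            evaluations.append(
                ToolEvaluation(tool=tool.name, n_pos=0, n_neg=0,
                               skipped_reason="no continuous output")
            )
            continue
        s = pm.scores[tool.name]
        keys = [v.format() for v in pm.variants]
        pos = np.array([s.iloc[i] for i, k in enumerate(keys)
                        if variant_labels.get(k) == "pathogenic"])
        neg = np.array([s.iloc[i] for i, k in enumerate(keys)
                        if variant_labels.get(k) == "benign"])
        pos, neg = pos[~np.isnan(pos)], neg[~np.isnan(neg)]
        if len(pos) < 3 or len(neg) < 3:
            evaluations.append(
                ToolEvaluation(tool=tool.name, n_pos=len(pos), n_neg=len(neg),
                               skipped_reason="fewer than 3 scored variants per class")
            )
            logger.warning("skipping %s: too few scored variants", tool.name)
            continue
        from .registry import oriented

        comp = compare_scores(oriented(pos, tool), oriented(neg, tool),
                              policy=comparison_policy)
        if comp.p_value >= alpha:
            ev = ToolEvaluation(
                tool=tool.name, n_pos=len(pos), n_neg=len(neg),
                comparison_p=comp.p_value,
                skipped_reason=f"class distributions not separated (p={comp.p_value:.3g})",
            )
            evaluations.append(ev)
            logger.warning("excluding %s from ROC: %s", tool.name, ev.skipped_reason)
            continue
        ev = evaluate_tool(tool, pos, neg, level=level, convention=convention)
        ev.comparison_p = comp.p_value
        evaluations.append(ev)
    aucs = [e.auc.auc for e in evaluations if e.auc is not None]
    summary = {
        "n_tools_evaluated": len(aucs),
        "n_tools_skipped": len(evaluations) - len(aucs),
        "auc_min": float(np.min(aucs)) if aucs else None,
        "auc_median": float(np.median(aucs)) if aucs else None,
        "auc_max": float(np.max(aucs)) if aucs else None,
    }
    return evaluations, summary
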