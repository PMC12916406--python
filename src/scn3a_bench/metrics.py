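"""Confusion matrices and the benchmark metric suite.

Positive class = pathogenic, predicted positive = deleterious. The suite:
accuracy, balanced accuracy ((sens+spec)/2, the ranking metric — robust to
the 20/45 class imbalance), sensitivity, specificity, PPV, NPV, F-score
(harmonic mean of precision and recall) and the Matthews correlation
coefficient

    MCC = (TP·TN − FP·FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN)).

Any metric with a zero denominator is *undefined* (None), never silently 0;
undefined balanced accuracy ranks a tool last.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

from .registry import DELETERIOUS, TOLERATED

POSITIVE_LABEL = "pathogenic"
NEGATIVE_LABEL = "benign"


class MetricsError(ValueError):
    pass


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise MetricsError("confusion counts must be non-negative")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def n_positive(self) -> int:
        return self.tp + self.fn

    @property
    def n_negative(self) -> int:
        return self.tn + self.fp


@dataclass(frozen=True)
class MetricsSet:
    accuracy: float | None
    balanced_accuracy: float | None
    sensitivity: float | None
    specificity: float | None
    ppv: float | None
    npv: float | None
    f_score: float | None
    mcc: float | None

    def to_dict(self) -> dict[str, float | None]:
        return {
            "accuracy": self.accuracy,
            "balanced_accuracy": self.balanced_accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "ppv": self.ppv,
            "npv": self.npv,
            "f_score": self.f_score,
            "mcc": self.mcc,
        }


def confusion(
    calls: Sequence[str], labels: Sequence[str]
) -> ConfusionMatrix:
    """Tabulate deleterious/tolerated calls against pathogenic/benign labels.

    Calls and labels must be aligned on the same variants; missing calls are
    excluded upstream (listwise per tool).
    """
    if len(calls) != len(labels):
        raise MetricsError(f"{len(calls)} calls vs {len(labels)} labels")
    if len(calls) == 0:
        raise MetricsError("empty input: no evaluated variants")
    tp = fp = tn = fn = 0
    for call, label in zip(calls, labels):
        if call not in (DELETERIOUS, TOLERATED):
            raise MetricsError(f"bad call {call!r}")
        if label not in (POSITIVE_LABEL, NEGATIVE_LABEL):
            raise MetricsError(f"bad label {label!r}")
        positive = label == POSITIVE_LABEL
        called = call == DELETERIOUS
        if positive and called:
            tp += 1
        elif positive:
            fn += 1
        elif called:
            fp += 1
        else:
            tn += 1
    return ConfusionMatrix(tp=tp, fp=fp, tn=tn, fn=fn)


def _ratio(num: int, den: int) -> float | None:
    return None if den == 0 else num / den


def metrics(cm: ConfusionMatrix) -> MetricsSet:
    """Derive the full metric suite from counts.

    Degenerate denominators yield None fields rather than exceptions: e.g.
    PPV is undefined when nothing is called deleterious.
    """
    sens = _ratio(cm.tp, cm.tp + cm.fn)
    spec = _ratio(cm.tn, cm.tn + cm.fp)
    ppv = _ratio(cm.tp, cm.tp + cm.fp)
    npv = _ratio(cm.tn, cm.tn + cm.fn)
    acc = _ratio(cm.tp + cm.tn, cm.n)
    bal = None if sens is None or spec is None else (sens + spec) / 2
    if ppv is None or sens is None or (ppv + sens) == 0:
        f = None
    else:
        f = 2 * ppv * sens / (ppv + sens)
    denom = (
        (cm.tp + cm.fp) * (cm.tp + cm.fn) * (cm.tn + cm.fp) * (cm.tn + cm.fn)
    )
    if denom == 0:
        mcc = None
    else:
        mcc = (cm.tp * cm.tn - cm.fp * cm.fn) / math.sqrt(denom)
    return MetricsSet(
        accuracy=acc,
        balanced_accuracy=bal,
        sensitivity=sens,
        specificity=spec,
        ppv=ppv,
        npv=npv,
        f_score=f,
        mcc=mcc,
    )


def rank_tools(results: Mapping[str, MetricsSet]) -> list[str]:
    """Rank tools by balanced accuracy (descending), ties by MCC then name.

    Tools with undefined balanced accuracy sort last.
    """
    if not results:
        raise MetricsError("no tools to rank")

    def key(item: tuple[str, MetricsSet]):
        name, ms = item
        bal = -math.inf if ms.balanced_accuracy is None else ms.balanced_accuracy
        mcc = -math.inf if ms.mcc is None else ms.mcc
        return (-bal, -mcc, name)

    return [name for name, _ in sorted(results.items(), key=key)]


def metrics_from_counts(tp: int, fp: int, tn: int, fn: int) -> MetricsSet:
    return metrics(ConfusionMatrix(tp=tp, fp=fp, tn=tn, fn=fn))
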