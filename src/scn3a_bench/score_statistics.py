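"""Two-group comparison of predictor scores with normality-gated test choice.

Per tool, the pathogenic and benign score distributions are compared with a
test selected by a fixed policy: Shapiro–Wilk normality in each group at
alpha; if both pass, an F-ratio equality-of-variance check decides between
Student's t (homogeneous) and Welch's t (heterogeneous); if either group is
non-normal, the Wilcoxon rank-sum test is used. A ``force_wilcoxon`` policy
skips the gate and always uses the rank-sum test.

The rank-sum p-value is exact (full enumeration) when both groups have
n <= 10 and the pooled sample is tie-free; otherwise it is the midrank
tie-corrected normal approximation with continuity correction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

STUDENT_T = "student_t"
WELCH_T = "welch_t"
WILCOXON = "wilcoxon_rank_sum"

AUTO = "auto"
FORCE_WILCOXON = "force_wilcoxon"


class ComparisonError(ValueError):
    pass


@dataclass(frozen=True)
class TestSelectionTrace:
    shapiro_p_pos: float | None
    shapiro_p_neg: float | None
    variance_test_p: float | None
    alpha: float = 0.05


@dataclass(frozen=True)
class ComparisonResult:
    tool: str
    test_used: str
    statistic: float
    p_value: float
    n_pos: int
    n_neg: int
    trace: TestSelectionTrace | None = None
    degenerate: bool = False  # constant pooled sample

    def to_dict(self) -> dict:
        return {
            "tool": self.tool,
            "test_used": self.test_used,
            "statistic": self.statistic,
            "p_value": self.p_value,
            "n_pos": self.n_pos,
            "n_neg": self.n_neg,
            "degenerate": self.degenerate,
        }


def _as_arrays(pos, neg) -> tuple[np.ndarray, np.ndarray]:
    pos = np.asarray(pos, dtype=float)
    neg = np.asarray(neg, dtype=float)
    pos = pos[~np.isnan(pos)]
    neg = neg[~np.isnan(neg)]
    if len(pos) < 3 or len(neg) < 3:
        raise ComparisonError(
            f"need >= 3 observations per group (got {len(pos)}, {len(neg)})"
        )
    return pos, neg


def _variance_ratio_test(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided F-ratio test of equal variances (normality assumed)."""
    va, vb = np.var(a, ddof=1), np.var(b, ddof=1)
    if va == 0 and vb == 0:
        return 1.0
    if vb == 0 or va == 0:
        return 0.0
    f = va / vb
    dfa, dfb = len(a) - 1, len(b) - 1
    p_one = stats.f.sf(f, dfa, dfb) if f >= 1 else stats.f.cdf(f, dfa, dfb)
    return float(min(1.0, 2 * p_one))


def select_test(
    pos_scores: Sequence[float],
    neg_scores: Sequence[float],
    alpha: float = 0.05,
) -> tuple[str, TestSelectionTrace]:
    """Choose the comparison test for two samples (see module docstring)."""
    pos, neg = _as_arrays(pos_scores, neg_scores)
    # Shapiro-Wilk is undefined on constant samples; constant = non-normal
    sw_pos = 0.0 if np.ptp(pos) == 0 else float(stats.shapiro(pos).pvalue)
    sw_neg = 0.0 if np.ptp(neg) == 0 else float(stats.shapiro(neg).pvalue)
    if sw_pos < alpha or sw_neg < alpha:
        return WILCOXON, TestSelectionTrace(sw_pos, sw_neg, None, alpha)
    var_p = _variance_ratio_test(pos, neg)
    test = STUDENT_T if var_p >= alpha else WELCH_T
    return test, TestSelectionTrace(sw_pos, sw_neg, var_p, alpha)


def _exact_rank_sum_p(pos: np.ndarray, neg: np.ndarray) -> float:
    """Exact two-sided rank-sum p by enumeration (tie-free samples)."""
    res = stats.mannwhitneyu(pos, neg, alternative="two-sided", method="exact")
    return float(res.pvalue)


def rank_sum_test(
    pos: np.ndarray, neg: np.ndarray
) -> tuple[float, float, bool]:
    """Wilcoxon rank-sum: (W statistic of the first group, two-sided p, exact?).

    W is the sum of pooled midranks of the first group. Exact enumeration
    when both n <= 10 and no ties across the pooled sample; otherwise the
    tie-corrected normal approximation with continuity correction (the
    convention of standard statistical environments).
    """
    m, n = len(pos), len(neg)
    pooled = np.concatenate([pos, neg])
    ranks = stats.rankdata(pooled)
    w = float(ranks[:m].sum())
    no_ties = len(np.unique(pooled)) == m + n
    if m <= 10 and n <= 10 and no_ties:
        return w, _exact_rank_sum_p(pos, neg), True
    res = stats.mannwhitneyu(
        pos, neg, alternative="two-sided", method="asymptotic", use_continuity=True
    )
    return w, float(res.pvalue), False


def compare_scores(
    pos_scores: Sequence[float],
    neg_scores: Sequence[float],
    tool: str = "",
    alpha: float = 0.05,
    policy: str = AUTO,
) -> ComparisonResult:
    """Compare pathogenic vs benign scores with the policy-selected test.

    A constant pooled sample carries no ordering information: the result is
    flagged degenerate with p = 1.
    """
    pos, neg = _as_arrays(pos_scores, neg_scores)
    if np.ptp(np.concatenate([pos, neg])) == 0:
        return ComparisonResult(
            tool=tool, test_used=WILCOXON, statistic=float("nan"),
            p_value=1.0, n_pos=len(pos), n_neg=len(neg), degenerate=True,
        )
    if policy == FORCE_WILCOXON:
        test, trace = WILCOXON, None
    elif policy == AUTO:
        test, trace = select_test(pos, neg, alpha=alpha)
    else:
        raise ComparisonError(f"unknown policy {policy!r}")
    if test == WILCOXON:
        statistic, p, _ = rank_sum_test(pos, neg)
    else:
        res = stats.ttest_ind(pos, neg, equal_var=(test == STUDENT_T))
        statistic, p = float(res.statistic), float(res.pvalue)
    return ComparisonResult(
        tool=tool, test_used=test, statistic=statistic, p_value=p,
        n_pos=len(pos), n_neg=len(neg), trace=trace,
    )
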