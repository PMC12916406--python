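import numpy as np
import pytest

import scn3a_bench as sb


@pytest.fixture(scope="session")
def curated_cases():
    return sb.load_curated_cases()


@pytest.fixture(scope="session")
def registry():
    return sb.default_registry()


@pytest.fixture(scope="session")
def topology():
    return sb.load_default_topology()


@pytest.fixture(scope="session")
def study_cohort():
    """Study-shaped synthetic cohort: 20 pathogenic / 45 benign, 19 tools."""
    return sb.generate_cohort(sb.study_config(seed=1))


@pytest.fixture()
def rng():
    return np.random.default_rng(20_240_901)


def brute_force_fisher_p(a: int, b: int, c: int, d: int) -> float:
    """Exhaustive minimum-likelihood two-sided Fisher p for a 2x2 table.

    Enumerates every table with the observed margins and sums the
    hypergeometric point probabilities not exceeding (up to a 1e-7 relative
    tie tolerance) that of the observed table. Independent of the package's
    implementation.
    """
    from math import comb

    row1, row2 = a + b, c + d
    col1 = a + c
    n = row1 + row2

    def point_prob(x: int) -> float:
        return comb(row1, x) * comb(row2, col1 - x) / comb(n, col1)

    lo = max(0, col1 - row2)
    hi = min(col1, row1)
    p_obs = point_prob(a)
    total = 0.0
    for x in range(lo, hi + 1):
        p = point_prob(x)
        if p <= p_obs * (1 + 1e-7):
            total += p
    return min(1.0, total)


def brute_force_auc(pos, neg) -> float:
    """O(n*m) pair-counting AUC with the half-tie convention."""
    total = 0.0
    for x in pos:
        for y in neg:
            total += 1.0 if x > y else (0.5 if x == y else 0.0)
    return total / (len(pos) * len(neg))


def brute_force_rank_sum_p(pos, neg) -> float:
    """Exact two-sided rank-sum p by enumerating all C(n+m, n) assignments."""
    from itertools import combinations

    import scipy.stats as st

    pooled = np.concatenate([pos, neg])
    ranks = st.rankdata(pooled)
    m = len(pos)
    w_obs = ranks[:m].sum()
    mean_w = m * (len(pooled) + 1) / 2
    dev_obs = abs(w_obs - mean_w)
    count = total = 0
    for subset in combinations(range(len(pooled)), m):
        w = ranks[list(subset)].sum()
        total += 1
        if abs(w - mean_w) >= dev_obs - 1e-9:
            count += 1
    return count / total
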