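import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import scn3a_bench as sb
from scn3a_bench.registry import registry_by_name
from scn3a_bench.roc import RocError, youden_best
from tests.conftest import brute_force_auc

score_lists = st.lists(
    st.floats(0, 1, allow_nan=False, width=32), min_size=2, max_size=20
)


class TestBuildRoc:
    def test_separated_classes(self):
        roc = sb.build_roc([0.9, 0.8], [0.1, 0.2])
        perfect = (roc.sensitivity == 1.0) & (roc.specificity == 1.0)
        t = roc.thresholds[perfect]
        assert len(t) == 1 and 0.2 < t[0] < 0.8

    def test_constant_scores_only_sentinels(self):
        roc = sb.build_roc([0.5, 0.5], [0.5, 0.5])
        assert len(roc) == 2
        assert np.isinf(roc.thresholds).all()
        assert roc.sensitivity.tolist() == [0.0, 1.0]
        assert roc.specificity.tolist() == [1.0, 0.0]

    def test_endpoints_reach_extremes(self):
        roc = sb.build_roc([0.3, 0.9, 0.5], [0.2, 0.6])
        assert (roc.sensitivity[0], roc.specificity[0]) == (0.0, 1.0)
        assert (roc.sensitivity[-1], roc.specificity[-1]) == (1.0, 0.0)

    def test_operating_points_match_exhaustive_scan(self):
        pos, neg = [0.7, 0.4, 0.4, 0.9], [0.4, 0.2]
        roc = sb.build_roc(pos, neg)
        for t, sens, spec in zip(roc.thresholds, roc.sensitivity, roc.specificity):
            assert sens == np.mean([s >= t for s in pos])
            assert spec == np.mean([s < t for s in neg])

    def test_single_class_rejected(self):
        with pytest.raises(RocError):
            sb.build_roc([0.5], [])


class TestAuc:
    def test_separated(self):
        assert sb.auc([0.9, 0.8], [0.1, 0.2]) == 1.0

    def test_label_swap_symmetry(self, rng):
        pos, neg = rng.random(10), rng.random(12)
        assert sb.auc(pos, neg) == pytest.approx(1 - sb.auc(neg, pos), abs=1e-12)

    @settings(max_examples=300, deadline=None)
    @given(pos=score_lists, neg=score_lists)
    def test_matches_pair_counting(self, pos, neg):
        assert sb.auc(pos, neg) == pytest.approx(brute_force_auc(pos, neg), abs=1e-12)

    @settings(max_examples=100, deadline=None)
    @given(pos=score_lists, neg=score_lists)
    def test_trapezoid_equals_pair_counting(self, pos, neg):
        """Trapezoidal integration of the ROC curve equals the Mann-Whitney
        AUC exactly (half-tie convention)."""
        roc = sb.build_roc(pos, neg)
        fpr = 1 - roc.specificity
        area = float(np.trapezoid(roc.sensitivity, fpr))
        assert area == pytest.approx(sb.auc(pos, neg), abs=1e-12)


def delong_variance_oracle(pos, neg):
    """Direct double-loop recomputation of the structural components."""
    pos, neg = np.asarray(pos, float), np.asarray(neg, float)
    m, n = len(pos), len(neg)
    psi = np.zeros((m, n))
    for i, x in enumerate(pos):
        for j, y in enumerate(neg):
            psi[i, j] = 1.0 if x > y else (0.5 if x == y else 0.0)
    v10 = psi.mean(axis=1)
    v01 = psi.mean(axis=0)
    return v10.var(ddof=1) / m + v01.var(ddof=1) / n


class TestDeLong:
    def test_separated_degenerate(self):
        res = sb.delong_inference([0.9, 0.8], [0.1, 0.2])
        assert res.auc == 1.0 and res.ci_high == 1.0 and res.degenerate

    def test_variance_matches_double_loop(self, rng):
        for _ in range(20):
            pos, neg = rng.random(10), rng.random(10)
            res = sb.delong_inference(pos, neg)
            assert res.variance == pytest.approx(
                delong_variance_oracle(pos, neg), abs=1e-12
            )

    def test_label_interchange_keeps_variance(self, rng):
        pos, neg = rng.random(8), rng.random(13)
        a = sb.delong_inference(pos, neg)
        b = sb.delong_inference(neg, pos)
        assert a.variance == pytest.approx(b.variance, abs=1e-12)

    def test_ci_brackets_auc_and_truncates(self, rng):
        pos = rng.random(15) + 0.5
        neg = rng.random(15)
        res = sb.delong_inference(pos, neg)
        assert 0.0 <= res.ci_low <= res.auc <= res.ci_high <= 1.0

    @settings(max_examples=50, deadline=None)
    @given(
        pos=st.lists(st.integers(0, 50), min_size=2, max_size=20),
        neg=st.lists(st.integers(0, 50), min_size=2, max_size=20),
    )
    def test_variance_invariant_under_monotone_transform(self, pos, neg):
        pos = [float(x) for x in pos]
        neg = [float(x) for x in neg]
        a = sb.delong_inference(pos, neg)
        f = lambda xs: [x**3 + 2 * x for x in xs]  # strictly increasing, exact on ints
        b = sb.delong_inference(f(pos), f(neg))
        assert b.auc == pytest.approx(a.auc, abs=1e-12)
        assert b.variance == pytest.approx(a.variance, abs=1e-12)

    def test_too_small_rejected(self):
        with pytest.raises(RocError):
            sb.delong_inference([0.9], [0.1, 0.2])


class TestYouden:
    def test_separated_j_one_at_gap_midpoint(self):
        roc = sb.build_roc([0.9, 0.8], [0.1, 0.2])
        report = youden_best(roc)
        assert report.youden_j == pytest.approx(1.0)
        assert report.best_threshold == pytest.approx((0.2 + 0.8) / 2)
        assert report.metrics_at_best.mcc == pytest.approx(1.0)

    def test_matches_exhaustive_scan(self, rng):
        for _ in range(30):
            pos, neg = rng.random(6), rng.random(6)
            roc = sb.build_roc(pos, neg)
            report = youden_best(roc)
            best = max(
                (np.mean(pos >= t) + np.mean(neg < t) - 1)
                for t in roc.thresholds
            )
            assert report.youden_j == pytest.approx(best, abs=1e-12)
            assert report.best_threshold in roc.thresholds

    def test_antilearner_never_positive_j(self, rng):
        # monotone-wrong scores: every threshold has J <= 0
        pos = rng.random(10) * 0.3
        neg = rng.random(10) * 0.3 + 0.5
        report = youden_best(sb.build_roc(pos, neg))
        assert report.youden_j <= 1e-12

    def test_winner_invariant_under_monotone_transform(self, rng):
        pos, neg = rng.random(9), rng.random(9)
        a = youden_best(sb.build_roc(pos, neg))
        g = lambda xs: np.arctan(4 * np.asarray(xs))
        b = youden_best(sb.build_roc(g(pos), g(neg)))
        assert b.youden_j == pytest.approx(a.youden_j, abs=1e-12)
        assert b.metrics_at_best.sensitivity == a.metrics_at_best.sensitivity
        assert b.metrics_at_best.specificity == a.metrics_at_best.specificity

    def test_ties_reported(self):
        roc = sb.build_roc([0.9, 0.6], [0.1, 0.4])
        report = youden_best(roc)
        assert report.best_threshold in report.ties


class TestEvaluateTools:
    def test_lower_damaging_threshold_reported_on_raw_scale(self, rng):
        sift = registry_by_name(sb.default_registry())["SIFT"]
        pos = rng.random(20) * 0.04  # damaging: low scores
        neg = rng.random(30) * 0.5 + 0.3
        ev = sb.evaluate_tool(sift, pos, neg)
        assert ev.auc.auc == 1.0
        assert 0.04 <= ev.calibration.best_threshold <= 0.3
        assert ev.calibration.metrics_at_best.sensitivity == 1.0

    def test_full_cohort_evaluates_all_19(self, study_cohort):
        labels = {
            v.change.format(): v.label for v in study_cohort.dataset.variants
        }
        evaluations, summary = sb.evaluate_all_tools(study_cohort.matrix, labels)
        assert len(evaluations) == 19
        assert summary["n_tools_evaluated"] == 19
        assert 0.5 < summary["auc_median"] <= 1.0
        for ev in evaluations:
            assert ev.auc.ci_low <= ev.auc.auc <= ev.auc.ci_high

    def test_uninformative_tool_flagged_not_dropped(self, rng, registry):
        cohort = sb.generate_cohort(
            sb.study_config(
                seed=3,
                tools=(registry[0],),
                tool_models={
                    registry[0].name: sb.ScoreModel(
                        sb.DistSpec("uniform", (0, 1)), sb.DistSpec("uniform", (0, 1))
                    )
                },
            )
        )
        labels = {v.change.format(): v.label for v in cohort.dataset.variants}
        evaluations, summary = sb.evaluate_all_tools(cohort.matrix, labels)
        assert len(evaluations) == 1
        assert evaluations[0].skipped_reason is not None
        assert summary["n_tools_skipped"] == 1
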