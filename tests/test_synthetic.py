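import dataclasses

import numpy as np
import pandas as pd
import pytest

import scn3a_bench as sb
from scn3a_bench.synthetic import (
    SyntheticError,
    _stream,
    study_models,
    variant_labels,
)
from scn3a_bench.topology import is_transmembrane


class TestDeterminism:
    def test_same_config_bit_identical(self):
        cfg = sb.study_config(seed=1, missingness_rate=0.1)
        a, b = sb.generate_cohort(cfg), sb.generate_cohort(cfg)
        assert a.dataset == b.dataset
        pd.testing.assert_frame_equal(a.matrix.scores, b.matrix.scores)
        pd.testing.assert_frame_equal(a.matrix.labels, b.matrix.labels)

    def test_adding_a_tool_never_perturbs_existing_columns(self, registry):
        cfg_two = sb.study_config(seed=2, tools=tuple(registry[:2]))
        cfg_three = sb.study_config(seed=2, tools=tuple(registry[:3]))
        a, b = sb.generate_cohort(cfg_two), sb.generate_cohort(cfg_three)
        for name in (t.name for t in registry[:2]):
            pd.testing.assert_series_equal(a.matrix.scores[name], b.matrix.scores[name])

    def test_independent_streams_per_label(self):
        x = _stream(5, "AlphaMissense").random(4)
        y = _stream(5, "SIFT").random(4)
        assert not np.allclose(x, y)
        assert np.allclose(x, _stream(5, "AlphaMissense").random(4))


class TestCohortShape:
    def test_exact_class_sizes(self, study_cohort):
        summary = sb.summarize_cohort(study_cohort.dataset)
        assert summary["pathogenic_unique"] == 20
        assert summary["benign_unique"] == 45
        assert summary["n_patients"] == 20

    def test_scores_within_documented_ranges(self, study_cohort):
        for tool in study_cohort.matrix.tools:
            if tool.score_range is None:
                continue
            col = study_cohort.matrix.scores[tool.name].dropna()
            lo, hi = tool.score_range
            assert col.between(lo, hi).all(), tool.name

    def test_categorical_labels_match_threshold_rule(self, study_cohort):
        pm = study_cohort.matrix
        for tool in pm.tools:
            calls_from_scores = pm.calls_at_threshold(tool.name)
            calls_from_labels = pm.calls_from_labels(tool.name)
            assert list(calls_from_scores) == list(calls_from_labels), tool.name

    def test_missingness_rate_applied(self):
        cohort = sb.generate_cohort(sb.study_config(seed=4, missingness_rate=0.3))
        frac = float(cohort.matrix.scores.isna().mean().mean())
        assert 0.2 < frac < 0.4

    def test_tm_fractions_shape_positions(self, topology):
        cohort = sb.generate_cohort(
            sb.study_config(
                seed=5, n_pathogenic=200, n_benign=200,
                tm_fraction_pathogenic=0.9, tm_fraction_benign=0.2,
            )
        )
        tm_frac = {"pathogenic": [], "benign": []}
        for v in cohort.dataset.variants:
            tm_frac[v.label].append(is_transmembrane(v.change.position, topology))
        assert np.mean(tm_frac["pathogenic"]) > 0.8
        assert np.mean(tm_frac["benign"]) < 0.35

    def test_infeasible_config_rejected(self, registry):
        with pytest.raises(SyntheticError):
            sb.generate_cohort(
                sb.study_config(
                    seed=1, n_pathogenic=500_000, n_benign=500_000,
                    tools=(registry[0],),
                )
            )

    def test_unknown_tool_without_model_rejected(self):
        rogue = dataclasses.replace(sb.default_registry()[0], name="RogueTool")
        with pytest.raises(SyntheticError, match="RogueTool"):
            sb.generate_cohort(sb.study_config(seed=1, tools=(rogue,)))


class TestTrueAuc:
    def test_identical_distributions_half(self):
        model = sb.ScoreModel(sb.DistSpec("beta", (2, 2)), sb.DistSpec("beta", (2, 2)))
        est = sb.true_auc(model, reps=20_000, seed=1)
        assert est.value == pytest.approx(0.5, abs=3 * est.std_error)

    def test_point_masses_exact_one(self):
        model = sb.ScoreModel(
            sb.DistSpec("uniform", (1.0, 1.0)), sb.DistSpec("uniform", (0.0, 0.0))
        )
        assert sb.true_auc(model, reps=10_000, seed=1).value == 1.0

    def test_matches_large_cohort_empirical_auc(self, registry):
        model = sb.ScoreModel(sb.DistSpec("beta", (8, 2)), sb.DistSpec("beta", (2, 8)))
        est = sb.true_auc(model, reps=100_000, seed=2)
        rng = np.random.default_rng(3)
        pos = model.pathogenic.sample(rng, 3000)
        neg = model.benign.sample(rng, 3000)
        empirical = sb.auc(pos, neg)
        # empirical AUC of a large cohort has its own noise; 3 s.e. of the
        # Monte-Carlo oracle plus a matching allowance for the cohort
        assert est.value == pytest.approx(empirical, abs=0.01)

    def test_lower_damaging_orientation_respected(self):
        model = study_models()["SIFT"]
        est = sb.true_auc(model, orientation="lower_damaging", reps=20_000, seed=4)
        assert est.value > 0.9

    def test_too_few_reps_rejected(self):
        model = sb.ScoreModel(sb.DistSpec("beta", (2, 2)), sb.DistSpec("beta", (2, 2)))
        with pytest.raises(SyntheticError):
            sb.true_auc(model, reps=100)


class TestExportParity:
    def test_exported_files_reload_through_pipeline_readers(
        self, study_cohort, tmp_path
    ):
        paths = sb.export_cohort(study_cohort, tmp_path)
        ds_p = sb.load_dataset(paths["patients"], format="patients")
        ds_v = sb.load_dataset(paths["variants"], format="variants")
        merged = ds_p.merge(ds_v)
        assert {v.change for v in merged.variants} == {
            v.change for v in study_cohort.dataset.variants
        }
        topo = sb.load_topology(paths["topology"])
        assert topo == study_cohort.topology
        pm = sb.load_scores(paths["scores"], study_cohort.matrix.tools)
        pd.testing.assert_frame_equal(pm.scores, study_cohort.matrix.scores)

    def test_truth_labels_cover_cohort(self, study_cohort):
        labels = variant_labels(study_cohort)
        assert len(labels) == 65
        assert set(labels.values()) == {"pathogenic", "benign"}
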