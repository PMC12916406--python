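import logging

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import scn3a_bench as sb
from scn3a_bench.predictions import PredictionError, load_scores
from scn3a_bench.registry import RegistryError, registry_by_name


@pytest.fixture(scope="module")
def by_name():
    return registry_by_name(sb.default_registry())


def _write_scores(tmp_path, rows, header):
    path = tmp_path / "scores.tsv"
    path.write_text("\n".join(["\t".join(header)] + ["\t".join(r) for r in rows]) + "\n")
    return path


class TestLoadScores:
    def test_multi_transcript_collapses_most_damaging(self, tmp_path, registry):
        header = ["variant", "AlphaMissense_score", "SIFT_score"]
        path = _write_scores(tmp_path, [["p.Ala10Cys", "0.98;0.97", "0.2;0.01"]], header)
        pm = load_scores(path, registry)
        assert pm.scores.loc["p.Ala10Cys", "AlphaMissense"] == 0.98  # max (higher_damaging)
        assert pm.scores.loc["p.Ala10Cys", "SIFT"] == 0.01  # min (lower_damaging)

    def test_dot_is_missing(self, tmp_path, registry):
        header = ["variant", "AlphaMissense_score", "AlphaMissense_pred"]
        path = _write_scores(tmp_path, [["p.Ala10Cys", ".", "."]], header)
        pm = load_scores(path, registry)
        assert np.isnan(pm.scores.loc["p.Ala10Cys", "AlphaMissense"])
        assert pm.labels.loc["p.Ala10Cys", "AlphaMissense"] is None

    def test_conflicting_duplicate_scores_error(self, tmp_path, registry):
        header = ["variant", "AlphaMissense_score"]
        rows = [["p.Ala10Cys", "0.9"], ["p.A10C", "0.5"]]
        with pytest.raises(PredictionError, match="conflicting"):
            load_scores(_write_scores(tmp_path, rows, header), registry)

    def test_unknown_tool_column_warns_and_ignores(self, tmp_path, registry, caplog):
        header = ["variant", "Mystery_score", "AlphaMissense_score"]
        path = _write_scores(tmp_path, [["p.Ala10Cys", "0.4", "0.8"]], header)
        with caplog.at_level(logging.WARNING):
            pm = load_scores(path, registry)
        assert "Mystery_score" in caplog.text
        assert "Mystery" not in pm.scores.columns

    def test_study_shaped_cohort_matrix(self, study_cohort, tmp_path):
        paths = sb.export_cohort(study_cohort, tmp_path)
        pm = load_scores(paths["scores"], study_cohort.matrix.tools)
        assert pm.n_variants == 65
        assert len(pm.tools) == 19

    def test_round_trip_scores_bit_identical(self, study_cohort, tmp_path):
        out = tmp_path / "roundtrip.tsv"
        study_cohort.matrix.to_tsv(out)
        back = load_scores(out, study_cohort.matrix.tools)
        pd.testing.assert_frame_equal(back.scores, study_cohort.matrix.scores)
        pd.testing.assert_frame_equal(back.labels, study_cohort.matrix.labels)


class TestCategoricalMaps:
    @pytest.mark.parametrize(
        "tool, raw, expected",
        [
            ("Polyphen2_HVAR", "P", "deleterious"),
            ("Polyphen2_HVAR", "D", "deleterious"),
            ("Polyphen2_HVAR", "B", "tolerated"),
            ("MutationTaster", "N", "tolerated"),
            ("MutationTaster", "A", "deleterious"),
            ("AlphaMissense", "A", "tolerated"),
            ("AlphaMissense", "P", "deleterious"),
            ("MutationAssessor", "M", "deleterious"),
            ("PROVEAN", "N", "tolerated"),
            ("SIFT", "D", "deleterious"),
        ],
    )
    def test_documented_mappings(self, by_name, tool, raw, expected):
        assert sb.map_class_label(by_name[tool], raw) == expected

    def test_unmapped_label_names_tool(self, by_name):
        with pytest.raises(RegistryError, match="AlphaMissense"):
            sb.map_class_label(by_name["AlphaMissense"], "Q")

    def test_maps_are_binary_and_unambiguous(self, registry):
        for tool in registry:
            mapped = set(tool.categorical_map.values())
            assert mapped <= {"deleterious", "tolerated"}
            assert len(tool.categorical_map) == len(set(tool.categorical_map))


class TestClassifyAtThreshold:
    def test_lower_damaging_semantics(self, by_name):
        sift = by_name["SIFT"]
        assert sb.classify_at_threshold(0.01, sift) == "deleterious"
        assert sb.classify_at_threshold(0.2, sift) == "tolerated"

    def test_boundary_counts_deleterious(self, by_name):
        am = by_name["AlphaMissense"]
        assert sb.classify_at_threshold(am.recommended_threshold, am) == "deleterious"
        sift = by_name["SIFT"]
        assert sb.classify_at_threshold(0.05, sift) == "deleterious"

    def test_calibrated_threshold_override(self, by_name):
        assert (
            sb.classify_at_threshold(0.70, by_name["AlphaMissense"], threshold=0.699)
            == "deleterious"
        )

    @settings(max_examples=100, deadline=None)
    @given(
        lo=st.floats(0, 1, allow_nan=False),
        hi=st.floats(0, 1, allow_nan=False),
        threshold=st.floats(0.1, 0.9, allow_nan=False),
    )
    def test_monotone_in_score(self, by_name, lo, hi, threshold):
        """Raising the score of a higher-damaging tool never flips a
        deleterious call back to tolerated."""
        am = by_name["AlphaMissense"]
        low, high = min(lo, hi), max(lo, hi)
        calls = [
            sb.classify_at_threshold(s, am, threshold=threshold) for s in (low, high)
        ]
        assert not (calls[0] == "deleterious" and calls[1] == "tolerated")


class TestCoverage:
    def test_counts_partition(self, study_cohort):
        report = sb.coverage_report(study_cohort.matrix)
        for counts in report.per_tool.values():
            assert counts["n_scored"] + counts["n_missing_score"] == counts["n_variants"]

    def test_missing_column_counted(self, registry, tmp_path):
        header = ["variant", "AlphaMissense_score", "SIFT_score"]
        rows = [["p.Ala10Cys", "0.9", "."], ["p.Ala11Cys", "0.8", "."]]
        pm = load_scores(_write_scores(tmp_path, rows, header), registry)
        report = sb.coverage_report(pm)
        assert report.per_tool["SIFT"]["n_missing_score"] == 2
        assert report.per_tool["AlphaMissense"]["n_missing_score"] == 0
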