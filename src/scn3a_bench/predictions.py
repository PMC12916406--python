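"""Loading per-variant predictor outputs into a variants × tools matrix.

Reads dbNSFP-style TSV tables: one row per variant keyed by the protein
change, one ``<Tool>_score`` / ``<Tool>_pred`` column pair per tool, "."
for missing, and ";"-separated values where a variant hits multiple
transcripts. Multi-transcript cells collapse to the most-damaging value
under the tool's orientation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .hgvs import AminoAcidChange, parse_protein_hgvs
from .registry import (
    HIGHER_DAMAGING,
    ToolSpec,
    classify_at_threshold,
    map_class_label,
)

logger = logging.getLogger(__name__)

MISSING = "."


class PredictionError(ValueError):
    """Raised for malformed or inconsistent score tables."""


@dataclass
class PredictionMatrix:
    """Continuous scores and raw categorical labels per variant × tool.

    ``scores`` is float with NaN for missing; ``labels`` is object with
    None for missing. Both are indexed by the three-letter HGVS string of
    the variant and share the same row order as ``variants``.
    """

    variants: list[AminoAcidChange]
    tools: list[ToolSpec]
    scores: pd.DataFrame
    labels: pd.DataFrame

    def __post_init__(self) -> None:
        index = [v.format() for v in self.variants]
        for frame, kind in ((self.scores, "scores"), (self.labels, "labels")):
            if list(frame.index) != index:
                raise PredictionError(f"{kind} index does not match variant list")
            if list(frame.columns) != [t.name for t in self.tools]:
                raise PredictionError(f"{kind} columns do not match tool list")

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def tool(self, name: str) -> ToolSpec:
        for t in self.tools:
            if t.name == name:
                return t
        raise KeyError(name)

    def tool_scores(self, name: str) -> pd.Series:
        return self.scores[name]

    def calls_at_threshold(
        self, name: str, threshold: float | None = None
    ) -> pd.Series:
        """Deleterious/tolerated calls from the continuous score; NaN scores
        yield missing (None) calls."""
        tool = self.tool(name)
        s = self.scores[name]
        return s.map(
            lambda x: None if pd.isna(x) else classify_at_threshold(x, tool, threshold)
        )

    def calls_from_labels(self, name: str) -> pd.Series:
        """Deleterious/tolerated calls from the raw categorical labels."""
        tool = self.tool(name)
        return self.labels[name].map(
            lambda x: None if x is None else map_class_label(tool, x)
        )

    def to_tsv(self, path: str | Path) -> None:
        """Write the matrix back out in the same dbNSFP-style shape."""
        out = pd.DataFrame({"variant": [v.format() for v in self.variants]})
        for tool in self.tools:
            col = self.scores[tool.name]
            out[tool.score_col()] = [
                MISSING if pd.isna(x) else repr(float(x)) for x in col
            ]
            out[tool.pred_col()] = [
                MISSING if x is None else x for x in self.labels[tool.name]
            ]
        out.to_csv(path, sep="\t", index=False)


@dataclass
class CoverageReport:
    per_tool: dict[str, dict[str, int]] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.per_tool).T.rename_axis("tool")


def _collapse_multi(cell: str, tool: ToolSpec) -> float:
    """";"-separated multi-transcript score -> the most damaging value."""
    values = [float(v) for v in cell.split(";") if v.strip() not in ("", MISSING)]
    if not values:
        return np.nan
    return max(values) if tool.orientation == HIGHER_DAMAGING else min(values)


def _collapse_label(cell: str, tool: ToolSpec) -> str | None:
    parts = [v.strip() for v in cell.split(";") if v.strip() not in ("", MISSING)]
    if not parts:
        return None
    # most-damaging label wins when transcripts disagree
    for part in parts:
        if map_class_label(tool, part) == "deleterious":
            return part
    return parts[0]


def load_scores(
    path: str | Path,
    registry: Sequence[ToolSpec],
    variants: Sequence[AminoAcidChange] | None = None,
) -> PredictionMatrix:
    """Read a dbNSFP-style TSV into a :class:`PredictionMatrix`.

    Parameters
    ----------
    path:
        TSV with a ``variant`` column (protein HGVS) and per-tool score /
        pred columns named ``<Tool>_score`` / ``<Tool>_pred`` (overridable
        per ToolSpec).
    registry:
        The tools to ingest. Score/pred columns not matching any registered
        tool are ignored with a warning.
    variants:
        Optional expected variant list; unmatched expected variants are
        logged and appear as all-missing rows.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if "variant" not in df.columns:
        raise PredictionError(f"{path}: required column 'variant' missing")

    known_cols = {"variant"}
    for tool in registry:
        known_cols |= {tool.score_col(), tool.pred_col()}
    for col in df.columns:
        if col not in known_cols and (col.endswith("_score") or col.endswith("_pred")):
            logger.warning("%s: ignoring unknown tool column %r", path, col)

    parsed = [parse_protein_hgvs(v) for v in df["variant"]]
    keys = [c.format() for c in parsed]

    # duplicate rows must agree per tool
    if len(set(keys)) != len(keys):
        dup_frame = df.assign(_key=keys)
        for key, group in dup_frame.groupby("_key"):
            if len(group) == 1:
                continue
            for tool in registry:
                col = tool.score_col()
                if col in group.columns:
                    vals = {v for v in group[col] if v.strip() not in ("", MISSING)}
                    if len(vals) > 1:
                        raise PredictionError(
                            f"{path}: variant {key} has conflicting {tool.name} "
                            f"scores {sorted(vals)}"
                        )
        df = dup_frame.drop_duplicates("_key").drop(columns="_key")
        parsed = [parse_protein_hgvs(v) for v in df["variant"]]
        keys = [c.format() for c in parsed]

    if variants is not None:
        want = {v.format(): v for v in variants}
        unmatched = sorted(set(want) - set(keys))
        if unmatched:
            logger.info("%s: %d expected variants unmatched: %s",
                        path, len(unmatched), ", ".join(unmatched))
        order = list(want.values()) + [
            c for c, k in zip(parsed, keys) if k not in want
        ]
    else:
        order = parsed

    index = [c.format() for c in order]
    row_of = {k: i for i, k in enumerate(keys)}
    names = [t.name for t in registry]
    scores = pd.DataFrame(np.nan, index=index, columns=names, dtype=float)
    labels = pd.DataFrame([[None] * len(names)] * len(index), index=index,
                          columns=names, dtype=object)
    for tool in registry:
        scol, pcol = tool.score_col(), tool.pred_col()
        for key in index:
            i = row_of.get(key)
            if i is None:
                continue
            if scol in df.columns:
                scores.loc[key, tool.name] = _collapse_multi(df[scol].iloc[i], tool)
            if pcol in df.columns:
                labels.loc[key, tool.name] = _collapse_label(df[pcol].iloc[i], tool)
    return PredictionMatrix(variants=list(order), tools=list(registry),
                            scores=scores, labels=labels)


def coverage_report(pm: PredictionMatrix) -> CoverageReport:
    """Per-tool counts of scored vs missing variants (scores and labels)."""
    report = CoverageReport()
    for tool in pm.tools:
        n_scored = int(pm.scores[tool.name].notna().sum())
        n_labeled = int(pm.labels[tool.name].notna().sum())
        report.per_tool[tool.name] = {
            "n_variants": pm.n_variants,
            "n_scored": n_scored,
            "n_missing_score": pm.n_variants - n_scored,
            "n_labeled": n_labeled,
            "n_missing_label": pm.n_variants - n_labeled,
        }
    return report
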