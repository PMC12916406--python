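"""Predictor tool registry: orientation, thresholds, categorical mappings.

Each in-silico missense predictor is described by a :class:`ToolSpec`:

* ``orientation`` — whether larger scores mean more damaging
  (``higher_damaging``, e.g. REVEL-style probabilities) or smaller scores do
  (``lower_damaging``, e.g. SIFT, PROVEAN, ESM1b);
* ``recommended_threshold`` — the genome-wide published cutoff, on the raw
  score scale; a score equal to the threshold counts as deleterious;
* ``categorical_map`` — raw label → deleterious/tolerated for tools that
  ship categorical calls (e.g. PolyPhen-2 "D"/"P"/"B").

The packaged default registry (``data/tool_registry.yaml``) covers the 19
benchmarked tools with dbNSFP-documented cutoffs; it is the single source
of truth and fully user-overridable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import yaml

DELETERIOUS = "deleterious"
TOLERATED = "tolerated"

HIGHER_DAMAGING = "higher_damaging"
LOWER_DAMAGING = "lower_damaging"


class RegistryError(ValueError):
    """Raised for invalid tool specifications or unmapped labels."""


@dataclass(frozen=True)
class ToolSpec:
    name: str
    output_kind: str = "both"  # continuous | categorical | both
    orientation: str = HIGHER_DAMAGING
    recommended_threshold: float | None = None
    categorical_map: Mapping[str, str] = field(default_factory=dict)
    score_range: tuple[float, float] | None = None
    score_column: str | None = None
    pred_column: str | None = None

    def __post_init__(self) -> None:
        if self.output_kind not in ("continuous", "categorical", "both"):
            raise RegistryError(f"{self.name}: bad output_kind {self.output_kind!r}")
        if self.output_kind != "categorical" and self.orientation not in (
            HIGHER_DAMAGING,
            LOWER_DAMAGING,
        ):
            raise RegistryError(f"{self.name}: bad orientation {self.orientation!r}")
        for raw, mapped in self.categorical_map.items():
            if mapped not in (DELETERIOUS, TOLERATED):
                raise RegistryError(
                    f"{self.name}: categorical map sends {raw!r} to {mapped!r}"
                )

    @property
    def has_continuous(self) -> bool:
        return self.output_kind in ("continuous", "both")

    @property
    def has_categorical(self) -> bool:
        return self.output_kind in ("categorical", "both")

    def score_col(self) -> str:
        return self.score_column or f"{self.name}_score"

    def pred_col(self) -> str:
        return self.pred_column or f"{self.name}_pred"


def map_class_label(tool: ToolSpec, raw: str) -> str:
    """Map a tool's raw categorical output to deleterious/tolerated."""
    key = raw.strip()
    if key in tool.categorical_map:
        return tool.categorical_map[key]
    raise RegistryError(f"{tool.name}: unmapped categorical label {raw!r}")


def classify_at_threshold(
    score: float, tool: ToolSpec, threshold: float | None = None
) -> str:
    """Binary call from a continuous score at a threshold (defaults to the
    tool's recommended threshold). Equality counts as deleterious."""
    if not tool.has_continuous:
        raise RegistryError(f"{tool.name} has no continuous output")
    if threshold is None:
        threshold = tool.recommended_threshold
    if threshold is None:
        raise RegistryError(f"{tool.name}: no threshold available")
    if tool.orientation == HIGHER_DAMAGING:
        return DELETERIOUS if score >= threshold else TOLERATED
    return DELETERIOUS if score <= threshold else TOLERATED


def oriented(scores, tool: ToolSpec):
    """Map raw scores to the 'larger = more damaging' scale."""
    import numpy as np

    arr = np.asarray(scores, dtype=float)
    return arr if tool.orientation == HIGHER_DAMAGING else -arr


def load_registry(path: str | Path) -> list[ToolSpec]:
    """Load a YAML tool registry (list of tool mappings under ``tools``)."""
    payload = yaml.safe_load(Path(path).read_text())
    entries = payload["tools"] if isinstance(payload, dict) else payload
    tools = []
    for entry in entries:
        rng = entry.get("score_range")
        tools.append(
            ToolSpec(
                name=entry["name"],
                output_kind=entry.get("output_kind", "both"),
                orientation=entry.get("orientation", HIGHER_DAMAGING),
                recommended_threshold=entry.get("recommended_threshold"),
                categorical_map=entry.get("categorical_map", {}),
                score_range=tuple(rng) if rng else None,
                score_column=entry.get("score_column"),
                pred_column=entry.get("pred_column"),
            )
        )
    names = [t.name for t in tools]
    if len(set(names)) != len(names):
        raise RegistryError("duplicate tool names in registry")
    return tools


def default_registry_path() -> Path:
    return Path(__file__).parent / "data" / "tool_registry.yaml"


def default_registry() -> list[ToolSpec]:
    """The packaged 19-tool registry."""
    return load_registry(default_registry_path())


def registry_by_name(tools: Sequence[ToolSpec]) -> dict[str, ToolSpec]:
    return {t.name: t for t in tools}
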