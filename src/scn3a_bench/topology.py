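"""Nav1.3 structural topology: region table, position mapping, validation.

The Nav1.3 α-subunit (2000 aa) folds into four homologous domains (DI–DIV),
each with six membrane-spanning segments (S1–S6) joined by extracellular
loops, with cytoplasmic inter-domain linkers and N-/C-termini. Segments
S1–S6 are transmembrane; everything else is "other". The packaged default
table (``data/nav13_topology.tsv``) is an approximate UniProt-style
annotation of this architecture and can be replaced by any table satisfying
the coverage invariant (non-overlapping, sorted, gap-free over
1..protein_length).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

TRANSMEMBRANE = "transmembrane"
OTHER = "other"

_TM_SEGMENTS = {"S1", "S2", "S3", "S4", "S5", "S6"}


class TopologyError(ValueError):
    """Raised for invalid topology tables or out-of-range positions."""


@dataclass(frozen=True)
class TopologyRegion:
    name: str
    domain: str  # DI | DII | DIII | DIV | none
    segment: str  # S1..S6 | loop | linker | terminus
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise TopologyError(f"{self.name}: start {self.start} > end {self.end}")
        if self.domain not in ("DI", "DII", "DIII", "DIV", "none"):
            raise TopologyError(f"{self.name}: bad domain {self.domain!r}")
        if self.segment not in _TM_SEGMENTS | {"loop", "linker", "terminus"}:
            raise TopologyError(f"{self.name}: bad segment {self.segment!r}")

    @property
    def tm_class(self) -> str:
        return TRANSMEMBRANE if self.segment in _TM_SEGMENTS else OTHER

    def __contains__(self, position: int) -> bool:
        return self.start <= position <= self.end


@dataclass(frozen=True)
class TopologyTable:
    regions: tuple[TopologyRegion, ...]
    protein_length: int

    def __post_init__(self) -> None:
        if not self.regions:
            raise TopologyError("topology table has no regions")
        expected = 1
        for region in self.regions:
            if region.start != expected:
                raise TopologyError(
                    f"coverage gap/overlap before {region.name}: expected start "
                    f"{expected}, got {region.start}"
                )
            expected = region.end + 1
        if expected != self.protein_length + 1:
            raise TopologyError(
                f"regions cover 1..{expected - 1} but protein_length is "
                f"{self.protein_length}"
            )

    def tm_positions(self) -> list[tuple[int, int]]:
        """(start, end) spans of all transmembrane segments."""
        return [(r.start, r.end) for r in self.regions if r.tm_class == TRANSMEMBRANE]

    def other_positions(self) -> list[tuple[int, int]]:
        return [(r.start, r.end) for r in self.regions if r.tm_class == OTHER]


def assign_region(position: int, topo: TopologyTable) -> TopologyRegion:
    """Return the unique region covering a 1-based residue position."""
    if not 1 <= position <= topo.protein_length:
        raise TopologyError(
            f"position {position} outside 1..{topo.protein_length}"
        )
    lo, hi = 0, len(topo.regions) - 1
    while lo <= hi:
        mid = (lo + hi) // 2
        region = topo.regions[mid]
        if position < region.start:
            hi = mid - 1
        elif position > region.end:
            lo = mid + 1
        else:
            return region
    raise TopologyError(f"no region covers position {position}")  # unreachable


def is_transmembrane(position: int, topo: TopologyTable) -> bool:
    return assign_region(position, topo).tm_class == TRANSMEMBRANE


def load_topology(path: str | Path) -> TopologyTable:
    """Load a topology table from TSV (columns: name, domain, segment, start,
    end) or YAML (list of region mappings plus optional protein_length)."""
    path = Path(path)
    if path.suffix.lower() in (".yaml", ".yml"):
        payload = yaml.safe_load(path.read_text())
        rows = payload["regions"] if isinstance(payload, dict) else payload
        df = pd.DataFrame(rows)
    else:
        df = pd.read_csv(path, sep="\t", dtype={"name": str})
    required = {"name", "domain", "segment", "start", "end"}
    missing = required - set(df.columns)
    if missing:
        raise TopologyError(f"{path}: missing columns {sorted(missing)}")
    regions = tuple(
        TopologyRegion(
            name=str(row["name"]),
            domain=str(row["domain"]),
            segment=str(row["segment"]),
            start=int(row["start"]),
            end=int(row["end"]),
        )
        for _, row in df.sort_values("start").iterrows()
    )
    return TopologyTable(regions=regions, protein_length=regions[-1].end)


def default_topology_path() -> Path:
    return Path(__file__).parent / "data" / "nav13_topology.tsv"


def load_default_topology() -> TopologyTable:
    """The packaged approximate Nav1.3 topology (override with your own
    table for structure-critical work)."""
    return load_topology(default_topology_path())


def make_topology(regions: Sequence[TopologyRegion]) -> TopologyTable:
    regions = tuple(sorted(regions, key=lambda r: r.start))
    return TopologyTable(regions=regions, protein_length=regions[-1].end)
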