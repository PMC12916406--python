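"""Subregional enrichment: 2×2 tabulation and Fisher's exact test.

Tests whether pathogenic variants (or a clinical phenotype among carriers)
concentrate in transmembrane segments. The two-sided p-value follows the
minimum-likelihood convention: it sums the probabilities, under the
hypergeometric null with fixed margins, of every table whose point
probability does not exceed that of the observed table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

from scipy import stats

from .topology import TRANSMEMBRANE, TopologyTable, assign_region


class EnrichmentError(ValueError):
    """Raised for degenerate contingency tables."""


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts with rows = axis-positive/negative, cols = TM/other.

    a = positive∧TM, b = positive∧other, c = negative∧TM, d = negative∧other.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise EnrichmentError("contingency counts must be non-negative")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    def as_rows(self) -> list[list[int]]:
        return [[self.a, self.b], [self.c, self.d]]

    def validate_margins(self) -> None:
        if self.a + self.b == 0 or self.c + self.d == 0:
            raise EnrichmentError("a row margin is zero: nothing to compare")
        if self.a + self.c == 0 or self.b + self.d == 0:
            raise EnrichmentError("a column margin is zero: nothing to compare")


@dataclass(frozen=True)
class EnrichmentResult:
    table: ContingencyTable2x2
    odds_ratio: float  # sample OR a*d/(b*c); may be inf
    odds_ratio_corrected: float  # Haldane–Anscombe +0.5 OR
    p_two_sided: float
    axis: str = "label"
    unit: str = "variants"
    n_dropped_missing: int = 0

    def to_dict(self) -> dict:
        return {
            "table": self.table.as_rows(),
            "odds_ratio": self.odds_ratio,
            "odds_ratio_corrected": self.odds_ratio_corrected,
            "p_two_sided": self.p_two_sided,
            "axis": self.axis,
            "unit": self.unit,
            "n_dropped_missing": self.n_dropped_missing,
        }


@dataclass
class TabulationInput:
    """One observation for tabulation: its TM membership and axis value."""

    tm: bool
    axis_value: bool | None


def build_contingency(
    items: Iterable[TabulationInput], axis: str = "label"
) -> tuple[ContingencyTable2x2, int]:
    """Tabulate axis-positive/negative × TM/other.

    Items with a missing axis value are dropped; the dropped count is
    returned alongside the table so reports can log it.
    """
    a = b = c = d = dropped = 0
    for item in items:
        if item.axis_value is None:
            dropped += 1
        elif item.axis_value:
            a, b = (a + 1, b) if item.tm else (a, b + 1)
        else:
            c, d = (c + 1, d) if item.tm else (c, d + 1)
    table = ContingencyTable2x2(a, b, c, d)
    if table.a + table.b == 0 or table.c + table.d == 0:
        raise EnrichmentError(
            f"degenerate table on axis {axis!r}: one group is empty "
            f"({dropped} items dropped for missing values)"
        )
    return table, dropped


def fisher_exact(
    table: ContingencyTable2x2,
    axis: str = "label",
    unit: str = "variants",
    n_dropped_missing: int = 0,
) -> EnrichmentResult:
    """Two-sided Fisher's exact test with the sample odds ratio.

    When exactly one of b, c is zero the sample OR is infinite (or 0 when a
    or d is zero); a Haldane–Anscombe corrected OR (+0.5 per cell) is always
    reported alongside.
    """
    table.validate_margins()
    _, p = stats.fisher_exact(table.as_rows(), alternative="two-sided")
    if table.b * table.c == 0:
        # valid margins guarantee a*d > 0 whenever b*c == 0
        odds = math.inf
    elif table.a * table.d == 0:
        odds = 0.0
    else:
        odds = (table.a * table.d) / (table.b * table.c)
    corrected = ((table.a + 0.5) * (table.d + 0.5)) / ((table.b + 0.5) * (table.c + 0.5))
    return EnrichmentResult(
        table=table,
        odds_ratio=odds,
        odds_ratio_corrected=corrected,
        p_two_sided=float(p),
        axis=axis,
        unit=unit,
        n_dropped_missing=n_dropped_missing,
    )


def tm_enrichment(
    positions_positive: Sequence[int],
    positions_negative: Sequence[int],
    topo: TopologyTable,
    axis: str = "label",
    unit: str = "variants",
) -> EnrichmentResult:
    """Convenience: Fisher test of TM membership between two position sets
    (e.g. pathogenic vs benign variant residues)."""
    items = [
        TabulationInput(tm=assign_region(p, topo).tm_class == TRANSMEMBRANE, axis_value=True)
        for p in positions_positive
    ] + [
        TabulationInput(tm=assign_region(p, topo).tm_class == TRANSMEMBRANE, axis_value=False)
        for p in positions_negative
    ]
    table, dropped = build_contingency(items, axis=axis)
    return fisher_exact(table, axis=axis, unit=unit, n_dropped_missing=dropped)
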