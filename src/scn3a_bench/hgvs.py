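"""Protein-level HGVS parsing for missense substitutions.

Handles the ``p.Ile875Thr`` / ``p.I875T`` notation used in clinical variant
tables. Only simple single-residue missense substitutions are supported —
frameshifts, stops, indels and synonymous changes are rejected, because the
benchmark is defined over missense variants only.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from Bio.Data.IUPACData import protein_letters_1to3, protein_letters_3to1

# Canonical code tables (one-letter <-> three-letter, title case e.g. "Ile").
_ONE_TO_THREE = dict(protein_letters_1to3)
_THREE_TO_ONE = {k.capitalize(): v for k, v in protein_letters_3to1.items()}

_HGVS_RE = re.compile(
    r"^(?:p\.)?\(?"
    r"(?P<ref>[A-Za-z]{1,3})"
    r"(?P<pos>\d+)"
    r"(?P<alt>[A-Za-z]{1,3})"
    r"\)?$"
)


class HgvsParseError(ValueError):
    """Raised when a protein HGVS string cannot be parsed as a missense change."""


def _canonical_aa(token: str) -> str:
    """Return the three-letter code for a one- or three-letter token."""
    if len(token) == 1:
        code = token.upper()
        if code not in _ONE_TO_THREE:
            raise HgvsParseError(f"unknown amino-acid code {token!r}")
        return _ONE_TO_THREE[code]
    token = token.capitalize()
    if token not in _THREE_TO_ONE:
        raise HgvsParseError(f"unknown amino-acid code {token!r}")
    return token


@dataclass(frozen=True, order=True)
class AminoAcidChange:
    """A single amino-acid substitution on the canonical protein.

    Ordering is (position, alt, ref) so sorted variant lists come out in
    ascending residue order with alphabetical tie-breaks.
    """

    position: int
    alt_aa: str
    ref_aa: str

    def __post_init__(self) -> None:
        if self.position < 1:
            raise HgvsParseError(f"residue position must be >= 1, got {self.position}")
        for aa in (self.ref_aa, self.alt_aa):
            if aa not in _THREE_TO_ONE:
                raise HgvsParseError(f"unknown amino-acid code {aa!r}")
        if self.ref_aa == self.alt_aa:
            raise HgvsParseError(
                f"synonymous change p.{self.ref_aa}{self.position}{self.alt_aa} "
                "is not a missense variant"
            )

    @property
    def ref_one(self) -> str:
        return _THREE_TO_ONE[self.ref_aa]

    @property
    def alt_one(self) -> str:
        return _THREE_TO_ONE[self.alt_aa]

    def format(self, style: str = "three") -> str:
        """Render as HGVS: ``p.Ile875Thr`` (three) or ``p.I875T`` (one)."""
        if style == "three":
            return f"p.{self.ref_aa}{self.position}{self.alt_aa}"
        if style == "one":
            return f"p.{self.ref_one}{self.position}{self.alt_one}"
        raise ValueError(f"unknown style {style!r}")

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.format()


def parse_protein_hgvs(text: str) -> AminoAcidChange:
    """Parse a protein HGVS missense string into an :class:`AminoAcidChange`.

    Accepts one-letter and three-letter residue codes, with or without the
    ``p.`` prefix; the result is canonicalized to three-letter codes so that
    ``parse_protein_hgvs(change.format())`` is the identity.

    Raises
    ------
    HgvsParseError
        On malformed input, unknown residue codes, or a synonymous change.
    """
    if not isinstance(text, str):
        raise HgvsParseError(f"expected a string, got {type(text).__name__}")
    m = _HGVS_RE.match(text.strip())
    if m is None:
        raise HgvsParseError(f"cannot parse protein change {text!r}")
    ref, alt = m.group("ref"), m.group("alt")
    if len(ref) == 2 or len(alt) == 2:
        raise HgvsParseError(f"cannot parse protein change {text!r}")
    return AminoAcidChange(
        position=int(m.group("pos")),
        ref_aa=_canonical_aa(ref),
        alt_aa=_canonical_aa(alt),
    )
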