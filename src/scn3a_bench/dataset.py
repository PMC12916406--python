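"""Curated variant/patient tables: parsing, validation, deduplication, summary.

The curated cohort has two shapes of input TSV:

``patients`` — one row per reported patient (clinical columns: sex, EEG, MRI,
development, diagnosis, inheritance, allele frequencies, source). All rows of
a patients table carry a curation label (typically ``pathogenic``).

``variants`` — one row per variant with a curation label (used for the
benign/likely-benign control list).

Labels collapse to the binary design: {pathogenic, likely pathogenic} ->
``pathogenic``; {benign, likely benign} -> ``benign``. Missing cells are "–",
"-", "." or empty, and parse to missing — never to False.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .hgvs import AminoAcidChange, HgvsParseError, parse_protein_hgvs

MISSING_TOKENS = {"", ".", "-", "–", "—", "na", "n/a", "nan", "none", "null"}

_LABEL_MAP = {
    "pathogenic": "pathogenic",
    "likely pathogenic": "pathogenic",
    "likely_pathogenic": "pathogenic",
    "p": "pathogenic",
    "lp": "pathogenic",
    "benign": "benign",
    "likely benign": "benign",
    "likely_benign": "benign",
    "benign/likely benign": "benign",
    "b": "benign",
    "lb": "benign",
}

_INHERITANCE_MAP = {
    "de novo": "de_novo",
    "de_novo": "de_novo",
    "denovo": "de_novo",
    "inherited": "inherited",
}


class DatasetError(ValueError):
    """Raised for malformed or inconsistent curated tables."""


@dataclass(frozen=True)
class VariantRecord:
    change: AminoAcidChange
    label: str  # "pathogenic" | "benign"
    cdna: str | None = None
    source_id: str | None = None
    allele_freqs: Mapping[str, float] | None = None

    def __post_init__(self) -> None:
        if self.label not in ("pathogenic", "benign"):
            raise DatasetError(f"label must be pathogenic|benign, got {self.label!r}")
        if self.allele_freqs:
            for cohort, freq in self.allele_freqs.items():
                if not (0.0 <= freq <= 1.0):
                    raise DatasetError(
                        f"allele frequency {freq!r} for cohort {cohort!r} outside [0, 1]"
                    )


@dataclass(frozen=True)
class PatientRecord:
    variant: VariantRecord
    sex: str = "unknown"  # M | F | unknown
    diagnosis: str | None = None
    seizures: bool | None = None
    polymicrogyria: bool | None = None
    inheritance: str = "unknown"  # de_novo | inherited | unknown
    annotations: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.sex not in ("M", "F", "unknown"):
            raise DatasetError(f"sex must be M|F|unknown, got {self.sex!r}")
        if self.inheritance not in ("de_novo", "inherited", "unknown"):
            raise DatasetError(f"bad inheritance {self.inheritance!r}")


@dataclass(frozen=True)
class CuratedDataset:
    """Patients plus the deduplicated variant list they map onto."""

    patients: tuple[PatientRecord, ...]
    variants: tuple[VariantRecord, ...]

    def __post_init__(self) -> None:
        changes = [v.change for v in self.variants]
        if len(set(changes)) != len(changes):
            raise DatasetError("variant list contains duplicate amino-acid changes")
        known = set(changes)
        for p in self.patients:
            if p.variant.change not in known:
                raise DatasetError(
                    f"patient variant {p.variant.change} missing from variant list"
                )

    @classmethod
    def from_patients(
        cls,
        patients: Iterable[PatientRecord],
        extra_variants: Iterable[VariantRecord] = (),
    ) -> "CuratedDataset":
        patients = tuple(patients)
        pool = [p.variant for p in patients] + list(extra_variants)
        return cls(patients=patients, variants=tuple(deduplicate_variants(pool)))

    def merge(self, other: "CuratedDataset") -> "CuratedDataset":
        return CuratedDataset.from_patients(
            self.patients + other.patients,
            extra_variants=self.variants + other.variants,
        )


def _clean(value: object) -> str | None:
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return None
    text = str(value).strip()
    return None if text.lower() in MISSING_TOKENS else text


def normalize_label(raw: str) -> str:
    try:
        return _LABEL_MAP[raw.strip().lower()]
    except KeyError:
        raise DatasetError(f"unrecognized curation label {raw!r}") from None


def _parse_inheritance(raw: str | None) -> str:
    if raw is None:
        return "unknown"
    text = raw.strip().lower().replace("*", "")
    for key, value in _INHERITANCE_MAP.items():
        if text.startswith(key) or key in text:
            return value
    return "unknown"


def _parse_sex(raw: str | None) -> str:
    if raw is None:
        return "unknown"
    text = raw.strip().upper()
    return text if text in ("M", "F") else "unknown"


def _derive_seizures(diagnosis: str | None) -> bool | None:
    """Seizure flag implied by the diagnosis tag.

    DEE and focal-epilepsy diagnoses imply seizures; an explicit
    "without EP" tag implies none; anything else stays missing.
    """
    if diagnosis is None:
        return None
    tag = diagnosis.strip().lower()
    if "without ep" in tag:
        return False
    if tag in ("dee", "fe") or "epilep" in tag or tag.endswith("with ep"):
        return True
    return None


def _derive_polymicrogyria(mri: str | None) -> bool | None:
    if mri is None:
        return None
    return "pmg" in mri.lower() or "polymicrogyria" in mri.lower()


def deduplicate_variants(
    variants: Iterable[VariantRecord],
) -> list[VariantRecord]:
    """Collapse repeated amino-acid changes to one record each.

    Records that repeat a change must agree on the curation label; a conflict
    is a hard error. Output order is deterministic: ascending residue
    position, then alphabetical alternate residue.
    """
    seen: dict[AminoAcidChange, VariantRecord] = {}
    for rec in variants:
        prev = seen.get(rec.change)
        if prev is None:
            seen[rec.change] = rec
        elif prev.label != rec.label:
            raise DatasetError(
                f"conflicting labels for {rec.change.format()}: "
                f"{prev.label!r} vs {rec.label!r}"
            )
    return [seen[c] for c in sorted(seen)]


_PATIENT_CLINICAL = ("cdna", "sex", "eeg", "mri", "development", "diagnosis",
                     "inheritance", "af_v4", "af_v2", "source")


def load_dataset(path: str | Path, format: str = "patients") -> CuratedDataset:
    """Read a curated TSV into a :class:`CuratedDataset`.

    Parameters
    ----------
    path:
        Tab-delimited UTF-8 file with a header row. Required columns:
        ``variant`` always; ``label`` for the variants format (patients
        tables default to pathogenic when the column is absent).
    format:
        ``"patients"`` (one row per reported case, clinical columns kept as
        annotations) or ``"variants"`` (one row per labeled variant).

    Raises
    ------
    DatasetError
        Missing required columns, unparseable rows (reported with their row
        number), or the same change carrying conflicting labels.
    """
    if format not in ("patients", "variants"):
        raise ValueError(f"format must be patients|variants, got {format!r}")
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    df.columns = [c.strip().lower().replace(" ", "_") for c in df.columns]
    if "variant" not in df.columns:
        raise DatasetError(f"{path}: required column 'variant' missing")
    if format == "variants" and "label" not in df.columns:
        raise DatasetError(f"{path}: required column 'label' missing")

    problems: list[str] = []
    patients: list[PatientRecord] = []
    variants: list[VariantRecord] = []
    for idx, row in df.iterrows():
        rownum = int(idx) + 2  # 1-based plus header line
        try:
            change = parse_protein_hgvs(row["variant"])
            raw_label = _clean(row.get("label"))
            label = normalize_label(raw_label) if raw_label else "pathogenic"
            freqs = {}
            for col, cohort in (("af_v4", "gnomad_v4"), ("af_v2", "gnomad_v2")):
                val = _clean(row.get(col))
                if val is not None:
                    freqs[cohort] = float(val)
            rec = VariantRecord(
                change=change,
                label=label,
                cdna=_clean(row.get("cdna")),
                source_id=_clean(row.get("source")),
                allele_freqs=freqs or None,
            )
            if format == "patients":
                diagnosis = _clean(row.get("diagnosis"))
                extras = {
                    col: val
                    for col in df.columns
                    if col not in ("variant", "label")
                    and (val := _clean(row.get(col))) is not None
                }
                patients.append(
                    PatientRecord(
                        variant=rec,
                        sex=_parse_sex(_clean(row.get("sex"))),
                        diagnosis=diagnosis,
                        seizures=_derive_seizures(diagnosis),
                        polymicrogyria=_derive_polymicrogyria(_clean(row.get("mri"))),
                        inheritance=_parse_inheritance(_clean(row.get("inheritance"))),
                        annotations=extras,
                    )
                )
            variants.append(rec)
        except (HgvsParseError, DatasetError, ValueError) as exc:
            problems.append(f"row {rownum}: {exc}")
    if problems:
        raise DatasetError(f"{path}: " + "; ".join(problems))
    return CuratedDataset(
        patients=tuple(patients), variants=tuple(deduplicate_variants(variants))
    )


def summarize_cohort(ds: CuratedDataset) -> dict:
    """Headline counts: patients, unique variants per label, diagnosis and
    inheritance tallies. Patients partition exactly across diagnosis tags
    plus ``untagged``."""
    by_label: dict[str, int] = {"pathogenic": 0, "benign": 0}
    for v in ds.variants:
        by_label[v.label] += 1
    diagnoses: dict[str, int] = {}
    inheritance: dict[str, int] = {}
    for p in ds.patients:
        diagnoses[p.diagnosis or "untagged"] = diagnoses.get(p.diagnosis or "untagged", 0) + 1
        inheritance[p.inheritance] = inheritance.get(p.inheritance, 0) + 1
    return {
        "n_patients": len(ds.patients),
        "n_variants": len(ds.variants),
        "pathogenic_unique": by_label["pathogenic"],
        "benign_unique": by_label["benign"],
        "diagnoses": diagnoses,
        "inheritance": inheritance,
    }


def curated_cases_path() -> Path:
    """Path of the packaged curated patients fixture (reported cases table)."""
    return Path(__file__).parent / "data" / "curated_case_table.tsv"


def load_curated_cases() -> CuratedDataset:
    """Load the packaged curated cohort of reported affected cases."""
    return load_dataset(curated_cases_path(), format="patients")
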