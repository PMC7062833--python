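"""Reading, validation and alignment of the cohort input tables.

Three tables describe a cohort:

* an immune-parameter table — one row per blood sample (subject id,
  postnatal age in days, then one column per flow-cytometry-derived
  parameter: subset frequencies in %, MFI, or absolute counts);
* a family-level taxa table — one row per stool sample, relative
  abundances summing to 1;
* an adult reference table — the same immune parameters, one row per
  adult donor.

Parameter kind is carried in the column name with a ``name|kind`` suffix
(``frequency_percent``, ``mfi`` or ``absolute_count``); a bare name means
``frequency_percent``.  Missing cells (empty or ``NA``) stay missing — no
imputation happens at I/O time.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PARAM_KINDS",
    "ClinicalRecord",
    "ImmuneMatrix",
    "TaxaTable",
    "CohortBundle",
    "read_immune_table",
    "read_taxa_table",
    "read_clinical_table",
    "read_adult_reference",
    "assemble_cohort",
    "write_immune_table",
    "write_taxa_table",
]

PARAM_KINDS = ("frequency_percent", "mfi", "absolute_count")
GROUPS = ("stable", "unstable", "BCM")
_KEY_COLS = ["subject_id", "postnatal_age_days"]

#: days in a 40-week term gestation; "days preterm" counts down from it
TERM_DAYS = 280.0


class CohortValidationError(ValueError):
    """Raised when an input table violates a structural contract."""


@dataclass(frozen=True)
class ClinicalRecord:
    subject_id: str
    gestational_age_days: float
    group: str
    sex: str = "unknown"

    @property
    def days_preterm(self) -> float:
        return TERM_DAYS - self.gestational_age_days


def _split_kind(name: str) -> tuple[str, str]:
    if "|" in name:
        base, kind = name.rsplit("|", 1)
        if kind not in PARAM_KINDS:
            raise CohortValidationError(
                f"unknown parameter kind {kind!r} in column {name!r}"
            )
        return base, kind
    return name, "frequency_percent"


@dataclass
class ImmuneMatrix:
    """Samples x parameters grid keyed by (subject_id, postnatal_age_days)."""

    data: pd.DataFrame  # index (subject_id, postnatal_age_days), float cols
    kinds: dict[str, str] = field(default_factory=dict)

    @property
    def parameters(self) -> list[str]:
        return list(self.data.columns)

    @property
    def sample_keys(self) -> pd.MultiIndex:
        return self.data.index

    def validate(self) -> "ImmuneMatrix":
        if self.data.index.duplicated().any():
            dup = self.data.index[self.data.index.duplicated()][0]
            raise CohortValidationError(f"duplicate sample key {dup}")
        if len(set(self.data.columns)) != len(self.data.columns):
            raise CohortValidationError("parameter names are not unique")
        ages = self.data.index.get_level_values("postnatal_age_days")
        if (np.asarray(ages, dtype=float) < 0).any():
            raise CohortValidationError("negative postnatal age")
        for col in self.data.columns:
            if self.kinds.get(col, "frequency_percent") == "frequency_percent":
                vals = self.data[col].dropna()
                bad = vals[(vals < 0) | (vals > 100)]
                if len(bad):
                    raise CohortValidationError(
                        f"frequency parameter {col!r} outside [0, 100] "
                        f"for sample {bad.index[0]} (value {bad.iloc[0]})"
                    )
        return self


@dataclass
class TaxaTable:
    """Relative family abundances; every row sums to 1."""

    data: pd.DataFrame  # index (subject_id, postnatal_age_days), one col/family

    @property
    def families(self) -> list[str]:
        return list(self.data.columns)

    def validate(self) -> "TaxaTable":
        if self.data.index.duplicated().any():
            dup = self.data.index[self.data.index.duplicated()][0]
            raise CohortValidationError(f"duplicate sample key {dup}")
        arr = self.data.to_numpy(dtype=float)
        if np.isnan(arr).any():
            raise CohortValidationError("taxa table contains missing abundances")
        if (arr < 0).any():
            r, c = np.argwhere(arr < 0)[0]
            raise CohortValidationError(
                f"negative abundance for {self.data.columns[c]!r} "
                f"in sample {self.data.index[r]}"
            )
        sums = arr.sum(axis=1)
        bad = np.where((sums < 0.99) | (sums > 1.01))[0]
        if len(bad):
            raise CohortValidationError(
                f"abundance row {self.data.index[bad[0]]} sums to "
                f"{sums[bad[0]]:.4f}, outside [0.99, 1.01]"
            )
        # renormalise rows within the 1% tolerance band
        self.data = self.data.div(sums, axis=0)
        return self


@dataclass
class CohortBundle:
    """Aligned immune + taxa + clinical view of one cohort."""

    immune: ImmuneMatrix
    clinical: dict[str, ClinicalRecord]
    taxa: TaxaTable | None = None
    adult_reference: pd.DataFrame | None = None  # adults x parameters

    @property
    def subjects(self) -> list[str]:
        subj = set(self.immune.data.index.get_level_values("subject_id"))
        if self.taxa is not None:
            subj |= set(self.taxa.data.index.get_level_values("subject_id"))
        return sorted(subj)

    def group_of(self, subject_id: str) -> str:
        return self.clinical[subject_id].group


def _read_keyed_table(path, sep) -> pd.DataFrame:
    df = pd.read_csv(path, sep=sep, na_values=["", "NA"], keep_default_na=False)
    missing = [c for c in _KEY_COLS if c not in df.columns]
    if missing:
        raise CohortValidationError(f"{path}: missing key column(s) {missing}")
    for col in df.columns:
        if col == "subject_id":
            continue
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df[col].notna() & coerced.isna()
        if bad.any():
            row = int(np.where(bad)[0][0])
            raise CohortValidationError(
                f"{path}: non-numeric value {df[col][bad].iloc[0]!r} "
                f"in row {row}, column {col!r}"
            )
        df[col] = coerced
    df["subject_id"] = df["subject_id"].astype(str)
    return df.set_index(_KEY_COLS)


def read_immune_table(path: str | Path) -> ImmuneMatrix:
    """Read a blood-sample immune-parameter CSV.

    Missing cells stay NaN (missing != zero).  Frequencies outside
    [0, 100] or duplicated (subject, age) keys are hard errors.
    """
    df = _read_keyed_table(path, sep=",")
    kinds, renames = {}, {}
    for col in df.columns:
        base, kind = _split_kind(col)
        renames[col] = base
        kinds[base] = kind
    df = df.rename(columns=renames)
    return ImmuneMatrix(data=df.astype(float), kinds=kinds).validate()


def read_taxa_table(path: str | Path) -> TaxaTable:
    """Read a family-level relative-abundance table (TSV or CSV by suffix)."""
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = _read_keyed_table(path, sep=sep)
    return TaxaTable(data=df.astype(float)).validate()


def read_clinical_table(path: str | Path) -> dict[str, ClinicalRecord]:
    df = pd.read_csv(path, na_values=["", "NA"], keep_default_na=False)
    records: dict[str, ClinicalRecord] = {}
    for _, row in df.iterrows():
        sid = str(row["subject_id"])
        if sid in records:
            raise CohortValidationError(f"subject {sid!r} has two clinical rows")
        group = str(row["group"])
        if group not in GROUPS:
            raise CohortValidationError(
                f"unknown clinical group {group!r} for subject {sid!r}"
            )
        records[sid] = ClinicalRecord(
            subject_id=sid,
            gestational_age_days=float(row["gestational_age_days"]),
            group=group,
            sex=str(row.get("sex", "unknown")) if pd.notna(row.get("sex")) else "unknown",
        )
    return records


def read_adult_reference(path: str | Path) -> pd.DataFrame:
    """Adult donor table: one row per donor, same parameter columns."""
    df = pd.read_csv(path, na_values=["", "NA"], keep_default_na=False)
    if "donor_id" in df.columns:
        df = df.set_index("donor_id")
    renames = {c: _split_kind(c)[0] for c in df.columns}
    return df.rename(columns=renames).astype(float)


def assemble_cohort(
    immune: ImmuneMatrix,
    clinical: Mapping[str, ClinicalRecord],
    taxa: TaxaTable | None = None,
    adult_reference: pd.DataFrame | None = None,
) -> CohortBundle:
    """Cross-reference the tables into one bundle.

    Every immune sample's subject must have a clinical record; subjects
    present only in the taxa table are retained (stool and blood sampling
    schedules differ, so a 100% match is not expected).
    """
    for sid in immune.data.index.get_level_values("subject_id").unique():
        if sid not in clinical:
            raise CohortValidationError(
                f"immune sample references unknown subject {sid!r}"
            )
    if taxa is not None:
        for sid in taxa.data.index.get_level_values("subject_id").unique():
            if sid not in clinical:
                raise CohortValidationError(
                    f"taxa sample references unknown subject {sid!r}"
                )
    if adult_reference is not None:
        if set(adult_reference.columns) != set(immune.parameters):
            raise CohortValidationError(
                "adult reference parameters do not match immune parameters"
            )
        adult_reference = adult_reference[immune.parameters]
    return CohortBundle(
        immune=immune,
        clinical=dict(clinical),
        taxa=taxa,
        adult_reference=adult_reference,
    )


def write_immune_table(matrix: ImmuneMatrix, path: str | Path) -> None:
    df = matrix.data.copy()
    df.columns = [
        f"{c}|{matrix.kinds[c]}" if matrix.kinds.get(c, "frequency_percent") != "frequency_percent" else c
        for c in df.columns
    ]
    df.reset_index().to_csv(path, index=False)


def write_taxa_table(table: TaxaTable, path: str | Path) -> None:
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    table.data.reset_index().to_csv(path, sep=sep, index=False)
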