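"""Data model, CSV I/O and harmonization of sperm metabolic-rate records.

One :class:`MetabolicRecord` is a single observation of ejaculate-level
oxygen consumption (µl O₂ h⁻¹) at a known sperm concentration
(sperm ml⁻¹), with the covariates the comparative analysis uses
(thermoregulation, fertilization mode, diluent chemistry and role, sperm
handling) and reporting provenance: whether the rate was reported as
measured ("actual") or linearly rescaled to a reference concentration
("standardized").

Harmonization undoes that linear rescaling: a standardized rate Z reported
at reference concentration C_std but measured at concentration C_actual is
mapped back to the measured rate Z / C_std × C_actual, exactly inverting
the transformation the original report applied.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import pandas as pd

THERMOREGULATION = frozenset({"endotherm", "ectotherm"})
FERTILIZATION_MODE = frozenset({"internal", "external"})
DILUENT = frozenset({"carbohydrate_free", "carbohydrate_containing"})
DILUENT_JOB = frozenset({"activator", "extender", "unknown"})
HANDLING = frozenset({"fresh", "cooled", "frozen_thawed", "unknown"})
REPORTING = frozenset({"actual", "standardized"})

#: Column order of the on-disk CSV schema.
CSV_COLUMNS = [
    "species",
    "thermoregulation",
    "fertilization_mode",
    "diluent",
    "diluent_job",
    "handling",
    "concentration_sperm_per_ml",
    "rate_ul_o2_per_h",
    "reporting",
    "std_concentration_sperm_per_ml",
    "assay_volume_ml",
    "n_replicates",
    "source",
]


class ValidationError(ValueError):
    """Raised when one or more rows violate the record schema.

    Carries a list of ``(row_number, message)`` diagnostics so no invalid
    row is silently dropped.
    """

    def __init__(self, problems: list[tuple[int, str]]):
        self.problems = problems
        lines = "; ".join(f"row {r}: {m}" for r, m in problems[:20])
        more = "" if len(problems) <= 20 else f" (+{len(problems) - 20} more)"
        super().__init__(f"{len(problems)} invalid row(s): {lines}{more}")


@dataclass
class MetabolicRecord:
    """One species-level observation of sperm metabolic rate.

    ``concentration`` is the sperm concentration at which respiration was
    actually measured; it may be ``None`` only for standardized reports
    whose source never disclosed the measured concentration — such records
    cannot be back-calculated and are excluded from model fits but kept
    for auditability.
    """

    species: str
    thermoregulation: str
    concentration: Optional[float]  # sperm ml^-1
    rate: float  # µl O2 h^-1
    reporting: str = "actual"
    fertilization_mode: str = "external"
    diluent: str = "carbohydrate_free"
    diluent_job: str = "unknown"
    handling: str = "unknown"
    std_concentration: Optional[float] = None  # sperm ml^-1
    assay_volume: Optional[float] = None  # ml
    n_replicates: Optional[int] = None
    source: str = ""
    duplicate: bool = field(default=False, compare=False)

    @property
    def excluded_from_fit(self) -> bool:
        """Standardized reports without a measured concentration cannot
        enter the scaling fit."""
        return self.reporting == "standardized" and self.concentration is None

    def validate(self) -> list[str]:
        """Return a list of problems (empty if the record is valid)."""
        problems: list[str] = []
        if self.thermoregulation not in THERMOREGULATION:
            problems.append(f"unknown thermoregulation {self.thermoregulation!r}")
        if self.fertilization_mode not in FERTILIZATION_MODE:
            problems.append(f"unknown fertilization_mode {self.fertilization_mode!r}")
        if self.diluent not in DILUENT:
            problems.append(f"unknown diluent {self.diluent!r}")
        if self.diluent_job not in DILUENT_JOB:
            problems.append(f"unknown diluent_job {self.diluent_job!r}")
        if self.handling not in HANDLING:
            problems.append(f"unknown handling {self.handling!r}")
        if self.reporting not in REPORTING:
            problems.append(f"unknown reporting {self.reporting!r}")
        if not (self.rate > 0):
            problems.append(f"rate must be > 0, got {self.rate!r}")
        if self.concentration is not None and not (self.concentration > 0):
            problems.append(f"concentration must be > 0, got {self.concentration!r}")
        if self.concentration is None and self.reporting == "actual":
            problems.append("actual record lacks a concentration")
        if self.reporting == "standardized" and self.std_concentration is None:
            problems.append("standardized record lacks std_concentration")
        if self.std_concentration is not None and not (self.std_concentration > 0):
            problems.append(
                f"std_concentration must be > 0, got {self.std_concentration!r}"
            )
        if self.assay_volume is not None and not (self.assay_volume > 0):
            problems.append(f"assay_volume must be > 0, got {self.assay_volume!r}")
        return problems


@dataclass
class Dataset:
    """An ordered collection of metabolic records with provenance text."""

    records: list[MetabolicRecord]
    provenance: str = ""

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def flag_duplicates(self) -> int:
        """Mark repeated (species, source, concentration, rate) tuples.

        Duplicates are flagged, never merged or dropped; the first
        occurrence stays unflagged. Returns the number flagged.
        """
        seen: set[tuple] = set()
        n = 0
        for rec in self.records:
            key = (rec.species, rec.source, rec.concentration, rec.rate)
            if key in seen:
                rec.duplicate = True
                n += 1
            else:
                seen.add(key)
        return n

    def fit_records(self) -> list[MetabolicRecord]:
        """Records usable by the scaling fit: actual reporting with a
        positive measured concentration."""
        return [
            r
            for r in self.records
            if r.reporting == "actual" and r.concentration is not None
        ]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            rows.append(
                {
                    "species": r.species,
                    "thermoregulation": r.thermoregulation,
                    "fertilization_mode": r.fertilization_mode,
                    "diluent": r.diluent,
                    "diluent_job": r.diluent_job,
                    "handling": r.handling,
                    "concentration_sperm_per_ml": r.concentration,
                    "rate_ul_o2_per_h": r.rate,
                    "reporting": r.reporting,
                    "std_concentration_sperm_per_ml": r.std_concentration,
                    "assay_volume_ml": r.assay_volume,
                    "n_replicates": r.n_replicates,
                    "source": r.source,
                }
            )
        return pd.DataFrame(rows, columns=CSV_COLUMNS)


def _opt_float(value) -> Optional[float]:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    if isinstance(value, str) and value.strip() == "":
        return None
    return float(value)


def _opt_int(value) -> Optional[int]:
    f = _opt_float(value)
    return None if f is None else int(f)


def read_records(path) -> Dataset:
    """Read a records CSV (UTF-8, comma separated, '.' decimal, header
    required; scientific notation accepted for concentrations).

    Every row is either accepted or reported in a :class:`ValidationError`
    with its line number (header = line 1, first data row = line 2).
    """
    df = pd.read_csv(path, dtype={"species": str, "source": str})
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError([(1, f"missing column(s): {', '.join(missing)}")])

    records: list[MetabolicRecord] = []
    problems: list[tuple[int, str]] = []
    for i, row in enumerate(df.itertuples(index=False)):
        line_no = i + 2
        try:
            rec = MetabolicRecord(
                species=str(getattr(row, "species")),
                thermoregulation=str(getattr(row, "thermoregulation")),
                fertilization_mode=str(getattr(row, "fertilization_mode")),
                diluent=str(getattr(row, "diluent")),
                diluent_job=str(getattr(row, "diluent_job")),
                handling=str(getattr(row, "handling")),
                concentration=_opt_float(getattr(row, "concentration_sperm_per_ml")),
                rate=float(getattr(row, "rate_ul_o2_per_h")),
                reporting=str(getattr(row, "reporting")),
                std_concentration=_opt_float(
                    getattr(row, "std_concentration_sperm_per_ml")
                ),
                assay_volume=_opt_float(getattr(row, "assay_volume_ml")),
                n_replicates=_opt_int(getattr(row, "n_replicates")),
                source="" if pd.isna(getattr(row, "source")) else str(getattr(row, "source")),
            )
        except (TypeError, ValueError) as exc:
            problems.append((line_no, f"unparseable row: {exc}"))
            continue
        row_problems = rec.validate()
        if row_problems:
            problems.extend((line_no, p) for p in row_problems)
        else:
            records.append(rec)
    if problems:
        raise ValidationError(problems)
    ds = Dataset(records=records, provenance=str(path))
    ds.flag_duplicates()
    return ds


def write_records(dataset: Dataset, path) -> None:
    """Write the dataset to CSV in the documented schema (lossless round
    trip with :func:`read_records`)."""
    dataset.to_frame().to_csv(path, index=False)


def back_calculate_actual_rate(
    standardized_rate: float,
    std_concentration: float,
    actual_concentration: float,
) -> float:
    """Invert linear standardization of a metabolic rate.

    A standardized rate is the measured rate multiplied by
    ``std_concentration / actual_concentration``; dividing by the reference
    concentration and multiplying by the measured one recovers the rate as
    measured:

        R_actual = Z / C_std × C_actual

    Parameters
    ----------
    standardized_rate : µl O₂ h⁻¹ reported at the reference concentration.
    std_concentration : reference sperm concentration (sperm ml⁻¹).
    actual_concentration : concentration at which respiration was measured.

    Examples
    --------
    >>> back_calculate_actual_rate(1.34, 1e8, 3e8)
    4.02
    """
    for name, v in (
        ("standardized_rate", standardized_rate),
        ("std_concentration", std_concentration),
        ("actual_concentration", actual_concentration),
    ):
        if not (v > 0):
            raise ValueError(f"{name} must be > 0, got {v!r}")
    return standardized_rate / std_concentration * actual_concentration


def back_calculate_record(record: MetabolicRecord) -> MetabolicRecord:
    """Return a copy of a standardized record restored to its measured
    ("actual") rate. Actual records pass through unchanged."""
    if record.reporting != "standardized":
        return record
    if record.concentration is None:
        raise ValueError(
            f"record from {record.source!r} is standardized without a measured "
            "concentration; cannot back-calculate"
        )
    rate = back_calculate_actual_rate(
        record.rate, record.std_concentration, record.concentration
    )
    return replace(record, rate=rate, reporting="actual")


def harmonize_dataset(dataset: Dataset) -> tuple[Dataset, int]:
    """Back-calculate every standardized record with a known measured
    concentration; leave non-convertible standardized records in place
    (they carry ``excluded_from_fit``).

    Returns the harmonized dataset and the count of records that could not
    be converted.
    """
    out: list[MetabolicRecord] = []
    n_excluded = 0
    for rec in dataset.records:
        if rec.excluded_from_fit:
            n_excluded += 1
            out.append(rec)
        else:
            out.append(back_calculate_record(rec))
    return Dataset(records=out, provenance=dataset.provenance), n_excluded


def per_capita_rate(record: MetabolicRecord, default_volume: float = 1.0) -> float:
    """Oxygen consumption per spermatozoon (µl O₂ spermatozoon⁻¹ h⁻¹).

    Divides the ejaculate-level rate by the total number of sperm in the
    assay chamber, ``concentration × volume``; the chamber volume is the
    record's ``assay_volume`` when reported, else ``default_volume`` (ml).
    The result is homogeneous of degree −1 in concentration, so on log-log
    axes the per-capita slope is the ejaculate-level slope minus one.
    """
    if record.concentration is None:
        raise ValueError("record has no measured concentration")
    volume = record.assay_volume if record.assay_volume is not None else default_volume
    if not (volume > 0):
        raise ValueError(f"volume must be > 0, got {volume!r}")
    return record.rate / (record.concentration * volume)
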