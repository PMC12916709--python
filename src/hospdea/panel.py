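"""Hospital-year panel handling.

A panel is a rectangular set of hospital-year records: staffing (salaried and
civil-law contract headcounts per role), bed stock, inpatient activity,
contextual indicators (length of stay, bed occupancy) and financial lines in
nominal currency. One record per (hospital, year) is one decision-making unit
(DMU) for frontier estimation.

The package ships the published 3-hospital x 10-year panel (2015-2024) as a
fixture. Surgical-procedure counts were never published for that panel and are
stored as missing; any DMU matrix that selects them must either fail loudly or
be built through a documented fallback.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .dea import DMUSet
from .errors import MissingOutputError, PanelValidationError, SchemaError

__all__ = [
    "HospitalYearRecord",
    "PanelDataset",
    "DomainSpec",
    "ValidationReport",
    "OPERATIONAL_SPEC",
    "FINANCIAL_SPEC",
    "OPERATIONAL_SINGLE_OUTPUT_SPEC",
    "FINANCIAL_NO_SURGERY_SPEC",
    "load_panel",
    "write_panel",
    "load_fixture_panel",
    "total_headcount",
    "derive_throughput",
    "percent_change",
    "round_half_away",
    "build_dmu_set",
    "validate_panel",
]

#: numeric record fields in canonical column order
NUMERIC_FIELDS = (
    "physicians_employed",
    "physicians_contract",
    "nurses_employed",
    "nurses_contract",
    "other_medical_staff",
    "beds",
    "hospitalisations",
    "avg_length_of_stay",
    "surgical_procedures",
    "bed_occupancy",
    "net_revenue",
    "operating_costs",
)

#: fields that must be non-negative counts/currency (extra financial lines
#: such as profit/loss may legitimately be negative and are exempt)
NON_NEGATIVE_FIELDS = tuple(f for f in NUMERIC_FIELDS)

STUDY_YEAR_RANGE = (1990, 2100)


@dataclass
class HospitalYearRecord:
    """One hospital-year observation."""

    hospital_id: str
    year: int
    beds: float
    physicians_employed: float
    physicians_contract: float
    nurses_employed: float
    nurses_contract: float
    other_medical_staff: float
    hospitalisations: float
    avg_length_of_stay: float
    bed_occupancy: float  # percent, reported as published (not re-derived)
    operating_costs: float  # nominal currency (thousand PLN for the fixture)
    net_revenue: float
    surgical_procedures: float | None = None  # None = unavailable
    extra_financial_lines: dict[str, float] = field(default_factory=dict)

    @property
    def key(self) -> tuple[str, int]:
        return (self.hospital_id, self.year)


@dataclass
class PanelDataset:
    """A keyed collection of hospital-year records."""

    records: list[HospitalYearRecord]
    provenance: str = "user file"  # fixture | user file | synthetic

    def __post_init__(self) -> None:
        keys = [r.key for r in self.records]
        if len(set(keys)) != len(keys):
            dupes = sorted({k for k in keys if keys.count(k) > 1})
            raise PanelValidationError(f"duplicate (hospital, year) keys: {dupes}")

    def __len__(self) -> int:
        return len(self.records)

    def __getitem__(self, key: tuple[str, int]) -> HospitalYearRecord:
        for r in self.records:
            if r.key == key:
                return r
        raise KeyError(key)

    @property
    def hospitals(self) -> list[str]:
        out: list[str] = []
        for r in self.records:
            if r.hospital_id not in out:
                out.append(r.hospital_id)
        return out

    @property
    def years(self) -> list[int]:
        return sorted({r.year for r in self.records})

    def subset(self, years: Iterable[int]) -> "PanelDataset":
        ys = set(years)
        return PanelDataset(
            [r for r in self.records if r.year in ys], provenance=self.provenance
        )


@dataclass(frozen=True)
class DomainSpec:
    """Which record fields enter the DMU matrices, and in what order.

    Selectors are record field names plus the derived aggregates
    ``physicians_total`` and ``nurses_total`` (salaried + civil-law contract,
    counted once at the institutional level).
    """

    name: str
    input_fields: tuple[str, ...]
    output_fields: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.input_fields or not self.output_fields:
            raise ValueError("a domain needs at least one input and one output")


OPERATIONAL_SPEC = DomainSpec(
    "operational",
    input_fields=("beds", "physicians_total", "nurses_total", "other_medical_staff"),
    output_fields=("hospitalisations", "surgical_procedures"),
)
FINANCIAL_SPEC = DomainSpec(
    "financial",
    input_fields=("operating_costs", "beds"),
    output_fields=("net_revenue", "hospitalisations", "surgical_procedures"),
)
# Documented fallbacks for panels without surgical-procedure counts.
OPERATIONAL_SINGLE_OUTPUT_SPEC = DomainSpec(
    "operational_single_output",
    input_fields=OPERATIONAL_SPEC.input_fields,
    output_fields=("hospitalisations",),
)
FINANCIAL_NO_SURGERY_SPEC = DomainSpec(
    "financial_no_surgery",
    input_fields=FINANCIAL_SPEC.input_fields,
    output_fields=("net_revenue", "hospitalisations"),
)


@dataclass
class ValidationReport:
    issues: list[tuple[str, tuple[str, int] | None, str]] = field(default_factory=list)

    def add(self, severity: str, key, message: str) -> None:
        self.issues.append((severity, key, message))

    @property
    def passed(self) -> bool:
        return not any(sev == "error" for sev, _, _ in self.issues)

    def errors(self):
        return [i for i in self.issues if i[0] == "error"]

    def warnings(self):
        return [i for i in self.issues if i[0] == "warning"]


def round_half_away(value: float, ndigits: int = 0) -> float:
    """Round half away from zero (reporting convention for all tables)."""
    factor = 10.0 ** ndigits
    scaled = value * factor
    return math.floor(abs(scaled) + 0.5) * (1.0 if scaled >= 0 else -1.0) / factor


def total_headcount(record: HospitalYearRecord, role: str) -> float:
    """Institution-level headcount: salaried plus civil-law contracts."""
    if role == "physicians":
        return record.physicians_employed + record.physicians_contract
    if role == "nurses":
        return record.nurses_employed + record.nurses_contract
    raise ValueError(f"unknown role {role!r}; expected 'physicians' or 'nurses'")


def derive_throughput(record: HospitalYearRecord) -> float:
    """Annual patients per bed. Reporting rounds to the nearest integer."""
    if record.beds <= 0:
        if record.hospitalisations > 0:
            raise PanelValidationError(
                f"{record.key}: activity with zero beds"
            )
        return 0.0
    return record.hospitalisations / record.beds


def percent_change(first: float, last: float) -> float:
    """100 * (last - first) / first."""
    if first == 0:
        raise ValueError("percent change undefined for a zero baseline")
    return 100.0 * (last - first) / first


def resolve_field(record: HospitalYearRecord, selector: str) -> float | None:
    if selector == "physicians_total":
        return total_headcount(record, "physicians")
    if selector == "nurses_total":
        return total_headcount(record, "nurses")
    try:
        return getattr(record, selector)
    except AttributeError:
        if selector in record.extra_financial_lines:
            return record.extra_financial_lines[selector]
        raise ValueError(f"unknown field selector {selector!r}") from None


# ---------------------------------------------------------------------------
# I/O

_CORE_COLUMNS = ("hospital", "year") + NUMERIC_FIELDS


def _parse_cell(raw: str, column: str, rownum: int) -> float | None:
    raw = raw.strip()
    if raw == "" or raw.upper() in {"NA", "NAN", "UNAVAILABLE"}:
        return None
    try:
        return float(raw)
    except ValueError:
        raise SchemaError(
            f"row {rownum}: cannot parse {column}={raw!r} as a number"
        ) from None


def load_panel(
    path: str | Path,
    schema: Mapping[str, str] | None = None,
    provenance: str = "user file",
) -> PanelDataset:
    """Read a long-format CSV (one row per hospital-year) into a panel.

    ``schema`` maps canonical field names to the file's column names; fields
    not mentioned keep their canonical name. Extra numeric columns are carried
    as labelled financial lines. Empty cells are explicit missing markers,
    never silently coerced; only ``surgical_procedures`` may be missing.
    """
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"panel file not found: {path}")
    colmap = {f: f for f in _CORE_COLUMNS}
    if schema:
        colmap.update(schema)

    with path.open(newline="") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        missing = [colmap[f] for f in _CORE_COLUMNS if colmap[f] not in header
                   and f != "surgical_procedures"]
        if not header:
            raise SchemaError(f"{path}: empty file")
        if missing:
            raise SchemaError(f"{path}: missing columns {missing}")
        extra_cols = [c for c in header if c not in set(colmap.values())]

        records = []
        for rownum, row in enumerate(reader, start=2):
            hospital = row[colmap["hospital"]].strip()
            year_raw = row[colmap["year"]].strip()
            try:
                year = int(year_raw)
            except ValueError:
                raise SchemaError(f"row {rownum}: bad year {year_raw!r}") from None
            values: dict[str, float | None] = {}
            for f in NUMERIC_FIELDS:
                col = colmap[f]
                values[f] = _parse_cell(row.get(col, ""), col, rownum)
            for f in NUMERIC_FIELDS:
                v = values[f]
                if v is None and f != "surgical_procedures":
                    raise SchemaError(f"row {rownum}: missing value for {f}")
                if v is not None and f in NON_NEGATIVE_FIELDS and v < 0:
                    raise PanelValidationError(
                        f"row {rownum}: negative value for {f}: {v}"
                    )
            extra = {}
            for c in extra_cols:
                v = _parse_cell(row.get(c, ""), c, rownum)
                if v is not None:
                    extra[c] = v
            records.append(
                HospitalYearRecord(
                    hospital_id=hospital,
                    year=year,
                    beds=values["beds"],
                    physicians_employed=values["physicians_employed"],
                    physicians_contract=values["physicians_contract"],
                    nurses_employed=values["nurses_employed"],
                    nurses_contract=values["nurses_contract"],
                    other_medical_staff=values["other_medical_staff"],
                    hospitalisations=values["hospitalisations"],
                    avg_length_of_stay=values["avg_length_of_stay"],
                    bed_occupancy=values["bed_occupancy"],
                    operating_costs=values["operating_costs"],
                    net_revenue=values["net_revenue"],
                    surgical_procedures=values["surgical_procedures"],
                    extra_financial_lines=extra,
                )
            )
    if not records:
        raise SchemaError(f"{path}: no data rows")
    return PanelDataset(records, provenance=provenance)


def _fmt(v: float | None) -> str:
    if v is None:
        return ""
    if float(v).is_integer():
        return str(int(v))
    return repr(float(v))


def write_panel(panel: PanelDataset, path: str | Path) -> None:
    """Write a panel back to CSV; numeric cells round-trip exactly."""
    extra_cols: list[str] = []
    for r in panel.records:
        for k in r.extra_financial_lines:
            if k not in extra_cols:
                extra_cols.append(k)
    with Path(path).open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(list(_CORE_COLUMNS) + extra_cols)
        for r in panel.records:
            row = [r.hospital_id, r.year]
            row += [_fmt(getattr(r, f)) for f in NUMERIC_FIELDS]
            row += [_fmt(r.extra_financial_lines.get(c)) for c in extra_cols]
            w.writerow(row)


def load_fixture_panel() -> PanelDataset:
    """The packaged published panel: 3 hospitals x 10 years (2015-2024)."""
    ref = resources.files("hospdea.data").joinpath("hospital_panel.csv")
    with resources.as_file(ref) as p:
        return load_panel(p, provenance="fixture")


# ---------------------------------------------------------------------------
# Validation and DMU construction

def validate_panel(panel: PanelDataset) -> ValidationReport:
    """Check invariants; issues are reported, never raised."""
    report = ValidationReport()
    lo, hi = STUDY_YEAR_RANGE
    for r in panel.records:
        for f in NON_NEGATIVE_FIELDS:
            v = getattr(r, f)
            if v is not None and v < 0:
                report.add("error", r.key, f"negative {f}: {v}")
        if not lo <= r.year <= hi:
            report.add("error", r.key, f"year {r.year} outside study range")
        if r.beds <= 0 and r.hospitalisations > 0:
            report.add("error", r.key, "activity reported with zero beds")
        if r.surgical_procedures is None:
            report.add("warning", r.key, "surgical_procedures unavailable")
    # key completeness: full hospital x year grid
    keys = {r.key for r in panel.records}
    for h in panel.hospitals:
        for y in panel.years:
            if (h, y) not in keys:
                report.add("error", (h, y), "missing (hospital, year) combination")
    return report


def build_dmu_set(
    panel: PanelDataset,
    spec: DomainSpec,
    years: Iterable[int] | str = "all",
) -> DMUSet:
    """Assemble the m x n input and s x n output matrices for a domain.

    Columns are hospital-year DMUs labelled ``HOSP:YEAR`` in record order.
    A selector hitting an unavailable field raises :class:`MissingOutputError`
    naming the field, so an impossible model specification cannot run silently.
    """
    if years == "all":
        records = list(panel.records)
    else:
        ys = set(years)
        if not ys:
            raise ValueError("empty year filter")
        records = [r for r in panel.records if r.year in ys]
    if not records:
        raise ValueError("no records selected")

    def column(selectors: Sequence[str]) -> np.ndarray:
        rows = []
        for sel in selectors:
            vals = []
            missing_keys = []
            for r in records:
                v = resolve_field(r, sel)
                if v is None:
                    missing_keys.append(r.key)
                vals.append(v)
            if missing_keys:
                raise MissingOutputError(sel, missing_keys)
            rows.append(vals)
        return np.asarray(rows, dtype=float)

    X = column(spec.input_fields)
    Y = column(spec.output_fields)
    labels = [f"{r.hospital_id}:{r.year}" for r in records]
    return DMUSet(inputs=X, outputs=Y, labels=labels)
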