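"""Readers for monthly claims report tables, eligibility counts and the CPI.

The national claims processor publishes, per calendar month, tabular
reports of the top-100 medications (ranked by prescribing frequency and,
separately, by ingredient cost) and of total prescribing by therapeutic
group, plus scheme-eligibility counts broken down by geographic area. A
column-mapping profile decouples these readers from file-layout drift:
the same reader handles the synthetic CSV dialect and (via a different
profile) portal/archive workbooks.

Cleaning rules applied downstream of reading:

* :func:`merge_rankings` unifies the frequency-ranked and cost-ranked
  medication lists for one month into a single entity set;
* :func:`exclude_nonmedication_groups` drops product groups from the
  "Various" (V) physiological system that are published at 3rd ATC level
  among the medications (urinary requisites, diagnostic agents, needles...)
  — these are not individual medications and are carried only in the
  therapeutic-group data.
"""

from __future__ import annotations

import enum
import json
import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict

from .atc import AtcCode, ancestor, parse_atc
from .errors import DataValidationError, RowParseError, SchemaError
from .months import Month

logger = logging.getLogger(__name__)


class Category(str, enum.Enum):
    MEDICATION = "medication"
    THERAPEUTIC_GROUP = "therapeutic_group"


class Basis(str, enum.Enum):
    FREQUENCY_RANKED = "frequency_ranked"
    COST_RANKED = "cost_ranked"


class ColumnMapping(BaseModel):
    """Maps the package's field names onto source-file column headers."""

    model_config = ConfigDict(extra="forbid")

    entity_name: str = "entity_name"
    atc_code: str = "atc_code"
    frequency: str = "frequency"
    pct_frequency: str = "pct_frequency"
    ingredient_cost: str = "ingredient_cost"
    pct_cost: str = "pct_cost"
    month: str = "month"
    area: str = "area"
    count: str = "count"
    sheet: str | int = 0

    @classmethod
    def load(cls, path: str | Path) -> "ColumnMapping":
        """Load a mapping profile from a YAML or JSON file."""
        text = Path(path).read_text()
        data = yaml.safe_load(text) if str(path).endswith((".yaml", ".yml")) else json.loads(text)
        return cls.model_validate(data)


#: profile matching the bundled synthetic-data generator's CSV dialect
SYNTHETIC_PROFILE = ColumnMapping()


def default_profile(name: str = "synthetic") -> ColumnMapping:
    """Load one of the mapping profiles shipped with the package."""
    here = Path(__file__).parent / "profiles" / f"{name}.yaml"
    if not here.exists():
        raise SchemaError(f"no bundled mapping profile named {name!r}")
    return ColumnMapping.load(here)


@dataclass(frozen=True)
class ReportRow:
    """One entity's line in a monthly report table.

    ``pct_frequency`` / ``pct_cost`` are the published shares of all scheme
    dispensings/cost for the month; they are carried through as printed,
    never re-derived.
    """

    entity_name: str
    atc: AtcCode
    frequency: float
    pct_frequency: float
    ingredient_cost: float
    pct_cost: float
    basis: Basis

    def __post_init__(self) -> None:
        if self.frequency < 0:
            raise DataValidationError(
                f"negative frequency {self.frequency} for {self.atc.code}"
            )
        if self.ingredient_cost < 0:
            raise DataValidationError(
                f"negative ingredient cost {self.ingredient_cost} for {self.atc.code}"
            )
        for label, pct in (("pct_frequency", self.pct_frequency), ("pct_cost", self.pct_cost)):
            if not 0 <= pct <= 100:
                raise DataValidationError(
                    f"{label} {pct} outside [0, 100] for {self.atc.code}"
                )


@dataclass
class MonthlyReport:
    """One month's parsed report table for one category.

    Rows preserve file order, which is the published rank order. At most
    one row per (ATC code, basis).
    """

    month: Month
    category: Category
    rows: list[ReportRow] = field(default_factory=list)
    scheme: str = "GMS"

    def __post_init__(self) -> None:
        seen = set()
        for row in self.rows:
            key = (row.atc.code, row.basis)
            if key in seen:
                raise DataValidationError(
                    f"duplicate row for {row.atc.code} ({row.basis.value}) in {self.month}"
                )
            seen.add(key)

    def row_for(self, code: str) -> ReportRow | None:
        for row in self.rows:
            if row.atc.code == code:
                return row
        return None

    @property
    def codes(self) -> set[str]:
        return {row.atc.code for row in self.rows}


def _read_table(path: str | Path, sheet: str | int) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"input file not found: {path}")
    if path.suffix.lower() in {".xlsx", ".xlsm"}:
        return pd.read_excel(path, sheet_name=sheet, engine="openpyxl")
    return pd.read_csv(path)


def _require_columns(frame: pd.DataFrame, needed: dict[str, str], path) -> None:
    missing = [col for col in needed.values() if col not in frame.columns]
    if missing:
        raise SchemaError(
            f"{path}: missing mapped column(s) {missing}; found {list(frame.columns)}"
        )


def _cell_float(value, column: str, row_index: int) -> float:
    """Parse a numeric cell, stripping currency formatting; NaN is an error."""
    if isinstance(value, str):
        value = value.replace(",", "").replace("€", "").strip()
    try:
        out = float(value)
    except (TypeError, ValueError):
        raise RowParseError(
            f"row {row_index}: cannot parse {column}={value!r} as a number",
            row=row_index,
        ) from None
    if math.isnan(out):
        raise RowParseError(f"row {row_index}: {column} is empty/NaN", row=row_index)
    return out


def read_monthly_report(
    path: str | Path,
    mapping: ColumnMapping,
    month: Month | str,
    category: Category | str,
    basis: Basis | str,
) -> MonthlyReport:
    """Read and validate one monthly report table (CSV or XLSX).

    Rows come back in file order, i.e. published rank order. A file with a
    header but zero data rows is a valid empty report; a missing file is an
    error.
    """
    month = Month.parse(month)
    category = Category(category)
    basis = Basis(basis)
    frame = _read_table(path, mapping.sheet)
    needed = {
        "entity_name": mapping.entity_name,
        "atc_code": mapping.atc_code,
        "frequency": mapping.frequency,
        "pct_frequency": mapping.pct_frequency,
        "ingredient_cost": mapping.ingredient_cost,
        "pct_cost": mapping.pct_cost,
    }
    _require_columns(frame, needed, path)

    rows = []
    for i, record in enumerate(frame.itertuples(index=False)):
        record = dict(zip(frame.columns, record))
        atc = parse_atc(str(record[mapping.atc_code]))
        rows.append(
            ReportRow(
                entity_name=str(record[mapping.entity_name]),
                atc=atc,
                frequency=_cell_float(record[mapping.frequency], "frequency", i),
                pct_frequency=_cell_float(record[mapping.pct_frequency], "pct_frequency", i),
                ingredient_cost=_cell_float(
                    record[mapping.ingredient_cost], "ingredient_cost", i
                ),
                pct_cost=_cell_float(record[mapping.pct_cost], "pct_cost", i),
                basis=basis,
            )
        )
    return MonthlyReport(month=month, category=category, rows=rows)


def read_eligibility(path: str | Path, mapping: ColumnMapping) -> dict[Month, int]:
    """Read scheme-eligibility counts; per month, the total over all areas.

    The source publishes counts by geographic area (at two overlapping
    breakdown levels); exactly one level must be present in the file handed
    to this reader so areas sum without double counting. Duplicate
    (month, area) pairs are an error.
    """
    frame = _read_table(path, mapping.sheet)
    _require_columns(
        frame, {"month": mapping.month, "area": mapping.area, "count": mapping.count}, path
    )
    totals: dict[Month, int] = {}
    seen: set[tuple[Month, str]] = set()
    for i, record in enumerate(frame.to_dict("records")):
        month = Month.parse(record[mapping.month])
        area = str(record[mapping.area])
        count = _cell_float(record[mapping.count], "count", i)
        if count < 0:
            raise DataValidationError(f"row {i}: negative eligibility count {count}")
        if (month, area) in seen:
            raise DataValidationError(f"duplicate eligibility record for {month}, area {area!r}")
        seen.add((month, area))
        totals[month] = totals.get(month, 0) + int(round(count))
    for month, total in totals.items():
        if total <= 0:
            raise DataValidationError(f"eligibility total for {month} is not positive")
    return dict(sorted(totals.items()))


def read_cpi(path: str | Path, mapping: ColumnMapping, value_column: str = "cpi") -> dict[Month, float]:
    """Read the monthly Consumer Price Index series (one positive value/month)."""
    frame = _read_table(path, mapping.sheet)
    _require_columns(frame, {"month": mapping.month, "cpi": value_column}, path)
    if len(frame) == 0:
        raise DataValidationError(f"{path}: no CPI rows")
    series: dict[Month, float] = {}
    for i, record in enumerate(frame.to_dict("records")):
        month = Month.parse(record[mapping.month])
        value = _cell_float(record[value_column], "cpi", i)
        if value <= 0:
            raise DataValidationError(f"row {i}: CPI index must be positive, got {value}")
        if month in series:
            raise DataValidationError(f"duplicate CPI record for {month}")
        series[month] = value
    return dict(sorted(series.items()))


def merge_rankings(
    freq_report: MonthlyReport,
    cost_report: MonthlyReport,
    rel_tol: float = 1e-6,
) -> MonthlyReport:
    """Union of the frequency-ranked and cost-ranked lists for one month.

    An entity on both lists yields one row. When the two listings disagree
    numerically beyond *rel_tol*, the frequency-ranked row is kept (frequency
    is the primary ordering) and a data-quality warning is logged.
    """
    if freq_report.month != cost_report.month:
        raise DataValidationError(
            f"cannot merge reports for different months "
            f"({freq_report.month} vs {cost_report.month})"
        )
    if freq_report.category != cost_report.category or freq_report.scheme != cost_report.scheme:
        raise DataValidationError("cannot merge reports with different category or scheme")

    merged = list(freq_report.rows)
    freq_codes = freq_report.codes
    for row in cost_report.rows:
        if row.atc.code not in freq_codes:
            merged.append(row)
            continue
        kept = freq_report.row_for(row.atc.code)
        agree = all(
            math.isclose(a, b, rel_tol=rel_tol, abs_tol=1e-9)
            for a, b in (
                (kept.frequency, row.frequency),
                (kept.ingredient_cost, row.ingredient_cost),
            )
        )
        if not agree:
            logger.warning(
                "ranking conflict for %s in %s: frequency-ranked row kept "
                "(freq %s vs %s, cost %s vs %s)",
                row.atc.code, freq_report.month,
                kept.frequency, row.frequency,
                kept.ingredient_cost, row.ingredient_cost,
            )
    return MonthlyReport(
        month=freq_report.month,
        category=freq_report.category,
        rows=merged,
        scheme=freq_report.scheme,
    )


def exclude_nonmedication_groups(report: MonthlyReport) -> MonthlyReport:
    """Drop V-system product groups published below ATC level 5.

    Applies only to medication reports: rows whose code is shallower than
    level 5 and whose physiological system is "V" (various — urinary
    requisites, diagnostic agents, needles...) are removed; they are not
    individual medications and remain available in the therapeutic-group
    data. Idempotent.
    """
    if report.category != Category.MEDICATION:
        raise DataValidationError("exclusion pass applies to medication reports only")
    kept = [
        row
        for row in report.rows
        if not (row.atc.level < 5 and ancestor(row.atc, 1).code == "V")
    ]
    removed = len(report.rows) - len(kept)
    if removed:
        logger.info(
            "excluded %d non-medication V-system row(s) from %s", removed, report.month
        )
    return replace(report, rows=kept)
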