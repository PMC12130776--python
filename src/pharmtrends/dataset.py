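"""Load a bundle directory into an analysable dataset.

A bundle directory holds one CSV per month and category, named
``<scheme>_<category>_<basis>_<YYYY-MM>.csv``, plus ``eligibility.csv``
and ``cpi.csv`` — the layout written by :mod:`pharmtrends.synthetic` and
expected from any adapter that normalises portal/archive files.

Loading applies the standard cleaning pass per month: the frequency- and
cost-ranked medication lists are merged into one entity set, and
non-medication V-system groups are excluded from the medication data.

Series for the three analysis levels come from different places:

* level 5 (medications): merged top-N medication reports (censored);
* level 2 (therapeutic groups): the group reports, complete totals;
* level 1 (physiological systems): sum of that system's level-2 group
  rows — valid because group reports are untruncated.
"""

from __future__ import annotations

import logging
import re
from pathlib import Path

from .atc import AtcCode, ancestor, parse_atc
from .errors import DataValidationError, SchemaError
from .ingest import (
    Basis,
    Category,
    ColumnMapping,
    MonthlyReport,
    exclude_nonmedication_groups,
    merge_rankings,
    read_cpi,
    read_eligibility,
    read_monthly_report,
)
from .metrics import (
    DeriveOptions,
    Metric,
    MetricName,
    MetricPoint,
    MetricSeries,
    PointStatus,
    build_series,
    derive_series,
)
from .months import Month, month_range

logger = logging.getLogger(__name__)

_FILE_RE = re.compile(
    r"^(?P<scheme>[A-Za-z0-9]+)_(?P<category>medication|therapeutic_group)"
    r"_(?P<basis>frequency|cost)_(?P<month>\d{4}-\d{2})\.csv$"
)


class Dataset:
    """All monthly reports, eligibility and CPI for one scheme, in memory."""

    def __init__(
        self,
        medication_reports: dict[Month, MonthlyReport],
        group_reports: dict[Month, MonthlyReport],
        eligibility: dict[Month, int],
        cpi: dict[Month, float],
        scheme: str = "GMS",
    ):
        self.medication_reports = medication_reports
        self.group_reports = group_reports
        self.eligibility = eligibility
        self.cpi = cpi
        self.scheme = scheme

    @classmethod
    def load(
        cls,
        directory: str | Path,
        mapping: ColumnMapping | None = None,
        scheme: str = "GMS",
    ) -> "Dataset":
        directory = Path(directory)
        if not directory.is_dir():
            raise SchemaError(f"dataset directory not found: {directory}")
        mapping = mapping or ColumnMapping()

        found: dict[tuple[str, str, Month], Path] = {}
        for path in sorted(directory.glob("*.csv")):
            m = _FILE_RE.match(path.name)
            if m and m.group("scheme") == scheme:
                found[(m.group("category"), m.group("basis"), Month.parse(m.group("month")))] = path
        if not found:
            raise SchemaError(f"no {scheme} report files found in {directory}")

        med_months = sorted({k[2] for k in found if k[0] == "medication"})
        med_reports: dict[Month, MonthlyReport] = {}
        for month in med_months:
            freq = read_monthly_report(
                found[("medication", "frequency", month)], mapping, month,
                Category.MEDICATION, Basis.FREQUENCY_RANKED,
            )
            cost_key = ("medication", "cost", month)
            if cost_key in found:
                cost = read_monthly_report(
                    found[cost_key], mapping, month,
                    Category.MEDICATION, Basis.COST_RANKED,
                )
                merged = merge_rankings(freq, cost)
            else:
                merged = freq
            med_reports[month] = exclude_nonmedication_groups(merged)

        group_reports = {
            month: read_monthly_report(
                path, mapping, month, Category.THERAPEUTIC_GROUP, Basis.FREQUENCY_RANKED
            )
            for (category, _basis, month), path in found.items()
            if category == "therapeutic_group"
        }

        elig_path = directory / "eligibility.csv"
        cpi_path = directory / "cpi.csv"
        eligibility = read_eligibility(elig_path, mapping) if elig_path.exists() else {}
        cpi = read_cpi(cpi_path, mapping) if cpi_path.exists() else {}
        return cls(med_reports, group_reports, eligibility, cpi, scheme=scheme)

    # -- introspection ------------------------------------------------------

    @property
    def months(self) -> list[Month]:
        keys = set(self.medication_reports) | set(self.group_reports)
        return sorted(keys)

    def entities(self, category: Category | str = Category.MEDICATION) -> dict[str, str]:
        """Available ATC codes → last-seen display name for a category."""
        category = Category(category)
        reports = (
            self.medication_reports
            if category == Category.MEDICATION
            else self.group_reports
        )
        out: dict[str, str] = {}
        for month in sorted(reports):
            for row in reports[month].rows:
                out[row.atc.code] = row.entity_name
        return out

    def available_codes(self) -> list[str]:
        """Every selectable code: medications, groups and their systems."""
        codes = set(self.entities(Category.MEDICATION))
        groups = set(self.entities(Category.THERAPEUTIC_GROUP))
        systems = {ancestor(parse_atc(g), 1).code for g in groups}
        return sorted(codes | groups | systems)

    # -- series -------------------------------------------------------------

    def raw_series(self, entity: AtcCode | str, metric_name: MetricName) -> MetricSeries:
        """Raw frequency or cost series at any of the three analysis levels."""
        if isinstance(entity, str):
            entity = parse_atc(entity)
        metric_name = MetricName(metric_name)
        if metric_name not in (MetricName.PRESCRIBING_FREQUENCY, MetricName.INGREDIENT_COST):
            raise DataValidationError("raw_series serves frequency and cost only")
        if entity.level == 5:
            return build_series(
                [self.medication_reports[m] for m in sorted(self.medication_reports)],
                entity, metric_name,
            )
        if entity.level == 2:
            return build_series(
                [self.group_reports[m] for m in sorted(self.group_reports)],
                entity, metric_name,
            )
        if entity.level == 1:
            return self._system_series(entity, metric_name)
        raise DataValidationError(
            f"no report category holds level-{entity.level} entities ({entity.code})"
        )

    def _system_series(self, entity: AtcCode, metric_name: MetricName) -> MetricSeries:
        # physiological system = sum of its (complete) level-2 group rows
        months = sorted(self.group_reports)
        if not months:
            raise DataValidationError("no therapeutic-group reports loaded")
        points = []
        for m in month_range(months[0], months[-1]):
            report = self.group_reports.get(m)
            if report is None:
                points.append(MetricPoint(m, None, PointStatus.MISSING))
                continue
            values = [
                row.frequency if metric_name is MetricName.PRESCRIBING_FREQUENCY else row.ingredient_cost
                for row in report.rows
                if ancestor(row.atc, 1).code == entity.code
            ]
            if values:
                points.append(MetricPoint(m, float(sum(values)), PointStatus.OBSERVED))
            else:
                points.append(MetricPoint(m, None, PointStatus.MISSING))
        return MetricSeries(entity, Metric(metric_name), points)

    def series(
        self,
        entity: AtcCode | str,
        metric: MetricName | Metric | str,
        options: DeriveOptions = DeriveOptions(),
    ) -> MetricSeries:
        """Fully derived metric series for one entity."""
        if isinstance(metric, str):
            metric = MetricName(metric)
        metric_name = metric.name if isinstance(metric, Metric) else metric
        freq = cost = None
        from .metrics import COST_BEARING  # local to avoid import cycle noise

        if metric_name in (
            MetricName.PRESCRIBING_FREQUENCY,
            MetricName.COST_PER_PRESCRIBING,
            MetricName.PRESCRIBING_RATE,
        ):
            freq = self.raw_series(entity, MetricName.PRESCRIBING_FREQUENCY)
        if metric_name in COST_BEARING:
            cost = self.raw_series(entity, MetricName.INGREDIENT_COST)
        return derive_series(
            freq, cost, metric,
            eligibility=self.eligibility, cpi=self.cpi, options=options,
        )

    def comparison(
        self,
        child: AtcCode | str,
        parent: AtcCode | str,
        metric: MetricName | str,
        options: DeriveOptions = DeriveOptions(),
    ):
        from .compare import proportion_of_parent

        child_series = self.series(child, metric, options)
        parent_series = self.series(parent, metric, options)
        return proportion_of_parent(child_series, parent_series)

    def summary(self) -> dict:
        """Validation summary used by the CLI's ingest/cache step."""
        months = self.months
        return {
            "scheme": self.scheme,
            "months": [str(m) for m in months],
            "n_months": len(months),
            "n_medications": len(self.entities(Category.MEDICATION)),
            "n_therapeutic_groups": len(self.entities(Category.THERAPEUTIC_GROUP)),
            "eligibility_months": len(self.eligibility),
            "cpi_months": len(self.cpi),
        }
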