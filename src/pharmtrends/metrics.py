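"""Month-indexed metric series and the five dispensing metrics.

Five metrics are derived per entity (medication, therapeutic group or
physiological system) and month:

====================  =======================================================
prescribing_frequency dispensings per month (raw report value)
ingredient_cost       total ingredient cost, EUR per month (raw report value)
cost_per_prescribing  mean ingredient cost per dispensing, EUR
prescribing_rate      dispensings per 1,000 scheme-eligible persons
cost_rate             ingredient cost (EUR) per 1,000 scheme-eligible persons
====================  =======================================================

Cost-bearing metrics can additionally be deflated with a monthly Consumer
Price Index, normalised to a reference month (by default the most recent
month the CPI covers), so costs are expressed at that month's prices.

Missing-data semantics are central: the medication reports are top-100
censored, so an entity absent from a month's report has an *unknown* value
(at most the 100th-ranked one) — represented as ``missing``, never as zero.
Missing propagates through every derivation step.

A known one-off transmission disruption shifted most of one month's claims
into the next (May → June 2021 in the national data). The correction
replaces both months, where both are observed, by their weighted mean
(weights default to calendar days per month); a value observed for only
one of the two months is kept as-is and never copied to the other.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace

from .atc import AtcCode
from .errors import DataValidationError
from .ingest import Category, MonthlyReport
from .months import Month, month_range

_EPS_ZERO = 0.0


class MetricName(str, enum.Enum):
    PRESCRIBING_FREQUENCY = "prescribing_frequency"
    INGREDIENT_COST = "ingredient_cost"
    COST_PER_PRESCRIBING = "cost_per_prescribing"
    PRESCRIBING_RATE = "prescribing_rate"
    COST_RATE = "cost_rate"


#: metrics with a EUR numerator, eligible for inflation adjustment
COST_BEARING = frozenset(
    {MetricName.INGREDIENT_COST, MetricName.COST_PER_PRESCRIBING, MetricName.COST_RATE}
)

#: units for presentation (axis labels, export documentation)
METRIC_UNITS = {
    MetricName.PRESCRIBING_FREQUENCY: "dispensings/month",
    MetricName.INGREDIENT_COST: "EUR/month",
    MetricName.COST_PER_PRESCRIBING: "EUR/dispensing",
    MetricName.PRESCRIBING_RATE: "dispensings per 1,000 eligible persons",
    MetricName.COST_RATE: "EUR per 1,000 eligible persons",
}


@dataclass(frozen=True)
class Metric:
    """A metric name plus whether it is inflation-adjusted."""

    name: MetricName
    adjusted_for_inflation: bool = False

    def __post_init__(self) -> None:
        if self.adjusted_for_inflation and self.name not in COST_BEARING:
            raise DataValidationError(
                f"inflation adjustment is undefined for {self.name.value}"
            )

    def __str__(self) -> str:
        return self.name.value + ("_adjusted" if self.adjusted_for_inflation else "")


class PointStatus(str, enum.Enum):
    OBSERVED = "observed"
    IMPUTED = "imputed"
    MISSING = "missing"


@dataclass(frozen=True)
class MetricPoint:
    month: Month
    value: float | None
    status: PointStatus = PointStatus.OBSERVED

    def __post_init__(self) -> None:
        if self.status is PointStatus.MISSING and self.value is not None:
            raise DataValidationError("a missing point cannot carry a value")
        if self.status is not PointStatus.MISSING and self.value is None:
            raise DataValidationError(f"{self.status.value} point requires a value")

    @property
    def missing(self) -> bool:
        return self.status is PointStatus.MISSING


MISSING = None  # sentinel alias for readability in constructors


@dataclass
class MetricSeries:
    """Month-indexed values of one metric for one entity.

    Months are strictly increasing with no duplicates; points with
    ``status=missing`` mark top-N censored (or otherwise unobservable)
    months and carry no value.
    """

    entity: AtcCode
    metric: Metric
    points: list[MetricPoint] = field(default_factory=list)

    def __post_init__(self) -> None:
        for prev, nxt in zip(self.points, self.points[1:]):
            if nxt.month <= prev.month:
                raise DataValidationError(
                    f"series months must be strictly increasing "
                    f"({prev.month} then {nxt.month})"
                )

    def __len__(self) -> int:
        return len(self.points)

    @property
    def months(self) -> list[Month]:
        return [p.month for p in self.points]

    def point_at(self, month: Month) -> MetricPoint | None:
        for p in self.points:
            if p.month == month:
                return p
        return None

    def value_at(self, month: Month) -> float | None:
        p = self.point_at(month)
        return None if p is None else p.value

    def observed(self) -> list[MetricPoint]:
        return [p for p in self.points if not p.missing]

    def map_values(self, fn, metric: Metric | None = None) -> "MetricSeries":
        """Apply *fn* to every non-missing value; missing passes through."""
        points = [
            p if p.missing else replace(p, value=fn(p.value)) for p in self.points
        ]
        return MetricSeries(self.entity, metric or self.metric, points)


def build_series(
    reports: list[MonthlyReport],
    entity: AtcCode,
    metric_name: MetricName,
) -> MetricSeries:
    """Assemble the raw series of one entity from a run of monthly reports.

    *reports* must span a contiguous month range (one report per month);
    months where the entity is absent (below the published top-N cutoff)
    become ``missing`` points — never zeros.
    """
    metric_name = MetricName(metric_name)
    if metric_name not in (MetricName.PRESCRIBING_FREQUENCY, MetricName.INGREDIENT_COST):
        raise DataValidationError(
            f"build_series reads raw report values only, not {metric_name.value}"
        )
    if not reports:
        raise DataValidationError("no reports supplied")
    by_month = {r.month: r for r in reports}
    if len(by_month) != len(reports):
        raise DataValidationError("duplicate report months supplied")
    months = month_range(min(by_month), max(by_month))
    gaps = [m for m in months if m not in by_month]
    if gaps:
        raise DataValidationError(f"reports do not span a contiguous range; missing {gaps[0]}")

    category = reports[0].category
    expected_level = 5 if category == Category.MEDICATION else 2
    if entity.level != expected_level:
        raise DataValidationError(
            f"entity {entity.code} is ATC level {entity.level}; "
            f"{category.value} reports hold level-{expected_level} entities"
        )

    points = []
    for m in months:
        row = by_month[m].row_for(entity.code)
        if row is None:
            points.append(MetricPoint(m, None, PointStatus.MISSING))
        else:
            value = row.frequency if metric_name is MetricName.PRESCRIBING_FREQUENCY else row.ingredient_cost
            points.append(MetricPoint(m, value, PointStatus.OBSERVED))
    name = next((by_month[m].row_for(entity.code).entity_name for m in months
                 if by_month[m].row_for(entity.code) is not None), None)
    entity = AtcCode(entity.code, entity.level, name=entity.name or name)
    return MetricSeries(entity, Metric(metric_name), points)


# ---------------------------------------------------------------------------
# scalar derivations


def prescribing_rate(frequency: float, eligible: float) -> float:
    """Dispensings per 1,000 eligible persons: frequency / eligible × 1000."""
    if eligible <= 0:
        raise DataValidationError(f"eligible persons must be positive, got {eligible}")
    return frequency / eligible * 1000.0


def cost_rate(cost: float, eligible: float) -> float:
    """EUR per 1,000 eligible persons: cost / eligible × 1000."""
    if eligible <= 0:
        raise DataValidationError(f"eligible persons must be positive, got {eligible}")
    return cost / eligible * 1000.0


def cost_per_prescribing(cost: float, frequency: float) -> float | None:
    """Mean ingredient cost per dispensing; undefined (None) at frequency 0."""
    if frequency < 0:
        raise DataValidationError(f"frequency must be non-negative, got {frequency}")
    if frequency == _EPS_ZERO:
        return None
    return cost / frequency


def deflate(value: float, cpi_month: float, cpi_reference: float) -> float:
    """Express a nominal EUR value at reference-month prices."""
    if cpi_month <= 0 or cpi_reference <= 0:
        raise DataValidationError("CPI indices must be positive")
    return value * cpi_reference / cpi_month


# ---------------------------------------------------------------------------
# disruption correction


def correct_disruption(
    series: MetricSeries,
    month_a: Month | str,
    month_b: Month | str,
    weights: tuple[float, float] | None = None,
) -> MetricSeries:
    """Smooth a known two-month transmission disruption.

    When both months carry values, both are replaced by the weighted mean
    ``(w_a·x_a + w_b·x_b) / (w_a + w_b)`` with ``status=imputed``. When only
    one month is observed the series is returned unchanged (the observed
    value is kept for its own month and never applied to the other); with
    neither observed the series is also unchanged.

    *weights* default to the number of calendar days in each month.
    """
    month_a, month_b = Month.parse(month_a), Month.parse(month_b)
    if weights is None:
        weights = (float(month_a.days), float(month_b.days))
    w_a, w_b = weights
    if w_a <= 0 or w_b <= 0:
        raise DataValidationError(f"disruption weights must be positive, got {weights}")
    months = series.months
    for m in (month_a, month_b):
        if m not in months:
            raise DataValidationError(f"disruption month {m} outside series range")

    p_a, p_b = series.point_at(month_a), series.point_at(month_b)
    if p_a.missing or p_b.missing:
        return series
    mean = (w_a * p_a.value + w_b * p_b.value) / (w_a + w_b)
    points = [
        MetricPoint(p.month, mean, PointStatus.IMPUTED)
        if p.month in (month_a, month_b)
        else p
        for p in series.points
    ]
    return MetricSeries(series.entity, series.metric, points)


# ---------------------------------------------------------------------------
# full derivation pipeline


@dataclass(frozen=True)
class DeriveOptions:
    """Knobs for the metric derivation pipeline.

    disruption        optional (month_a, month_b) pair to correct
    weights           disruption weights; None → calendar days per month
    adjust_inflation  deflate cost-bearing metrics with the CPI
    reference_month   CPI normalisation month; None → latest CPI month
    """

    disruption: tuple[Month | str, Month | str] | None = None
    weights: tuple[float, float] | None = None
    adjust_inflation: bool = False
    reference_month: Month | str | None = None


def _combine_status(*statuses: PointStatus) -> PointStatus:
    if PointStatus.MISSING in statuses:
        return PointStatus.MISSING
    if PointStatus.IMPUTED in statuses:
        return PointStatus.IMPUTED
    return PointStatus.OBSERVED


def derive_series(
    frequency: MetricSeries | None,
    cost: MetricSeries | None,
    metric: MetricName | Metric,
    eligibility: dict[Month, int] | None = None,
    cpi: dict[Month, float] | None = None,
    options: DeriveOptions = DeriveOptions(),
) -> MetricSeries:
    """Derive one of the five metrics from raw frequency/cost series.

    The steps run in a fixed order so all five metrics stay mutually
    consistent: (1) disruption correction on the raw frequency and cost
    inputs, (2) ratio/rate derivation, (3) inflation adjustment (cost
    metrics only, when requested). Missing propagates through every step.
    """
    if isinstance(metric, Metric):
        adjust = metric.adjusted_for_inflation or options.adjust_inflation
        metric_name = metric.name
    else:
        metric_name = MetricName(metric)
        adjust = options.adjust_inflation
    if adjust and metric_name not in COST_BEARING:
        raise DataValidationError(
            f"inflation adjustment requested for non-cost metric {metric_name.value}"
        )

    needs_freq = metric_name in (
        MetricName.PRESCRIBING_FREQUENCY,
        MetricName.COST_PER_PRESCRIBING,
        MetricName.PRESCRIBING_RATE,
    )
    needs_cost = metric_name in COST_BEARING
    if needs_freq and frequency is None:
        raise DataValidationError(f"{metric_name.value} requires the raw frequency series")
    if needs_cost and cost is None:
        raise DataValidationError(f"{metric_name.value} requires the raw cost series")
    needs_elig = metric_name in (MetricName.PRESCRIBING_RATE, MetricName.COST_RATE)
    if needs_elig and eligibility is None:
        raise DataValidationError(f"{metric_name.value} requires an eligibility series")

    # step 1: disruption correction on the raw inputs
    if options.disruption is not None:
        a, b = options.disruption
        if frequency is not None:
            frequency = correct_disruption(frequency, a, b, options.weights)
        if cost is not None:
            cost = correct_disruption(cost, a, b, options.weights)

    base = frequency if needs_freq else cost
    entity = base.entity
    out_metric = Metric(metric_name, adjusted_for_inflation=adjust)

    # step 2: ratio / rate derivation
    points: list[MetricPoint] = []
    for p in base.points:
        m = p.month
        if metric_name is MetricName.PRESCRIBING_FREQUENCY:
            value, status = p.value, p.status
        elif metric_name is MetricName.INGREDIENT_COST:
            value, status = p.value, p.status
        elif metric_name is MetricName.COST_PER_PRESCRIBING:
            cp = cost.point_at(m)
            if cp is None or cp.missing or p.missing:
                value, status = None, PointStatus.MISSING
            else:
                value = cost_per_prescribing(cp.value, p.value)
                status = (
                    PointStatus.MISSING
                    if value is None
                    else _combine_status(p.status, cp.status)
                )
        else:  # rates
            if p.missing or m not in eligibility:
                value, status = None, PointStatus.MISSING
            else:
                fn = prescribing_rate if metric_name is MetricName.PRESCRIBING_RATE else cost_rate
                value, status = fn(p.value, eligibility[m]), p.status
        points.append(MetricPoint(m, value, status))

    # step 3: inflation adjustment
    if adjust:
        if not cpi:
            raise DataValidationError("inflation adjustment requires a CPI series")
        reference = (
            Month.parse(options.reference_month)
            if options.reference_month is not None
            else max(cpi)
        )
        if reference not in cpi:
            raise DataValidationError(f"reference month {reference} not in CPI series")
        cpi_ref = cpi[reference]
        adjusted = []
        for p in points:
            if p.missing:
                adjusted.append(p)
            elif p.month not in cpi:
                adjusted.append(MetricPoint(p.month, None, PointStatus.MISSING))
            else:
                adjusted.append(replace(p, value=deflate(p.value, cpi[p.month], cpi_ref)))
        points = adjusted

    return MetricSeries(entity, out_metric, points)
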