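"""Hierarchy comparisons, date-range filtering and seasonal profiles.

The comparison of interest is *what proportion of a higher-level ATC
entity's prescribing (or cost) does a descendant account for* — e.g. the
share of one proton-pump inhibitor within all drugs for acid-related
disorders (A02). Parent values come from the therapeutic-group /
physiological-system reports, which are complete totals; they are never
reconstructed by summing top-N censored children.

Proportions are reported on the [0, 1] scale. Because the rate metrics
share the same per-1,000-persons denominator month-wise, a ratio of rates
equals the ratio of the underlying raw values — proportions are computed
directly from whichever consistent pair of series is supplied, and the
equivalence is covered by a property test rather than special-cased here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .atc import AtcCode, is_strict_descendant
from .errors import DataValidationError
from .metrics import Metric, MetricPoint, MetricSeries, PointStatus
from .months import Month

__all__ = ["ComparisonSeries", "proportion_of_parent", "filter_range", "seasonal_profile"]


@dataclass
class ComparisonSeries:
    """Month-indexed proportion of a parent entity made up by a descendant."""

    child: AtcCode
    parent: AtcCode
    metric: Metric
    points: list[MetricPoint] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not is_strict_descendant(self.child, self.parent):
            raise DataValidationError(
                f"{self.child.code} is not a strict descendant of {self.parent.code}"
            )

    def __len__(self) -> int:
        return len(self.points)

    @property
    def months(self) -> list[Month]:
        return [p.month for p in self.points]

    def value_at(self, month: Month) -> float | None:
        for p in self.points:
            if p.month == month:
                return p.value
        return None

    def observed(self) -> list[MetricPoint]:
        return [p for p in self.points if not p.missing]


def proportion_of_parent(
    child_series: MetricSeries, parent_series: MetricSeries
) -> ComparisonSeries:
    """Month-wise child ÷ parent for two series of the same metric.

    A month is missing in the result when either side is missing there or
    the parent value is zero. Only months covered by both series appear.
    """
    if child_series.metric != parent_series.metric:
        raise DataValidationError(
            f"metric mismatch: {child_series.metric} vs {parent_series.metric}"
        )
    child, parent = child_series.entity, parent_series.entity
    if not is_strict_descendant(child, parent):
        raise DataValidationError(
            f"{child.code} is not a strict ATC descendant of {parent.code}; "
            "comparison requires a lower-level entity within a higher-level one"
        )
    parent_months = set(parent_series.months)
    points = []
    for p in child_series.points:
        if p.month not in parent_months:
            continue
        q = parent_series.point_at(p.month)
        if p.missing or q.missing or q.value == 0:
            points.append(MetricPoint(p.month, None, PointStatus.MISSING))
        else:
            status = (
                PointStatus.IMPUTED
                if PointStatus.IMPUTED in (p.status, q.status)
                else PointStatus.OBSERVED
            )
            points.append(MetricPoint(p.month, p.value / q.value, status))
    return ComparisonSeries(child, parent, child_series.metric, points)


def filter_range(series, start: Month | str, end: Month | str):
    """Restrict a metric or comparison series to start ≤ month ≤ end.

    Inclusive on both ends; metadata (entity, metric) is preserved. A range
    outside the series' coverage yields a valid empty point set.
    """
    start, end = Month.parse(start), Month.parse(end)
    if start > end:
        raise DataValidationError(f"range start {start} is after end {end}")
    points = [p for p in series.points if start <= p.month <= end]
    if isinstance(series, ComparisonSeries):
        return ComparisonSeries(series.child, series.parent, series.metric, points)
    return MetricSeries(series.entity, series.metric, points)


def seasonal_profile(series: MetricSeries) -> dict[int, float | None]:
    """Per-calendar-month seasonal indices of a series.

    For each calendar month m (1–12), the index is the mean of the
    observed values falling in m divided by the overall mean of all
    observed values; missing points are excluded from both means. A
    calendar month with no observations gets ``None``. The
    observation-count-weighted mean of the indices is 1 by construction.

    Requires at least 12 observed points (one year of signal).
    """
    observed = series.observed()
    if len(observed) < 12:
        raise DataValidationError(
            f"seasonal profile needs >= 12 observed points, got {len(observed)}"
        )
    overall = sum(p.value for p in observed) / len(observed)
    profile: dict[int, float | None] = {}
    for m in range(1, 13):
        values = [p.value for p in observed if p.month.month == m]
        if not values:
            profile[m] = None
        elif overall == 0:
            profile[m] = math.nan
        else:
            profile[m] = (sum(values) / len(values)) / overall
    return profile


def seasonal_peak_month(profile: dict[int, float | None]) -> int:
    """Calendar month (1–12) with the largest seasonal index."""
    available = {m: v for m, v in profile.items() if v is not None}
    if not available:
        raise DataValidationError("seasonal profile has no computed indices")
    return max(available, key=available.get)
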