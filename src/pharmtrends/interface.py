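"""Tidy CSV export and static plot export.

The export layout is one row per (month, entity) with all five metric
columns side by side — the shape a spreadsheet user expects from a
"download my selection" button. Values are rounded only here, at the
presentation boundary: 2 decimals for EUR and per-1,000 rates, integers
for dispensing frequencies. Missing (top-N censored) months appear as
empty cells with ``status=missing``, never as zeros.

Plots are one axes per metric with one trace per entity; missing months
render as line gaps. PNG output is a plain raster; HTML output embeds
the same figure as inline SVG, so traces remain inspectable by id.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field
from pathlib import Path

import matplotlib
import pandas as pd

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .atc import AtcCode, parse_atc
from .dataset import Dataset
from .errors import DataValidationError
from .metrics import (
    COST_BEARING,
    METRIC_UNITS,
    DeriveOptions,
    Metric,
    MetricName,
    MetricSeries,
)
from .months import Month

ALL_METRICS = tuple(MetricName)


@dataclass(frozen=True)
class Selection:
    """What the user asked for: entities, metrics, a date range."""

    entities: tuple[AtcCode, ...]
    metrics: tuple[MetricName, ...] = ALL_METRICS
    date_range: tuple[Month, Month] | None = None
    comparison: tuple[AtcCode, AtcCode] | None = None  # (child, parent)

    def __post_init__(self) -> None:
        if not self.entities:
            raise DataValidationError("selection must name at least one entity")
        if self.date_range is not None and self.date_range[0] > self.date_range[1]:
            raise DataValidationError("selection date range start is after end")

    @classmethod
    def of(cls, codes, metrics=None, start=None, end=None) -> "Selection":
        entities = tuple(parse_atc(c) if isinstance(c, str) else c for c in codes)
        date_range = None
        if start is not None and end is not None:
            date_range = (Month.parse(start), Month.parse(end))
        metric_names = (
            tuple(MetricName(m) for m in metrics) if metrics else ALL_METRICS
        )
        return cls(entities, metric_names, date_range)


def _series_for(
    dataset: Dataset,
    entity: AtcCode,
    metric: MetricName,
    selection: Selection,
    options: DeriveOptions,
    adjusted: bool,
) -> MetricSeries:
    from .compare import filter_range

    m = Metric(metric, adjusted_for_inflation=adjusted)
    series = dataset.series(entity, m, options)
    if selection.date_range is not None:
        series = filter_range(series, *selection.date_range)
    return series


def _round(value: float | None, metric: MetricName) -> float | int | None:
    if value is None:
        return None
    if metric is MetricName.PRESCRIBING_FREQUENCY:
        return int(round(value))
    return round(value, 2)


EXPORT_COLUMNS = [
    "month",
    "atc_code",
    "entity_name",
    "prescribing_frequency",
    "ingredient_cost",
    "cost_per_prescribing",
    "prescribing_rate",
    "cost_rate",
]
ADJUSTED_COLUMNS = [f"{m.value}_adjusted" for m in MetricName if m in COST_BEARING]


def selection_frame(
    selection: Selection,
    dataset: Dataset,
    options: DeriveOptions = DeriveOptions(),
    include_adjusted: bool = False,
) -> pd.DataFrame:
    """The tidy one-row-per-(month, entity) table behind export_csv."""
    names = {**dataset.entities("therapeutic_group"), **dataset.entities("medication")}
    frames = []
    for entity in selection.entities:
        per_metric: dict[str, MetricSeries] = {}
        for metric in selection.metrics:
            per_metric[metric.value] = _series_for(
                dataset, entity, metric, selection, options, adjusted=False
            )
            if include_adjusted and metric in COST_BEARING:
                per_metric[f"{metric.value}_adjusted"] = _series_for(
                    dataset, entity, metric, selection, options, adjusted=True
                )
        months = next(iter(per_metric.values())).months
        rows = []
        for month in months:
            record: dict = {
                "month": str(month),
                "atc_code": entity.code,
                "entity_name": entity.name or names.get(entity.code, entity.code),
            }
            statuses = []
            for column, series in per_metric.items():
                point = series.point_at(month)
                base = MetricName(column.removesuffix("_adjusted"))
                record[column] = None if point is None else _round(point.value, base)
                if point is not None:
                    statuses.append(point.status.value)
            if "missing" in statuses:
                record["status"] = "missing"
            elif "imputed" in statuses:
                record["status"] = "imputed"
            else:
                record["status"] = "observed"
            rows.append(record)
        frames.append(pd.DataFrame(rows))
    out = pd.concat(frames, ignore_index=True)
    ordered = ["month", "atc_code", "entity_name"]
    ordered += [m.value for m in selection.metrics]
    if include_adjusted:
        ordered += [f"{m.value}_adjusted" for m in selection.metrics if m in COST_BEARING]
    ordered.append("status")
    return out[ordered]


def export_csv(
    selection: Selection,
    dataset: Dataset,
    path: str | Path,
    options: DeriveOptions = DeriveOptions(),
    include_adjusted: bool = False,
) -> Path:
    """Write the selection as UTF-8 CSV; returns the output path."""
    frame = selection_frame(selection, dataset, options, include_adjusted)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, index=False, encoding="utf-8")
    return path


def render_plot(
    selection: Selection,
    dataset: Dataset,
    path: str | Path,
    format: str = "png",
    options: DeriveOptions = DeriveOptions(),
) -> Path:
    """Render the selection: one axes per metric, one trace per entity.

    ``format`` is ``"png"`` or ``"html"`` (inline-SVG page). Missing months
    appear as gaps in the line, never as zeros.
    """
    format = format.lower()
    if format not in {"png", "html"}:
        raise DataValidationError(f"unsupported plot format {format!r}; use png or html")
    metrics = list(selection.metrics)
    fig, axes = plt.subplots(
        len(metrics), 1, figsize=(9, 2.8 * len(metrics)), squeeze=False, sharex=True
    )
    for ax, metric in zip(axes[:, 0], metrics):
        for entity in selection.entities:
            series = _series_for(dataset, entity, metric, selection, options, adjusted=False)
            xs = [p.month.index for p in series.points]
            ys = [math.nan if p.missing else p.value for p in series.points]
            label = entity.name or entity.code
            (line,) = ax.plot(xs, ys, label=label, marker=".", markersize=3)
            line.set_gid(f"trace-{entity.code}-{metric.value}")
        ax.set_ylabel(METRIC_UNITS[metric], fontsize=8)
        ax.set_title(metric.value.replace("_", " "), fontsize=9)
        ax.legend(fontsize=7)
        ticks = ax.get_xticks()
        ax.set_xticks(ticks)
        ax.set_xticklabels(
            [str(Month.from_index(int(t))) if t >= 0 else "" for t in ticks],
            rotation=45, fontsize=7,
        )
    fig.tight_layout()

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if format == "png":
        fig.savefig(path, dpi=110)
    else:
        buf = io.StringIO()
        fig.savefig(buf, format="svg")
        html = (
            "<!DOCTYPE html>\n<html><head><meta charset='utf-8'>"
            "<title>pharmtrends plot</title></head><body>\n"
            + buf.getvalue()
            + "\n</body></html>\n"
        )
        path.write_text(html, encoding="utf-8")
    plt.close(fig)
    return path
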