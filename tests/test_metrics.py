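"""Metric derivations: rates, cost per dispensing, deflation, disruption."""

import math

import pytest
from hypothesis import given
from hypothesis import strategies as st

from pharmtrends import (
    Category,
    DeriveOptions,
    Metric,
    MetricName,
    MetricPoint,
    MetricSeries,
    Month,
    MonthlyReport,
    PointStatus,
    ReportRow,
    build_series,
    correct_disruption,
    cost_per_prescribing,
    cost_rate,
    deflate,
    derive_series,
    parse_atc,
    prescribing_rate,
)
from pharmtrends.errors import DataValidationError
from pharmtrends.ingest import Basis
from pharmtrends.months import month_range

ENTITY = parse_atc("A02BC02")

positive = st.floats(min_value=1e-3, max_value=1e9, allow_nan=False)


def _series(values, metric=MetricName.PRESCRIBING_FREQUENCY, start="2020-01",
            entity=ENTITY):
    """values: list of float | None (None -> missing)."""
    months = month_range(start, Month.parse(start) + len(values) - 1)
    points = [
        MetricPoint(m, v, PointStatus.MISSING if v is None else PointStatus.OBSERVED)
        for m, v in zip(months, values)
    ]
    return MetricSeries(entity, Metric(metric), points)


# -- scalar derivations -------------------------------------------------------


@pytest.mark.parametrize(
    "freq,elig,expected", [(33000, 1_500_000, 22.0), (0, 1_500_000, 0.0), (1500, 1_000_000, 1.5)]
)
def test_prescribing_rate(freq, elig, expected):
    assert prescribing_rate(freq, elig) == pytest.approx(expected, rel=1e-12)


def test_cost_rate():
    assert cost_rate(300000, 1_500_000) == pytest.approx(200.0)
    assert cost_rate(0, 42) == 0.0


@pytest.mark.parametrize("bad", [0, -10])
def test_rates_require_positive_denominator(bad):
    with pytest.raises(DataValidationError):
        prescribing_rate(100, bad)
    with pytest.raises(DataValidationError):
        cost_rate(100, bad)


def test_cost_per_prescribing():
    assert cost_per_prescribing(64980, 2000) == pytest.approx(32.49)
    assert cost_per_prescribing(0, 500) == 0.0
    assert cost_per_prescribing(0, 0) is None  # undefined ratio -> missing


def test_deflate():
    assert deflate(100.0, 95.0, 104.5) == pytest.approx(110.0)
    assert deflate(250.0, 101.3, 101.3) == 250.0  # identity at reference
    assert deflate(0.0, 95.0, 104.5) == 0.0
    with pytest.raises(DataValidationError):
        deflate(10.0, 0.0, 100.0)


@given(positive, positive, st.floats(min_value=0.1, max_value=10))
def test_rate_homogeneity(freq, elig, k):
    assert prescribing_rate(k * freq, elig) == pytest.approx(
        k * prescribing_rate(freq, elig), rel=1e-9
    )


@given(positive, positive, positive)
def test_deflate_linear_in_value(value, cpi_m, cpi_ref):
    assert deflate(2 * value, cpi_m, cpi_ref) == pytest.approx(
        2 * deflate(value, cpi_m, cpi_ref), rel=1e-9
    )


@given(positive, positive, positive, positive)
def test_deflation_commutes_with_cost_per_prescribing(cost, freq, cpi_m, cpi_ref):
    """Same month's CPI: deflate-then-divide equals divide-then-deflate."""
    a = cost_per_prescribing(deflate(cost, cpi_m, cpi_ref), freq)
    b = deflate(cost_per_prescribing(cost, freq), cpi_m, cpi_ref)
    assert a == pytest.approx(b, rel=1e-9)


# -- build_series -------------------------------------------------------------


def _report(month, present):
    rows = [
        ReportRow(entity_name=c, atc=parse_atc(c), frequency=f, pct_frequency=1.0,
                  ingredient_cost=f * 10.0, pct_cost=1.0, basis=Basis.FREQUENCY_RANKED)
        for c, f in present
    ]
    return MonthlyReport(month=Month.parse(month), category=Category.MEDICATION, rows=rows)


def test_build_series_full_coverage():
    months = month_range("2020-01", "2020-12")
    reports = [_report(str(m), [("A02BC02", 100 + i)]) for i, m in enumerate(months)]
    series = build_series(reports, ENTITY, MetricName.PRESCRIBING_FREQUENCY)
    assert len(series) == 12
    assert all(p.status is PointStatus.OBSERVED for p in series.points)
    assert series.points[3].value == 103


def test_build_series_absent_months_are_missing_not_zero():
    months = month_range("2020-01", "2020-12")
    reports = [
        _report(str(m), [] if 4 <= i + 1 <= 6 else [("A02BC02", 100)])
        for i, m in enumerate(months)
    ]
    series = build_series(reports, ENTITY, MetricName.PRESCRIBING_FREQUENCY)
    assert len(series) == 12
    missing = [p.month.month for p in series.points if p.missing]
    assert missing == [4, 5, 6]
    assert all(p.value is None for p in series.points if p.missing)


def test_build_series_never_present_is_all_missing():
    reports = [_report("2020-01", [("N03AX16", 5)])]
    series = build_series(reports, ENTITY, MetricName.PRESCRIBING_FREQUENCY)
    assert all(p.missing for p in series.points)


def test_build_series_level_mismatch_is_an_error():
    reports = [_report("2020-01", [("A02BC02", 5)])]
    with pytest.raises(DataValidationError, match="level"):
        build_series(reports, parse_atc("A02"), MetricName.PRESCRIBING_FREQUENCY)


# -- disruption correction ----------------------------------------------------


def test_disruption_equal_weights_is_arithmetic_mean():
    series = _series([10.0, 30.0, 5.0])
    out = correct_disruption(series, "2020-01", "2020-02", weights=(1, 1))
    assert out.points[0].value == out.points[1].value == 20.0
    assert out.points[0].status is PointStatus.IMPUTED
    assert out.points[2] == series.points[2]  # untouched


def test_disruption_day_weighted_mean():
    series = _series([10.0, 30.0], start="2021-05")  # May (31d), June (30d)
    out = correct_disruption(series, "2021-05", "2021-06", weights=(31, 30))
    assert out.points[0].value == pytest.approx(1210 / 61)
    # default weights are calendar days, so the same result
    default = correct_disruption(series, "2021-05", "2021-06")
    assert default.points[0].value == pytest.approx(1210 / 61)


def test_disruption_single_observation_left_untouched():
    series = _series([10.0, None, 5.0])
    out = correct_disruption(series, "2020-01", "2020-02")
    assert out.points == series.points
    both_missing = _series([None, None])
    assert correct_disruption(both_missing, "2020-01", "2020-02").points == both_missing.points


def test_disruption_month_outside_range_is_an_error():
    with pytest.raises(DataValidationError, match="outside"):
        correct_disruption(_series([1.0, 2.0]), "2020-01", "2020-05")


@given(positive, positive, st.floats(min_value=0.1, max_value=10),
       st.floats(min_value=0.1, max_value=10))
def test_disruption_bounded_and_equal(x_a, x_b, w_a, w_b):
    out = correct_disruption(_series([x_a, x_b]), "2020-01", "2020-02", weights=(w_a, w_b))
    v_a, v_b = out.points[0].value, out.points[1].value
    assert v_a == v_b
    lo, hi = min(x_a, x_b), max(x_a, x_b)
    slack = 1e-12 * hi
    assert lo - slack <= v_a <= hi + slack


@given(positive, positive)
def test_disruption_equal_weights_conserve_two_month_sum(x_a, x_b):
    out = correct_disruption(_series([x_a, x_b]), "2020-01", "2020-02", weights=(1, 1))
    assert out.points[0].value + out.points[1].value == pytest.approx(x_a + x_b, rel=1e-12)


# -- derive_series pipeline ---------------------------------------------------


def _raw_pair(freqs, costs, start="2020-01"):
    return (
        _series(freqs, MetricName.PRESCRIBING_FREQUENCY, start),
        _series(costs, MetricName.INGREDIENT_COST, start),
    )


def test_derive_cost_per_prescribing_is_monthwise_ratio():
    freq, cost = _raw_pair([2000.0, 1000.0], [64980.0, 10140.0])
    out = derive_series(freq, cost, MetricName.COST_PER_PRESCRIBING)
    assert [p.value for p in out.points] == pytest.approx([32.49, 10.14])


def test_derive_rate_with_missing_eligibility_month():
    freq, cost = _raw_pair([1000.0, 1000.0], [1.0, 1.0])
    eligibility = {Month(2020, 1): 1_000_000}  # no February
    out = derive_series(freq, cost, MetricName.PRESCRIBING_RATE, eligibility=eligibility)
    assert out.points[0].value == pytest.approx(1.0)
    assert out.points[1].missing


def test_derive_all_missing_eligibility_gives_all_missing():
    freq, cost = _raw_pair([1000.0, 1000.0], [1.0, 1.0])
    out = derive_series(freq, cost, MetricName.PRESCRIBING_RATE, eligibility={})
    assert all(p.missing for p in out.points)


def test_derive_adjusted_frequency_is_an_error():
    freq, cost = _raw_pair([1.0], [1.0])
    with pytest.raises(DataValidationError, match="inflation"):
        derive_series(freq, cost, MetricName.PRESCRIBING_FREQUENCY,
                      options=DeriveOptions(adjust_inflation=True))


def test_derive_corrects_raw_inputs_before_ratios():
    # disruption on months 1-2; cpp must equal corrected cost / corrected freq
    freq, cost = _raw_pair([1000.0, 3000.0, 1000.0], [5000.0, 21000.0, 5000.0])
    options = DeriveOptions(disruption=("2020-01", "2020-02"), weights=(1, 1))
    out = derive_series(freq, cost, MetricName.COST_PER_PRESCRIBING, options=options)
    corrected_f, corrected_c = 2000.0, 13000.0
    assert out.points[0].value == pytest.approx(corrected_c / corrected_f)
    assert out.points[0].status is PointStatus.IMPUTED
    assert out.points[2].status is PointStatus.OBSERVED


def test_derive_inflation_adjustment_uses_reference_month():
    freq, cost = _raw_pair([100.0, 100.0], [95.0, 104.5])
    cpi = {Month(2020, 1): 95.0, Month(2020, 2): 104.5}
    out = derive_series(
        freq, cost, MetricName.INGREDIENT_COST, cpi=cpi,
        options=DeriveOptions(adjust_inflation=True),  # reference = latest = 2020-02
    )
    assert out.points[0].value == pytest.approx(95.0 * 104.5 / 95.0)
    assert out.points[1].value == pytest.approx(104.5)
    assert out.metric.adjusted_for_inflation


def test_series_month_ordering_enforced():
    points = [
        MetricPoint(Month(2020, 2), 1.0, PointStatus.OBSERVED),
        MetricPoint(Month(2020, 1), 1.0, PointStatus.OBSERVED),
    ]
    with pytest.raises(DataValidationError, match="increasing"):
        MetricSeries(ENTITY, Metric(MetricName.PRESCRIBING_FREQUENCY), points)


def test_missing_point_cannot_carry_value():
    with pytest.raises(DataValidationError):
        MetricPoint(Month(2020, 1), 3.0, PointStatus.MISSING)
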