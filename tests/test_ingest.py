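"""Report/eligibility/CPI readers, ranking merge and V-group exclusion."""

import pandas as pd
import pytest

from pharmtrends import (
    Basis,
    Category,
    ColumnMapping,
    Month,
    MonthlyReport,
    ReportRow,
    exclude_nonmedication_groups,
    merge_rankings,
    parse_atc,
    read_cpi,
    read_eligibility,
    read_monthly_report,
)
from pharmtrends.errors import (
    DataValidationError,
    RowParseError,
    SchemaError,
)
from pharmtrends.ingest import default_profile

MAPPING = ColumnMapping()


def _report_frame(rows):
    return pd.DataFrame(
        rows,
        columns=["entity_name", "atc_code", "frequency", "pct_frequency",
                 "ingredient_cost", "pct_cost"],
    )


def _row(code, freq, cost, basis=Basis.FREQUENCY_RANKED, name=None):
    return ReportRow(
        entity_name=name or code, atc=parse_atc(code), frequency=freq,
        pct_frequency=1.0, ingredient_cost=cost, pct_cost=1.0, basis=basis,
    )


@pytest.fixture
def report_csv(tmp_path):
    path = tmp_path / "report.csv"
    _report_frame(
        [
            ("pantoprazole", "A02BC02", 50000, 1.1, 600000.0, 1.3),
            ("esomeprazole", "A02BC05", 80000, 1.8, 800000.5, 1.7),
            ("pregabalin", "N03AX16", 40000, 0.9, 1299600.0, 2.8),
        ]
    ).to_csv(path, index=False)
    return path


def test_read_report_round_trips_three_rows(report_csv):
    report = read_monthly_report(
        report_csv, MAPPING, "2020-01", Category.MEDICATION, Basis.FREQUENCY_RANKED
    )
    assert len(report.rows) == 3
    assert [r.atc.code for r in report.rows] == ["A02BC02", "A02BC05", "N03AX16"]
    assert report.rows[1].ingredient_cost == 800000.5
    assert report.rows[0].basis is Basis.FREQUENCY_RANKED
    assert report.month == Month(2020, 1)


def test_read_report_from_xlsx(report_csv, tmp_path):
    xlsx = tmp_path / "report.xlsx"
    pd.read_csv(report_csv).to_excel(xlsx, index=False)
    report = read_monthly_report(
        xlsx, MAPPING, "2020-01", Category.MEDICATION, Basis.FREQUENCY_RANKED
    )
    assert [r.frequency for r in report.rows] == [50000, 80000, 40000]


def test_empty_table_is_a_valid_report(tmp_path):
    path = tmp_path / "empty.csv"
    _report_frame([]).to_csv(path, index=False)
    report = read_monthly_report(
        path, MAPPING, "2020-01", Category.MEDICATION, Basis.FREQUENCY_RANKED
    )
    assert report.rows == []


def test_missing_file_is_an_error(tmp_path):
    with pytest.raises(SchemaError, match="not found"):
        read_monthly_report(
            tmp_path / "nope.csv", MAPPING, "2020-01",
            Category.MEDICATION, Basis.FREQUENCY_RANKED,
        )


def test_missing_mapped_column_lists_names(tmp_path):
    path = tmp_path / "bad.csv"
    pd.DataFrame({"entity_name": ["x"], "atc_code": ["A02BC02"]}).to_csv(path, index=False)
    with pytest.raises(SchemaError, match="frequency"):
        read_monthly_report(
            path, MAPPING, "2020-01", Category.MEDICATION, Basis.FREQUENCY_RANKED
        )


def test_non_numeric_cell_cites_row(tmp_path):
    path = tmp_path / "bad.csv"
    _report_frame(
        [
            ("a", "A02BC02", 10, 0.1, 100.0, 0.1),
            ("b", "A02BC05", 10, 0.1, 100.0, 0.1),
            ("c", "N03AX16", 10, 0.1, "n/a", 0.1),
        ]
    ).to_csv(path, index=False)
    with pytest.raises(RowParseError, match="row 2") as excinfo:
        read_monthly_report(
            path, MAPPING, "2020-01", Category.MEDICATION, Basis.FREQUENCY_RANKED
        )
    assert excinfo.value.row == 2


def test_negative_value_rejected(tmp_path):
    path = tmp_path / "bad.csv"
    _report_frame([("a", "A02BC02", -10, 0.1, 100.0, 0.1)]).to_csv(path, index=False)
    with pytest.raises(DataValidationError, match="negative"):
        read_monthly_report(
            path, MAPPING, "2020-01", Category.MEDICATION, Basis.FREQUENCY_RANKED
        )


def test_bundled_profiles_load():
    assert default_profile("synthetic") == MAPPING
    zenodo = default_profile("zenodo_workbook")
    assert zenodo.frequency == "Prescribing Frequency"


# -- eligibility ------------------------------------------------------------


def test_eligibility_sums_areas_per_month(tmp_path):
    path = tmp_path / "elig.csv"
    pd.DataFrame(
        {
            "month": ["2020-01", "2020-01", "2020-02"],
            "area": ["East", "West", "East"],
            "count": [600000, 900000, 610000],
        }
    ).to_csv(path, index=False)
    series = read_eligibility(path, MAPPING)
    assert series[Month(2020, 1)] == 1_500_000
    assert series[Month(2020, 2)] == 610000


def test_eligibility_negative_count_rejected(tmp_path):
    path = tmp_path / "elig.csv"
    pd.DataFrame(
        {"month": ["2020-01"], "area": ["East"], "count": [-5]}
    ).to_csv(path, index=False)
    with pytest.raises(DataValidationError, match="negative"):
        read_eligibility(path, MAPPING)


def test_eligibility_duplicate_month_area_rejected(tmp_path):
    path = tmp_path / "elig.csv"
    pd.DataFrame(
        {"month": ["2020-01"] * 2, "area": ["East"] * 2, "count": [1, 2]}
    ).to_csv(path, index=False)
    with pytest.raises(DataValidationError, match="duplicate"):
        read_eligibility(path, MAPPING)


# -- CPI ---------------------------------------------------------------------


def test_cpi_reader(tmp_path):
    path = tmp_path / "cpi.csv"
    pd.DataFrame(
        {"month": ["2020-01", "2020-02", "2020-03"], "cpi": [100.0, 100.5, 101.2]}
    ).to_csv(path, index=False)
    series = read_cpi(path, MAPPING)
    assert len(series) == 3
    assert series[Month(2020, 2)] == 100.5


def test_cpi_empty_file_is_an_error(tmp_path):
    path = tmp_path / "cpi.csv"
    pd.DataFrame({"month": [], "cpi": []}).to_csv(path, index=False)
    with pytest.raises(DataValidationError, match="no CPI rows"):
        read_cpi(path, MAPPING)


def test_cpi_nonpositive_index_rejected(tmp_path):
    path = tmp_path / "cpi.csv"
    pd.DataFrame({"month": ["2020-01"], "cpi": [0.0]}).to_csv(path, index=False)
    with pytest.raises(DataValidationError, match="positive"):
        read_cpi(path, MAPPING)


# -- ranking merge ------------------------------------------------------------


def _report(month, rows, basis):
    return MonthlyReport(
        month=Month.parse(month), category=Category.MEDICATION,
        rows=[_row(*r, basis=basis) for r in rows],
    )


def test_merge_identical_entity_yields_single_row():
    freq = _report("2020-01", [("A02BC02", 10, 100.0)], Basis.FREQUENCY_RANKED)
    cost = _report("2020-01", [("A02BC02", 10, 100.0)], Basis.COST_RANKED)
    merged = merge_rankings(freq, cost)
    assert len(merged.rows) == 1
    assert merged.rows[0].basis is Basis.FREQUENCY_RANKED


def test_merge_union_count():
    # 100 frequency-ranked + 100 cost-ranked sharing 60 codes -> 140 rows
    codes = [f"A{i:02d}AA{j:02d}" for i in range(1, 11) for j in range(1, 15)]
    freq_codes, cost_codes = codes[:100], codes[40:140]
    freq = _report("2020-01", [(c, 10, 100.0) for c in freq_codes], Basis.FREQUENCY_RANKED)
    cost = _report("2020-01", [(c, 10, 100.0) for c in cost_codes], Basis.COST_RANKED)
    merged = merge_rankings(freq, cost)
    assert len(merged.rows) == 140
    assert merged.codes == set(freq_codes) | set(cost_codes)
    # union membership is order-independent
    assert merge_rankings(freq, cost).codes == set(cost_codes) | set(freq_codes)


def test_merge_cost_only_entity_keeps_cost_basis():
    freq = _report("2020-01", [("A02BC02", 10, 100.0)], Basis.FREQUENCY_RANKED)
    cost = _report("2020-01", [("N03AX16", 5, 500.0)], Basis.COST_RANKED)
    merged = merge_rankings(freq, cost)
    assert merged.row_for("N03AX16").basis is Basis.COST_RANKED


def test_merge_conflict_keeps_frequency_row_and_warns(caplog):
    freq = _report("2020-01", [("A02BC02", 10, 100.0)], Basis.FREQUENCY_RANKED)
    cost = _report("2020-01", [("A02BC02", 12, 100.0)], Basis.COST_RANKED)
    with caplog.at_level("WARNING", logger="pharmtrends.ingest"):
        merged = merge_rankings(freq, cost)
    assert merged.row_for("A02BC02").frequency == 10
    assert any("ranking conflict" in r.message for r in caplog.records)


def test_merge_month_mismatch_is_an_error():
    freq = _report("2020-01", [("A02BC02", 10, 100.0)], Basis.FREQUENCY_RANKED)
    cost = _report("2020-02", [("A02BC02", 10, 100.0)], Basis.COST_RANKED)
    with pytest.raises(DataValidationError, match="different months"):
        merge_rankings(freq, cost)


# -- V-group exclusion --------------------------------------------------------


def test_exclusion_removes_sublevel_v_rows_only_and_is_idempotent():
    rows = [
        _row("V04C", 10, 100.0),    # 3rd-level V group: diagnostic agents
        _row("A02BC05", 20, 200.0), # level-5 non-V medication stays
        _row("V03AB14", 5, 50.0),   # level-5 V code stays (a real medication)
        _row("A02B", 7, 70.0),      # sub-level non-V row also stays
    ]
    report = MonthlyReport(month=Month(2020, 1), category=Category.MEDICATION, rows=rows)
    cleaned = exclude_nonmedication_groups(report)
    assert {r.atc.code for r in cleaned.rows} == {"A02BC05", "V03AB14", "A02B"}
    again = exclude_nonmedication_groups(cleaned)
    assert [r.atc.code for r in again.rows] == [r.atc.code for r in cleaned.rows]


def test_exclusion_noop_without_v_rows():
    report = MonthlyReport(
        month=Month(2020, 1), category=Category.MEDICATION,
        rows=[_row("A02BC05", 20, 200.0)],
    )
    assert exclude_nonmedication_groups(report).rows == report.rows


def test_duplicate_atc_basis_rejected():
    with pytest.raises(DataValidationError, match="duplicate"):
        MonthlyReport(
            month=Month(2020, 1), category=Category.MEDICATION,
            rows=[_row("A02BC05", 1, 1.0), _row("A02BC05", 2, 2.0)],
        )
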