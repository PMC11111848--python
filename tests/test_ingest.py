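"""Parsing, deduplication, case selection, SOC mapping and demographics."""

import numpy as np
import pandas as pd
import pytest

from faers_signal import (
    CaseSet,
    ConfigurationError,
    InputError,
    deduplicate,
    map_events,
    select_cases,
    summarize_demographics,
)
from faers_signal.ingest import RawQuarter, _read_dollar_table, parse_quarter

from conftest import small_config
from faers_signal import generate_quarters


def make_demo(rows):
    return pd.DataFrame(rows, columns=["PRIMARYID", "CASEID", "FDA_DT"], dtype=str)


# --- parsing ----------------------------------------------------------------


def test_parse_row_counts_match_generator_bookkeeping(corpus, raw):
    _, _, truth = corpus
    for name, n in truth.row_counts.items():
        assert len(raw.table(name)) == n
    assert sum(raw.skipped_rows.values()) == 0


def test_header_only_file_parses_to_zero_rows(tmp_path):
    cfg = small_config(seed=2, n_background_reports=50, n_target_reports=10,
                       duplicate_fraction=0.0, quarters=("22Q1",), year_weights={2022: 1.0})
    generate_quarters(cfg, tmp_path)
    reac = tmp_path / "REAC22Q1.txt"
    reac.write_text("PRIMARYID$PT\n")
    q = parse_quarter(tmp_path, "22Q1")
    assert len(q.reac) == 0 and len(q.demo) == 60


def test_row_with_extra_delimiter_is_skipped_and_counted(tmp_path):
    f = tmp_path / "t.txt"
    f.write_text("PRIMARYID$PT\n1$HEADACHE\n2$BAD$EXTRA\n3$NAUSEA\n")
    frame, skipped = _read_dollar_table(f)
    assert len(frame) == 2 and skipped == 1


def test_missing_mandatory_file_names_it(tmp_path):
    cfg = small_config(seed=2, n_background_reports=50, n_target_reports=10,
                       quarters=("22Q1",), year_weights={2022: 1.0})
    generate_quarters(cfg, tmp_path)
    (tmp_path / "OUTC22Q1.txt").unlink()
    with pytest.raises(InputError, match="OUTC22Q1"):
        parse_quarter(tmp_path, "22Q1")


# --- deduplication ----------------------------------------------------------


@pytest.mark.parametrize(
    "rows, survivor",
    [
        ([("100", "X", "20220101"), ("101", "X", "20220301")], "101"),
        ([("100", "X", "20220101"), ("101", "X", "20220101")], "101"),
        ([("200", "Y", ""), ("150", "Y", "20200101")], "150"),  # dated beats undated
    ],
)
def test_dedup_survivor_rule(rows, survivor):
    assert list(deduplicate(make_demo(rows))) == [survivor]


def test_dedup_is_idempotent_and_exhaustive(raw):
    surv = deduplicate(raw.demo)
    again = deduplicate(raw.demo[raw.demo["PRIMARYID"].isin(set(surv))])
    assert sorted(surv) == sorted(again)
    assert len(surv) == raw.demo["CASEID"].nunique()


def test_dedup_matches_ground_truth_survivors(corpus, survivors):
    _, _, truth = corpus
    assert sorted(map(int, survivors)) == sorted(map(int, truth.survivor_primaryids))


# --- case selection ---------------------------------------------------------


def _mini_raw():
    demo = pd.DataFrame(
        {
            "PRIMARYID": ["1", "2", "3"],
            "CASEID": ["a", "b", "c"],
            "FDA_DT": ["20220105"] * 3,
            "EVENT_DT": ["20220101"] * 3,
            "SEX": ["F", "M", "F"],
            "AGE": ["30", "", "44"],
            "AGE_COD": ["YR", "", "YR"],
            "OCCR_COUNTRY": ["US"] * 3,
            "OCCP_COD": ["MD"] * 3,
        }
    )
    drug = pd.DataFrame(
        {
            "PRIMARYID": ["1", "2", "3"],
            "DRUG_SEQ": ["1", "1", "1"],
            "ROLE_COD": ["PS", "C", "PS"],
            "DRUGNAME": ["Caplyta ", "CAPLYTA", "IBUPROFEN"],
            "PROD_AI": ["", "", ""],
        }
    )
    reac = pd.DataFrame({"PRIMARYID": ["1", "1", "2", "3"], "PT": ["MANIA", "mania ", "NAUSEA", "RASH"]})
    empty = lambda cols: pd.DataFrame({c: pd.Series(dtype=str) for c in cols})
    return RawQuarter(
        demo=demo,
        drug=drug,
        reac=reac,
        ther=empty(["PRIMARYID", "DSG_DRUG_SEQ", "START_DT"]),
        indi=empty(["PRIMARYID", "INDI_PT"]),
        outc=empty(["PRIMARYID", "OUTC_COD"]),
    )


def test_name_normalisation_and_role_filter():
    cs = select_cases(_mini_raw(), ["CAPLYTA"], "PS")
    # report 1 matches after upper+trim; report 2 is concomitant only
    assert list(cs.report_ids) == ["1"]
    # repeated identical PTs collapse to one report-event pair
    assert len(cs.events) == 1 and cs.events.iloc[0]["pt"] == "MANIA"


def test_empty_name_list_is_a_configuration_error():
    with pytest.raises(ConfigurationError):
        select_cases(_mini_raw(), [])


def test_case_count_matches_ground_truth(corpus, cases):
    _, _, truth = corpus
    assert len(cases) == truth.n_target_cases


def test_case_extraction_matches_independent_scan(corpus, cases):
    """Case ids equal the target survivor ids recorded by the generator."""
    _, _, truth = corpus
    expected = set(map(int, truth.onset_days_true.index))
    assert set(map(int, cases.report_ids)) == expected


# --- SOC mapping ------------------------------------------------------------


def test_map_events_lookup_and_unmapped():
    cs = select_cases(_mini_raw(), ["CAPLYTA"], "PS")
    mapped = map_events(cs, {"MANIA": "Psychiatric disorders"})
    assert mapped.events.iloc[0]["soc"] == "Psychiatric disorders"
    assert mapped.unmapped_pts == 0
    unmapped = map_events(cs, {"OTHER": "X"})
    assert unmapped.events.iloc[0]["soc"] == "UNMAPPED"
    assert unmapped.unmapped_pts == 1


def test_duplicate_map_keys_rejected():
    cs = select_cases(_mini_raw(), ["CAPLYTA"], "PS")
    with pytest.raises(ConfigurationError):
        map_events(cs, {"MANIA": "A", "mania ": "B"})


def test_all_mapped_synthetic_has_zero_unmapped(cases):
    assert cases.unmapped_pts == 0


# --- demographics -----------------------------------------------------------


def test_percentages_recompute_from_counts(cases):
    s = summarize_demographics(cases)
    total = s.total_cases
    for section, frame in s.sections.items():
        for _, r in frame.iterrows():
            assert abs(r["pct"] - r["count"] / total * 100) <= 0.05
        if section in ("Gender", "Age", "Reporting year"):
            assert frame["count"].sum() == total


def test_single_case_degenerate_percentages():
    cs = select_cases(_mini_raw(), ["CAPLYTA"], "PS")
    s = summarize_demographics(cs)
    assert s.total_cases == 1 and s.mean_events_per_case == 1.0
    for frame in s.sections.values():
        assert set(frame["pct"]).issubset({0.0, 100.0})


def test_empty_case_set_rejected():
    cs = select_cases(_mini_raw(), ["NOT A DRUG"], "PS")
    with pytest.raises(InputError):
        summarize_demographics(cs)


def test_pipeline_conservation_cases_plus_noncases(raw, survivors, cases):
    non_cases = len(survivors) - len(cases)
    assert len(cases) + non_cases == len(survivors)
    assert len(cases) <= len(survivors)
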