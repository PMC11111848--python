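"""ROR, BCPNN IC, dual-criterion flags, comparator odds ratios, strata
and rankings, with hand-computed and generator oracles."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from faers_signal import (
    ConfigurationError,
    ContingencyTable,
    DisproportionalityModel,
    ICResult,
    InputError,
    RORResult,
    build_contingency,
    comparator_odds_ratio,
    flag_signal,
    ic_with_ci,
    rank_signals,
    ror_with_ci,
    stratified_signals,
)
from faers_signal.synthetic import expected_contingency

tables = st.builds(
    ContingencyTable,
    st.integers(1, 500),
    st.integers(1, 5_000),
    st.integers(1, 5_000),
    st.integers(1, 200_000),
)


def pairs_frame(spec):
    """Build a report-event pair frame from {report_id: [terms]}."""
    rows = [(rid, t) for rid, terms in spec.items() for t in terms]
    return pd.DataFrame(rows, columns=["report_id", "term"])


# --- ROR ---------------------------------------------------------------------


@pytest.mark.parametrize(
    "cells, expected",
    [
        ((11, 4766, 177, 214937), (2.80, 1.52, 5.16)),
        ((8, 4769, 200, 214914), (1.80, 0.89, 3.66)),
        ((10, 100, 20, 200), (1.00, None, None)),
    ],
)
def test_ror_point_and_woolf_ci(cells, expected):
    res = ror_with_ci(ContingencyTable(*cells))
    assert round(res.ror, 2) == expected[0]
    if expected[1] is not None:
        assert (round(res.ci_low, 2), round(res.ci_high, 2)) == expected[1:]


def test_zero_cell_is_undefined_not_corrected():
    res = ror_with_ci(ContingencyTable(0, 10, 5, 100))
    assert not res.defined and math.isnan(res.ror)


@settings(derandomize=True, max_examples=200)
@given(tables)
def test_ror_reciprocity(table):
    fwd, rev = ror_with_ci(table), ror_with_ci(table.swapped())
    assert fwd.ror * rev.ror == pytest.approx(1.0)
    assert fwd.ci_low * rev.ci_high == pytest.approx(1.0)


@settings(derandomize=True, max_examples=100)
@given(st.integers(1, 300), st.integers(500, 5_000), st.integers(500, 5_000),
       st.integers(50_000, 500_000))
def test_ror_and_ic_monotone_in_a(a, b, c, d):
    """With b, c, d fixed at case/non-case scale (a small against the
    background), ROR and the noren IC strictly increase in a."""
    t1, t2 = ContingencyTable(a, b, c, d), ContingencyTable(a + 1, b, c, d)
    assert ror_with_ci(t2).ror > ror_with_ci(t1).ror
    assert ic_with_ci(t2).ic > ic_with_ci(t1).ic


# --- IC ----------------------------------------------------------------------


def test_ic_noren_hand_arithmetic():
    # E = 1000*1000/100000 = 10; IC = log2(60.5/10.5) = 2.52655;
    # IC025 = IC - 3.3/sqrt(60.5) - 2/60.5**1.5 = 2.09803
    res = ic_with_ci(ContingencyTable(60, 940, 940, 98060))
    assert res.ic == pytest.approx(math.log2(60.5 / 10.5), abs=1e-12)
    assert res.ic025 == pytest.approx(2.098, abs=5e-4)
    assert res.variant == "noren"


def test_ic_near_zero_at_independence():
    # a == E with a large: shrinkage is negligible
    res = ic_with_ci(ContingencyTable(100, 900, 9900, 89100))
    assert abs(res.ic) < 0.01


@settings(derandomize=True, max_examples=200)
@given(tables, st.sampled_from(["noren", "bate1998"]))
def test_ic025_below_ic(table, variant):
    res = ic_with_ci(table, variant)
    assert res.ic025 < res.ic


def test_unknown_variant_rejected():
    with pytest.raises(ConfigurationError):
        ic_with_ci(ContingencyTable(1, 1, 1, 1), "mystery")


# --- dual criterion ----------------------------------------------------------


def test_flag_requires_all_three_criteria():
    # Published mania row: n=60, ROR ci_low 57.09, IC025 4.49 -> signal
    mania = flag_signal(
        RORResult(73.82, 57.09, 95.46, 60), ICResult(6.16, 4.49, "noren"), 60
    )
    assert mania
    # SOC with ROR ci_low 1.12 but IC025 -1.39 -> not a dual signal
    gastro = flag_signal(
        RORResult(1.23, 1.12, 1.35, 450), ICResult(0.27, -1.39, "noren"), 450
    )
    assert not gastro
    # huge ROR but only two reports -> below the n >= 3 rule
    assert not flag_signal(
        RORResult(500.0, 80.0, 3000.0, 2), ICResult(5.0, 3.0, "noren"), 2
    )
    # undefined statistics never flag
    assert not flag_signal(
        RORResult(math.nan, math.nan, math.nan, 5, defined=False),
        ICResult(1.0, 0.5, "noren"),
        5,
    )


# --- contingency construction -------------------------------------------------


def test_build_contingency_degenerate_everyone_has_term():
    events = pairs_frame({1: ["X"], 2: ["X"], 3: ["X"]})
    t = build_contingency(events, {1}, "X")
    assert (t.a, t.b, t.c, t.d) == (1, 0, 2, 0)


def test_repeated_pt_in_one_report_counts_once():
    events = pd.DataFrame(
        {"report_id": [1, 1, 2], "term": ["MANIA", "MANIA", "OTHER"]}
    )
    t = build_contingency(events, {1}, "MANIA")
    assert t.a == 1 and t.b == 0


def test_unobserved_term_gives_zero_a_and_c():
    events = pairs_frame({1: ["X"], 2: ["Y"]})
    t = build_contingency(events, {1}, "NEVER SEEN")
    assert t.a == 0 and t.c == 0


def test_pipeline_tables_equal_generator_oracle(corpus, pt_results):
    _, _, truth = corpus
    checked = 0
    for pt in truth.pt_names:
        exp = expected_contingency(truth, pt)
        if exp.a + exp.c == 0:
            continue
        assert pt_results.contingency(pt) == exp
        checked += 1
    assert checked > 100


def test_planted_signals_flagged_unplanted_rarely(corpus, pt_results):
    _, cfg, truth = corpus
    pooled = pt_results.pooled.set_index("term")
    planted = {pt.upper() for pt, _m in cfg.planted_signals}
    for pt, mult in cfg.planted_signals:
        row = pooled.loc[pt.upper()]
        if mult >= 10 and row["a"] >= 20:
            assert bool(row["is_signal"])
    target_terms = set(truth.target_pt_counts[truth.target_pt_counts > 0].index)
    unplanted = pooled.loc[sorted(target_terms - planted)]
    assert unplanted["is_signal"].mean() < 0.05


# --- comparator ---------------------------------------------------------------


def test_comparator_or_from_published_counts():
    target = pairs_frame(
        {**{i: ["SEROTONIN SYNDROME"] for i in range(11)},
         **{1000 + i: [f"T{i}"] for i in range(4766)}}
    )
    comp = pairs_frame(
        {**{-(i + 1): ["SEROTONIN SYNDROME"] for i in range(177)},
         **{10_000_000 + i: [f"C{i}"] for i in range(214_937)}}
    )
    res = comparator_odds_ratio(target, comp, "SEROTONIN SYNDROME")
    assert (round(res.ror, 2), round(res.ci_low, 2), round(res.ci_high, 2)) == (
        2.80, 1.52, 5.16,
    )


def test_comparator_zero_cell_is_undefined():
    target = pairs_frame({1: ["PSEUDOSTROKE"], 2: ["OTHER"]})
    comp = pairs_frame({3: ["OTHER"], 4: ["OTHER2"]})
    res = comparator_odds_ratio(target, comp, "PSEUDOSTROKE")
    assert not res.defined


def test_comparator_symmetry_gives_or_one():
    target = pairs_frame({1: ["X"], 2: ["Y"], 3: ["Z"]})
    comp = pairs_frame({4: ["X"], 5: ["Y"], 6: ["Z"]})
    assert comparator_odds_ratio(target, comp, "X").ror == pytest.approx(1.0)


def test_comparator_requires_reports():
    with pytest.raises(InputError):
        comparator_odds_ratio(pairs_frame({1: ["X"]}), pairs_frame({}), "X")


# --- strata -------------------------------------------------------------------


def test_signal_planted_only_in_one_stratum_detected_there():
    rng = np.random.default_rng(17)
    rows, strata = [], {}
    rid = 0
    for sex, n_target, planted in (("female", 300, True), ("male", 300, False)):
        for _ in range(n_target):
            rid += 1
            strata[rid] = sex
            rows.append((rid, "MANIA" if (planted and rng.random() < 0.3) else f"PT_{rng.integers(50)}"))
    target_ids = set(strata)
    for _ in range(8000):  # background, both strata
        rid += 1
        strata[rid] = "female" if rng.random() < 0.5 else "male"
        rows.append((rid, "MANIA" if rng.random() < 0.01 else f"PT_{rng.integers(50)}"))
    events = pd.DataFrame(rows, columns=["report_id", "term"])
    per = stratified_signals(events, target_ids, pd.Series(strata))
    f = per["female"].set_index("term")
    m = per["male"].set_index("term")
    assert bool(f.loc["MANIA", "is_signal"])
    assert "MANIA" not in m.index or not bool(m.loc["MANIA", "is_signal"])


def test_stratum_counts_sum_to_pooled(raw, survivors, cases, meddra):
    from faers_signal import event_pairs

    pairs = event_pairs(raw, survivors)
    demo = raw.demo.drop_duplicates("PRIMARYID").set_index("PRIMARYID")
    sex = demo["SEX"].map({"M": "male", "F": "female", "UNK": "unknown"})
    sex = sex[sex.index.isin(set(survivors))]
    res = DisproportionalityModel(
        pairs, set(cases.report_ids), strata=sex
    ).fit()
    pooled = res.pooled.set_index("term")["a"]
    parts = [res.stratum(s).set_index("term")["a"] for s in ("male", "female", "unknown")]
    summed = pd.concat(parts, axis=1).fillna(0).sum(axis=1)
    for term in pooled.index:
        assert summed.get(term, 0) == pooled[term]


def test_single_stratum_equals_pooled():
    events = pairs_frame({1: ["A", "B"], 2: ["A"], 3: ["B"], 4: ["C"]})
    strata = pd.Series({1: "only", 2: "only", 3: "only", 4: "only"})
    res = DisproportionalityModel(events, {1, 2}, strata=strata).fit()
    pooled = res.pooled.drop(columns="stratum").reset_index(drop=True)
    only = res.stratum("only").drop(columns="stratum").reset_index(drop=True)
    pd.testing.assert_frame_equal(pooled, only)


# --- ranking ------------------------------------------------------------------


def rows_for_ranking():
    return pd.DataFrame(
        {
            "term": ["DIZZINESS", "SOMNOLENCE", "TRANCE", "PERFORMANCE STATUS DECREASED"],
            "n": [215, 123, 3, 39],
            "ror": [6.77, 9.23, 176.47, 167.28],
        }
    )


def test_rank_by_frequency_and_strength():
    rows = rows_for_ranking()
    by_freq = rank_signals(rows, "frequency", 2)
    assert list(by_freq["term"]) == ["DIZZINESS", "SOMNOLENCE"]
    by_strength = rank_signals(rows, "strength", 2)
    assert list(by_strength["term"]) == ["TRANCE", "PERFORMANCE STATUS DECREASED"]


def test_rank_clamps_and_validates_k():
    rows = rows_for_ranking()
    assert len(rank_signals(rows, "frequency", 100)) == 4
    with pytest.raises(ConfigurationError):
        rank_signals(rows, "frequency", 0)


def test_rank_tie_break_deterministic():
    rows = pd.DataFrame(
        {"term": ["B", "A", "C"], "n": [5, 5, 5], "ror": [2.0, 2.0, 3.0]}
    )
    out = rank_signals(rows, "frequency", 3)
    assert list(out["term"]) == ["C", "A", "B"]


# --- null calibration ---------------------------------------------------------


def test_woolf_interval_null_calibration():
    """Under independence, ROR ci_low > 1 in at most ~5% of tables."""
    rng = np.random.default_rng(101)
    n_flag = n_def = 0
    for _ in range(400):
        n = 100_000
        p_drug, p_evt = 0.02, 0.01
        a = rng.binomial(n, p_drug * p_evt)
        row = rng.binomial(n, p_drug)
        col = rng.binomial(n, p_evt)
        b, c = max(row - a, 0), max(col - a, 0)
        d = n - a - b - c
        res = ror_with_ci(ContingencyTable(a, b, c, d))
        if res.defined:
            n_def += 1
            n_flag += res.ci_low > 1
    assert n_def > 300
    assert n_flag / n_def <= 0.05
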