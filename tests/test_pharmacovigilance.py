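"""Sex-biased pair detection: filters, contingency building, scoring."""

import numpy as np
import pandas as pd
import pytest

from sbaenet import pharmacovigilance as pv
from sbaenet.io import TermHierarchy
from tests.conftest import make_cases


# ---------------------------------------------------------------------------
# filter_cases
# ---------------------------------------------------------------------------

def base_rows():
    return [
        ("C1", "2020-01-01", "female", "US", "1", {"D1"}, {"E1"}),
        ("C2", "2020-01-01", "male", "US", "4", {"D1"}, {"E1"}),      # qual 4
        ("C3", "2020-01-01", "unknown", "US", "1", {"D1"}, {"E1"}),   # no sex
        ("C4", "2020-01-01", "male", "CA", "1", {"D1"}, {"E1"}),      # country
        ("C5", "2020-01-01", "male", "US", "2", set(), {"E1"}),       # no drugs
        ("C6", "2020-01-01", "male", "US", "3", {"D1"}, set()),       # no events
        ("C7", "2020-01-01", "2020-01-01", "US", "1", {"D1"}, {"E1"}),
    ]


def test_filter_cases_rules():
    out = pv.filter_cases(make_cases(base_rows()))
    assert set(out["case_id"]) == {"C1"}


def test_filter_cases_keeps_newest_duplicate():
    cases = make_cases([
        ("C1", "2020-01-01", "female", "US", "1", {"D1"}, {"E1"}),
        ("C1", "2021-01-01", "female", "US", "1", {"D2"}, {"E2"}),
    ])
    out = pv.filter_cases(cases)
    assert len(out) == 1
    assert out.loc[0, "drugs"] == frozenset({"D2"})


def test_filter_cases_unknown_date_loses_tiebreak():
    cases = make_cases([
        ("C1", "2020-05-05", "female", "US", "1", {"D1"}, {"E1"}),
    ])
    nodate = make_cases([
        ("C1", "2020-01-01", "female", "US", "1", {"D2"}, {"E2"}),
    ])
    nodate.loc[0, "report_date"] = pd.NaT
    out = pv.filter_cases(pd.concat([nodate, cases], ignore_index=True))
    assert out.loc[0, "drugs"] == frozenset({"D1"})


def test_filter_cases_idempotent():
    cases = make_cases(base_rows())
    once = pv.filter_cases(cases)
    twice = pv.filter_cases(once)
    pd.testing.assert_frame_equal(once, twice)


# ---------------------------------------------------------------------------
# map_terms
# ---------------------------------------------------------------------------

def test_map_terms_maps_collapses_and_passes_through():
    hierarchy = TermHierarchy(
        lower_to_preferred={"abnormal EEG": "EEG abnormal",
                            "eeg abnormality": "EEG abnormal"},
        preferred_to_soc={"EEG abnormal": {"nervous system"}})
    cases = make_cases([
        ("C1", "2020-01-01", "female", "US", "1", {"D1"},
         {"abnormal EEG", "eeg abnormality", "rash"}),
        ("C2", "2020-01-01", "male", "US", "1", {"D1"}, {"EEG abnormal"}),
    ])
    out = pv.map_terms(cases, hierarchy)
    assert out.loc[0, "events"] == frozenset({"EEG abnormal", "rash"})
    # already-preferred terms unchanged (idempotence)
    assert out.loc[1, "events"] == frozenset({"EEG abnormal"})
    pd.testing.assert_frame_equal(pv.map_terms(out, hierarchy), out)


# ---------------------------------------------------------------------------
# build_contingency
# ---------------------------------------------------------------------------

def test_contingency_hand_count():
    cases = make_cases([
        ("C1", "2020-01-01", "female", "US", "1", {"X"}, {"Y"}),
        ("C2", "2020-01-01", "male", "US", "1", {"X"}, {"Z"}),
    ])
    tables = pv.build_contingency(cases).set_index(["drug", "event"])
    row = tables.loc[("X", "Y")]
    assert (row["A"], row["B"], row["C"], row["D"]) == (1, 0, 0, 1)
    # pair never co-reported still enumerable with A = C = 0
    row = tables.loc[("X", "Z")]
    assert (row["A"], row["C"]) == (0, 1)


def test_contingency_case_level_denominators():
    # a case exposed to a drug counts once in B/D no matter how many other
    # events it lists
    cases = make_cases([
        ("C1", "2020-01-01", "female", "US", "1", {"X"}, {"E1", "E2", "E3"}),
        ("C2", "2020-01-01", "male", "US", "1", {"X"}, {"E9"}),
    ])
    tables = pv.build_contingency(cases).set_index(["drug", "event"])
    assert tables.loc[("X", "E1"), "A"] == 1
    assert tables.loc[("X", "E1"), "B"] == 0
    assert tables.loc[("X", "E9"), "C"] == 1
    assert tables.loc[("X", "E9"), "D"] == 0
    # margins: A+B = exposed females, C+D = exposed males, for every pair
    assert ((tables["A"] + tables["B"]) == 1).all()
    assert ((tables["C"] + tables["D"]) == 1).all()


# ---------------------------------------------------------------------------
# apply_report_filters
# ---------------------------------------------------------------------------

def make_table(a, b, c, d):
    return pd.DataFrame({"drug": ["X"], "event": ["Y"],
                         "A": [a], "B": [b], "C": [c], "D": [d]})


def test_report_filters_boundaries():
    # fails (A >= 30 or C >= 30)
    assert pv.apply_report_filters(make_table(29, 950, 29, 992)).empty
    # boundary pass: A=30, C=20, total exactly 1000
    assert len(pv.apply_report_filters(make_table(30, 480, 20, 470))) == 1
    # fails A > 5 and C > 5
    assert pv.apply_report_filters(make_table(40, 500, 5, 500)).empty
    # fails A + C >= 50
    assert pv.apply_report_filters(make_table(30, 950, 19, 1001)).empty
    # fails total >= 1000
    assert pv.apply_report_filters(make_table(30, 400, 25, 400)).empty


def test_report_filters_idempotent_and_order_independent(rng):
    tables = pd.DataFrame({
        "drug": [f"D{i}" for i in range(200)],
        "event": ["E0"] * 200,
        "A": rng.integers(0, 60, 200), "B": rng.integers(0, 1500, 200),
        "C": rng.integers(0, 60, 200), "D": rng.integers(0, 1500, 200),
    })
    once = pv.apply_report_filters(tables)
    pd.testing.assert_frame_equal(pv.apply_report_filters(once), once)
    shuffled = tables.sample(frac=1.0, random_state=0)
    again = pv.apply_report_filters(shuffled).sort_values("drug")
    assert list(again["drug"]) == sorted(once["drug"])


# ---------------------------------------------------------------------------
# score_pairs
# ---------------------------------------------------------------------------

def test_score_pairs_hand_arithmetic():
    out = pv.score_pairs(make_table(30, 70, 10, 90))
    assert out.loc[0, "ror"] == pytest.approx(2700 / 700)
    assert out.loc[0, "log2ror"] == pytest.approx(np.log2(2700 / 700), abs=1e-9)
    assert out.loc[0, "log2ror"] == pytest.approx(1.9475, abs=1e-4)


def test_score_pairs_balanced_table_unbiased():
    out = pv.score_pairs(make_table(50, 50, 50, 50))
    assert out.loc[0, "ror"] == 1.0
    assert out.loc[0, "log2ror"] == 0.0
    assert out.loc[0, "bias"] == "none"


def test_score_pairs_haldane_on_zero_cell():
    out = pv.score_pairs(make_table(30, 0, 10, 90))
    assert bool(out.loc[0, "zero_cell"])
    expected = (30.5 * 90.5) / (0.5 * 10.5)
    assert out.loc[0, "ror"] == pytest.approx(expected)
    # non-zero-cell rows are untouched
    out2 = pv.score_pairs(make_table(30, 70, 10, 90))
    assert not bool(out2.loc[0, "zero_cell"])


def test_score_pairs_bias_thresholds():
    # strong female bias: log2ror > 1 and tiny p
    strong = make_table(200, 100, 40, 400)
    out = pv.score_pairs(strong)
    assert out.loc[0, "log2ror"] > 1
    assert out.loc[0, "bias"] == "female"
    # effect passes the cut (log2ROR = log2(2.25) > 1) but the Fisher p
    # does not reach 0.05 -> no bias call
    weak = make_table(6, 4, 4, 6)
    out_weak = pv.score_pairs(weak)
    assert out_weak.loc[0, "log2ror"] > 1
    assert out_weak.loc[0, "p"] >= 0.05 or out_weak.loc[0, "p_adj"] >= 0.05
    assert out_weak.loc[0, "bias"] == "none"


def test_score_pairs_sex_swap_antisymmetry():
    tables = pd.DataFrame({
        "drug": ["X", "X"], "event": ["E1", "E2"],
        "A": [200, 30], "B": [100, 300], "C": [40, 90], "D": [400, 200],
    })
    swapped = tables.rename(columns={"A": "C", "C": "A", "B": "D", "D": "B"})
    out = pv.score_pairs(tables)
    out_sw = pv.score_pairs(swapped)
    assert out_sw["log2ror"].values == pytest.approx(-out["log2ror"].values)
    assert out_sw["p"].values == pytest.approx(out["p"].values)
    flip = {"female": "male", "male": "female", "none": "none"}
    assert list(out_sw["bias"]) == [flip[b] for b in out["bias"]]


def test_score_pairs_empty_input():
    empty = pd.DataFrame(columns=["drug", "event", "A", "B", "C", "D"])
    out = pv.score_pairs(empty)
    assert out.empty
    assert "bias" in out.columns


# ---------------------------------------------------------------------------
# overlap_summary
# ---------------------------------------------------------------------------

def scored_frame(rows):
    return pd.DataFrame(rows, columns=["drug", "event", "bias"])


def test_overlap_summary_counts_and_test():
    results = scored_frame([
        ("D1", "E1", "female"), ("D2", "E2", "female"),
        ("D1", "E3", "male"), ("D3", "E4", "male"),
        ("D4", "E5", "none"), ("D5", "E6", "none"),
    ])
    summary = pv.overlap_summary(results)
    assert summary["drug"]["n_female"] == 2
    assert summary["drug"]["n_male"] == 2
    assert summary["drug"]["n_shared"] == 1
    assert summary["drug"]["n_universe"] == 5
    assert summary["n_pairs_tested"] == 6
    assert 0 < summary["drug"]["p"] <= 1


def test_overlap_summary_identical_sets_minimal_p():
    results = scored_frame([
        ("D1", "E1", "female"), ("D2", "E2", "female"),
        ("D1", "E3", "male"), ("D2", "E4", "male"),
        ("D3", "E5", "none"), ("D4", "E6", "none"), ("D5", "E7", "none"),
    ])
    summary = pv.overlap_summary(results)
    assert summary["drug"]["n_shared"] == 2
    # maximal overlap of 2-sets in a 5-universe: p = 1/C(5,2)
    assert summary["drug"]["p"] == pytest.approx(0.1)


def test_overlap_summary_disjoint_sets_p_one():
    results = scored_frame([
        ("D1", "E1", "female"), ("D2", "E2", "male"),
    ])
    summary = pv.overlap_summary(results)
    assert summary["drug"]["n_shared"] == 0
    assert summary["drug"]["p"] == pytest.approx(1.0)
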