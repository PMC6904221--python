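import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from phenostrat.comorbidity_networks import (
    comorbidity_score,
    first_occurrences,
    group_unique_pairs,
    lag_anova,
    pair_cooccurrence,
    pair_directionality,
    pair_lags_by_group,
    top_pairs_by_unique_codes,
)
from .conftest import events_frame


# ---- comorbidity score


def test_comorbidity_score_examples():
    assert comorbidity_score(5, 5) == 0.0
    assert comorbidity_score(3, 1) == pytest.approx(1.0)  # log2(4/2)
    assert comorbidity_score(0, 3) == pytest.approx(-2.0)  # log2(1/4)
    assert comorbidity_score(0, 0, smoothing=1) == 0.0  # smoothing guards log(0)


def test_comorbidity_score_antisymmetric_in_ratio():
    assert comorbidity_score(7, 3) == pytest.approx(-comorbidity_score(3, 7))


# ---- co-occurrence


def cooccurrence_fixture():
    rows = []
    # 10 patients with both A and B, 5 with A only, 3 with B only, 12 neither
    for i in range(10):
        rows += [(f"PAB{i}", "A01", "2001-01-01"), (f"PAB{i}", "B01", "2001-06-01")]
    for i in range(5):
        rows.append((f"PA{i}", "A01", "2001-01-01"))
    for i in range(3):
        rows.append((f"PB{i}", "B01", "2001-01-01"))
    for i in range(12):
        rows.append((f"PN{i}", "C01", "2001-01-01"))
    return events_frame(rows)


def test_pair_cooccurrence_counts_and_fisher():
    res = pair_cooccurrence(cooccurrence_fixture())
    row = res.set_index(["code_a", "code_b"]).loc[("A01", "B01")]
    assert (row["n_both"], row["n_a_only"], row["n_b_only"], row["n_neither"]) == (
        10, 5, 3, 12,
    )
    assert row["expected"] == pytest.approx(15 * 13 / 30)
    _, p_ref = sps.fisher_exact([[10, 5], [3, 12]], alternative="two-sided")
    assert row["p_cooccur"] == pytest.approx(p_ref)
    assert row["cs"] == pytest.approx(np.log2(11 / (15 * 13 / 30 + 1)))


def test_pair_cooccurrence_repeat_events_count_once():
    rows = [("P1", "A01", "2001-01-01")] * 5 + [("P1", "B01", "2001-02-01")]
    rows += [("P2", "A01", "2001-01-01"), ("P2", "B01", "2001-01-01")]
    res = pair_cooccurrence(events_frame(rows))
    assert res.iloc[0]["n_both"] == 2


def test_pair_cooccurrence_min_carriers_and_population():
    ev = cooccurrence_fixture()
    res = pair_cooccurrence(ev, min_carriers=5)
    assert set(res["code_a"]).union(res["code_b"]) == {"A01", "B01", "C01"}
    res = pair_cooccurrence(ev, min_carriers=14)
    assert set(res["code_a"]).union(res["code_b"]) == {"A01"} or len(res) == 0
    res = pair_cooccurrence(ev, population=100)
    row = res.set_index(["code_a", "code_b"]).loc[("A01", "B01")]
    assert row["n_neither"] == 100 - 18


def test_bonferroni_adjustment():
    res = pair_cooccurrence(cooccurrence_fixture())
    assert np.allclose(
        res["p_cooccur_adj"], np.minimum(res["p_cooccur"] * len(res), 1.0)
    )


# ---- directionality


def test_first_occurrences_takes_min_date():
    ev = events_frame(
        [
            ("P1", "A01", "2003-01-01"),
            ("P1", "A01", "2001-01-01", "mined"),
        ]
    )
    first = first_occurrences(ev)
    assert first.iloc[0]["date"] == pd.Timestamp("2001-01-01")


def test_directionality_closed_form():
    # 12 carriers, A always 100 days before B: p = 0.5^12 one-sided
    rows = []
    for i in range(12):
        d0 = pd.Timestamp("2001-01-01") + pd.Timedelta(days=10 * i)
        rows.append((f"P{i}", "A01", d0))
        rows.append((f"P{i}", "B01", d0 + pd.Timedelta(days=100)))
    res = pair_directionality(events_frame(rows))
    row = res.iloc[0]
    assert row["n_ab"] == 12 and row["n_ba"] == 0 and row["ties"] == 0
    assert row["p_a_before_b"] == pytest.approx(0.5**12)
    assert row["p_b_before_a"] == pytest.approx(1.0)
    assert row["mean_lag_days"] == pytest.approx(100.0)
    assert row["directional"]


def test_directionality_ties_excluded():
    rows = []
    for i in range(6):
        rows.append((f"P{i}", "A01", "2001-01-01"))
        rows.append((f"P{i}", "B01", "2001-01-01"))  # same day: tie
    rows.append(("PX", "A01", "2001-01-01"))
    rows.append(("PX", "B01", "2001-03-01"))
    res = pair_directionality(events_frame(rows))
    row = res.iloc[0]
    assert row["ties"] == 6
    assert row["n_ab"] == 1
    assert row["p_a_before_b"] == pytest.approx(0.5)
    assert row["mean_lag_days"] == pytest.approx(59.0)


def test_directionality_balanced_not_flagged():
    rows = []
    for i in range(20):
        first, second = ("A01", "B01") if i % 2 else ("B01", "A01")
        rows.append((f"P{i}", first, "2001-01-01"))
        rows.append((f"P{i}", second, "2001-06-01"))
    res = pair_directionality(events_frame(rows))
    assert not res.iloc[0]["directional"]


def test_directionality_restricted_to_given_pairs():
    ev = cooccurrence_fixture()
    pairs = pd.DataFrame({"code_a": ["A01"], "code_b": ["B01"]})
    res = pair_directionality(ev, pairs=pairs)
    assert len(res) == 1


# ---- pair selection helpers


def test_top_pairs_by_unique_codes_budget():
    pairs = pd.DataFrame(
        {
            "code_a": ["A", "A", "C", "E"],
            "code_b": ["B", "C", "D", "F"],
            "p_cooccur_adj": [0.001, 0.002, 0.003, 0.004],
        }
    )
    top = top_pairs_by_unique_codes(pairs, max_unique=4)
    assert len(top) == 3  # A-B, A-C, C-D use exactly 4 codes; E-F would exceed
    assert set(top["code_a"]).union(top["code_b"]) == {"A", "B", "C", "D"}
    assert len(top_pairs_by_unique_codes(pairs, max_unique=100)) == 4


def test_group_unique_pairs():
    by_group = {
        "g1": [("A", "B"), ("C", "D")],
        "g2": [("B", "A"), ("E", "F")],  # (A,B) shared despite ordering
    }
    unique = group_unique_pairs(by_group)
    assert unique == {"g1": [("C", "D")], "g2": [("E", "F")]}


# ---- lag ANOVA


def test_lag_anova_degenerate_cases():
    assert np.isnan(lag_anova({"g1": [1.0, 2.0]}))
    assert np.isnan(lag_anova({"g1": [1.0, 2.0], "g2": [3.0]}))  # below min_obs
    assert lag_anova({"g1": [5.0, 5.0], "g2": [5.0, 5.0]}) == 1.0


def test_lag_anova_detects_group_difference():
    rng = np.random.default_rng(0)
    lags = {
        "g1": list(rng.normal(100, 10, 30)),
        "g2": list(rng.normal(300, 10, 30)),
    }
    assert lag_anova(lags) < 1e-6
    assert lag_anova(lags) == pytest.approx(
        sps.f_oneway(np.array(lags["g1"]), np.array(lags["g2"])).pvalue
    )


def test_pair_lags_by_group():
    rows = [
        ("P1", "A01", "2001-01-01"), ("P1", "B01", "2001-04-11"),  # lag 100
        ("P2", "A01", "2001-01-01"), ("P2", "B01", "2001-01-01"),  # tie: dropped
        ("P3", "A01", "2001-02-01"), ("P3", "B01", "2001-01-01"),  # lag -31
    ]
    group_of = {"P1": "g1", "P3": "g2"}
    lags = pair_lags_by_group(events_frame(rows), "A01", "B01", group_of)
    assert lags == {"g1": [100.0], "g2": [-31.0]}
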