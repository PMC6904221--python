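import itertools

import numpy as np
import pandas as pd
import pytest

from phenostrat.dysregulation import (
    BocpdConfig,
    HbA1cSeries,
    bocpd_changepoint_probability,
    changepoint_flag,
    code_criteria,
    dysregulation_profiles,
    dysregulation_score,
    lab_contrasts,
    normalize_labs,
    onset_level_flag,
    preprocess_hba1c,
    severity_flag,
)
from .conftest import events_frame


def hba1c_frame(series: dict) -> pd.DataFrame:
    rows = []
    for pid, (dates, values) in series.items():
        for d, v in zip(dates, values):
            rows.append({"patient_id": pid, "date": pd.Timestamp(d), "value": v})
    return pd.DataFrame(rows)


def monthly(start, n):
    return [pd.Timestamp(start) + pd.Timedelta(days=30 * i) for i in range(n)]


def make_series(values, start="2005-01-01", pid="P1"):
    values = np.asarray(values, float)
    dates = pd.DatetimeIndex(monthly(start, len(values)))
    return HbA1cSeries(pid, dates, values, [(0, len(values))])


# ---- preprocessing


def test_segment_filter_exact_boundaries():
    ok5 = hba1c_frame({"P1": (monthly("2005-01-01", 5), [50] * 5)})  # 120-day span
    assert preprocess_hba1c(ok5)["P1"].segments == [(0, 5)]

    four = hba1c_frame({"P1": (monthly("2005-01-01", 4), [50] * 4)})
    assert preprocess_hba1c(four)["P1"].segments == []

    # 5 points across exactly 90 days passes; 89 days fails
    d90 = [pd.Timestamp("2005-01-01") + pd.Timedelta(days=x) for x in [0, 20, 40, 60, 90]]
    assert preprocess_hba1c(hba1c_frame({"P1": (d90, [50] * 5)}))["P1"].segments == [(0, 5)]
    d89 = [pd.Timestamp("2005-01-01") + pd.Timedelta(days=x) for x in [0, 20, 40, 60, 89]]
    assert preprocess_hba1c(hba1c_frame({"P1": (d89, [50] * 5)}))["P1"].segments == []


def test_out_of_range_values_removed():
    vals = [10, 50, 51, 52, 53, 54, 200]  # 10 and 200 out of [15, 184]
    df = hba1c_frame({"P1": (monthly("2005-01-01", 7), vals)})
    s = preprocess_hba1c(df)["P1"]
    assert len(s.values) == 5
    assert s.values.min() >= 15 and s.values.max() <= 184


def test_same_day_duplicates_averaged():
    dates = [pd.Timestamp("2005-01-01")] * 2 + monthly("2005-02-01", 4)
    df = hba1c_frame({"P1": (dates, [40, 60] + [50] * 4)})
    s = preprocess_hba1c(df)["P1"]
    assert len(s.values) == 5
    assert s.values[0] == pytest.approx(50.0)


def test_gap_splits_segments():
    dates = monthly("2003-01-01", 5) + monthly("2006-01-01", 6)
    df = hba1c_frame({"P1": (dates, [50] * 11)})
    s = preprocess_hba1c(df)["P1"]
    assert s.segments == [(0, 5), (5, 11)]
    # a 365-day gap does NOT split (strictly greater than)
    dates = monthly("2003-01-01", 5)
    dates += [dates[-1] + pd.Timedelta(days=365)] + monthly("2005-01-01", 0)
    df = hba1c_frame({"P1": (dates, [50] * 6)})
    assert preprocess_hba1c(df)["P1"].segments == [(0, 6)]


# ---- code criteria


def test_code_criteria_flags():
    ev = events_frame(
        [
            ("P1", "sdcL03", "2001-01-01"),
            ("P2", "R73", "2001-01-01"),
            ("P3", "E89", "2001-01-01"),
            ("P4", "E11", "2001-01-01"),
        ]
    )
    flags = code_criteria(ev)
    assert flags.loc["P1", "has_dysregulation_code"]
    assert not flags.loc["P1", "has_hyperglycemia_code"]
    assert flags.loc["P2", "has_hyperglycemia_code"]
    assert flags.loc["P3", "has_hyperglycemia_code"]
    assert not flags.loc["P4"].any()


# ---- BOCPD change-point criterion


def test_changepoint_short_series_scores_zero():
    assert bocpd_changepoint_probability(np.array([50.0])).tolist() == [0.0]


def test_changepoint_detects_planted_shift():
    rng = np.random.default_rng(0)
    x = np.concatenate([rng.normal(46, 2, 10), rng.normal(61, 2, 10)])
    flag, positions = changepoint_flag(make_series(x))
    assert flag
    assert any(abs(p - 10) <= 2 for p in positions)


def test_changepoint_constant_series_never_flags():
    flag, positions = changepoint_flag(make_series([50.0] * 20))
    assert not flag and positions == []


def test_changepoint_noise_only_rarely_flags():
    rng = np.random.default_rng(1)
    hits = 0
    for _ in range(20):
        x = rng.normal(50, 2, 20)
        hits += changepoint_flag(make_series(x))[0]
    assert hits <= 2


def test_magnitude_gate_blocks_small_shifts():
    # clear statistical change but only 3 mmol/mol: below the 5 mmol/mol gate
    rng = np.random.default_rng(2)
    x = np.concatenate([rng.normal(46, 0.3, 10), rng.normal(49, 0.3, 10)])
    cfg = BocpdConfig()
    cp = bocpd_changepoint_probability(x, cfg)
    assert cp.max() >= cfg.posterior_threshold  # the detector does see it
    assert not changepoint_flag(make_series(x), cfg)[0]  # but the gate holds


def test_changepoint_respects_segments():
    rng = np.random.default_rng(3)
    x = np.concatenate([rng.normal(46, 2, 10), rng.normal(61, 2, 10)])
    dates = pd.DatetimeIndex(monthly("2005-01-01", 20))
    series = HbA1cSeries("P1", dates, x, [(0, 10)])  # shift lies outside
    assert not changepoint_flag(series)[0]


# ---- onset mixed model


def test_onset_level_recovery_and_flag():
    rng = np.random.default_rng(4)
    rows = []
    onsets = {}
    truth = {}
    for i in range(40):
        pid = f"P{i:02d}"
        onset = pd.Timestamp("2004-01-01")
        onsets[pid] = onset
        level = 45.0 if i < 20 else 62.0
        truth[pid] = level
        for k in range(6):
            rows.append(
                {
                    "patient_id": pid,
                    "date": onset + pd.Timedelta(days=180 * k),
                    "value": level + 1.5 * (180 * k / 365.25) + rng.normal(0, 1.5),
                }
            )
    res = onset_level_flag(pd.DataFrame(rows), pd.Series(onsets))
    errs = [abs(res.loc[p, "onset_level"] - truth[p]) for p in truth]
    assert np.mean(errs) < 2.0
    assert (res["status"] == "ok").all()
    # both planted levels sit far from the 53 threshold, so flags are exact
    for pid, level in truth.items():
        assert res.loc[pid, "flag"] == (level >= 53.0)


def test_onset_missing_dates_not_evaluable():
    rows = [
        {"patient_id": p, "date": pd.Timestamp("2005-01-01") + pd.Timedelta(days=30 * k),
         "value": 50.0 + k}
        for p in ("P1", "P2", "P3")
        for k in range(5)
    ]
    onsets = pd.Series({"P1": pd.Timestamp("2004-01-01"), "P2": pd.Timestamp("2004-06-01")})
    res = onset_level_flag(pd.DataFrame(rows), onsets)
    assert res.loc["P3", "status"] == "no_onset"
    assert not res.loc["P3", "flag"]
    assert res.loc["P1", "status"] == "ok"


# ---- severity


def test_severity_flag_and_bins():
    s = make_series([40, 50, 54, 60, 80])
    flag, freqs = severity_flag(s)
    assert freqs == pytest.approx([0.2, 0.2, 0.4, 0.2])
    assert flag  # 3/5 >= 53
    # exactly half at threshold does NOT flag (strict >)
    s = make_series([40, 40, 60, 60])
    assert not severity_flag(s)[0]
    empty = HbA1cSeries("P1", pd.DatetimeIndex([]), np.array([]), [])
    flag, freqs = severity_flag(empty)
    assert not flag and freqs.sum() == 0


# ---- score truth table


def test_score_truth_table_all_32_combinations():
    cols = [
        "has_dysregulation_code",
        "has_hyperglycemia_code",
        "changepoint",
        "onset_level",
        "severity",
    ]
    combos = list(itertools.product([False, True], repeat=5))
    flags = pd.DataFrame(combos, columns=cols, index=[f"P{i}" for i in range(32)])
    scored = dysregulation_score(flags)
    for i, combo in enumerate(combos):
        assert scored.iloc[i]["score"] == sum(combo)
        assert scored.iloc[i]["dysregulated"] == (sum(combo) >= 3)


def test_score_treats_missing_as_false():
    flags = pd.DataFrame(
        {
            "has_dysregulation_code": [True],
            "has_hyperglycemia_code": [True],
            "changepoint": [np.nan],
            "onset_level": [True],
            "severity": [np.nan],
        },
        index=["P1"],
    )
    scored = dysregulation_score(flags)
    assert scored.iloc[0]["score"] == 3 and scored.iloc[0]["dysregulated"]


def test_dysregulation_profiles_end_to_end(small_cohort, small_events):
    hb = small_cohort.labs[small_cohort.labs["test_id"] == "NPU27300"]
    onsets = small_cohort.patients.set_index("patient_id")["onset_date"]
    prof = dysregulation_profiles(small_events, hb, onsets)
    assert set(prof.index) == set(small_cohort.patients["patient_id"])
    truth = pd.Series(small_cohort.truth.dysregulated)
    agreement = (prof["dysregulated"].reindex(truth.index) == truth).mean()
    assert agreement >= 0.85
    assert prof["hba1c_evaluable"].all()


# ---- lab normalization and contrasts


def test_normalize_labs_coverage_filter():
    rows = []
    for i in range(20):
        rows.append({"patient_id": f"P{i}", "test_id": "T1", "date": "2001-01-01",
                     "value": float(i)})
        if i < 5:  # 25% coverage: dropped at 0.75
            rows.append({"patient_id": f"P{i}", "test_id": "T2", "date": "2001-01-01",
                         "value": float(i)})
    out, kept = normalize_labs(pd.DataFrame(rows))
    assert kept == ["T1"]
    vals = out["value"].to_numpy()
    assert vals.mean() == pytest.approx(0.0, abs=1e-9)
    assert vals.std(ddof=0) == pytest.approx(1.0)


def test_normalize_labs_log_transform_for_skewed():
    rng = np.random.default_rng(0)
    vals = np.exp(rng.normal(0, 1, 200))  # log-normal: fails normality, positive
    rows = [
        {"patient_id": f"P{i}", "test_id": "T1", "date": "2001-01-01", "value": v}
        for i, v in enumerate(vals)
    ]
    out, _ = normalize_labs(pd.DataFrame(rows))
    # after log + z-scoring the data must look symmetric
    from scipy import stats as sps

    assert abs(sps.skew(out["value"])) < 0.5


def test_lab_contrasts_detect_planted_shift():
    rng = np.random.default_rng(5)
    rows = []
    groups = {}
    for i in range(80):
        pid = f"P{i:02d}"
        g = "dys" if i < 40 else "reg"
        groups[pid] = g
        for tid, shift in [("T1", 1.5 if g == "dys" else 0.0), ("T2", 0.0)]:
            for k in range(3):
                rows.append(
                    {"patient_id": pid, "test_id": tid,
                     "date": pd.Timestamp("2001-01-01") + pd.Timedelta(days=k),
                     "value": rng.normal(shift, 1.0)}
                )
    res = lab_contrasts(pd.DataFrame(rows), pd.Series(groups))
    assert res["tests"] == ["T1", "T2"]
    assert res["manova_p"] < 1e-6
    ks = res["ks"].set_index(["test_id", "group"])
    assert ks.loc[("T1", "dys"), "significant"]
    assert ks.loc[("T1", "dys"), "direction"] == "higher"
    assert not ks.loc[("T2", "dys"), "significant"]
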