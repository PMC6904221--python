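import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from phenostrat.containers import Partition
from phenostrat.enrichment_stats import (
    benjamini_hochberg,
    metadata_contrasts,
    patient_strata,
    poisson_binomial_tail,
    prescription_enrichment,
    stratified_binomial_enrichment,
    truncate_atc,
)
from .conftest import events_frame


# ---- multiple testing


def test_bh_known_example():
    p = [0.01, 0.02, 0.03, 0.04]
    # BH: p_(i) * m / i, cumulative min from the right
    expect = [0.04, 0.04, 0.04, 0.04]
    assert np.allclose(benjamini_hochberg(p), expect)


def test_bh_monotone_and_nan_passthrough():
    p = np.array([0.001, np.nan, 0.5, 0.04])
    adj = benjamini_hochberg(p)
    assert np.isnan(adj[1])
    order = np.argsort(p[~np.isnan(p)])
    vals = adj[~np.isnan(adj)][order]
    assert (np.diff(vals) >= -1e-12).all()
    assert (adj[~np.isnan(adj)] >= p[~np.isnan(p)] - 1e-12).all()


def test_poisson_binomial_reduces_to_binomial():
    probs = np.full(12, 0.3)
    for k in range(13):
        assert poisson_binomial_tail(probs, k) == pytest.approx(
            sps.binom.sf(k - 1, 12, 0.3)
        )


def test_poisson_binomial_brute_force():
    probs = np.array([0.1, 0.5, 0.9])
    for k in range(4):
        exact = 0.0
        for bits in itertools.product([0, 1], repeat=3):
            if sum(bits) >= k:
                exact += np.prod([p if b else 1 - p for p, b in zip(probs, bits)])
        assert poisson_binomial_tail(probs, k) == pytest.approx(exact)


# ---- strata


def test_patient_strata_labels():
    patients = pd.DataFrame(
        {
            "patient_id": ["P1", "P2"],
            "sex": ["F", "M"],
            "birth_date": pd.to_datetime(["1947-05-01", "1951-12-31"]),
        }
    )
    s = patient_strata(patients)
    assert s["P1"] == "F:1940"
    assert s["P2"] == "M:1950"


# ---- stratified binomial enrichment


def uniform_strata(pids):
    return pd.Series("F:1950", index=pids)


def test_single_stratum_reduces_to_plain_binomial():
    # 40 patients, cluster A = 20; code X carried by all of A and 4 of B
    pids = [f"P{i:02d}" for i in range(40)]
    part = Partition({p: ("A" if i < 20 else "B") for i, p in enumerate(pids)})
    carriers = pids[:20] + pids[20:24]
    events = events_frame([(p, "X01", "2001-01-01") for p in carriers])
    res = stratified_binomial_enrichment(part, events, uniform_strata(pids))
    row = res.set_index(["cluster", "code"]).loc[("A", "X01")]
    prevalence = 24 / 40
    assert row["expected"] == pytest.approx(20 * prevalence)
    assert row["p"] == pytest.approx(sps.binom.sf(19, 20, prevalence))
    assert row["direction"] == "enriched"
    assert row["significant"]


def test_stratum_correction_removes_confounding():
    # code prevalence differs by stratum; cluster A is pure stratum s1.
    # within-stratum prevalence is uniform, so A must NOT look enriched.
    pids = [f"P{i:02d}" for i in range(60)]
    strata = pd.Series(["s1"] * 30 + ["s2"] * 30, index=pids)
    part = Partition(
        {p: ("A" if i < 15 else "B") for i, p in enumerate(pids)}
    )  # A entirely inside s1
    rows = []
    for i, p in enumerate(pids):
        if strata[p] == "s1" and i % 3 != 0:  # 2/3 prevalence in s1
            rows.append((p, "X01", "2001-01-01"))
        if strata[p] == "s2" and i % 10 == 0:  # 1/10 prevalence in s2
            rows.append((p, "X01", "2001-01-01"))
    res = stratified_binomial_enrichment(part, events_frame(rows), strata)
    row = res.set_index(["cluster", "code"]).loc[("A", "X01")]
    # expected probability equals the s1 prevalence, not the global one
    assert row["expected"] == pytest.approx(15 * (20 / 30))
    assert row["p"] > 0.05


def test_min_support_filter():
    pids = [f"P{i}" for i in range(30)]
    part = Partition({p: 0 for p in pids})
    events = events_frame([(p, "X01", "2001-01-01") for p in pids[:5]])
    res = stratified_binomial_enrichment(
        part, events, uniform_strata(pids), min_support=10
    )
    assert len(res) == 0
    res = stratified_binomial_enrichment(
        part, events, uniform_strata(pids), min_support=5
    )
    assert len(res) == 1


def test_missing_strata_raise():
    part = Partition({"P1": 0, "P2": 0})
    events = events_frame([("P1", "X01", "2001-01-01")])
    with pytest.raises(ValueError):
        stratified_binomial_enrichment(part, events, pd.Series({"P1": "F:1950"}))


def test_exact_poisson_binomial_close_to_binomial_single_stratum():
    pids = [f"P{i:02d}" for i in range(40)]
    part = Partition({p: ("A" if i < 20 else "B") for i, p in enumerate(pids)})
    events = events_frame([(p, "X01", "2001-01-01") for p in pids[:24]])
    approx = stratified_binomial_enrichment(part, events, uniform_strata(pids))
    exact = stratified_binomial_enrichment(
        part, events, uniform_strata(pids), exact_poisson_binomial=True
    )
    a = approx.set_index(["cluster", "code"])["p"]
    e = exact.set_index(["cluster", "code"])["p"]
    # with one stratum the Poisson-binomial IS the binomial
    assert np.allclose(a.sort_index(), e.sort_index())


# ---- metadata contrasts


def test_metadata_contrasts_planted_shift():
    rng = np.random.default_rng(0)
    pids = [f"P{i:03d}" for i in range(120)]
    part = Partition({p: i % 3 for i, p in enumerate(pids)})
    age = rng.normal(60, 5, 120)
    age[::3] += 15  # cluster 0 is older
    meta = pd.DataFrame({"patient_id": pids, "age": age, "flat": 1.0})
    res = metadata_contrasts(part, meta)
    res = res.set_index(["cluster", "field"])
    assert res.loc[(0, "age"), "significant"]
    assert res.loc[(0, "age"), "mean"] > res.loc[(1, "age"), "mean"]
    assert np.isnan(res.loc[(0, "flat"), "p"])  # constant field


def test_metadata_contrasts_field_selection():
    pids = ["P1", "P2", "P3", "P4"]
    part = Partition({p: i % 2 for i, p in enumerate(pids)})
    meta = pd.DataFrame({"patient_id": pids, "x": [1.0, 2, 3, 4], "name": list("abcd")})
    res = metadata_contrasts(part, meta)
    assert set(res["field"]) == {"x"}  # non-numeric column ignored


# ---- ATC handling and prescriptions


@pytest.mark.parametrize(
    "code,level,expect",
    [
        ("A10BA02", 3, "A10B"),
        ("A10BA02", 1, "A"),
        ("A10BA02", 4, "A10BA"),
        ("A10BA02", 5, "A10BA02"),
        ("a10ba02", 3, "A10B"),
        ("A10", 3, None),  # too short for level 3
        ("10AB", 3, None),  # malformed
        (None, 3, None),
        ("", 3, None),
    ],
)
def test_truncate_atc(code, level, expect):
    assert truncate_atc(code, level) == expect


def test_prescription_enrichment_recovers_signature():
    rng = np.random.default_rng(1)
    pids = [f"P{i:03d}" for i in range(120)]
    part = Partition({p: i % 2 for i, p in enumerate(pids)})
    rows = []
    for i, p in enumerate(pids):
        if i % 2 == 0:  # cluster 0 signature: A10B
            rows.append({"patient_id": p, "atc_code": "A10BA02", "date": "2001-01-01"})
        if rng.random() < 0.3:  # background in both clusters
            rows.append({"patient_id": p, "atc_code": "N02BE01", "date": "2001-01-01"})
    rx = pd.DataFrame(rows)
    rx["date"] = pd.to_datetime(rx["date"])
    res = prescription_enrichment(part, rx, min_cluster=50)
    res = res.set_index(["cluster", "atc_class"])
    assert res.loc[(0, "A10B"), "significant"]
    assert res.loc[(0, "A10B"), "direction"] == "enriched"
    assert not res.loc[(0, "N02B"), "significant"]


def test_prescription_enrichment_respects_min_cluster():
    pids = [f"P{i:03d}" for i in range(60)]
    part = Partition({p: (0 if i < 55 else 1) for i, p in enumerate(pids)})
    rx = pd.DataFrame(
        {"patient_id": pids, "atc_code": "A10BA02", "date": pd.Timestamp("2001-01-01")}
    )
    res = prescription_enrichment(part, rx, min_cluster=50)
    assert set(res["cluster"]) == {0}  # the 5-patient cluster is out


def test_prescription_enrichment_warns_on_malformed_atc():
    pids = ["P1", "P2"] * 30
    part = Partition({p: 0 for p in set(pids)})
    rx = pd.DataFrame(
        {
            "patient_id": ["P1", "P2"],
            "atc_code": ["A10BA02", "bogus"],
            "date": pd.Timestamp("2001-01-01"),
        }
    )
    with pytest.warns(UserWarning, match="malformed"):
        prescription_enrichment(part, rx, min_cluster=1)
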