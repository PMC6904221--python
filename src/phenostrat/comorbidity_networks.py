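"""Pairwise comorbidity statistics.

For every unordered diagnosis-code pair the module computes:

* a two-sided Fisher's exact test on joint patient-level presence, with a
  comorbidity score CS = log2((observed + s) / (expected + s)) where the
  expected co-occurrence is n_A * n_B / N and s is an additive smoothing
  constant (default 1) guarding against log of zero;
* temporal directionality: among patients carrying both codes on distinct
  first-occurrence dates, exact binomial sign tests of "A first" and
  "B first" against 0.5, plus the mean signed lag (days, date_B - date_A);
* greedy extraction of the most significant pairs up to a budget of unique
  codes, per-symptom-group unique pairs, and a one-way ANOVA comparing a
  pair's per-patient lags across symptom groups.

Co-occurrence and directionality p-values are Bonferroni-adjusted within
their families (significance at adjusted p <= 0.01 by convention).
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .containers import as_events

DEFAULT_SMOOTHING = 1.0
DEFAULT_ALPHA = 0.01


def _bonferroni(p: np.ndarray) -> np.ndarray:
    return np.minimum(np.asarray(p, float) * len(p), 1.0) if len(p) else np.asarray(p)


def comorbidity_score(
    observed: float, expected: float, smoothing: float = DEFAULT_SMOOTHING
) -> float:
    """log2 of observing the pair more or less than expected."""
    return float(np.log2((observed + smoothing) / (expected + smoothing)))


def _presence(events: pd.DataFrame) -> pd.DataFrame:
    ev = as_events(events)
    return ev.drop_duplicates(["patient_id", "code"])


def pair_cooccurrence(
    events: pd.DataFrame,
    population: int | None = None,
    smoothing: float = DEFAULT_SMOOTHING,
    alpha: float = DEFAULT_ALPHA,
    min_carriers: int = 1,
) -> pd.DataFrame:
    """Fisher co-occurrence tests and comorbidity scores for all code pairs.

    ``population`` is the total patient count N (defaults to the number of
    patients in the event stream). Codes carried by fewer than
    ``min_carriers`` patients are skipped.
    """
    pres = _presence(events)
    n_total = population or pres["patient_id"].nunique()
    carriers = pres.groupby("code")["patient_id"].apply(set)
    carriers = carriers[carriers.map(len) >= min_carriers]
    codes = sorted(carriers.index)
    rows = []
    for a, b in combinations(codes, 2):
        sa, sb = carriers[a], carriers[b]
        n_both = len(sa & sb)
        n_a_only = len(sa) - n_both
        n_b_only = len(sb) - n_both
        n_neither = n_total - n_both - n_a_only - n_b_only
        if n_both == 0 and n_a_only == 0:
            continue
        expected = len(sa) * len(sb) / n_total
        _, p = sps.fisher_exact(
            [[n_both, n_a_only], [n_b_only, n_neither]], alternative="two-sided"
        )
        rows.append(
            {
                "code_a": a,
                "code_b": b,
                "n_both": n_both,
                "n_a_only": n_a_only,
                "n_b_only": n_b_only,
                "n_neither": n_neither,
                "expected": expected,
                "cs": comorbidity_score(n_both, expected, smoothing),
                "p_cooccur": float(p),
            }
        )
    res = pd.DataFrame(
        rows,
        columns=["code_a", "code_b", "n_both", "n_a_only", "n_b_only", "n_neither",
                 "expected", "cs", "p_cooccur"],
    )
    res["p_cooccur_adj"] = _bonferroni(res["p_cooccur"].to_numpy())
    res["significant"] = res["p_cooccur_adj"] <= alpha
    return res.sort_values(["p_cooccur_adj", "code_a", "code_b"], ignore_index=True)


def first_occurrences(events: pd.DataFrame) -> pd.DataFrame:
    """Earliest date per (patient, code) over assigned + mined events."""
    ev = as_events(events)
    return ev.groupby(["patient_id", "code"], as_index=False)["date"].min()


def pair_directionality(
    events: pd.DataFrame,
    pairs: pd.DataFrame | None = None,
    alpha: float = DEFAULT_ALPHA,
    min_carriers: int = 1,
) -> pd.DataFrame:
    """Temporal directionality tests on first-occurrence order.

    For each pair, among patients carrying both codes, occurrences on
    distinct dates are split into n_ab (A first) and n_ba (B first);
    same-day ties are excluded from the counts but reported. Each direction
    gets an exact upper-tail binomial p against 0.5; both families are
    Bonferroni-adjusted together with one correction factor per direction
    family. The mean lag is mean(first_B - first_A) in days over all
    ordered carriers (positive = A typically first).
    """
    first = first_occurrences(events)
    wide = first.pivot(index="patient_id", columns="code", values="date")
    if pairs is not None:
        todo = list(zip(pairs["code_a"], pairs["code_b"]))
    else:
        carriers = first.groupby("code")["patient_id"].nunique()
        codes = sorted(carriers.index[carriers >= min_carriers])
        todo = list(combinations(codes, 2))
    rows = []
    for a, b in todo:
        if a not in wide.columns or b not in wide.columns:
            continue
        both = wide[[a, b]].dropna()
        if both.empty:
            continue
        diff = (both[b] - both[a]).dt.days
        n_ab = int((diff > 0).sum())
        n_ba = int((diff < 0).sum())
        ties = int((diff == 0).sum())
        n_dir = n_ab + n_ba
        if n_dir == 0:
            p_ab = p_ba = np.nan
        else:
            p_ab = float(sps.binom.sf(n_ab - 1, n_dir, 0.5))
            p_ba = float(sps.binom.sf(n_ba - 1, n_dir, 0.5))
        ordered = diff[diff != 0]
        rows.append(
            {
                "code_a": a,
                "code_b": b,
                "n_ab": n_ab,
                "n_ba": n_ba,
                "ties": ties,
                "p_a_before_b": p_ab,
                "p_b_before_a": p_ba,
                "mean_lag_days": float(ordered.mean()) if len(ordered) else np.nan,
            }
        )
    res = pd.DataFrame(
        rows,
        columns=["code_a", "code_b", "n_ab", "n_ba", "ties", "p_a_before_b",
                 "p_b_before_a", "mean_lag_days"],
    )
    if len(res):
        res["p_a_before_b_adj"] = _bonferroni(res["p_a_before_b"].to_numpy())
        res["p_b_before_a_adj"] = _bonferroni(res["p_b_before_a"].to_numpy())
        res["directional"] = (res["p_a_before_b_adj"] <= alpha) | (
            res["p_b_before_a_adj"] <= alpha
        )
    return res


def top_pairs_by_unique_codes(
    pairs: pd.DataFrame, max_unique: int = 100, rank_by: str = "p_cooccur_adj"
) -> pd.DataFrame:
    """Greedily take pairs in rank order until adding the next pair would
    push the count of distinct codes above ``max_unique``."""
    ranked = pairs.sort_values(rank_by, kind="mergesort")
    seen: set = set()
    take = []
    for idx, row in ranked.iterrows():
        new = {row["code_a"], row["code_b"]} - seen
        if len(seen) + len(new) > max_unique:
            break
        seen |= new
        take.append(idx)
    return ranked.loc[take].reset_index(drop=True)


def group_unique_pairs(pairs_by_group: dict) -> dict:
    """Pairs significant in exactly one symptom group.

    ``pairs_by_group`` maps group label -> iterable of (code_a, code_b)
    significant pairs; returns group -> sorted list of its unique pairs.
    """
    norm = {
        g: {tuple(sorted(p)) for p in ps} for g, ps in pairs_by_group.items()
    }
    counts: dict = {}
    for ps in norm.values():
        for p in ps:
            counts[p] = counts.get(p, 0) + 1
    return {
        g: sorted(p for p in ps if counts[p] == 1) for g, ps in norm.items()
    }


def lag_anova(lags_by_group: dict, min_obs: int = 2) -> float:
    """One-way ANOVA p-value for lag differences across symptom groups.

    Groups with fewer than ``min_obs`` observations are dropped; returns
    NaN when fewer than two groups remain (degenerate case, skipped).
    """
    samples = [np.asarray(v, float) for v in lags_by_group.values() if len(v) >= min_obs]
    if len(samples) < 2:
        return float("nan")
    if all(np.ptp(s) == 0 for s in samples) and len({s[0] for s in samples}) == 1:
        return 1.0
    return float(sps.f_oneway(*samples).pvalue)


def pair_lags_by_group(
    events: pd.DataFrame, code_a: str, code_b: str, group_of: dict
) -> dict:
    """Per-patient first-occurrence lags (days, B minus A) split by the
    symptom group of each patient."""
    first = first_occurrences(events)
    wide = first.pivot(index="patient_id", columns="code", values="date")
    if code_a not in wide.columns or code_b not in wide.columns:
        return {}
    both = wide[[code_a, code_b]].dropna()
    diff = (both[code_b] - both[code_a]).dt.days
    diff = diff[diff != 0]
    out: dict = {}
    for pid, lag in diff.items():
        g = group_of.get(pid)
        if g is None:
            continue
        out.setdefault(g, []).append(float(lag))
    return out
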