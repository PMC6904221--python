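"""Per-cluster enrichment statistics.

Three test families, each with multiple-testing control:

* diagnosis/custom-code enrichment per cluster: an upper-tail binomial test
  against a sex- and birth-decade-corrected expected probability (the
  cluster's stratum mix weighted by corpus-wide stratum prevalences), with
  Benjamini-Hochberg adjustment; an exact Poisson-binomial tail is
  available behind a flag for small clusters;
* metadata contrasts: per-cluster two-sided Wilcoxon rank-sum tests of each
  numeric field against the remaining clusters, BH-adjusted;
* prescription enrichment: two-sided Fisher's exact tests at ATC level 3
  restricted to analysis clusters (>= 50 patients), BH-adjusted.
"""

from __future__ import annotations

import re
import warnings

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .containers import Partition, as_events

DEFAULT_MIN_SUPPORT = 10
DEFAULT_ALPHA = 0.05

_ATC_RE = re.compile(r"^[A-Z]\d{2}[A-Z]")


def benjamini_hochberg(pvals) -> np.ndarray:
    """BH-adjusted p-values (NaNs pass through)."""
    p = np.asarray(pvals, float)
    out = np.full_like(p, np.nan)
    ok = ~np.isnan(p)
    if ok.sum():
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out


def poisson_binomial_tail(probs: np.ndarray, k: int) -> float:
    """Exact P(X >= k) for a sum of independent Bernoulli(probs) draws,
    by dynamic programming over the count distribution."""
    dist = np.zeros(len(probs) + 1)
    dist[0] = 1.0
    for p in probs:
        dist[1:] = dist[1:] * (1 - p) + dist[:-1] * p
        dist[0] *= 1 - p
    return float(dist[k:].sum())


def patient_strata(patients: pd.DataFrame) -> pd.Series:
    """(sex, birth decade) stratum label per patient."""
    decade = (pd.to_datetime(patients["birth_date"]).dt.year // 10) * 10
    lab = patients["sex"].astype(str) + ":" + decade.astype(str)
    return pd.Series(lab.to_numpy(), index=patients["patient_id"].to_numpy())


def stratified_binomial_enrichment(
    partition: Partition,
    events: pd.DataFrame,
    strata: pd.Series,
    min_support: int = DEFAULT_MIN_SUPPORT,
    alpha: float = DEFAULT_ALPHA,
    exact_poisson_binomial: bool = False,
) -> pd.DataFrame:
    """Codes found more often than expected in each cluster.

    For each (cluster, code), the expected per-patient probability is the
    sum over strata of (stratum share within the cluster) x (corpus-wide
    code prevalence in that stratum); the p-value is the upper binomial
    tail at the observed patient count. Results observed in fewer than
    ``min_support`` patients are excluded before BH adjustment.
    """
    ev = as_events(events)
    clustered = sorted(set(partition.labels) & set(strata.index))
    if not clustered:
        raise ValueError("no clustered patient has stratum information")
    missing = set(partition.labels) - set(strata.index)
    if missing:
        raise ValueError(f"strata undefined for {len(missing)} clustered patients")
    strata = strata.loc[clustered]
    ev = ev.loc[ev["patient_id"].isin(clustered)]
    presence = ev.drop_duplicates(["patient_id", "code"])

    # corpus-wide prevalence per (stratum, code)
    pres = presence.copy()
    pres["stratum"] = pres["patient_id"].map(strata)
    stratum_sizes = strata.value_counts()
    prev = (
        pres.groupby(["stratum", "code"]).size().unstack(fill_value=0).div(
            stratum_sizes, axis=0
        )
    )

    clusters = pd.Series({p: partition.labels[p] for p in clustered})
    rows = []
    for cl in sorted(set(clusters)):
        members = clusters.index[clusters == cl]
        size = len(members)
        mix = strata.loc[members].value_counts(normalize=True)
        mix = mix.reindex(prev.index, fill_value=0.0)
        expected_p = prev.mul(mix, axis=0).sum(axis=0)  # per code
        obs = (
            presence.loc[presence["patient_id"].isin(members)]
            .groupby("code")["patient_id"]
            .nunique()
        )
        for code, o in obs.items():
            if o < min_support:
                continue
            pe = float(expected_p.get(code, 0.0))
            if exact_poisson_binomial:
                per_patient = prev[code].reindex(strata.loc[members]).to_numpy(float)
                p = poisson_binomial_tail(np.nan_to_num(per_patient), int(o))
            else:
                p = float(sps.binom.sf(int(o) - 1, size, min(pe, 1.0)))
            rows.append(
                {
                    "cluster": cl,
                    "code": code,
                    "cluster_size": size,
                    "observed": int(o),
                    "expected": pe * size,
                    "p": p,
                }
            )
    res = pd.DataFrame(
        rows, columns=["cluster", "code", "cluster_size", "observed", "expected", "p"]
    )
    res["p_adj"] = benjamini_hochberg(res["p"]) if len(res) else []
    res["significant"] = res["p_adj"] <= alpha
    res["direction"] = np.where(res["observed"] >= res["expected"], "enriched", "depleted")
    return res.sort_values(["p_adj", "cluster", "code"], ignore_index=True)


def metadata_contrasts(
    partition: Partition,
    metadata: pd.DataFrame,
    fields: list | None = None,
    alpha: float = DEFAULT_ALPHA,
) -> pd.DataFrame:
    """Cluster-vs-rest Wilcoxon rank-sum contrasts of numeric metadata.

    ``metadata`` must carry a patient_id column; ``fields`` defaults to all
    numeric columns. Clusters of size one are skipped; constant fields
    yield missing p-values. BH adjustment is applied within each field.
    """
    meta = metadata.set_index("patient_id")
    if fields is None:
        fields = [c for c in meta.columns if pd.api.types.is_numeric_dtype(meta[c])]
    labels = pd.Series(partition.labels)
    labels = labels.loc[labels.index.intersection(meta.index)]
    rows = []
    for field in fields:
        col = meta[field]
        for cl in sorted(labels.unique()):
            inside = col.loc[labels.index[labels == cl]].dropna()
            outside = col.loc[labels.index[labels != cl]].dropna()
            rec = {
                "cluster": cl,
                "field": field,
                "n": len(inside),
                "mean": float(inside.mean()) if len(inside) else np.nan,
                "median": float(inside.median()) if len(inside) else np.nan,
                "p": np.nan,
            }
            if len(inside) >= 2 and len(outside) >= 2:
                if inside.nunique() > 1 or outside.nunique() > 1:
                    rec["p"] = float(
                        sps.mannwhitneyu(inside, outside, alternative="two-sided").pvalue
                    )
            rows.append(rec)
    res = pd.DataFrame(rows)
    if len(res):
        res["p_adj"] = np.nan
        for field in fields:
            m = res["field"] == field
            res.loc[m, "p_adj"] = benjamini_hochberg(res.loc[m, "p"])
        res["significant"] = res["p_adj"] <= alpha
    return res


def truncate_atc(code: str, level: int = 3) -> str | None:
    """Truncate an ATC code to the requested level (level 3 = 4 chars,
    e.g. A10B). Malformed codes return None."""
    if not isinstance(code, str):
        return None
    code = code.strip().upper()
    if not _ATC_RE.match(code):
        return None
    n_chars = {1: 1, 2: 3, 3: 4, 4: 5, 5: 7}[level]
    return code[:n_chars] if len(code) >= n_chars else None


def prescription_enrichment(
    partition: Partition,
    prescriptions: pd.DataFrame,
    level: int = 3,
    min_cluster: int = 50,
    alpha: float = DEFAULT_ALPHA,
) -> pd.DataFrame:
    """Fisher's exact prescription enrichment at ATC level ``level``,
    restricted to clusters with at least ``min_cluster`` patients."""
    rx = prescriptions.copy()
    rx["atc_class"] = rx["atc_code"].map(lambda c: truncate_atc(c, level))
    bad = rx["atc_class"].isna().sum()
    if bad:
        warnings.warn(f"dropped {bad} prescriptions with malformed ATC codes")
    rx = rx.dropna(subset=["atc_class"])
    view = partition.analysis(min_cluster)
    labels = pd.Series(view.labels)
    population = set(partition.labels)
    has_class = (
        rx.loc[rx["patient_id"].isin(population)]
        .drop_duplicates(["patient_id", "atc_class"])
        .groupby("atc_class")["patient_id"]
        .apply(set)
    )
    n_total = len(population)
    rows = []
    for cl in sorted(labels.unique()):
        members = set(labels.index[labels == cl])
        for atc, carriers in has_class.items():
            a = len(members & carriers)
            b = len(members) - a
            c = len(carriers) - a
            d = n_total - a - b - c
            odds, p = sps.fisher_exact([[a, b], [c, d]], alternative="two-sided")
            rows.append(
                {
                    "cluster": cl,
                    "atc_class": atc,
                    "observed": a,
                    "cluster_size": len(members),
                    "expected": len(carriers) * len(members) / n_total,
                    "odds_ratio": odds,
                    "p": p,
                }
            )
    res = pd.DataFrame(
        rows,
        columns=["cluster", "atc_class", "observed", "cluster_size", "expected",
                 "odds_ratio", "p"],
    )
    res["p_adj"] = benjamini_hochberg(res["p"]) if len(res) else []
    res["significant"] = res["p_adj"] <= alpha
    res["direction"] = np.where(res["observed"] >= res["expected"], "enriched", "depleted")
    return res.sort_values(["p_adj", "cluster", "atc_class"], ignore_index=True)
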