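"""Glycemic dysregulation scoring from codes and HbA1c time series.

Five per-patient criteria are evaluated and summed into a 0-5 score, with
score >= 3 defining the dysregulated class:

1. the custom dysregulation code (sdcL03) is present;
2. a hyperglycemia code (R73 or E89) is present;
3. a change point is detected in the HbA1c series (Bayesian online
   change-point detection under a Gaussian model with a conjugate
   Normal-Gamma prior and geometric hazard);
4. the model-based HbA1c level at diabetes onset (linear mixed model with
   patient-level random intercept, random slope when the data support it)
   is at or above the 53 mmol/mol diagnosis threshold;
5. the fraction of HbA1c measurements at or above 53 mmol/mol exceeds a
   threshold (default 0.5), summarizing the severity-bin distribution.

HbA1c series are pre-processed first: values outside [15, 184] mmol/mol
are removed, same-day duplicates averaged, and the series is split into
segments at gaps longer than a year; only segments with at least five
values spanning at least three months are analyzed. Patients without any
valid segment are excluded from the HbA1c-based criteria (their flags are
False with an excluded status).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

HBA1C_MIN, HBA1C_MAX = 15.0, 184.0
DIAGNOSIS_THRESHOLD = 53.0  # mmol/mol, T1D/T2D diagnosis level
DYSREGULATION_CODE = "sdcL03"
HYPERGLYCEMIA_CODES = ("R73", "E89")
#: Severity bins (clinical convention): normal, prediabetic, diabetic, critical.
SEVERITY_BIN_EDGES = (48.0, 53.0, 75.0)


# --------------------------------------------------------------------------
# HbA1c pre-processing


@dataclass
class HbA1cSeries:
    """One patient's filtered HbA1c measurements and valid segments."""

    patient_id: str
    dates: pd.DatetimeIndex
    values: np.ndarray
    segments: list = field(default_factory=list)  # list of (start, stop) slices

    @property
    def has_valid_segment(self) -> bool:
        return len(self.segments) > 0

    def segment_values(self):
        return [self.values[a:b] for a, b in self.segments]


def preprocess_hba1c(
    hba1c: pd.DataFrame,
    low: float = HBA1C_MIN,
    high: float = HBA1C_MAX,
    min_points: int = 5,
    min_span_days: int = 90,
    gap_days: int = 365,
) -> dict:
    """Filter and segment HbA1c series per patient.

    ``hba1c`` is long format (patient_id, date, value). Out-of-range values
    are removed, same-day duplicates averaged; series are split at gaps
    longer than ``gap_days`` and only segments with >= ``min_points``
    values spanning >= ``min_span_days`` are retained.

    Returns {patient_id: HbA1cSeries}; exclusion is visible as an empty
    segment list, not an error.
    """
    df = hba1c[["patient_id", "date", "value"]].copy()
    df["date"] = pd.to_datetime(df["date"])
    df = df.loc[(df["value"] >= low) & (df["value"] <= high)]
    df = df.groupby(["patient_id", "date"], as_index=False)["value"].mean()
    out: dict = {}
    for pid, grp in df.groupby("patient_id", sort=True):
        grp = grp.sort_values("date")
        dates = pd.DatetimeIndex(grp["date"])
        values = grp["value"].to_numpy(float)
        segments = []
        start = 0
        gaps = np.diff(dates.to_numpy()).astype("timedelta64[D]").astype(int)
        for i, g in enumerate(list(gaps) + [None]):
            if g is None or g > gap_days:
                stop = i + 1
                span = (dates[stop - 1] - dates[start]).days
                if stop - start >= min_points and span >= min_span_days:
                    segments.append((start, stop))
                start = stop
        out[pid] = HbA1cSeries(pid, dates, values, segments)
    return out


# --------------------------------------------------------------------------
# code-based criteria


def code_criteria(events: pd.DataFrame) -> pd.DataFrame:
    """Per-patient flags for the dysregulation and hyperglycemia codes.

    Returns a DataFrame indexed by patient with boolean columns
    ``has_dysregulation_code`` and ``has_hyperglycemia_code``.
    """
    pres = events.drop_duplicates(["patient_id", "code"])
    by_patient = pres.groupby("patient_id")["code"].apply(set)
    return pd.DataFrame(
        {
            "has_dysregulation_code": by_patient.map(
                lambda s: DYSREGULATION_CODE in s
            ),
            "has_hyperglycemia_code": by_patient.map(
                lambda s: any(c in s for c in HYPERGLYCEMIA_CODES)
            ),
        }
    )


# --------------------------------------------------------------------------
# Bayesian online change-point detection (Gaussian, Normal-Gamma prior)


@dataclass
class BocpdConfig:
    hazard_lambda: float = 20.0  # geometric expected run length
    mu0: float | None = None  # prior mean; defaults to the first observation
    kappa0: float = 0.01  # near-vague prior on the run mean
    alpha0: float = 1.0
    beta0: float | None = None  # defaults to alpha0 * (robust scale)^2
    posterior_threshold: float = 0.5
    min_shift: float = 5.0  # mmol/mol level change needed to flag
    window: int = 1  # change-point mass pooled over +/- window indices


def bocpd_run_length_posteriors(
    x: np.ndarray, cfg: BocpdConfig | None = None
) -> np.ndarray:
    """Run-length filtering with a Student-t predictive (Normal-Gamma prior).

    Returns the (n, n+1) matrix R with R[t, r] = P(run length = r after
    observing x_t). Row t has support on r = 0..t.
    """
    cfg = cfg or BocpdConfig()
    x = np.asarray(x, float)
    n = len(x)
    mu0 = float(x[0]) if cfg.mu0 is None else cfg.mu0
    diffs = np.abs(np.diff(x)) if n > 1 else np.array([1.0])
    scale = max(float(np.median(diffs)) / np.sqrt(2.0), 1e-3)
    beta0 = cfg.beta0 if cfg.beta0 is not None else cfg.alpha0 * scale**2
    h = 1.0 / cfg.hazard_lambda

    mu = np.array([mu0])
    kappa = np.array([cfg.kappa0])
    alpha = np.array([cfg.alpha0])
    beta = np.array([beta0])
    r = np.array([1.0])
    posteriors = np.zeros((n, n + 1))
    for t in range(n):
        df_t = 2.0 * alpha
        var_t = beta * (kappa + 1.0) / (alpha * kappa)
        pred = sps.t.pdf(x[t], df_t, loc=mu, scale=np.sqrt(var_t))
        pred = np.maximum(pred, 1e-300)
        r_new = np.empty(len(r) + 1)
        r_new[0] = float(np.sum(r * pred * h))
        r_new[1:] = r * pred * (1.0 - h)
        r_new /= r_new.sum()
        posteriors[t, : len(r_new)] = r_new
        mu_new = np.empty(len(mu) + 1)
        kappa_new = np.empty_like(mu_new)
        alpha_new = np.empty_like(mu_new)
        beta_new = np.empty_like(mu_new)
        mu_new[0], kappa_new[0], alpha_new[0], beta_new[0] = (
            mu0, cfg.kappa0, cfg.alpha0, beta0,
        )
        mu_new[1:] = (kappa * mu + x[t]) / (kappa + 1.0)
        kappa_new[1:] = kappa + 1.0
        alpha_new[1:] = alpha + 0.5
        beta_new[1:] = beta + 0.5 * kappa * (x[t] - mu) ** 2 / (kappa + 1.0)
        mu, kappa, alpha, beta = mu_new, kappa_new, alpha_new, beta_new
        r = r_new
    return posteriors


def bocpd_changepoint_probability(
    x: np.ndarray, cfg: BocpdConfig | None = None
) -> np.ndarray:
    """Posterior credence that a change point sits at each position.

    A run length of r after observation t places the most recent change at
    position t - r (observation t - r opened the current run). The score
    for position c is the maximum, over subsequent time steps, of the
    posterior mass aligned with c:

        cp[c] = max_{t >= c} R[t, t - c]

    Position 0 (the start of the series) is not a change and scores 0.
    After a genuine level shift the run-length posterior collapses onto
    the new run within a few observations, pushing the aligned mass toward
    1; on stationary data the mass stays on the full-length run.
    """
    x = np.asarray(x, float)
    n = len(x)
    if n < 2:
        return np.zeros(n)
    posteriors = bocpd_run_length_posteriors(x, cfg)
    cp = np.zeros(n)
    for c in range(1, n):
        cp[c] = float(np.max(posteriors[c:, :][np.arange(n - c), np.arange(n - c)]))
        # posteriors[t, t-c] for t = c..n-1 via the shifted diagonal
    return cp


def _level_shift(x: np.ndarray, t: int, width: int = 5) -> float:
    before = x[max(0, t - width) : t]
    after = x[t : t + width]
    if len(before) == 0 or len(after) == 0:
        return 0.0
    return float(abs(after.mean() - before.mean()))


def changepoint_flag(
    series: HbA1cSeries, cfg: BocpdConfig | None = None
) -> tuple[bool, list]:
    """Change-point criterion for one patient.

    Per valid segment, the run-length filter yields the posterior mass of a
    change at each observation; mass is pooled over ``window`` neighbouring
    indices to score a change *near* t. Positions where the pooled mass
    exceeds the posterior threshold and the local level shift is at least
    ``min_shift`` are reported; the flag is True when any exist. Constant
    segments never flag.
    """
    cfg = cfg or BocpdConfig()
    positions = []
    for start, stop in series.segments:
        x = series.values[start:stop]
        if np.ptp(x) == 0:
            continue
        cp = bocpd_changepoint_probability(x, cfg)
        cand = np.where(cp >= cfg.posterior_threshold)[0]
        # candidates within `window` of each other describe the same change;
        # keep the highest-credence position of each group
        group: list[int] = []
        for t in [*cand, None]:
            if t is not None and (not group or t - group[-1] <= cfg.window + 1):
                group.append(int(t))
                continue
            if group:
                best = max(group, key=lambda i: cp[i])
                if _level_shift(x, best) >= cfg.min_shift:
                    positions.append(start + best)
            group = [int(t)] if t is not None else []
    return len(positions) > 0, positions


# --------------------------------------------------------------------------
# HbA1c level at diabetes onset (linear mixed model)


def onset_level_flag(
    hba1c: pd.DataFrame,
    onset_dates: pd.Series,
    threshold: float = DIAGNOSIS_THRESHOLD,
    random_slope_min_points: int = 4,
    valid_patients: set | None = None,
) -> pd.DataFrame:
    """Mixed-model estimate of each patient's HbA1c at diabetes onset.

    Fits value ~ years-since-onset with a patient-level random intercept
    (plus random slope when the median measurement count reaches
    ``random_slope_min_points``) and predicts each patient's level at
    time zero. Patients with a missing onset date are not evaluable:
    flag False with status "no_onset".

    Returns a DataFrame indexed by patient with columns onset_level,
    flag, status.
    """
    from statsmodels.regression.mixed_linear_model import MixedLM

    df = hba1c[["patient_id", "date", "value"]].copy()
    df["date"] = pd.to_datetime(df["date"])
    df = df.loc[(df["value"] >= HBA1C_MIN) & (df["value"] <= HBA1C_MAX)]
    if valid_patients is not None:
        df = df.loc[df["patient_id"].isin(valid_patients)]
    onset = pd.to_datetime(pd.Series(onset_dates))
    all_patients = sorted(df["patient_id"].unique())
    df["onset"] = df["patient_id"].map(onset)
    fit_df = df.dropna(subset=["onset"]).copy()
    fit_df["t"] = (fit_df["date"] - fit_df["onset"]).dt.days / 365.25

    out = pd.DataFrame(
        {"onset_level": np.nan, "flag": False, "status": "no_onset"},
        index=pd.Index(all_patients, name="patient_id"),
    )
    if fit_df["patient_id"].nunique() < 2:
        return out
    per_patient = fit_df.groupby("patient_id").size()
    use_slope = per_patient.median() >= random_slope_min_points
    exog = np.column_stack([np.ones(len(fit_df)), fit_df["t"].to_numpy()])
    exog_re = exog if use_slope else exog[:, :1]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = MixedLM(
            fit_df["value"].to_numpy(), exog, groups=fit_df["patient_id"].to_numpy(),
            exog_re=exog_re,
        )
        result = model.fit(reml=True, method="lbfgs")
    fe_intercept = float(result.fe_params[0])
    for pid, re in result.random_effects.items():
        level = fe_intercept + float(np.asarray(re)[0])
        out.loc[pid, "onset_level"] = level
        out.loc[pid, "flag"] = bool(level >= threshold)
        out.loc[pid, "status"] = "ok"
    return out


# --------------------------------------------------------------------------
# severity bins


def severity_flag(
    series: HbA1cSeries,
    threshold: float = DIAGNOSIS_THRESHOLD,
    min_fraction: float = 0.5,
    bin_edges: tuple = SEVERITY_BIN_EDGES,
) -> tuple[bool, np.ndarray]:
    """Fraction of segment measurements at or above the diagnosis level.

    Returns (flag, bin_frequencies) with bins
    (<48, [48,53), [53,75), >=75) by default; the flag is True when the
    fraction of values >= ``threshold`` exceeds ``min_fraction``.
    """
    vals = np.concatenate(series.segment_values()) if series.segments else np.array([])
    if len(vals) == 0:
        return False, np.zeros(len(bin_edges) + 1)
    freqs = np.histogram(vals, bins=[-np.inf, *bin_edges, np.inf])[0] / len(vals)
    return bool(np.mean(vals >= threshold) > min_fraction), freqs


# --------------------------------------------------------------------------
# combined score


def dysregulation_score(flags: pd.DataFrame, min_criteria: int = 3) -> pd.DataFrame:
    """0-5 score = number of true criteria; >= ``min_criteria`` flags the
    patient dysregulated. Non-evaluable criteria count as False."""
    cols = [
        "has_dysregulation_code",
        "has_hyperglycemia_code",
        "changepoint",
        "onset_level",
        "severity",
    ]
    out = pd.DataFrame(
        {c: [bool(v) if pd.notna(v) else False for v in flags[c]] for c in cols},
        index=flags.index,
    )
    out["score"] = out[cols].sum(axis=1).astype(int)
    out["dysregulated"] = out["score"] >= min_criteria
    return out


def dysregulation_profiles(
    events: pd.DataFrame,
    hba1c: pd.DataFrame,
    onset_dates: pd.Series,
    bocpd: BocpdConfig | None = None,
    min_criteria: int = 3,
) -> pd.DataFrame:
    """Full five-criteria evaluation over a cohort.

    Patients are the union of patients in the event stream and the HbA1c
    table; HbA1c criteria are evaluated only on patients with a valid
    segment (the mixed model is also restricted to those patients).
    """
    processed = preprocess_hba1c(hba1c)
    valid = {p for p, s in processed.items() if s.has_valid_segment}
    patients = sorted(set(events["patient_id"]) | set(processed))
    codes = code_criteria(events).reindex(patients).fillna(False)
    onset = onset_level_flag(hba1c, onset_dates, valid_patients=valid)

    rows = []
    for pid in patients:
        s = processed.get(pid)
        evaluable = s is not None and s.has_valid_segment
        cp_flag = changepoint_flag(s, bocpd)[0] if evaluable else False
        sev_flag = severity_flag(s)[0] if evaluable else False
        onset_flag = bool(onset["flag"].get(pid, False)) if evaluable else False
        rows.append(
            {
                "patient_id": pid,
                "has_dysregulation_code": bool(codes.loc[pid, "has_dysregulation_code"]),
                "has_hyperglycemia_code": bool(codes.loc[pid, "has_hyperglycemia_code"]),
                "changepoint": cp_flag,
                "onset_level": onset_flag,
                "severity": sev_flag,
                "hba1c_evaluable": evaluable,
            }
        )
    flags = pd.DataFrame(rows).set_index("patient_id")
    scored = dysregulation_score(flags, min_criteria)
    scored["hba1c_evaluable"] = flags["hba1c_evaluable"]
    return scored


# --------------------------------------------------------------------------
# lab-panel contrasts between patient groups


def normalize_labs(
    labs: pd.DataFrame,
    coverage: float = 0.75,
    normality_alpha: float = 0.05,
    population: int | None = None,
) -> tuple[pd.DataFrame, list]:
    """Coverage filter plus per-test standardization.

    Tests performed on fewer than ``coverage`` of the population are
    dropped. Per retained test, a normality check (D'Agostino-Pearson) on
    the raw values triggers a log transform when the values are positive;
    values are then standardized to corpus mean 0, SD 1.

    Returns (normalized long DataFrame, retained test ids).
    """
    df = labs[["patient_id", "test_id", "date", "value"]].copy()
    n_pop = population or df["patient_id"].nunique()
    per_test = df.groupby("test_id")["patient_id"].nunique()
    keep = sorted(per_test.index[per_test >= coverage * n_pop])
    df = df.loc[df["test_id"].isin(keep)].copy()
    pieces = []
    for tid, grp in df.groupby("test_id", sort=True):
        vals = grp["value"].to_numpy(float)
        if len(vals) >= 20:
            try:
                p_norm = float(sps.normaltest(vals).pvalue)
            except ValueError:
                p_norm = 1.0
            if p_norm < normality_alpha and np.all(vals > 0):
                vals = np.log(vals)
        sd = vals.std(ddof=0)
        vals = (vals - vals.mean()) / (sd if sd > 0 else 1.0)
        g = grp.copy()
        g["value"] = vals
        pieces.append(g)
    out = pd.concat(pieces, ignore_index=True) if pieces else df.iloc[:0]
    return out, keep


def lab_summaries(normalized: pd.DataFrame) -> pd.DataFrame:
    """Per-patient mean, median and SD per test, wide on (stat, test)."""
    g = normalized.groupby(["patient_id", "test_id"])["value"]
    return pd.concat(
        {"mean": g.mean().unstack(), "median": g.median().unstack(),
         "sd": g.std().unstack()},
        axis=1,
    )


def lab_contrasts(
    labs: pd.DataFrame,
    groups: pd.Series,
    coverage: float = 0.75,
    alpha: float = 0.05,
) -> dict:
    """MANOVA + per-test KS contrasts of lab means across patient groups.

    ``groups`` maps patient -> group label (clusters, symptom groups, or
    dysregulation classes). Groups with fewer than two patients are
    excluded. Per-test two-sample KS compares each group against the rest
    on per-patient mean values; KS p-values are Bonferroni-adjusted.

    Returns {"manova_p": float, "ks": DataFrame, "summaries": DataFrame,
    "tests": [test ids]}.
    """
    groups = pd.Series(groups).dropna()
    sizes = groups.value_counts()
    groups = groups[groups.isin(sizes.index[sizes >= 2])]
    labs = labs.loc[labs["patient_id"].isin(groups.index)]
    normalized, tests = normalize_labs(labs, coverage, population=len(groups))
    summaries = lab_summaries(normalized)
    means = summaries["mean"].reindex(groups.index)

    manova_p = np.nan
    complete = means.dropna()
    grp_vec = groups.loc[complete.index]
    if len(tests) >= 1 and grp_vec.nunique() >= 2 and len(complete) > len(tests) + 2:
        from statsmodels.multivariate.manova import MANOVA

        data = complete.copy()
        data.columns = [f"t{i}" for i in range(len(data.columns))]
        data["grp"] = grp_vec.astype(str).to_numpy()
        formula = " + ".join(data.columns[:-1]) + " ~ grp"
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            mv = MANOVA.from_formula(formula, data=data)
            stat = mv.mv_test().results["grp"]["stat"]
        manova_p = float(stat.loc["Pillai's trace", "Pr > F"])

    ks_rows = []
    for tid in tests:
        col = means[tid] if tid in means.columns else pd.Series(dtype=float)
        for g in sorted(grp_vec.unique()):
            inside = col.loc[groups.index[groups == g]].dropna()
            outside = col.loc[groups.index[groups != g]].dropna()
            if len(inside) < 2 or len(outside) < 2:
                continue
            stat, p = sps.ks_2samp(inside, outside)
            ks_rows.append(
                {"test_id": tid, "group": g, "ks_stat": float(stat), "p": float(p),
                 "direction": "higher" if inside.mean() > outside.mean() else "lower"}
            )
    ks = pd.DataFrame(ks_rows, columns=["test_id", "group", "ks_stat", "p", "direction"])
    if len(ks):
        ks["p_adj"] = np.minimum(ks["p"] * len(ks), 1.0)
        ks["significant"] = ks["p_adj"] <= alpha
    return {"manova_p": manova_p, "ks": ks, "summaries": summaries, "tests": tests}
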