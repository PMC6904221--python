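"""Synthetic EHR cohort generator with planted ground truth.

Emulates the statistical structure the stratification pipeline assumes —
k phenotype clusters with distinct diagnosis-code profiles, clinical notes
embedding dictionary terms with controllable negation and single-edit typo
rates, HbA1c trajectories with optional level-shift change points,
lab panels with group-level mean shifts, and cluster-specific prescription
profiles — so every downstream stage is testable without confidential data.

Note language is synthetic English-like templates ("patient has <term>",
"no sign of <term>"); the tagging contract is language-agnostic given a
dictionary, so realistic clinical prose adds nothing to the tests. The
term vocabulary is constructed so that every pair of terms is at least
Levenshtein distance 3 apart and every term is at least distance 2 from
all template and cue words: a single-edit typo therefore always resolves
to its own term and never to a neighbour or a stop word.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import ConfigurationError
from .dictionary_ner import (
    DEFAULT_NEGATION_CUES,
    DEFAULT_SUBJECT_CUES,
    DictionaryEntry,
    levenshtein,
)

# --------------------------------------------------------------------------
# note templates (sentence-final punctuation matters for sentence splitting)

AFFIRM_TEMPLATES = [
    "patient has {t}.",
    "the patient reports {t}.",
    "examination shows {t}.",
    "follow up for {t}.",
    "treatment adjusted due to {t}.",
]
NEGATION_TEMPLATES = [
    "no sign of {t}.",
    "the patient denies {t}.",
    "without evidence of {t}.",
    "the patient's mother had {t}.",
    "family history of {t}.",
]

_TEMPLATE_WORDS = {
    "patient", "patients", "has", "the", "reports", "examination", "shows",
    "follow", "up", "for", "treatment", "adjusted", "due", "to", "no",
    "sign", "of", "denies", "without", "evidence", "mother", "had",
    "family", "history", "s",
}
_RESERVED = frozenset(
    _TEMPLATE_WORDS | set(DEFAULT_NEGATION_CUES) | set(DEFAULT_SUBJECT_CUES)
)

_PREFIXES = [
    "retino", "nephro", "neuro", "cardio", "gastro", "hepato", "dermato",
    "angio", "arthro", "broncho", "entero", "myelo", "osteo", "thrombo",
    "glomerulo", "pancreato", "cysto", "kerato", "rhino", "phlebo",
    "spleno", "colono", "laryngo", "pneumo", "adeno",
]
_SUFFIXES = [
    "pathy", "sclerosis", "megaly", "stenosis", "spasm", "plegia",
    "dynia", "ptosis", "lithiasis", "trophism",
]


def build_term_pool(min_pairwise: int = 3, min_reserved: int = 2) -> list[str]:
    """Deterministic pool of synthetic clinical terms.

    Greedy filter over prefix x suffix composites keeping only terms at
    least ``min_pairwise`` edits from every kept term and ``min_reserved``
    edits from every template/cue word.
    """
    pool: list[str] = ["dysregulation"]  # reserved for the sdcL03 custom code
    for suf in _SUFFIXES:
        for pre in _PREFIXES:
            cand = pre + suf
            if any(levenshtein(cand, t, cap=min_pairwise) < min_pairwise for t in pool):
                continue
            if any(
                levenshtein(cand, w, cap=min_reserved) < min_reserved
                for w in _RESERVED
            ):
                continue
            pool.append(cand)
    return pool


def _icd10_code_pool() -> list[str]:
    """ICD-10-like level-3 codes, excluding the stripped diabetes codes and
    chapter XVIII (R-codes are reserved for symptom profiles)."""
    excluded = {"E10", "E11"}
    return [
        f"{ch}{i:02d}"
        for ch in "CDFGIJKLMN"
        for i in range(100)
        if f"{ch}{i:02d}" not in excluded
    ]


# One representative level-3 code per chapter-XVIII block, used for the
# per-cluster symptom signatures.
SYMPTOM_BLOCK_CODES = [
    "R05", "R11", "R21", "R26", "R31", "R42", "R47", "R55",
    "R73", "R80", "R87", "R91", "R99",
]

CLUSTER_ATC_CODES = [
    "A10BA02", "C07AB02", "C10AA01", "N05AH03", "A02BC01",
    "C09AA02", "B01AC06", "R03AC02", "N06AB04", "M01AE01",
]
BACKGROUND_ATC_CODES = ["N02BE01", "A12AX01", "C03CA01", "H03AA01"]

HBA1C_TEST_ID = "NPU27300"


@dataclass
class CohortConfig:
    """Generator knobs; defaults define the standard study conditions."""

    n_patients: int = 600
    k_clusters: int = 6
    profile_codes_per_cluster: int = 8
    profile_code_prob: float = 0.8  # P(cluster patient carries a profile code)
    background_code_rate: float = 0.02
    n_background_codes: int = 30
    note_terms_per_patient: float = 6.0  # Poisson mean
    negation_rate: float = 0.1
    typo_rate: float = 0.05
    hba1c_points_per_patient: int = 12
    hba1c_changepoint_fraction: float = 0.3
    hba1c_shift: float = 15.0  # mmol/mol level jump at a change point
    hba1c_noise_sd: float = 2.0
    dysregulated_fraction: float = 0.25
    lab_effect_size: float = 1.0  # standardized mean difference
    n_lab_tests: int = 8
    lab_points_per_test: int = 3
    study_start: str = "2000-01-01"
    study_end: str = "2012-12-31"
    seed: int = 0

    def validate(self) -> None:
        probs = {
            "profile_code_prob": self.profile_code_prob,
            "background_code_rate": self.background_code_rate,
            "negation_rate": self.negation_rate,
            "typo_rate": self.typo_rate,
            "hba1c_changepoint_fraction": self.hba1c_changepoint_fraction,
            "dysregulated_fraction": self.dysregulated_fraction,
        }
        for name, p in probs.items():
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"{name}={p} outside [0, 1]")
        if self.n_patients < 1 or self.k_clusters < 1:
            raise ConfigurationError("n_patients and k_clusters must be positive")
        if self.k_clusters > self.n_patients:
            raise ConfigurationError("k_clusters cannot exceed n_patients")
        if self.hba1c_points_per_patient < 0 or self.profile_codes_per_cluster < 0:
            raise ConfigurationError("counts must be non-negative")


@dataclass
class GroundTruth:
    """Planted structure for scoring every downstream stage."""

    labels: dict = field(default_factory=dict)  # patient -> cluster
    mentions: pd.DataFrame | None = None  # planted note-mention inventory
    changepoints: dict = field(default_factory=dict)  # patient -> index | None
    dysregulated: dict = field(default_factory=dict)  # patient -> bool
    cluster_profile_codes: dict = field(default_factory=dict)
    cluster_symptom_codes: dict = field(default_factory=dict)
    cluster_atc: dict = field(default_factory=dict)


@dataclass
class Cohort:
    """Bundle of all generated tables, dictionaries and ground truth."""

    patients: pd.DataFrame
    notes: pd.DataFrame
    diagnoses: pd.DataFrame  # assigned code events
    labs: pd.DataFrame
    prescriptions: pd.DataFrame
    icd10_dictionary: pd.DataFrame
    custom_dictionary: pd.DataFrame
    truth: GroundTruth
    config: CohortConfig


def _apply_typo(term: str, rng: np.random.Generator) -> tuple[str, str]:
    """One character edit: substitution, deletion or insertion."""
    letters = "abcdefghijklmnopqrstuvwxyz"
    kind = rng.choice(["substitution", "deletion", "insertion"])
    pos = int(rng.integers(len(term)))
    if kind == "substitution":
        repl = letters[int(rng.integers(26))]
        while repl == term[pos]:
            repl = letters[int(rng.integers(26))]
        return term[:pos] + repl + term[pos + 1 :], kind
    if kind == "deletion":
        return term[:pos] + term[pos + 1 :], kind
    ins = letters[int(rng.integers(26))]
    return term[:pos] + ins + term[pos:], kind


def _random_dates(rng, start: pd.Timestamp, end: pd.Timestamp, n: int):
    span = (end - start).days
    offs = np.sort(rng.integers(0, span + 1, size=n))
    return [start + pd.Timedelta(days=int(d)) for d in offs]


def generate_cohort(config: CohortConfig | None = None, **kwargs) -> Cohort:
    """Generate a fully labelled synthetic cohort.

    A fixed seed yields byte-identical outputs. Patients are assigned to
    the k planted clusters in balanced fashion; each cluster owns a
    disjoint set of profile diagnosis codes, two symptom (R-block) codes
    and one signature ATC prescription class.
    """
    cfg = config or CohortConfig(**kwargs)
    if config is not None and kwargs:
        raise TypeError("pass either a CohortConfig or keyword overrides, not both")
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    start = pd.Timestamp(cfg.study_start)
    end = pd.Timestamp(cfg.study_end)

    # ---- vocabulary and code assignment
    terms = build_term_pool()
    n_profile = cfg.k_clusters * cfg.profile_codes_per_cluster
    n_needed = n_profile + cfg.n_background_codes
    if n_needed > len(terms) - 1:
        raise ConfigurationError(
            f"term pool ({len(terms) - 1}) too small for "
            f"{n_profile} profile + {cfg.n_background_codes} background codes"
        )
    codes = _icd10_code_pool()
    profile_codes = codes[:n_profile]
    background_codes = codes[n_profile:n_needed]
    term_for_code = dict(zip(profile_codes + background_codes, terms[1:n_needed + 1]))
    term_for_code["sdcL03"] = terms[0]

    cluster_profiles = {
        c: profile_codes[c * cfg.profile_codes_per_cluster : (c + 1) * cfg.profile_codes_per_cluster]
        for c in range(cfg.k_clusters)
    }
    n_blocks = len(SYMPTOM_BLOCK_CODES)
    cluster_symptoms = {
        c: sorted({SYMPTOM_BLOCK_CODES[c % n_blocks],
                   SYMPTOM_BLOCK_CODES[(c + 3) % n_blocks]})
        for c in range(cfg.k_clusters)
    }
    cluster_atc = {
        c: CLUSTER_ATC_CODES[c % len(CLUSTER_ATC_CODES)]
        for c in range(cfg.k_clusters)
    }

    # ---- patients and planted labels (balanced, shuffled)
    width = max(4, len(str(cfg.n_patients)))
    pids = [f"P{i:0{width}d}" for i in range(1, cfg.n_patients + 1)]
    labels = rng.permutation(np.arange(cfg.n_patients) % cfg.k_clusters)
    dysregulated = rng.random(cfg.n_patients) < cfg.dysregulated_fraction
    sexes = np.where(rng.random(cfg.n_patients) < 0.5, "F", "M")
    dtypes = np.where(rng.random(cfg.n_patients) < 0.3, "E10", "E11")
    birth_years = rng.integers(1930, 1986, size=cfg.n_patients)
    patients = pd.DataFrame(
        {
            "patient_id": pids,
            "sex": sexes,
            "birth_date": [
                f"{y}-{m:02d}-{d:02d}"
                for y, m, d in zip(
                    birth_years,
                    rng.integers(1, 13, size=cfg.n_patients),
                    rng.integers(1, 29, size=cfg.n_patients),
                )
            ],
            "diabetes_type": dtypes,
            "onset_date": "",
        }
    )
    onset_years = birth_years + rng.integers(20, 61, size=cfg.n_patients)
    onset_years = np.minimum(onset_years, 2005)
    patients["onset_date"] = [
        f"{y}-{m:02d}-{d:02d}"
        for y, m, d in zip(
            onset_years,
            rng.integers(1, 13, size=cfg.n_patients),
            rng.integers(1, 29, size=cfg.n_patients),
        )
    ]
    patients["birth_date"] = pd.to_datetime(patients["birth_date"])
    patients["onset_date"] = pd.to_datetime(patients["onset_date"])

    # ---- assigned diagnosis events
    diag_rows = []
    for i, pid in enumerate(pids):
        c = int(labels[i])
        # uncomplicated primary diabetes codes (removed by the vector stage)
        for _ in range(int(rng.integers(1, 3))):
            diag_rows.append((pid, dtypes[i], _random_dates(rng, start, end, 1)[0]))
        for code in cluster_profiles[c]:
            if rng.random() < cfg.profile_code_prob:
                for d in _random_dates(rng, start, end, int(rng.integers(1, 4))):
                    diag_rows.append((pid, code, d))
        for code in cluster_symptoms[c]:
            if rng.random() < 0.7:
                diag_rows.append((pid, code, _random_dates(rng, start, end, 1)[0]))
        for code in background_codes:
            if rng.random() < cfg.background_code_rate:
                diag_rows.append((pid, code, _random_dates(rng, start, end, 1)[0]))
        if dysregulated[i]:
            d0 = _random_dates(rng, start, end, 1)[0]
            diag_rows.append((pid, "sdcL03", d0))
            diag_rows.append((pid, "R73", d0))
    diagnoses = pd.DataFrame(diag_rows, columns=["patient_id", "code", "date"])
    diagnoses["source"] = "assigned"

    # ---- notes with planted mention inventory
    note_rows, inv_rows = [], []
    mentionable = {c: t for c, t in term_for_code.items() if c != "sdcL03"}
    bg_mention_codes = background_codes
    for i, pid in enumerate(pids):
        c = int(labels[i])
        n_mentions = int(rng.poisson(cfg.note_terms_per_patient))
        made = []
        for _ in range(n_mentions):
            if rng.random() < 0.75:
                code = cluster_profiles[c][int(rng.integers(len(cluster_profiles[c])))]
            else:
                code = bg_mention_codes[int(rng.integers(len(bg_mention_codes)))]
            term = mentionable[code]
            negated = bool(rng.random() < cfg.negation_rate)
            typo = bool(rng.random() < cfg.typo_rate)
            written, typo_kind = (term, "")
            if typo:
                written, typo_kind = _apply_typo(term, rng)
            tmpl_pool = NEGATION_TEMPLATES if negated else AFFIRM_TEMPLATES
            sentence = tmpl_pool[int(rng.integers(len(tmpl_pool)))].format(t=written)
            made.append((sentence, code, written, negated, typo, typo_kind))
        # group mentions into notes of 1-3 sentences
        j = 0
        while j < len(made):
            take = int(rng.integers(1, 4))
            chunk = made[j : j + take]
            date = _random_dates(rng, start, end, 1)[0]
            note_rows.append(
                {
                    "patient_id": pid,
                    "date": date,
                    "text": " ".join(s for s, *_ in chunk),
                }
            )
            for _, code, written, negated, typo, typo_kind in chunk:
                inv_rows.append(
                    {
                        "patient_id": pid,
                        "date": date,
                        "term": written,
                        "code": code,
                        "negated": negated,
                        "typo": typo,
                        "typo_kind": typo_kind,
                    }
                )
            j += take
    notes = pd.DataFrame(note_rows, columns=["patient_id", "date", "text"])
    inventory = pd.DataFrame(
        inv_rows,
        columns=["patient_id", "date", "term", "code", "negated", "typo", "typo_kind"],
    )

    # ---- HbA1c series (piecewise constant + noise)
    lab_rows = []
    changepoints: dict = {}
    n_pts = cfg.hba1c_points_per_patient
    for i, pid in enumerate(pids):
        if n_pts == 0:
            changepoints[pid] = None
            continue
        baseline = rng.normal(75.0 if dysregulated[i] else 46.0, 4.0)
        has_cp = (
            n_pts >= 9 and rng.random() < cfg.hba1c_changepoint_fraction
        )
        cp = int(rng.integers(4, n_pts - 4)) if has_cp else None
        changepoints[pid] = cp
        t0 = start + pd.Timedelta(days=int(rng.integers(366, 2922)))
        vals = baseline + rng.normal(0.0, cfg.hba1c_noise_sd, size=n_pts)
        if cp is not None:
            vals[cp:] += cfg.hba1c_shift
        vals = np.clip(vals, 20.0, 180.0)
        for k in range(n_pts):
            lab_rows.append(
                (pid, HBA1C_TEST_ID, t0 + pd.Timedelta(days=30 * k), round(float(vals[k]), 1))
            )

    # ---- general lab panel with group-level mean shift
    test_ids = [f"NPU{10000 + t}" for t in range(cfg.n_lab_tests)]
    shifted = set(test_ids[: cfg.n_lab_tests // 2])
    for i, pid in enumerate(pids):
        for tid in test_ids:
            mu = cfg.lab_effect_size if (dysregulated[i] and tid in shifted) else 0.0
            for d in _random_dates(rng, start, end, cfg.lab_points_per_test):
                lab_rows.append((pid, tid, d, round(float(rng.normal(mu, 1.0)), 3)))
    labs = pd.DataFrame(lab_rows, columns=["patient_id", "test_id", "date", "value"])

    # ---- prescriptions
    rx_rows = []
    for i, pid in enumerate(pids):
        c = int(labels[i])
        if rng.random() < 0.6:
            for d in _random_dates(rng, start, end, int(rng.integers(1, 4))):
                rx_rows.append((pid, cluster_atc[c], d))
        for atc in BACKGROUND_ATC_CODES:
            if rng.random() < 0.1:
                rx_rows.append((pid, atc, _random_dates(rng, start, end, 1)[0]))
    prescriptions = pd.DataFrame(rx_rows, columns=["patient_id", "atc_code", "date"])

    # ---- dictionaries
    icd10_dictionary = pd.DataFrame(
        {
            "term": [term_for_code[c] for c in profile_codes + background_codes],
            "code": profile_codes + background_codes,
            "vocabulary": "ICD10",
        }
    )
    custom_dictionary = pd.DataFrame(
        {"term": [term_for_code["sdcL03"]], "code": ["sdcL03"], "vocabulary": "CUSTOM"}
    )

    truth = GroundTruth(
        labels=dict(zip(pids, (int(x) for x in labels))),
        mentions=inventory,
        changepoints=changepoints,
        dysregulated=dict(zip(pids, (bool(x) for x in dysregulated))),
        cluster_profile_codes=cluster_profiles,
        cluster_symptom_codes=cluster_symptoms,
        cluster_atc=cluster_atc,
    )
    return Cohort(
        patients=patients,
        notes=notes,
        diagnoses=diagnoses,
        labs=labs,
        prescriptions=prescriptions,
        icd10_dictionary=icd10_dictionary,
        custom_dictionary=custom_dictionary,
        truth=truth,
        config=cfg,
    )


def dictionary_entries(cohort: Cohort) -> list[DictionaryEntry]:
    """Both cohort dictionaries as a flat entry list for the tagger."""
    from .dictionary_ner import entries_from_frame

    return entries_from_frame(cohort.icd10_dictionary) + entries_from_frame(
        cohort.custom_dictionary
    )


# --------------------------------------------------------------------------
# writers — the canonical on-disk input formats of the pipeline


def write_cohort(cohort: Cohort, outdir) -> dict:
    """Write all tables; returns the path map. Output is byte-stable."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}

    def _tsv(df: pd.DataFrame, name: str):
        p = out / name
        df2 = df.copy()
        for col in df2.columns:
            if pd.api.types.is_datetime64_any_dtype(df2[col]):
                df2[col] = df2[col].dt.strftime("%Y-%m-%d")
        df2.to_csv(p, sep="\t", index=False)
        paths[name] = p

    _tsv(cohort.patients, "patients.tsv")
    _tsv(cohort.diagnoses, "diagnoses.tsv")
    _tsv(cohort.labs, "labs.tsv")
    _tsv(cohort.prescriptions, "prescriptions.tsv")
    _tsv(cohort.icd10_dictionary, "dict_icd10.tsv")
    _tsv(cohort.custom_dictionary, "dict_custom.tsv")

    notes_path = out / "notes.jsonl"
    with open(notes_path, "w") as fh:
        for pid, date, text in cohort.notes.itertuples(index=False):
            fh.write(
                json.dumps(
                    {"patient_id": pid, "date": str(pd.Timestamp(date).date()), "text": text},
                    sort_keys=True,
                )
                + "\n"
            )
    paths["notes.jsonl"] = notes_path

    truth_path = out / "ground_truth.json"
    inv = cohort.truth.mentions.copy()
    inv["date"] = pd.to_datetime(inv["date"]).dt.strftime("%Y-%m-%d")
    payload = {
        "labels": cohort.truth.labels,
        "mentions": inv.to_dict(orient="records"),
        "changepoints": cohort.truth.changepoints,
        "dysregulated": cohort.truth.dysregulated,
        "cluster_profile_codes": {
            str(k): v for k, v in cohort.truth.cluster_profile_codes.items()
        },
        "cluster_symptom_codes": {
            str(k): v for k, v in cohort.truth.cluster_symptom_codes.items()
        },
        "cluster_atc": {str(k): v for k, v in cohort.truth.cluster_atc.items()},
        "config": asdict(cohort.config),
    }
    with open(truth_path, "w") as fh:
        json.dump(payload, fh, sort_keys=True, indent=1)
    paths["ground_truth.json"] = truth_path
    return paths


def read_notes(path) -> pd.DataFrame:
    rows = [json.loads(line) for line in open(path) if line.strip()]
    df = pd.DataFrame(rows, columns=["patient_id", "date", "text"])
    df["date"] = pd.to_datetime(df["date"])
    return df
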