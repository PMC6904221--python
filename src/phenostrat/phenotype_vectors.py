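"""Per-patient diagnosis-code vectors with BM25 weighting.

Combines assigned and text-mined code events into per-patient code
frequency lists, removes the uncomplicated primary diabetes codes (E10,
E109, E11, E119) so that the primary diabetes type does not dominate the
stratification, and transforms frequencies with the BM25 weighting scheme:

    Score(p, c) = IDF(c) * f(c,p) * (k1 + 1)
                  / (f(c,p) + k1 * (1 - b + b * |p| / |p_ave|))

    IDF(c) = ln((N - n(c) + 0.5) / (n(c) + 0.5))

with N the number of patients, n(c) the number of patients carrying code
c, f(c,p) the frequency of code c in patient p, |p| the patient's total
code-event count (with multiplicity) and |p_ave| its corpus mean. Defaults
b = 0.75 (partial document-length normalization) and k1 = 1.2 (strong
term-frequency saturation). Natural log is used; the base only rescales
weights uniformly and cancels in cosine similarity. Codes carried by more
than half the corpus receive negative IDF weights (allowed, documented).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import sparse

from .containers import UndefinedCodeError, as_events

#: Uncomplicated primary diabetes codes stripped before vectorization.
EXCLUDED_DIABETES_CODES = ("E10", "E109", "E11", "E119")


@dataclass
class BM25Params:
    b: float = 0.75
    k1: float = 1.2

    def validate(self) -> None:
        if not 0.0 <= self.b <= 1.0:
            raise ValueError(f"b={self.b} outside [0, 1]")
        if self.k1 <= 0:
            raise ValueError(f"k1={self.k1} must be positive")


@dataclass
class CorpusStats:
    """N, per-code patient counts n(c) and mean code-list length |p_ave|."""

    n_patients: int
    code_counts: pd.Series  # code -> number of patients carrying it
    mean_length: float  # |p_ave|: mean per-patient code-event count

    def n(self, code: str) -> int:
        if code not in self.code_counts.index:
            raise UndefinedCodeError(code)
        return int(self.code_counts[code])


class PhenotypeVectors:
    """Sparse patient x code weight matrix with labelled axes."""

    def __init__(self, matrix: sparse.csr_matrix, patients: pd.Index, codes: pd.Index):
        self.matrix = sparse.csr_matrix(matrix)
        self.patients = pd.Index(patients)
        self.codes = pd.Index(codes)

    def __len__(self) -> int:
        return self.matrix.shape[0]

    def weight(self, patient_id, code) -> float:
        i = self.patients.get_loc(patient_id)
        if code not in self.codes:
            return 0.0
        return float(self.matrix[i, self.codes.get_loc(code)])

    def to_frame(self) -> pd.DataFrame:
        """Sparse triplet form: (patient_id, code, weight)."""
        coo = self.matrix.tocoo()
        return pd.DataFrame(
            {
                "patient_id": self.patients[coo.row],
                "code": self.codes[coo.col],
                "weight": coo.data,
            }
        ).sort_values(["patient_id", "code"], ignore_index=True)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "PhenotypeVectors":
        patients = pd.Index(sorted(df["patient_id"].unique()))
        codes = pd.Index(sorted(df["code"].unique()))
        mat = sparse.coo_matrix(
            (
                df["weight"].to_numpy(float),
                (
                    patients.get_indexer(df["patient_id"]),
                    codes.get_indexer(df["code"]),
                ),
            ),
            shape=(len(patients), len(codes)),
        ).tocsr()
        return cls(mat, patients, codes)


def build_code_lists(
    events: pd.DataFrame,
    exclude: tuple = EXCLUDED_DIABETES_CODES,
) -> tuple[pd.DataFrame, CorpusStats, list]:
    """Per-patient code frequencies and corpus statistics.

    Frequencies count combined assigned + mined events with multiplicity;
    excluded codes are stripped before counting. Patients whose every event
    is excluded are retained with an empty vector and returned in the
    flagged list.

    Returns (freq, stats, empty_patients) where freq has columns
    (patient_id, code, f).
    """
    ev = as_events(events)
    if ev.empty:
        raise ValueError("event stream is empty")
    all_patients = pd.Index(sorted(ev["patient_id"].unique()))
    kept = ev.loc[~ev["code"].isin(exclude)]
    freq = (
        kept.groupby(["patient_id", "code"], sort=True)
        .size()
        .rename("f")
        .reset_index()
    )
    lengths = freq.groupby("patient_id")["f"].sum()
    lengths = lengths.reindex(all_patients, fill_value=0)
    code_counts = freq.groupby("code")["patient_id"].nunique().sort_index()
    stats = CorpusStats(
        n_patients=len(all_patients),
        code_counts=code_counts,
        mean_length=float(lengths.mean()),
    )
    empty = sorted(lengths.index[lengths == 0])
    return freq, stats, empty


def idf(code: str, stats: CorpusStats) -> float:
    """Inverse document frequency ln((N - n + 0.5) / (n + 0.5))."""
    n = stats.n(code)
    return float(np.log((stats.n_patients - n + 0.5) / (n + 0.5)))


def bm25_score(
    freq: pd.DataFrame,
    stats: CorpusStats,
    params: BM25Params | None = None,
    patients: pd.Index | None = None,
) -> PhenotypeVectors:
    """BM25-transform per-patient code frequencies.

    ``patients`` optionally fixes the row universe (so patients with empty
    vectors keep a row of zeros); defaults to the patients present in
    ``freq``.
    """
    params = params or BM25Params()
    params.validate()
    if patients is None:
        patients = pd.Index(sorted(freq["patient_id"].unique()))
    else:
        patients = pd.Index(patients)
    codes = pd.Index(sorted(stats.code_counts.index))

    f = freq["f"].to_numpy(float)
    n_c = stats.code_counts.reindex(freq["code"]).to_numpy(float)
    idf_vals = np.log((stats.n_patients - n_c + 0.5) / (n_c + 0.5))
    lengths = freq.groupby("patient_id")["f"].sum()
    p_len = lengths.reindex(freq["patient_id"]).to_numpy(float)
    denom_norm = params.k1 * (
        1.0 - params.b + params.b * p_len / stats.mean_length
    )
    weights = idf_vals * f * (params.k1 + 1.0) / (f + denom_norm)

    rows = patients.get_indexer(freq["patient_id"])
    cols = codes.get_indexer(freq["code"])
    ok = (rows >= 0) & (cols >= 0)
    mat = sparse.coo_matrix(
        (weights[ok], (rows[ok], cols[ok])), shape=(len(patients), len(codes))
    ).tocsr()
    return PhenotypeVectors(mat, patients, codes)


def vectorize(
    events: pd.DataFrame,
    params: BM25Params | None = None,
    exclude: tuple = EXCLUDED_DIABETES_CODES,
) -> tuple[PhenotypeVectors, CorpusStats, list]:
    """Convenience: build_code_lists followed by bm25_score, keeping all
    patients (including those with empty vectors) as rows."""
    freq, stats, empty = build_code_lists(events, exclude)
    ev_patients = pd.Index(sorted(pd.unique(events["patient_id"])))
    vectors = bm25_score(freq, stats, params, patients=ev_patients)
    return vectors, stats, empty


def bm25_score_naive(
    freq: pd.DataFrame, stats: CorpusStats, params: BM25Params | None = None
) -> dict:
    """Reference two-loop implementation, for cross-checking only.

    Returns {patient_id: {code: weight}} computed code by code with plain
    Python floats. Kept deliberately independent of the vectorized path.
    """
    import math

    params = params or BM25Params()
    lengths: dict = {}
    for pid, _, fval in freq[["patient_id", "code", "f"]].itertuples(index=False):
        lengths[pid] = lengths.get(pid, 0) + fval
    out: dict = {}
    for pid, code, fval in freq[["patient_id", "code", "f"]].itertuples(index=False):
        n = int(stats.code_counts[code])
        idf_val = math.log((stats.n_patients - n + 0.5) / (n + 0.5))
        denom = fval + params.k1 * (
            1.0 - params.b + params.b * lengths[pid] / stats.mean_length
        )
        out.setdefault(pid, {})[code] = idf_val * fval * (params.k1 + 1.0) / denom
    return out
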