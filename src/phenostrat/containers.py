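"""Shared containers and exceptions used across pipeline stages.

Tabular payloads (code events, mentions, labs, prescriptions) travel as
pandas DataFrames with documented column schemas; this module holds the
small typed objects that several stages share, plus schema helpers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

#: Column schema of a code-event table: one row per dated (patient, code)
#: assignment, the atomic unit joining mined and assigned diagnoses.
EVENT_COLUMNS = ["patient_id", "code", "date", "source"]

#: Column schema of a mention table emitted by the dictionary tagger.
MENTION_COLUMNS = [
    "patient_id",
    "date",
    "code",
    "vocabulary",
    "start",
    "end",
    "matched",
    "negated",
    "fuzzy",
]


class PhenostratError(Exception):
    """Base class for pipeline errors."""


class ConfigurationError(PhenostratError):
    """Invalid configuration value (e.g. probability outside [0, 1])."""


class EmptyNetworkError(PhenostratError):
    """Similarity network has no usable nodes or edges."""


class ConvergenceError(PhenostratError):
    """Iterative procedure failed to converge within its iteration cap."""


class UndefinedCodeError(PhenostratError, KeyError):
    """A code was queried that has zero corpus support."""


def as_events(df: pd.DataFrame) -> pd.DataFrame:
    """Validate and coerce a DataFrame to the code-event schema."""
    missing = [c for c in EVENT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"event table missing columns: {missing}")
    out = df.loc[:, EVENT_COLUMNS].copy()
    out["date"] = pd.to_datetime(out["date"])
    return out


@dataclass
class Partition:
    """A patient -> cluster-label map with size-filter views.

    Labels are small non-negative integers assigned in decreasing cluster
    size (ties broken by the smallest member id), so label 0 is always a
    largest cluster. The two standard views mirror the downstream analysis
    conventions: clusters of more than ``retain_min - 1`` patients are kept
    for reporting, and clusters of at least ``analysis_min`` patients enter
    the statistical contrasts.
    """

    labels: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.labels)

    def sizes(self) -> pd.Series:
        """Cluster sizes indexed by label, descending."""
        s = pd.Series(self.labels, dtype="int64")
        return s.value_counts().sort_index().sort_values(ascending=False)

    def n_clusters(self) -> int:
        return len(set(self.labels.values()))

    def view(self, min_size: int) -> "Partition":
        """Restriction to clusters of at least ``min_size`` patients."""
        keep = {lab for lab, n in self.sizes().items() if n >= min_size}
        return Partition({p: l for p, l in self.labels.items() if l in keep})

    def retained(self, min_size: int = 11) -> "Partition":
        """Clusters with more than ten patients (reporting view)."""
        return self.view(min_size)

    def analysis(self, min_size: int = 50) -> "Partition":
        """Clusters with at least 50 patients (statistics view)."""
        return self.view(min_size)

    def as_sets(self) -> list:
        """Clusters as a label-free list of frozensets (for comparisons)."""
        by_label: dict = {}
        for p, l in self.labels.items():
            by_label.setdefault(l, set()).add(p)
        return sorted(
            (frozenset(v) for v in by_label.values()),
            key=lambda s: (-len(s), min(s)),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            sorted(self.labels.items()), columns=["patient_id", "cluster"]
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "Partition":
        return cls(dict(zip(df["patient_id"], df["cluster"])))

    @classmethod
    def relabel_by_size(cls, labels: dict) -> "Partition":
        """Canonicalize arbitrary labels to 0..K-1 by (size desc, min id)."""
        by_label: dict = {}
        for p, l in labels.items():
            by_label.setdefault(l, []).append(p)
        order = sorted(by_label.values(), key=lambda v: (-len(v), min(map(str, v))))
        out = {}
        for new, members in enumerate(order):
            for p in members:
                out[p] = new
        return cls(out)
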