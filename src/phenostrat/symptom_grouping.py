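"""Grouping clusters into symptom groups.

Each analysis cluster (>= 50 patients) is profiled by the fraction of its
patients carrying at least one code in each ICD-10 chapter XVIII level-1
symptom block (R00-R09 general symptoms through R95-R99), over combined
assigned + mined events. Profiles are then agglomerated by hierarchical
clustering with Euclidean distance and the classical Ward.D update applied
to unsquared distances (Ward.D2, which squares them, is available as an
option), and the tree is cut into k symptom groups.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist

from .containers import Partition, as_events

#: ICD-10 chapter XVIII level-1 blocks (symptoms, signs and abnormal findings).
SYMPTOM_BLOCKS = [
    ("R00", "R09"),
    ("R10", "R19"),
    ("R20", "R23"),
    ("R25", "R29"),
    ("R30", "R39"),
    ("R40", "R46"),
    ("R47", "R49"),
    ("R50", "R69"),
    ("R70", "R79"),
    ("R80", "R82"),
    ("R83", "R89"),
    ("R90", "R94"),
    ("R95", "R99"),
]
BLOCK_NAMES = [f"{lo}-{hi}" for lo, hi in SYMPTOM_BLOCKS]


def _block_of(code: str) -> str | None:
    if not isinstance(code, str) or len(code) < 3 or not code.startswith("R"):
        return None
    try:
        num = int(code[1:3])
    except ValueError:
        return None
    for (lo, hi), name in zip(SYMPTOM_BLOCKS, BLOCK_NAMES):
        if int(lo[1:]) <= num <= int(hi[1:]):
            return name
    return None


def symptom_profiles(partition: Partition, events: pd.DataFrame) -> pd.DataFrame:
    """Per-cluster symptom-block frequency profiles.

    Returns a DataFrame indexed by cluster label with one column per
    chapter-XVIII block, entries = fraction of the cluster's patients
    having >= 1 code in the block. Empty clusters are excluded.
    """
    if len(partition) == 0:
        raise ValueError("partition is empty")
    ev = as_events(events)
    ev = ev.loc[ev["patient_id"].isin(partition.labels)].copy()
    ev["block"] = ev["code"].map(_block_of)
    ev = ev.dropna(subset=["block"])
    members = pd.Series(partition.labels, name="cluster")
    sizes = members.value_counts()
    # patients with >=1 code per (cluster, block)
    hit = ev.drop_duplicates(["patient_id", "block"]).copy()
    hit["cluster"] = hit["patient_id"].map(partition.labels)
    counts = hit.groupby(["cluster", "block"]).size().unstack(fill_value=0)
    profiles = counts.reindex(index=sorted(sizes.index), columns=BLOCK_NAMES, fill_value=0)
    return profiles.div(sizes.reindex(profiles.index), axis=0).astype(float)


@dataclass
class SymptomGrouping:
    groups: dict  # cluster label -> group label (1..k)
    linkage_matrix: np.ndarray
    k: int
    clusters: list  # row order of the linkage input

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            sorted(self.groups.items()), columns=["cluster", "group"]
        )

    def newick(self) -> str:
        """Dendrogram as a Newick-like nested string with merge heights."""
        n = len(self.clusters)
        names = {i: str(self.clusters[i]) for i in range(n)}
        heights = {i: 0.0 for i in range(n)}
        for step, (a, b, h, _) in enumerate(self.linkage_matrix):
            a, b = int(a), int(b)
            la = (h - heights[a])
            lb = (h - heights[b])
            node = n + step
            names[node] = f"({names[a]}:{la:.6g},{names[b]}:{lb:.6g})"
            heights[node] = h
        return names[n + len(self.linkage_matrix) - 1] + ";"


def ward_groups(
    profiles: pd.DataFrame, k: int = 7, method: str = "ward.d"
) -> SymptomGrouping:
    """Hierarchical Ward clustering of symptom profiles, cut into k groups.

    ``ward.d`` applies the Ward update to unsquared Euclidean distances;
    ``ward.d2`` is the variant operating on squared distances.
    """
    n = len(profiles)
    if k < 1 or k > n:
        raise ValueError(f"k={k} must be in [1, {n}]")
    if n == 1:
        z = np.empty((0, 4))
        return SymptomGrouping({profiles.index[0]: 1}, z, k, list(profiles.index))
    x = profiles.to_numpy(float)
    if method.lower() in ("ward.d", "ward_d", "wardd"):
        # classical Ward update applied to UNSQUARED Euclidean distances.
        # scipy's "ward" runs the Lance-Williams recurrence on the squares
        # of its input, so feeding sqrt(d) makes it recur on d itself;
        # squaring the returned heights undoes the final square root.
        z = linkage(np.sqrt(pdist(x)), method="ward")
        z = z.copy()
        z[:, 2] = z[:, 2] ** 2
    elif method.lower() in ("ward.d2", "ward_d2", "wardd2"):
        # Ward on squared distances: scipy's native behaviour.
        z = linkage(pdist(x), method="ward")
    else:
        raise ValueError(f"unknown method {method!r}")
    flat = fcluster(z, t=k, criterion="maxclust")
    groups = dict(zip(profiles.index, (int(g) for g in flat)))
    return SymptomGrouping(groups, z, k, list(profiles.index))
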