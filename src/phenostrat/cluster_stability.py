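"""Robustness of the MCL clusters under network perturbation.

Two perturbation modes probe the reference clustering: *dilution* deletes
each edge independently with probability alpha, and *shuffling* rewires a
fraction alpha of the edges by degree-preserving double-edge swaps (node
set, edge count and every node's degree are unchanged). Perturbed networks
are re-clustered and compared to the reference partition with the
Variation of Information (VI) distance,

    VI(P, Q) = H(P) + H(Q) - 2 I(P; Q),

computed in nats from the cluster-size proportions of the contingency
table. Two Monte-Carlo reference lines — the expected VI after randomly
reassigning 10% and 20% of the vertices to different random clusters —
calibrate the curve.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .containers import Partition
from .patient_clustering import mcl_partition


@dataclass
class PerturbationSpec:
    mode: str  # "dilute" | "shuffle"
    alpha: float
    replicates: int = 5
    seed: int | None = None

    def validate(self) -> None:
        if self.mode not in ("dilute", "shuffle"):
            raise ValueError(f"unknown perturbation mode {self.mode!r}")
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError(f"alpha={self.alpha} outside [0, 1]")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")


def _dilute(g: nx.Graph, alpha: float, rng: np.random.Generator) -> nx.Graph:
    h = g.copy()
    if alpha <= 0:
        return h
    doomed = [e for e in h.edges() if rng.random() < alpha]
    h.remove_edges_from(doomed)
    return h


def _shuffle(g: nx.Graph, alpha: float, rng: np.random.Generator) -> nx.Graph:
    """Degree-preserving rewiring of ~alpha * |E| edges.

    Double-edge swap (u-v, x-y) -> (u-x, v-y); each new edge inherits the
    attribute dict of one removed edge so weights stay on the graph.
    """
    h = g.copy()
    n_edges = h.number_of_edges()
    target = int(round(alpha * n_edges))
    if target == 0 or n_edges < 2:
        return h
    edges = [(u, v, dict(d)) for u, v, d in h.edges(data=True)]
    swaps = 0
    tries = 0
    max_tries = 200 * target + 100
    while swaps < target and tries < max_tries:
        tries += 1
        i, j = int(rng.integers(len(edges))), int(rng.integers(len(edges)))
        if i == j:
            continue
        u, v, d1 = edges[i]
        x, y, d2 = edges[j]
        if len({u, v, x, y}) < 4:
            continue
        if h.has_edge(u, x) or h.has_edge(v, y):
            continue
        h.remove_edge(u, v)
        h.remove_edge(x, y)
        h.add_edge(u, x, **d1)
        h.add_edge(v, y, **d2)
        edges[i] = (u, x, d1)
        edges[j] = (v, y, d2)
        swaps += 1
    return h


def perturb_network(
    network: nx.Graph,
    spec: PerturbationSpec,
    rng: np.random.Generator | None = None,
) -> nx.Graph:
    """One perturbed realization of the network (nodes always retained)."""
    spec.validate()
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    if spec.mode == "dilute":
        return _dilute(network, spec.alpha, rng)
    return _shuffle(network, spec.alpha, rng)


def _entropy(counts: np.ndarray) -> float:
    p = counts / counts.sum()
    p = p[p > 0]
    return float(-(p * np.log(p)).sum())


def variation_of_information(p: Partition, q: Partition) -> float:
    """VI between two partitions, in nats.

    Partitions over different node sets are compared on their common nodes
    (the only well-defined comparison after size filtering).
    """
    common = sorted(set(p.labels) & set(q.labels))
    if not common:
        raise ValueError("partitions share no nodes")
    pl = pd.Series([p.labels[x] for x in common])
    ql = pd.Series([q.labels[x] for x in common])
    table = pd.crosstab(pl, ql).to_numpy(float)
    n = table.sum()
    hp = _entropy(table.sum(axis=1))
    hq = _entropy(table.sum(axis=0))
    joint = table[table > 0] / n
    h_joint = float(-(joint * np.log(joint)).sum())
    mutual = hp + hq - h_joint
    return max(0.0, hp + hq - 2.0 * mutual)


def random_reassignment_vi(
    reference: Partition,
    fraction: float,
    replicates: int = 5,
    rng: np.random.Generator | None = None,
) -> float:
    """Mean VI after reassigning ``fraction`` of nodes to different random
    clusters — the calibration reference line."""
    rng = rng or np.random.default_rng()
    nodes = sorted(reference.labels)
    labels_all = sorted(set(reference.labels.values()))
    if len(labels_all) < 2:
        return 0.0
    vis = []
    for _ in range(replicates):
        perturbed = dict(reference.labels)
        chosen = rng.choice(len(nodes), size=int(round(fraction * len(nodes))), replace=False)
        for idx in chosen:
            node = nodes[idx]
            others = [l for l in labels_all if l != reference.labels[node]]
            perturbed[node] = others[rng.integers(len(others))]
        vis.append(variation_of_information(reference, Partition(perturbed)))
    return float(np.mean(vis))


@dataclass
class StabilityCurve:
    """Per-replicate VI values plus the random-reassignment reference lines."""

    values: pd.DataFrame  # columns: mode, alpha, replicate, vi
    reference_lines: dict  # fraction -> mean VI

    def mean_by_alpha(self) -> pd.Series:
        return self.values.groupby("alpha")["vi"].mean()

    def to_tsv(self, path) -> None:
        self.values.to_csv(path, sep="\t", index=False)


def stability_curve(
    reference: Partition,
    network: nx.Graph,
    alphas,
    mode: str = "dilute",
    replicates: int = 5,
    seed: int | None = None,
    inflation: float = 1.2,
    reference_fractions: tuple = (0.1, 0.2),
    **mcl_kwargs,
) -> StabilityCurve:
    """Re-cluster perturbed replicates over an alpha grid and score VI.

    Clustering failures in individual replicates are recorded as missing
    values rather than aborting the whole curve.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for alpha in alphas:
        spec = PerturbationSpec(mode=mode, alpha=float(alpha), replicates=replicates)
        for rep in range(replicates):
            h = perturb_network(network, spec, rng)
            try:
                part = mcl_partition(h, inflation=inflation, **mcl_kwargs)
                vi = variation_of_information(reference, part)
            except Exception as exc:  # noqa: BLE001 - recorded, not fatal
                rows.append(
                    {"mode": mode, "alpha": float(alpha), "replicate": rep,
                     "vi": np.nan, "error": str(exc)}
                )
                continue
            rows.append(
                {"mode": mode, "alpha": float(alpha), "replicate": rep,
                 "vi": vi, "error": ""}
            )
    lines = {
        frac: random_reassignment_vi(reference, frac, replicates, rng)
        for frac in reference_fractions
    }
    return StabilityCurve(values=pd.DataFrame(rows), reference_lines=lines)
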