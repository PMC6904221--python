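"""Patient similarity network and Markov clustering.

Pairwise cosine similarities between BM25 code vectors are thresholded at
0.5 and rescaled linearly to edge weights in [10, 100] (the unique affine
map between the two stated intervals, w = 10 + 180*(s - 0.5)), giving an
undirected patient network. The network is partitioned with the Markov
Cluster algorithm (MCL): the column-stochastic transition matrix is
alternately expanded (matrix squaring) and inflated (entrywise power
followed by column renormalization) until the matrix stops changing, and
clusters are read off the attractor rows. A low inflation (default 1.2)
yields coarse clusters.
"""

from __future__ import annotations

import networkx as nx
import numpy as np
from sklearn.metrics.pairwise import cosine_similarity

from .containers import ConvergenceError, EmptyNetworkError, Partition
from .phenotype_vectors import PhenotypeVectors

COSINE_CUTOFF = 0.5
WEIGHT_LO, WEIGHT_HI = 10.0, 100.0


def rescale_similarity(s: np.ndarray | float, cutoff: float = COSINE_CUTOFF):
    """Affine map from cosine in [cutoff, 1] to weight in [10, 100]."""
    return WEIGHT_LO + (WEIGHT_HI - WEIGHT_LO) * (np.asarray(s) - cutoff) / (
        1.0 - cutoff
    )


def cosine_network(
    vectors: PhenotypeVectors, cutoff: float = COSINE_CUTOFF
) -> nx.Graph:
    """Thresholded, rescaled cosine-similarity network.

    Every patient becomes a node; pairs with cosine >= cutoff become edges
    carrying the raw ``cosine`` and the rescaled ``weight``. Patients with
    empty vectors stay as isolated nodes (cosine with an all-zero vector is
    treated as 0).
    """
    if len(vectors) < 2:
        raise EmptyNetworkError("need at least two vectors")
    norms = np.sqrt(vectors.matrix.multiply(vectors.matrix).sum(axis=1)).A1
    if not np.any(norms > 0):
        raise EmptyNetworkError("all vectors are empty")
    sims = cosine_similarity(vectors.matrix)  # zero rows give 0 similarity
    np.fill_diagonal(sims, 0.0)
    g = nx.Graph()
    g.add_nodes_from(vectors.patients)
    ii, jj = np.nonzero(np.triu(sims >= cutoff, k=1))
    for i, j in zip(ii, jj):
        s = float(sims[i, j])
        g.add_edge(
            vectors.patients[i],
            vectors.patients[j],
            cosine=s,
            weight=float(rescale_similarity(s, cutoff)),
        )
    return g


def _mcl_matrix(
    m: np.ndarray,
    inflation: float,
    max_iter: int,
    tol: float,
    prune: float,
) -> np.ndarray:
    """Run expansion/inflation on a column-stochastic matrix to convergence."""
    for _ in range(max_iter):
        expanded = m @ m
        np.power(expanded, inflation, out=expanded)
        expanded[expanded < prune] = 0.0
        colsum = expanded.sum(axis=0)
        colsum[colsum == 0] = 1.0
        expanded /= colsum
        delta = float(np.max(np.abs(expanded - m)))
        m = expanded
        if delta < tol:
            return m
    raise ConvergenceError(
        f"MCL did not converge within {max_iter} iterations (last delta={delta:.3e})"
    )


def mcl_partition(
    network: nx.Graph,
    inflation: float = 1.2,
    weight: str = "weight",
    max_iter: int = 200,
    tol: float = 1e-8,
    self_loops: float = 1.0,
    prune: float = 1e-12,
    attractor_tol: float = 1e-6,
) -> Partition:
    """Markov clustering of the similarity network.

    Every node receives exactly one label. A node attracted to several
    attractor systems is assigned to the one holding the most of its
    probability mass, ties broken toward the lowest cluster label. Labels
    are canonicalized by decreasing cluster size. Isolated nodes come out
    as singleton clusters (identity dynamics).
    """
    if network.number_of_nodes() == 0:
        raise EmptyNetworkError("network has no nodes")
    nodes = sorted(network.nodes())
    n = len(nodes)
    a = nx.to_numpy_array(network, nodelist=nodes, weight=weight)
    a = a + self_loops * np.eye(n)
    m = a / a.sum(axis=0)
    m = _mcl_matrix(m, inflation, max_iter, tol, prune)

    attractors = np.where(np.diag(m) > attractor_tol)[0]
    if len(attractors) == 0:  # pathological; treat max-diagonal as attractor
        attractors = np.array([int(np.argmax(np.diag(m)))])
    # union attractors whose rows overlap into attractor systems
    parent = {int(a_): int(a_) for a_ in attractors}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    member_rows = {int(a_): set(np.where(m[a_] > attractor_tol)[0]) for a_ in attractors}
    for a1 in attractors:
        for a2 in attractors:
            if a2 <= a1:
                continue
            if int(a2) in member_rows[int(a1)] or int(a1) in member_rows[int(a2)]:
                r1, r2 = find(int(a1)), find(int(a2))
                if r1 != r2:
                    parent[max(r1, r2)] = min(r1, r2)
    systems: dict[int, list[int]] = {}
    for a_ in attractors:
        systems.setdefault(find(int(a_)), []).append(int(a_))
    system_ids = sorted(systems)

    # assign each node to the system holding most of its column mass
    labels: dict = {}
    col_mass = np.zeros((len(system_ids), n))
    for si, sid in enumerate(system_ids):
        col_mass[si] = m[systems[sid], :].sum(axis=0)
    best = np.argmax(col_mass, axis=0)
    max_mass = col_mass[best, np.arange(n)]
    next_label = len(system_ids)
    for j in range(n):
        if max_mass[j] > attractor_tol:
            labels[nodes[j]] = int(best[j])
        else:  # no attractor reaches this node: singleton
            labels[nodes[j]] = next_label
            next_label += 1
    return Partition.relabel_by_size(labels)


def cluster_patients(
    vectors: PhenotypeVectors,
    cutoff: float = COSINE_CUTOFF,
    inflation: float = 1.2,
    **mcl_kwargs,
) -> tuple[Partition, nx.Graph]:
    """Cosine network construction followed by MCL."""
    g = cosine_network(vectors, cutoff)
    return mcl_partition(g, inflation, **mcl_kwargs), g


def write_edge_list(network: nx.Graph, path) -> None:
    """Edge list TSV: patient_a, patient_b, cosine, weight."""
    import pandas as pd

    rows = [
        (min(u, v), max(u, v), d.get("cosine", float("nan")), d.get("weight", float("nan")))
        for u, v, d in network.edges(data=True)
    ]
    pd.DataFrame(
        sorted(rows), columns=["patient_a", "patient_b", "cosine", "weight"]
    ).to_csv(path, sep="\t", index=False)
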