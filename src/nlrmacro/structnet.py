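"""Structure-similarity networks and Louvain community detection.

Nodes are structure models; edges connect pairs whose normalized
structure-similarity score (TM-score-like, in [0, 1]) reaches a
threshold (0.5 by default — the conventional shared-fold cutoff).
Communities are found by Louvain modularity optimization on the
weighted graph; modularity is recomputed independently of the
optimizer so the reported Q is self-consistent.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClusterMixin


def build_graph(scores, tau: float = 0.5) -> nx.Graph:
    """Thresholded similarity graph from a pairwise score list.

    *scores* is a DataFrame with columns ``id_a, id_b, score`` or an
    iterable of such triples. Every id appears as a node; an edge is
    kept iff score >= tau (boundary inclusive) with the score as its
    weight. Self-pairs are ignored. Scores outside [0, 1] or duplicate
    pairs with conflicting scores raise ValueError.
    """
    if isinstance(scores, pd.DataFrame):
        triples = scores[["id_a", "id_b", "score"]].itertuples(index=False)
    else:
        triples = scores
    g = nx.Graph(tau=tau)
    seen: dict[frozenset, float] = {}
    for a, b, s in triples:
        s = float(s)
        if not 0.0 <= s <= 1.0:
            raise ValueError(f"score {s} for pair ({a}, {b}) outside [0, 1]")
        g.add_node(a)
        g.add_node(b)
        if a == b:
            continue
        key = frozenset((a, b))
        if key in seen and abs(seen[key] - s) > 1e-12:
            raise ValueError(f"conflicting duplicate scores for pair ({a}, {b})")
        seen[key] = s
        if s >= tau:
            g.add_edge(a, b, weight=s)
    return g


def modularity(graph: nx.Graph, partition: dict, weighted: bool = True) -> float:
    """Weighted Newman-Girvan modularity of a node->community mapping.

    Q sums, over communities, the within-community edge-weight fraction
    minus the squared degree fraction of a degree-preserving null model;
    Q lies in [-0.5, 1] and is 0 for the one-community partition. A
    partition missing any node raises ValueError. An edgeless graph has
    Q = 0 by convention.
    """
    missing = [n for n in graph.nodes if n not in partition]
    if missing:
        raise ValueError(f"partition does not cover nodes: {missing[:5]}")
    w = (lambda d: d.get("weight", 1.0)) if weighted else (lambda d: 1.0)
    m2 = sum(w(d) for _, _, d in graph.edges(data=True)) * 2.0
    if m2 == 0:
        return 0.0
    internal: dict = {}
    degree: dict = {}
    for u, v, d in graph.edges(data=True):
        wt = w(d)
        degree[u] = degree.get(u, 0.0) + wt
        degree[v] = degree.get(v, 0.0) + wt
        if partition[u] == partition[v]:
            internal[partition[u]] = internal.get(partition[u], 0.0) + wt
    q = 0.0
    communities = set(partition.values())
    for c in communities:
        s_in = 2.0 * internal.get(c, 0.0)
        s_tot = sum(degree.get(n, 0.0) for n in partition if partition[n] == c)
        q += s_in / m2 - (s_tot / m2) ** 2
    return q


@dataclass
class Partition:
    """Community assignment plus its modularity on the source graph."""

    membership: dict  # node -> community index (0..k-1, canonical order)
    q: float

    @property
    def n_communities(self) -> int:
        return len(set(self.membership.values()))

    def communities(self) -> list[set]:
        out: dict[int, set] = {}
        for n, c in self.membership.items():
            out.setdefault(c, set()).add(n)
        return [out[c] for c in sorted(out)]


def _refine_local_moves(graph: nx.Graph, membership: dict, weighted: bool = True) -> dict:
    """Node-level local-move sweeps on the unaggregated graph.

    Repeatedly offers each node (sorted order) its best community among
    its neighbours' communities and a fresh singleton, accepting strict
    modularity gains, until a full sweep makes no move. This is the
    Louvain first phase re-applied to the final partition, which undoes
    the occasional suboptimal merge the aggregation phase locks in.
    """
    membership = dict(membership)
    w = (lambda d: d.get("weight", 1.0)) if weighted else (lambda d: 1.0)
    m2 = sum(w(d) for _, _, d in graph.edges(data=True)) * 2.0
    if m2 == 0:
        return membership
    degree = {n: 0.0 for n in graph.nodes}
    for u, v, d in graph.edges(data=True):
        degree[u] += w(d)
        degree[v] += w(d)
    sigma_tot: dict = {}
    for n, c in membership.items():
        sigma_tot[c] = sigma_tot.get(c, 0.0) + degree[n]
    nodes = sorted(graph.nodes, key=str)
    next_label = max(sigma_tot, default=-1) + 1
    improved = True
    while improved:
        improved = False
        for n in nodes:
            home = membership[n]
            links: dict = {}
            for nb, d in graph[n].items():
                if nb != n:
                    links[membership[nb]] = links.get(membership[nb], 0.0) + w(d)
            sigma_tot[home] -= degree[n]
            best_c, best_gain = home, links.get(home, 0.0) - sigma_tot[home] * degree[n] / m2
            candidates = set(links) | {next_label}
            for c in sorted(candidates, key=str):
                if c == home:
                    continue
                gain = links.get(c, 0.0) - sigma_tot.get(c, 0.0) * degree[n] / m2
                if gain > best_gain + 1e-12:
                    best_c, best_gain = c, gain
            membership[n] = best_c
            sigma_tot[best_c] = sigma_tot.get(best_c, 0.0) + degree[n]
            if best_c != home:
                improved = True
                if best_c == next_label:
                    next_label += 1
    return membership


class LouvainCommunities(BaseEstimator, ClusterMixin):
    """Louvain community detection on a weighted similarity graph.

    Runs the two-phase local-move + aggregation heuristic
    ``n_restarts`` times with seeds derived from ``random_state``,
    applies a final node-level local-move refinement to each result,
    and keeps the partition with the highest independently recomputed
    modularity (ties keep the earliest restart), which makes the result
    deterministic for a fixed seed. Community indices are canonicalized
    by each community's smallest node id.

    Attributes after fit: ``partition_`` (:class:`Partition`),
    ``labels_`` (community index per node in sorted node order),
    ``modularity_``.
    """

    def __init__(self, resolution: float = 1.0, random_state: int = 0,
                 n_restarts: int = 8, n_perturb: int = 4, weighted: bool = True):
        self.resolution = resolution
        self.random_state = random_state
        self.n_restarts = n_restarts
        self.n_perturb = n_perturb
        self.weighted = weighted

    def fit(self, X, y=None):
        """Detect communities. *X* is a networkx Graph."""
        graph = X
        if graph.number_of_nodes() == 0:
            self.partition_ = Partition(membership={}, q=0.0)
            self.labels_ = []
            self.modularity_ = 0.0
            return self
        weight = "weight" if self.weighted else None
        best: Partition | None = None
        for k in range(self.n_restarts):
            comms = nx.community.louvain_communities(
                graph,
                weight=weight,
                resolution=self.resolution,
                seed=int(self.random_state) + k,
            )
            raw = {}
            for ci, members in enumerate(sorted(comms, key=lambda c: min(map(str, c)))):
                for n in members:
                    raw[n] = ci
            refined = _refine_local_moves(graph, raw, weighted=self.weighted)
            # iterated local search: seeded perturbations re-refined,
            # kept only on strict modularity improvement
            rng = np.random.default_rng([max(int(self.random_state), 0), k])
            q_ref = modularity(graph, refined, weighted=self.weighted)
            nodes = sorted(graph.nodes, key=str)
            for _ in range(self.n_perturb):
                perturbed = dict(refined)
                fresh = max(perturbed.values(), default=-1) + 1
                labels = sorted(set(perturbed.values()))
                for n in nodes:
                    if rng.random() < 0.25:
                        choice = int(rng.integers(len(labels) + 1))
                        perturbed[n] = labels[choice] if choice < len(labels) else fresh
                candidate = _refine_local_moves(graph, perturbed, weighted=self.weighted)
                q_cand = modularity(graph, candidate, weighted=self.weighted)
                if q_cand > q_ref + 1e-12:
                    refined, q_ref = candidate, q_cand
            # canonicalize community ids by smallest member
            order = sorted(
                {c: min(map(str, (n for n in refined if refined[n] == c))) for c in set(refined.values())}.items(),
                key=lambda kv: kv[1],
            )
            relabel = {c: i for i, (c, _) in enumerate(order)}
            membership = {n: relabel[c] for n, c in refined.items()}
            q = modularity(graph, membership, weighted=self.weighted)
            if best is None or q > best.q + 1e-12:
                best = Partition(membership=membership, q=q)
        self.partition_ = best
        nodes = sorted(graph.nodes, key=str)
        self.labels_ = [best.membership[n] for n in nodes]
        self.modularity_ = best.q
        return self


def louvain(graph: nx.Graph, seed: int = 0, resolution: float = 1.0,
            n_restarts: int = 8, weighted: bool = True) -> Partition:
    """Functional wrapper over :class:`LouvainCommunities`."""
    est = LouvainCommunities(
        resolution=resolution, random_state=seed, n_restarts=n_restarts, weighted=weighted
    )
    return est.fit(graph).partition_


def filter_communities(partition: Partition, min_size: int = 2, major_min: int = 20):
    """Split detected communities into reported and major sets.

    Communities below ``min_size`` members are dropped from the
    reported tally; the major set holds communities with at least
    ``major_min`` members. Returns ``(kept, major)`` as lists of member
    sets (kept order: by community index).
    """
    comms = partition.communities()
    kept = [c for c in comms if len(c) >= min_size]
    major = [c for c in comms if len(c) >= major_min]
    return kept, major


def crosstab(og_assignment: dict, af_partition: dict):
    """Cross-tabulate sequence-group vs structure-community membership.

    Both arguments map member id -> group id. Returns ``(matrix,
    remainder)``: *matrix* is a DataFrame of shared-member counts
    (rows: sequence groups, columns: structure communities) over ids
    present in both assignments; *remainder* reports ids found in only
    one of the two.
    """
    shared = set(og_assignment) & set(af_partition)
    remainder = {
        "only_sequence": sorted(set(og_assignment) - shared),
        "only_structure": sorted(set(af_partition) - shared),
    }
    rows = sorted({og_assignment[i] for i in shared}, key=str)
    cols = sorted({af_partition[i] for i in shared}, key=str)
    mat = pd.DataFrame(0, index=rows, columns=cols, dtype=int)
    for i in shared:
        mat.loc[og_assignment[i], af_partition[i]] += 1
    return mat, remainder
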