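"""Independent brute-force oracles used by the test suite.

Everything here is implemented from first principles, deliberately
avoiding the package's own code paths (and, where feasible, the
libraries those paths delegate to), so that agreement is evidence of
correctness rather than self-confirmation.
"""

from __future__ import annotations

import math

import numpy as np

# ---------------------------------------------------------------- newick

def parse_newick(text: str):
    """Minimal recursive-descent newick parser.

    Returns a node as a dict {"name", "length", "children"}; lengths
    default to 0.0.
    """
    s = text.strip().rstrip(";")
    pos = 0

    def parse_node():
        nonlocal pos
        node = {"name": None, "length": 0.0, "children": []}
        if s[pos] == "(":
            pos += 1
            while True:
                node["children"].append(parse_node())
                if s[pos] == ",":
                    pos += 1
                    continue
                if s[pos] == ")":
                    pos += 1
                    break
        # label
        start = pos
        while pos < len(s) and s[pos] not in ",():;":
            pos += 1
        if pos > start:
            node["name"] = s[start:pos]
        if pos < len(s) and s[pos] == ":":
            pos += 1
            start = pos
            while pos < len(s) and s[pos] not in ",():;":
                pos += 1
            node["length"] = float(s[start:pos])
        return node

    root = parse_node()
    return root


def _tips_below(node):
    if not node["children"]:
        return frozenset([node["name"]])
    out = set()
    for c in node["children"]:
        out |= _tips_below(c)
    return frozenset(out)


def oracle_flag_branches(newick: str, abs_cutoff: float = 1.0, rel_cutoff: float = 0.5,
                         rel_ratio: float = 10.0):
    """Enumerate every branch of a newick tree and apply the two
    long-branch predicates independently.

    Mirrors the unrooted view: a degree-2 root is merged (the internal
    child is spliced into the root with its stem length added to the
    other child's branch) before evaluation. At polytomies the longest
    sister is the comparator. Returns a set of
    (tips_below, terminal, rule) triples.
    """
    root = parse_newick(newick)
    if len(root["children"]) == 2:
        # shared convention: the first internal child is spliced into the root
        c1, c2 = root["children"]
        internal = c1 if c1["children"] else (c2 if c2["children"] else None)
        if internal is not None:
            other = c2 if internal is c1 else c1
            other["length"] += internal["length"]
            root["children"] = [other] + internal["children"]

    flagged = set()

    def walk(node):
        for child in node["children"]:
            length = child["length"]
            sisters = [c["length"] for c in node["children"] if c is not child]
            smax = max(sisters) if sisters else None
            rule = None
            if length >= abs_cutoff:
                rule = "absolute"
            elif smax is not None and length >= rel_cutoff and length >= rel_ratio * smax:
                rule = "relative"
            if rule:
                flagged.add((_tips_below(child), not child["children"], rule))
            walk(child)

    walk(root)
    return flagged


# ------------------------------------------------- pairwise alignment

def brute_force_affine_align(a: str, b: str, matrix, gap_open: float = 11.0,
                             gap_extend: float = 1.0) -> float:
    """Best global alignment score by exhaustive enumeration.

    A gap run of length L costs gap_open + (L - 1) * gap_extend. Only
    practical for sequences of length <= ~7.
    """
    best = -math.inf

    def rec(i, j, score, prev):
        nonlocal best
        if i == len(a) and j == len(b):
            best = max(best, score)
            return
        if i < len(a) and j < len(b):
            rec(i + 1, j + 1, score + matrix[a[i]][b[j]], "M")
        if i < len(a):
            cost = gap_extend if prev == "X" else gap_open
            rec(i + 1, j, score - cost, "X")
        if j < len(b):
            cost = gap_extend if prev == "Y" else gap_open
            rec(i, j + 1, score - cost, "Y")

    rec(0, 0, 0.0, "")
    return best


# ------------------------------------------------------- profile HMM

def enumerate_hmm_paths(hmm, seq: str) -> list:
    """All path log-odds scores of the local profile alignment.

    Enumerates every entry point and every match/insert/delete state
    path from model position 0 (begin) to M; feasible for M <= 4 and
    len(seq) <= 8.
    """
    from nlrmacro.motifprof import ALPHABET

    M, t, L = hmm.n_match_, hmm.transitions_, len(seq)
    index = {a: i for i, a in enumerate(ALPHABET)}
    lo = hmm.log_odds_

    def emit(k, i):
        idx = index.get(seq[i])
        return lo[k - 1][idx] if idx is not None else 0.0

    out = []

    def rec(state, k, i, score):
        if k == M and state in ("M", "D"):
            out.append(score)
            return
        if state == "M":
            if i < L:
                rec("M", k + 1, i + 1, score + t["mm"][k] + emit(k + 1, i))
            if 1 <= k < M and i < L:
                rec("I", k, i + 1, score + t["mi"][k])
            rec("D", k + 1, i, score + t["md"][k])
        elif state == "I":
            if i < L:
                rec("M", k + 1, i + 1, score + t["im"][k] + emit(k + 1, i))
            if i < L:
                rec("I", k, i + 1, score + t["ii"][k])
        else:
            if i < L:
                rec("M", k + 1, i + 1, score + t["dm"][k] + emit(k + 1, i))
            rec("D", k + 1, i, score + t["dd"][k])

    for j in range(L + 1):
        rec("M", 0, j, 0.0)
    return out


def logsumexp2(values) -> float:
    values = np.asarray(values, dtype=float)
    top = values.max()
    return float(top + np.log2(np.sum(np.exp2(values - top))))


# ----------------------------------------------------- set partitions

def set_partitions(items):
    """All partitions of a list (Bell-number many; fine for n <= 8)."""
    items = list(items)
    if not items:
        yield []
        return
    first = items[0]
    for rest in set_partitions(items[1:]):
        for i in range(len(rest)):
            yield rest[:i] + [[first] + rest[i]] + rest[i + 1:]
        yield [[first]] + rest


def modularity_pair_sum(graph, membership: dict) -> float:
    """Modularity via the per-node-pair formula (independent route).

    Q = (1/2m) * sum_ij (A_ij - k_i k_j / 2m) delta(c_i, c_j).
    """
    nodes = list(graph.nodes)
    m2 = 2.0 * sum(d.get("weight", 1.0) for _, _, d in graph.edges(data=True))
    if m2 == 0:
        return 0.0
    k = {n: 0.0 for n in nodes}
    for u, v, d in graph.edges(data=True):
        w = d.get("weight", 1.0)
        k[u] += w
        k[v] += w
    q = 0.0
    for u in nodes:
        for v in nodes:
            if membership[u] != membership[v]:
                continue
            w = graph[u][v].get("weight", 1.0) if graph.has_edge(u, v) and u != v else 0.0
            q += w - k[u] * k[v] / m2
    return q / m2


def best_partition_modularity(graph) -> float:
    """Exhaustive maximum modularity over all partitions (n <= 8)."""
    best = -1.0
    for part in set_partitions(list(graph.nodes)):
        membership = {n: i for i, block in enumerate(part) for n in block}
        best = max(best, modularity_pair_sum(graph, membership))
    return best


# --------------------------------------------------------- statistics

def hypergeom_upper_tail(k: int, n_universe: int, n_term: int, n_set: int) -> float:
    """P(X >= k) for X ~ Hypergeom(N, K, n), via direct combinatorial sums."""
    hi = min(n_term, n_set)
    lo_bound = max(0, n_term + n_set - n_universe)
    if k > hi:
        return 0.0
    total = math.comb(n_universe, n_set)
    return sum(
        math.comb(n_term, x) * math.comb(n_universe - n_term, n_set - x)
        for x in range(max(k, lo_bound), hi + 1)
    ) / total


def bh_step_up(pvalues) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values by the closed-form step-up."""
    p = np.asarray(pvalues, dtype=float)
    n = p.size
    order = np.argsort(p, kind="stable")
    adjusted = np.empty(n)
    running_min = 1.0
    for rank_from_top in range(n - 1, -1, -1):
        idx = order[rank_from_top]
        running_min = min(running_min, p[idx] * n / (rank_from_top + 1))
        adjusted[idx] = running_min
    return adjusted
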