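"""Iterative homolog-tree cleaning by long-branch removal.

The cleaning loop mirrors the phylogenomic practice of repeatedly
aligning, filtering alignment columns for occupancy, inferring a tree,
and deleting branches that are implausibly long for a single-gene
history: branches of at least 1.0 substitutions/site (absolute rule)
and branches of at least 0.5 substitutions/site that are also at least
10x longer than their sister branch (relative rule). Both predicates
are evaluated in a single pass over the input tree of each round;
cascading effects are handled by iterating the loop (13 rounds by
default) to a fixed point, with a final terminal-branch-only pass.

Trees are treated as unrooted: a degree-2 root is merged before branch
evaluation. The sister of a branch is the stem branch of its sibling
subtree at the parent node; at polytomies the longest sister is used,
which only removes unambiguous outliers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd
from skbio import DistanceMatrix
from skbio.tree import nj as _skbio_nj

GAP_CHARS = "-."


@dataclass
class Msa:
    """Aligned sequences: parallel lists of ids and equal-length rows."""

    ids: list
    rows: list

    def __post_init__(self):
        self.ids = list(self.ids)
        self.rows = [str(r) for r in self.rows]
        if len(self.ids) != len(self.rows):
            raise ValueError("ids and rows differ in length")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("duplicate sequence ids in alignment")
        if self.rows and len({len(r) for r in self.rows}) > 1:
            raise ValueError("ragged alignment: rows have unequal lengths")

    @property
    def n_cols(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def select(self, keep_ids) -> "Msa":
        keep = set(keep_ids)
        pairs = [(i, r) for i, r in zip(self.ids, self.rows) if i in keep]
        return Msa([p[0] for p in pairs], [p[1] for p in pairs])

    @classmethod
    def from_records(cls, records) -> "Msa":
        records = list(records)
        return cls([r[0] for r in records], [r[1] for r in records])


@dataclass
class TrimPolicy:
    """Branch-length cutoffs and loop controls for homolog cleaning.

    Units are substitutions/site. Defaults: absolute cutoff 1.0,
    relative cutoff 0.5 with a 10x sister ratio, 13 cleaning rounds,
    10% minimum column occupancy, terminal-only final pass.
    """

    abs_cutoff: float = 1.0
    rel_cutoff: float = 0.5
    rel_ratio: float = 10.0
    rounds: int = 13
    occupancy_min: float = 0.10
    terminal_only_final: bool = True

    def __post_init__(self):
        if not (self.abs_cutoff > self.rel_cutoff > 0):
            raise ValueError("require abs_cutoff > rel_cutoff > 0")
        if self.rel_ratio <= 1:
            raise ValueError("rel_ratio must exceed 1")
        if self.rounds < 1:
            raise ValueError("rounds must be >= 1")
        if not (0 < self.occupancy_min <= 1):
            raise ValueError("occupancy_min must lie in (0, 1]")


def filter_columns(msa: Msa, occupancy_min: float = 0.10) -> Msa:
    """Keep exactly the columns whose non-gap fraction is >= occupancy_min.

    Row order is preserved; rows left with only gaps are dropped.
    Idempotent: filtering a filtered alignment changes nothing.
    """
    if not msa.rows:
        return Msa(list(msa.ids), list(msa.rows))
    arr = np.array([list(r) for r in msa.rows])
    nongap = ~np.isin(arr, list(GAP_CHARS))
    keep_cols = nongap.mean(axis=0) >= occupancy_min
    arr = arr[:, keep_cols]
    keep_rows = (~np.isin(arr, list(GAP_CHARS))).any(axis=1) if arr.shape[1] else np.zeros(len(msa.ids), bool)
    ids = [i for i, k in zip(msa.ids, keep_rows) if k]
    rows = ["".join(r) for r, k in zip(arr, keep_rows) if k]
    return Msa(ids, rows)


def p_distance_matrix(msa: Msa) -> tuple[np.ndarray, list]:
    """Pairwise p-distances ignoring columns gapped in either sequence.

    Pairs with no shared ungapped column get the maximal distance 1.0.
    """
    arr = np.array([list(r) for r in msa.rows])
    nongap = ~np.isin(arr, list(GAP_CHARS))
    n = len(msa.ids)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            shared = nongap[i] & nongap[j]
            m = shared.sum()
            d[i, j] = d[j, i] = (
                (arr[i, shared] != arr[j, shared]).mean() if m else 1.0
            )
    return d, list(msa.ids)


def nj_tree(distances, ids=None) -> dendropy.Tree:
    """Neighbor-joining tree from a symmetric distance matrix.

    Negative estimated branch lengths are clamped to zero. Additive
    matrices are recovered exactly (tip-to-tip path lengths equal the
    input distances).
    """
    d = np.asarray(distances, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    if d.shape[0] < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    if not np.allclose(d, d.T, atol=1e-12):
        raise ValueError("distance matrix must be symmetric")
    if not np.allclose(np.diag(d), 0.0, atol=1e-12):
        raise ValueError("distance matrix must have a zero diagonal")
    if ids is None:
        ids = [f"x{i}" for i in range(d.shape[0])]
    dm = DistanceMatrix(d, [str(i) for i in ids])
    newick = str(_skbio_nj(dm))
    return dendropy.Tree.get(data=newick, schema="newick", preserve_underscores=True)


def tip_distances(tree: dendropy.Tree) -> dict:
    """Tip-to-tip path lengths keyed by frozenset({a, b})."""
    pdm = tree.phylogenetic_distance_matrix()
    out = {}
    taxa = [leaf.taxon for leaf in tree.leaf_node_iter()]
    for i, t1 in enumerate(taxa):
        for t2 in taxa[i + 1 :]:
            out[frozenset((t1.label, t2.label))] = pdm.distance(t1, t2)
    return out


def _merge_degree2_root(tree: dendropy.Tree) -> None:
    """Collapse a degree-2 root into a basal polytomy (unrooted view)."""
    seed = tree.seed_node
    kids = seed.child_nodes()
    if len(kids) != 2:
        return
    internal = next((c for c in kids if not c.is_leaf()), None)
    if internal is None:  # two-taxon tree
        return
    other = kids[0] if kids[1] is internal else kids[1]
    other.edge.length = (other.edge.length or 0.0) + (internal.edge.length or 0.0)
    grandchildren = list(internal.child_nodes())
    seed.remove_child(internal)
    for gc in grandchildren:
        seed.add_child(gc)


def _clone(tree: dendropy.Tree) -> dendropy.Tree:
    return dendropy.Tree.get(
        data=tree.as_string(schema="newick"), schema="newick", preserve_underscores=True
    )


def flag_long_branches(tree: dendropy.Tree, policy: TrimPolicy | None = None) -> list:
    """Evaluate both long-branch predicates on every branch of the tree.

    The tree is viewed unrooted (a degree-2 root is merged first). Each
    flagged branch is reported as a dict with the tip set below it, a
    terminal marker, the rule fired ("absolute" takes precedence), its
    length and the longest sister length. Branches are enumerated in
    preorder; flags are independent of one another.
    """
    policy = policy or TrimPolicy()
    work = _clone(tree)
    _merge_degree2_root(work)
    seed = work.seed_node
    flags = []
    for node in work.preorder_node_iter():
        if node is seed:
            continue
        length = node.edge.length or 0.0
        sisters = [c for c in node.parent_node.child_nodes() if c is not node]
        sister_len = max(((c.edge.length or 0.0) for c in sisters), default=None)
        if length >= policy.abs_cutoff:
            rule = "absolute"
        elif (
            sister_len is not None
            and length >= policy.rel_cutoff
            and length >= policy.rel_ratio * sister_len
        ):
            rule = "relative"
        else:
            continue
        flags.append(
            {
                "tips_below": frozenset(l.taxon.label for l in node.leaf_iter()),
                "terminal": node.is_leaf(),
                "rule": rule,
                "branch_length": length,
                "sister_length": sister_len,
            }
        )
    return flags


def trim_long_branches(tree: dendropy.Tree, policy: TrimPolicy | None = None,
                       terminal_only: bool = True):
    """Flag and remove long branches in a single pass over the input tree.

    A branch is flagged by the absolute rule when its length is
    >= ``abs_cutoff``, and by the relative rule when its length is
    >= ``rel_cutoff`` and at least ``rel_ratio`` times the (longest)
    sister branch. Flags are evaluated once on the input tree; removals
    do not trigger re-evaluation within the pass.

    Flagged terminal branches delete their tip (degree-2 nodes are
    suppressed with branch lengths summed). Flagged internal branches —
    only when ``terminal_only`` is False — split the tree and retain the
    larger tip-set (ties keep the side holding the lexicographically
    smallest tip label).

    Returns ``(trimmed_tree, removed_tip_labels, log_rows)`` where each
    log row records the rule fired, the branch length and the sister
    length.
    """
    policy = policy or TrimPolicy()
    all_tips = sorted(leaf.taxon.label for leaf in tree.leaf_node_iter())
    flags = flag_long_branches(tree, policy)

    remove: set[str] = set()
    log_rows = []
    for f in flags:
        if f["terminal"]:
            (label,) = f["tips_below"]
            remove.add(label)
            log_rows.append(
                {
                    "tip": label,
                    "rule": f["rule"],
                    "kind": "terminal",
                    "branch_length": f["branch_length"],
                    "sister_length": f["sister_length"],
                }
            )
        elif not terminal_only:
            below = sorted(f["tips_below"])
            above = sorted(set(all_tips) - set(below))
            if len(below) < len(above):
                lost = below
            elif len(above) < len(below):
                lost = above
            else:  # tie: keep the side with the lexicographically smallest tip
                lost = above if min(below) < min(above) else below
            remove.update(lost)
            log_rows.append(
                {
                    "tip": ";".join(lost),
                    "rule": f["rule"],
                    "kind": "internal",
                    "branch_length": f["branch_length"],
                    "sister_length": f["sister_length"],
                }
            )

    survivors = [t for t in all_tips if t not in remove]
    if not survivors:
        raise ValueError("trimming removed every tip")
    out = _clone(tree)
    _merge_degree2_root(out)
    if remove:
        out.retain_taxa_with_labels(survivors)
    return out, sorted(remove), log_rows


@dataclass
class CleanResult:
    """Outcome of the iterative cleaning loop."""

    survivors: list
    log: pd.DataFrame
    status: str = "ok"               # ok | too-few-survivors
    rounds_run: int = 0
    removed: list = field(default_factory=list)


_LOG_COLS = ["round", "tip", "rule", "kind", "branch_length", "sister_length"]


def _empty_log() -> list:
    return []


def iterative_clean(msa: Msa, policy: TrimPolicy | None = None,
                    aligner=None, treebuilder=None) -> CleanResult:
    """Run the align / occupancy-filter / tree / trim loop on sequences.

    *aligner* maps an Msa to a (re)aligned Msa; the default passes the
    input through unchanged (pre-aligned input). *treebuilder* maps a
    filtered Msa to a tree; the default is neighbor joining on
    p-distances. Each round trims both terminal and internal flagged
    branches; after the loop reaches its round budget or a fixed point,
    one extra terminal-only pass runs when ``terminal_only_final`` is
    set. The loop stops with a warning status when fewer than 4
    sequences survive.
    """
    policy = policy or TrimPolicy()
    if treebuilder is None:
        treebuilder = lambda m: nj_tree(*p_distance_matrix(m))

    current = msa
    removed_all: list[str] = []
    log = _empty_log()
    status = "ok"
    rounds_run = 0

    for rnd in range(1, policy.rounds + 1):
        aligned = aligner(current) if aligner is not None else current
        filtered = filter_columns(aligned, policy.occupancy_min)
        if len(filtered.ids) < 4:
            status = "too-few-survivors"
            current = filtered
            break
        tree = treebuilder(filtered)
        _, removed, rows = trim_long_branches(tree, policy, terminal_only=False)
        rounds_run = rnd
        if not removed:
            break
        for r in rows:
            log.append({"round": rnd, **r})
        removed_all.extend(removed)
        current = current.select([i for i in current.ids if i not in set(removed)])
        if len(current.ids) < 4:
            status = "too-few-survivors"
            break

    if status == "ok" and policy.terminal_only_final and len(current.ids) >= 4:
        aligned = aligner(current) if aligner is not None else current
        filtered = filter_columns(aligned, policy.occupancy_min)
        if len(filtered.ids) >= 4:
            tree = treebuilder(filtered)
            _, removed, rows = trim_long_branches(tree, policy, terminal_only=True)
            for r in rows:
                log.append({"round": rounds_run + 1, **r})
            removed_all.extend(removed)
            current = current.select([i for i in current.ids if i not in set(removed)])

    return CleanResult(
        survivors=list(current.ids),
        log=pd.DataFrame(log, columns=_LOG_COLS),
        status=status,
        rounds_run=rounds_run,
        removed=removed_all,
    )


def restriction_treebuilder(master: dendropy.Tree):
    """Treebuilder that restricts a fixed tree to the surviving taxa.

    Used to clean an existing tree (rather than re-inferring one from
    sequences each round): each call extracts the subtree induced by the
    ids of the alignment it receives.
    """

    def build(msa: Msa) -> dendropy.Tree:
        keep = set(msa.ids)
        sub = _clone(master)
        sub.retain_taxa_with_labels([t for t in sorted(keep)])
        return sub

    return build


def iterative_clean_tree(tree: dendropy.Tree, policy: TrimPolicy | None = None) -> CleanResult:
    """Iterative cleaning applied directly to a tree with branch lengths.

    Each round re-restricts the input tree to the surviving tips
    (summing merged branch lengths) and trims; terminal-only final pass
    as in :func:`iterative_clean`.
    """
    policy = policy or TrimPolicy()
    tips = sorted(leaf.taxon.label for leaf in tree.leaf_node_iter())
    dummy = Msa(tips, ["A" for _ in tips])
    return iterative_clean(
        dummy, policy, aligner=None, treebuilder=restriction_treebuilder(tree)
    )
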