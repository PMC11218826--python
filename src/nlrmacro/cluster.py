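"""Greedy identity/coverage clustering of N-terminal domain sequences.

Pairwise engine: optimal global alignment under BLOSUM62 with affine
gaps (a gap of length L costs 11 + (L - 1)). Identity is counted over
alignment columns holding residues in both sequences; coverage of a
sequence is the fraction of its residues aligned against residues of
the other. Clustering is centroid-greedy at 50% identity / 50%
bidirectional coverage by default, mirroring the sequence-grouping
step of the survey pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices
from sklearn.base import BaseEstimator, ClusterMixin

_VALID = set("ACDEFGHIKLMNPQRSTVWYBZX*")


@dataclass(frozen=True)
class PairwiseAlignment:
    """Global pairwise alignment plus the derived similarity statistics."""

    aligned_a: str
    aligned_b: str
    identity: float
    coverage_a: float
    coverage_b: float
    score: float


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    aligner.mode = "global"
    return aligner


_ALIGNER = _make_aligner()


def global_align(a: str, b: str) -> PairwiseAlignment:
    """Optimal global alignment of two protein sequences.

    Raises ValueError on empty input or residues outside the amino-acid
    alphabet (B/Z/X ambiguity codes are accepted).
    """
    for name, s in (("a", a), ("b", b)):
        if not s:
            raise ValueError(f"sequence {name} is empty")
        bad = set(s.upper()) - _VALID
        if bad:
            raise ValueError(f"invalid residues in sequence {name}: {sorted(bad)}")
    a, b = a.upper(), b.upper()
    aln = _ALIGNER.align(a, b)[0]
    row_a, row_b = str(aln[0]), str(aln[1])
    both = ident = 0
    for x, y in zip(row_a, row_b):
        if x != "-" and y != "-":
            both += 1
            if x == y:
                ident += 1
    return PairwiseAlignment(
        aligned_a=row_a,
        aligned_b=row_b,
        identity=ident / both if both else 0.0,
        coverage_a=both / len(a),
        coverage_b=both / len(b),
        score=float(aln.score),
    )


@dataclass
class ClusterAssignment:
    """Result of greedy clustering: a partition of the input ids."""

    member_to_cluster: dict      # member id -> cluster index
    cluster_to_centroid: dict    # cluster index -> centroid member id

    @property
    def n_clusters(self) -> int:
        return len(self.cluster_to_centroid)

    def members(self, cluster: int) -> list:
        return [m for m, c in self.member_to_cluster.items() if c == cluster]


class GreedySequenceClusterer(BaseEstimator, ClusterMixin):
    """Centroid-greedy sequence clustering at identity/coverage thresholds.

    Sequences are processed longest-first (ties broken lexicographically
    by id) and joined to the first existing centroid reaching
    ``id_min`` identity with coverage >= ``cov_min``; with
    ``bidirectional=True`` (default) the coverage bound must hold for
    both sequences, otherwise for the shorter one only. A sequence
    matching no centroid opens a new cluster with itself as centroid.

    Attributes after fit: ``labels_`` (cluster index per input, input
    order), ``assignment_`` (ClusterAssignment), ``n_clusters_``.
    """

    def __init__(self, id_min: float = 0.5, cov_min: float = 0.5, bidirectional: bool = True):
        self.id_min = id_min
        self.cov_min = cov_min
        self.bidirectional = bidirectional

    def fit(self, X, y=None):
        """Cluster sequences. *X*: iterable of (id, sequence) pairs or a dict."""
        records = list(X.items()) if isinstance(X, dict) else [tuple(r) for r in X]
        if not records:
            raise ValueError("need at least one sequence")
        ids = [r[0] for r in records]
        if len(set(ids)) != len(ids):
            raise ValueError("sequence ids must be unique")
        order = sorted(records, key=lambda r: (-len(r[1]), r[0]))

        centroids: list[tuple[str, str]] = []
        member_to_cluster: dict[str, int] = {}
        for sid, seq in order:
            placed = False
            for ci, (cid, cseq) in enumerate(centroids):
                aln = global_align(seq, cseq)
                cov_ok = (
                    aln.coverage_a >= self.cov_min and aln.coverage_b >= self.cov_min
                    if self.bidirectional
                    else max(aln.coverage_a, aln.coverage_b) >= self.cov_min
                )
                if aln.identity >= self.id_min and cov_ok:
                    member_to_cluster[sid] = ci
                    placed = True
                    break
            if not placed:
                member_to_cluster[sid] = len(centroids)
                centroids.append((sid, seq))

        self.assignment_ = ClusterAssignment(
            member_to_cluster=member_to_cluster,
            cluster_to_centroid={i: cid for i, (cid, _) in enumerate(centroids)},
        )
        self.labels_ = np.array([member_to_cluster[i] for i in ids])
        self.n_clusters_ = len(centroids)
        return self


def greedy_cluster(seqs, id_min: float = 0.5, cov_min: float = 0.5,
                   bidirectional: bool = True) -> ClusterAssignment:
    """Functional wrapper over :class:`GreedySequenceClusterer`."""
    est = GreedySequenceClusterer(id_min=id_min, cov_min=cov_min, bidirectional=bidirectional)
    return est.fit(seqs).assignment_


def major_groups(assignment: ClusterAssignment, species_map: dict,
                 min_loci: int = 30, min_species: int = 3) -> set:
    """Clusters with at least ``min_loci`` members spanning at least
    ``min_species`` species (the "major sequence group" filter)."""
    missing = [m for m in assignment.member_to_cluster if m not in species_map]
    if missing:
        raise ValueError(f"members without species assignment: {missing[:5]}")
    sizes: dict[int, int] = {}
    species: dict[int, set] = {}
    for member, cl in assignment.member_to_cluster.items():
        sizes[cl] = sizes.get(cl, 0) + 1
        species.setdefault(cl, set()).add(species_map[member])
    return {
        cl
        for cl in sizes
        if sizes[cl] >= min_loci and len(species[cl]) >= min_species
    }
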