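"""Profile HMMs for N-terminal motifs (MAEPL/MADA style) and bit-score scans.

A profile is built from a curated motif alignment: columns with at
least 50% residue occupancy become match states; match emissions are
pseudocount-smoothed column frequencies expressed as log-odds against a
background distribution (bits); match/insert/delete transitions are
estimated from the observed gap structure with Laplace smoothing.

Scoring is global-in-motif, local-in-sequence: the model must be
traversed from its first to its last match/delete state, but may start
at any sequence position, and flanking residues cost nothing — matching
how a short N-terminal motif is sought inside full-length receptor
sequences. Viterbi returns the best single-path bit score and its
start; forward log-sums over all paths (and therefore never scores
below Viterbi). Insert states emit at background (zero log-odds);
following plan7 conventions there are no insert-delete transitions.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {a: i for i, a in enumerate(ALPHABET)}
GAP_CHARS = set("-.")
NEG_INF = float("-inf")

#: Robinson & Robinson amino-acid frequencies, in ALPHABET order.
ROBINSON_BACKGROUND = np.array(
    [
        0.07805, 0.01925, 0.05364, 0.06295, 0.03856, 0.07377, 0.02199,
        0.05142, 0.05744, 0.09019, 0.02243, 0.04487, 0.05203, 0.04264,
        0.05129, 0.07120, 0.05841, 0.06441, 0.01330, 0.03216,
    ]
)


@dataclass(frozen=True)
class MotifHit:
    """Best motif match for one sequence."""

    seq_id: str
    bit_score: float
    start: int          # 1-based position of the first model-matched residue
    mode: str           # viterbi | forward


def _as_rows(alignment) -> list[str]:
    if hasattr(alignment, "rows"):
        return list(alignment.rows)
    alignment = list(alignment)
    if alignment and isinstance(alignment[0], (tuple, list)):
        return [str(r[1]) for r in alignment]
    return [str(r) for r in alignment]


class ProfileHMM(BaseEstimator):
    """Profile hidden Markov model over a fixed motif alignment.

    Transition layout (source position ``p``; ``M_0`` is the begin
    state): ``mm[p] = M_p->M_{p+1}``, ``mi[p] = M_p->I_p`` (p >= 1),
    ``md[p] = M_p->D_{p+1}``, ``im[p]/ii[p] = I_p->M_{p+1}/I_p``,
    ``dm[p]/dd[p] = D_p->M_{p+1}/D_{p+1}``. ``M_M`` and ``D_M`` exit to
    the end state with probability 1. All stored as log2 probabilities.

    Parameters
    ----------
    match_occupancy:
        Minimum non-gap fraction for a column to become a match state
        (boundary inclusive).
    pseudocount:
        Total pseudocount weight added to each match column's emission
        counts, distributed according to the background.
    background:
        ``"uniform"``, ``"robinson"``, or an explicit length-20 array of
        frequencies in ALPHABET order.
    transition_pseudocount:
        Laplace weight added to each allowed transition count.
    """

    def __init__(self, match_occupancy: float = 0.5, pseudocount: float = 1.0,
                 background="uniform", transition_pseudocount: float = 1.0):
        self.match_occupancy = match_occupancy
        self.pseudocount = pseudocount
        self.background = background
        self.transition_pseudocount = transition_pseudocount

    # -- construction -------------------------------------------------

    def _background_freqs(self) -> np.ndarray:
        if isinstance(self.background, str):
            if self.background == "uniform":
                return np.full(20, 1.0 / 20)
            if self.background == "robinson":
                bg = ROBINSON_BACKGROUND.copy()
                return bg / bg.sum()
            raise ValueError(f"unknown background {self.background!r}")
        bg = np.asarray(self.background, dtype=float)
        if bg.shape != (20,) or not np.isclose(bg.sum(), 1.0):
            raise ValueError("explicit background must be 20 frequencies summing to 1")
        return bg

    def fit(self, X, y=None):
        """Build the profile from an alignment (Msa, aligned strings, or
        (id, row) pairs); needs >= 2 sequences and >= 1 match column."""
        rows = _as_rows(X)
        if len(rows) < 2:
            raise ValueError("profile needs at least 2 aligned sequences")
        if len({len(r) for r in rows}) > 1:
            raise ValueError("ragged alignment")
        arr = np.array([list(r.upper()) for r in rows])
        n_seq, n_col = arr.shape
        nongap = ~np.isin(arr, list(GAP_CHARS))
        occupancy = nongap.mean(axis=0)
        match_cols = np.flatnonzero(occupancy >= self.match_occupancy)
        if match_cols.size == 0:
            raise ValueError("no column meets the match-occupancy rule")
        M = int(match_cols.size)

        bg = self._background_freqs()
        probs = np.zeros((M, 20))
        for k, col in enumerate(match_cols):
            counts = np.zeros(20)
            for ch in arr[nongap[:, col], col]:
                idx = _AA_INDEX.get(ch)
                if idx is not None:
                    counts[idx] += 1
            probs[k] = (counts + self.pseudocount * bg) / (counts.sum() + self.pseudocount)

        # transitions from the observed gap structure
        is_match_col = np.zeros(n_col, dtype=bool)
        is_match_col[match_cols] = True
        col_rank = np.cumsum(is_match_col)  # match index reached at/after column
        tcounts = {k: np.zeros(M) for k in ("mm", "mi", "md", "im", "ii", "dm", "dd")}
        for r in range(n_seq):
            events = [("M", 0)]  # begin
            for col in range(n_col):
                k = int(col_rank[col])
                if is_match_col[col]:
                    events.append(("M" if nongap[r, col] else "D", k))
                elif nongap[r, col] and 0 < k < M:
                    # insert columns outside the first..last match span
                    # belong to the unmodelled flank
                    events.append(("I", k))
            for (s1, p), (s2, _) in zip(events, events[1:]):
                key = (s1 + s2).lower()
                # observed I->D / D->I transitions have no counterpart in
                # the plan7-style topology; they are dropped and the
                # Laplace pseudocounts keep every row normalized
                if key in tcounts:
                    tcounts[key][p] += 1.0

        pc = self.transition_pseudocount
        t = {k: np.full(M, NEG_INF) for k in tcounts}
        for p in range(M):  # from M_p (p=0 is begin)
            targets = ["mm", "md"] + (["mi"] if p >= 1 else [])
            tot = sum(tcounts[k][p] + pc for k in targets)
            for k in targets:
                t[k][p] = np.log2((tcounts[k][p] + pc) / tot)
        for p in range(1, M):  # from I_p and D_p
            tot = tcounts["im"][p] + tcounts["ii"][p] + 2 * pc
            t["im"][p] = np.log2((tcounts["im"][p] + pc) / tot)
            t["ii"][p] = np.log2((tcounts["ii"][p] + pc) / tot)
            tot = tcounts["dm"][p] + tcounts["dd"][p] + 2 * pc
            t["dm"][p] = np.log2((tcounts["dm"][p] + pc) / tot)
            t["dd"][p] = np.log2((tcounts["dd"][p] + pc) / tot)

        self.n_match_ = M
        self.match_columns_ = match_cols
        self.background_ = bg
        self.emission_probs_ = probs
        self.log_odds_ = np.log2(probs / bg)
        self.transitions_ = t
        return self

    # -- scoring ------------------------------------------------------

    def _emissions(self, seq: str) -> np.ndarray:
        """(M, L) match log-odds; unknown residues score as background."""
        cols = []
        for ch in seq.upper():
            idx = _AA_INDEX.get(ch)
            cols.append(self.log_odds_[:, idx] if idx is not None else np.zeros(self.n_match_))
        return np.array(cols).T

    def _dp(self, seq: str, viterbi: bool):
        """Shared Viterbi/forward recursion.

        Returns (score, start). Rows are state indices 1..M stored at
        index k-1; ``vd[k-1][j]`` covers paths ending in D_k after
        consuming j residues.
        """
        M, t = self.n_match_, self.transitions_
        L = len(seq)
        lo = self._emissions(seq)

        def combine(pairs):
            # pairs: iterable of (score, start); max for Viterbi,
            # log-sum for forward (start then tracks the best summand)
            best_s, best_i = NEG_INF, 1
            total = NEG_INF
            for s, i in pairs:
                if s > best_s:
                    best_s, best_i = s, i
                total = np.logaddexp2(total, s)
            return (best_s, best_i) if viterbi else (float(total), best_i)

        vm = np.full((M, L), NEG_INF)
        sm = np.ones((M, L), dtype=int)
        vi = np.full((M, L), NEG_INF)
        si = np.ones((M, L), dtype=int)
        vd = np.full((M, L + 1), NEG_INF)
        sd = np.ones((M, L + 1), dtype=int)

        for i in range(L):
            vm[0, i] = t["mm"][0] + lo[0, i]
            sm[0, i] = i + 1
        vd[0, :] = t["md"][0]
        sd[0, :] = np.minimum(np.arange(L + 1) + 1, max(L, 1))

        for p in range(1, M):
            # I_p, fed by M_p (row p-1) and itself
            for i in range(L):
                cands = []
                if i > 0:
                    cands.append((vm[p - 1, i - 1] + t["mi"][p], sm[p - 1, i - 1]))
                    cands.append((vi[p, i - 1] + t["ii"][p], si[p, i - 1]))
                if cands:
                    vi[p, i], si[p, i] = combine(cands)
            # M_{p+1} and D_{p+1}
            for i in range(L):
                cands = [(vd[p - 1, i] + t["dm"][p], sd[p - 1, i])]
                if i > 0:
                    cands.append((vm[p - 1, i - 1] + t["mm"][p], sm[p - 1, i - 1]))
                    cands.append((vi[p, i - 1] + t["im"][p], si[p, i - 1]))
                s, st = combine(cands)
                vm[p, i] = s + lo[p, i]
                sm[p, i] = st
            for j in range(L + 1):
                cands = [(vd[p - 1, j] + t["dd"][p], sd[p - 1, j])]
                if j > 0:
                    cands.append((vm[p - 1, j - 1] + t["md"][p], sm[p - 1, j - 1]))
                vd[p, j], sd[p, j] = combine(cands)

        ends = [(vm[M - 1, i], sm[M - 1, i]) for i in range(L)]
        ends += [(vd[M - 1, j], sd[M - 1, j]) for j in range(L + 1)]
        score, start = combine(ends)
        return float(score), int(start)

    def viterbi(self, seq: str) -> tuple[float, int]:
        """Best single-path bit score and its 1-based start position."""
        return self._dp(seq, viterbi=True)

    def forward(self, seq: str) -> float:
        """Log-sum bit score over all paths and start positions."""
        return self._dp(seq, viterbi=False)[0]

    def score(self, seq: str, mode: str = "viterbi", seq_id: str = "") -> MotifHit:
        if not seq:
            raise ValueError("sequence must be non-empty")
        if mode == "viterbi":
            bits, start = self.viterbi(seq)
        elif mode == "forward":
            bits, start = self._dp(seq, viterbi=False)
        else:
            raise ValueError(f"unknown mode {mode!r}")
        return MotifHit(seq_id=seq_id, bit_score=bits, start=start, mode=mode)

    def score_sequences(self, records, mode: str = "viterbi") -> list[MotifHit]:
        return [self.score(s, mode=mode, seq_id=str(i)) for i, s in records]

    # -- (de)serialization --------------------------------------------

    def to_json(self) -> str:
        params = self.get_params()
        if not isinstance(params["background"], str):
            params["background"] = list(np.asarray(params["background"], dtype=float))
        payload = {
            "params": params,
            "n_match": int(self.n_match_),
            "match_columns": self.match_columns_.tolist(),
            "background": self.background_.tolist(),
            "emission_probs": self.emission_probs_.tolist(),
            "transitions": {k: v.tolist() for k, v in self.transitions_.items()},
        }
        return json.dumps(payload, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "ProfileHMM":
        payload = json.loads(text)
        est = cls(**payload["params"])
        est.n_match_ = payload["n_match"]
        est.match_columns_ = np.array(payload["match_columns"], dtype=int)
        est.background_ = np.array(payload["background"])
        est.emission_probs_ = np.array(payload["emission_probs"])
        est.log_odds_ = np.log2(est.emission_probs_ / est.background_)
        est.transitions_ = {
            k: np.array(v, dtype=float) for k, v in payload["transitions"].items()
        }
        return est


def build_profile(alignment, match_occupancy: float = 0.5, pseudocount_weight: float = 1.0,
                  background="uniform") -> ProfileHMM:
    """Functional wrapper over :meth:`ProfileHMM.fit`."""
    return ProfileHMM(
        match_occupancy=match_occupancy,
        pseudocount=pseudocount_weight,
        background=background,
    ).fit(alignment)


def score_sequence(hmm: ProfileHMM, seq: str, mode: str = "viterbi") -> MotifHit:
    return hmm.score(seq, mode=mode)


def consensus_counts(alignment):
    """Per-column residue counts/frequencies and the consensus string.

    Returns ``(table, consensus)``: *table* has one row per (column,
    residue) with count and frequency over residues present in that
    column; the consensus takes each column's most frequent residue
    (ties broken alphabetically) and skips all-gap columns.
    """
    rows = _as_rows(alignment)
    if len({len(r) for r in rows}) > 1:
        raise ValueError("ragged alignment")
    arr = np.array([list(r.upper()) for r in rows])
    out = []
    consensus = []
    for col in range(arr.shape[1]):
        residues = [c for c in arr[:, col] if c not in GAP_CHARS]
        if not residues:
            continue
        vals, cnts = np.unique(residues, return_counts=True)
        total = int(cnts.sum())
        for v, c in zip(vals, cnts):
            out.append(
                {"column": col + 1, "residue": v, "count": int(c), "freq": c / total}
            )
        top = cnts.max()
        consensus.append(sorted(v for v, c in zip(vals, cnts) if c == top)[0])
    return pd.DataFrame(out), "".join(consensus)


def scan_and_summarize(hmm: ProfileHMM, proteome_sets: dict, mode: str = "viterbi",
                       n_term_window: int | None = None):
    """Score labeled proteome sets and summarize per-set distributions.

    *proteome_sets* maps a set label to (id, sequence) records. Returns
    ``(hits, summary)``: one hit row per sequence (id, set, bitscore,
    start) and one summary row per set (n, mean, median). With
    ``n_term_window`` scoring is restricted to the first that many
    residues of each sequence. Empty sets produce a warning and no rows.
    """
    if not proteome_sets:
        raise ValueError("need at least one proteome set")
    hit_rows, summary_rows = [], []
    for label, records in proteome_sets.items():
        records = list(records)
        if not records:
            warnings.warn(f"proteome set {label!r} is empty")
            continue
        scores = []
        for sid, seq in records:
            window = seq[:n_term_window] if n_term_window else seq
            hit = hmm.score(window, mode=mode, seq_id=sid)
            hit_rows.append(
                {"id": sid, "set": label, "bitscore": hit.bit_score, "start": hit.start}
            )
            scores.append(hit.bit_score)
        summary_rows.append(
            {
                "set": label,
                "n": len(scores),
                "mean": float(np.mean(scores)),
                "median": float(np.median(scores)),
            }
        )
    return pd.DataFrame(hit_rows), pd.DataFrame(summary_rows)
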