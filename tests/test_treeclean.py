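"""Occupancy filtering, neighbor joining and long-branch trimming."""

import dendropy
import numpy as np
import pytest

from conftest import random_trees
from helpers_oracles import oracle_flag_branches
from nlrmacro.simulate import SimConfig, gen_tree_with_outliers
from nlrmacro.treeclean import (
    Msa,
    TrimPolicy,
    filter_columns,
    flag_long_branches,
    iterative_clean,
    iterative_clean_tree,
    nj_tree,
    p_distance_matrix,
    tip_distances,
    trim_long_branches,
)


def tree_of(newick):
    return dendropy.Tree.get(data=newick, schema="newick", preserve_underscores=True)


class TestFilterColumns:
    def test_exact_boundary_column_kept(self):
        # 10 rows, one residue in the column: occupancy exactly 0.10
        rows = ["A-"] + ["--"] * 9
        out = filter_columns(Msa([f"s{i}" for i in range(10)], rows), 0.10)
        assert out.n_cols == 1
        assert out.ids == ["s0"]  # all-gap rows dropped

    def test_all_gap_column_removed(self):
        out = filter_columns(Msa(["a", "b"], ["A-C", "G-T"]), 0.10)
        assert out.rows == ["AC", "GT"]

    def test_survivors_match_per_column_recount(self, rng):
        for _ in range(20):
            n, m = int(rng.integers(2, 12)), int(rng.integers(1, 30))
            rows = [
                "".join(rng.choice(list("ACDG-"), p=[0.2, 0.2, 0.2, 0.1, 0.3], size=m))
                for _ in range(n)
            ]
            threshold = float(rng.choice([0.1, 0.3, 0.5]))
            out = filter_columns(Msa([f"s{i}" for i in range(n)], rows), threshold)
            expected_cols = [
                c
                for c in range(m)
                if sum(rows[r][c] != "-" for r in range(n)) / n >= threshold
            ]
            expected_rows = [
                (f"s{i}", "".join(rows[i][c] for c in expected_cols))
                for i in range(n)
                if any(rows[i][c] != "-" for c in expected_cols)
            ]
            assert list(zip(out.ids, out.rows)) == expected_rows

    def test_idempotent(self, rng):
        rows = ["AC-DE", "A--DE", "-C-D-", "ACQD-"]
        once = filter_columns(Msa(list("abcd"), rows), 0.5)
        twice = filter_columns(once, 0.5)
        assert once.rows == twice.rows and once.ids == twice.ids

    def test_ragged_alignment_rejected(self):
        with pytest.raises(ValueError, match="ragged"):
            Msa(["a", "b"], ["AC", "ACG"])


class TestNjTree:
    def test_three_taxa_closed_form(self):
        # star lengths: la = (dab + dac - dbc) / 2, etc.
        d = np.array([[0, 5, 9], [5, 0, 10], [9, 10, 0]], float)
        tree = nj_tree(d, list("abc"))
        dist = tip_distances(tree)
        assert dist[frozenset("ab")] == pytest.approx(5)
        assert dist[frozenset("ac")] == pytest.approx(9)
        assert dist[frozenset("bc")] == pytest.approx(10)

    def test_additive_four_taxon_matrix_recovered_exactly(self):
        d = np.array(
            [[0, 3, 7, 8], [3, 0, 8, 9], [7, 8, 0, 5], [8, 9, 5, 0]], float
        )
        dist = tip_distances(nj_tree(d, list("abcd")))
        for i, a in enumerate("abcd"):
            for j, b in enumerate("abcd"):
                if i < j:
                    assert dist[frozenset((a, b))] == pytest.approx(d[i, j], abs=1e-9)

    def test_additive_matrices_from_random_trees(self):
        for seed in range(5):
            cfg = SimConfig(seed=seed, n_taxa=int(4 + seed), long_branch_fraction=0.0)
            tree, _ = gen_tree_with_outliers(cfg)
            ref = tip_distances(tree)
            ids = sorted({x for pair in ref for x in pair})
            d = np.zeros((len(ids), len(ids)))
            for i, a in enumerate(ids):
                for j, b in enumerate(ids):
                    if i != j:
                        d[i, j] = ref[frozenset((a, b))]
            rebuilt = tip_distances(nj_tree(d, ids))
            for pair, expected in ref.items():
                assert rebuilt[pair] == pytest.approx(expected, abs=1e-9)

    def test_invalid_matrices_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            nj_tree(np.array([[0, 1, 2], [9, 0, 1], [2, 1, 0]], float))
        with pytest.raises(ValueError, match="at least 3"):
            nj_tree(np.zeros((2, 2)))


class TestTrimLongBranches:
    def test_absolute_rule(self):
        tree = tree_of("((A:0.1,B:0.1):0.05,(C:1.2,D:0.1):0.05);")
        _, removed, log = trim_long_branches(tree, TrimPolicy())
        assert removed == ["C"]
        assert log[0]["rule"] == "absolute"

    def test_relative_rule_fires_at_boundary(self):
        tree = tree_of("((A:0.1,B:0.1):0.05,(C:0.55,D:0.05):0.05);")
        _, removed, log = trim_long_branches(tree, TrimPolicy())
        assert removed == ["C"]
        assert log[0]["rule"] == "relative"

    def test_relative_rule_requires_half_sub_per_site(self):
        tree = tree_of("((A:0.1,B:0.1):0.05,(C:0.45,D:0.01):0.05);")
        _, removed, _ = trim_long_branches(tree, TrimPolicy())
        assert removed == []  # 45x sister but below 0.5

    def test_internal_branch_split_keeps_larger_side(self):
        tree = tree_of("((A:0.1,B:0.1):1.5,(C:0.1,(D:0.1,E:0.1):0.1):0.05);")
        _, removed, log = trim_long_branches(tree, TrimPolicy(), terminal_only=False)
        assert removed == ["A", "B"]
        assert log[0]["kind"] == "internal"

    def test_terminal_only_ignores_internal_flags(self):
        tree = tree_of("((A:0.1,B:0.1):1.5,(C:0.1,(D:0.1,E:0.1):0.1):0.05);")
        _, removed, _ = trim_long_branches(tree, TrimPolicy(), terminal_only=True)
        assert removed == []

    def test_path_lengths_conserved_after_tip_removal(self):
        tree = tree_of("((A:0.1,B:0.1):0.05,(C:1.2,D:0.1):0.05);")
        before = tip_distances(tree)
        trimmed, _, _ = trim_long_branches(tree, TrimPolicy())
        after = tip_distances(trimmed)
        for pair, dist in after.items():
            assert dist == pytest.approx(before[pair])

    def test_flags_match_independent_newick_oracle(self):
        policy = TrimPolicy()
        for newick in random_trees(40, max_tips=25, seed=5):
            ours = {
                (f["tips_below"], f["terminal"], f["rule"])
                for f in flag_long_branches(tree_of(newick), policy)
            }
            assert ours == oracle_flag_branches(newick)

    def test_relabel_equivariance(self):
        newick = "((A:0.1,B:1.4):0.05,(C:0.6,D:0.05):0.3,E:0.2);"
        mapping = {"A": "W", "B": "X", "C": "Y", "D": "Z", "E": "V"}
        relabeled = newick
        for old, new in mapping.items():
            relabeled = relabeled.replace(old + ":", new + ":")
        _, removed1, _ = trim_long_branches(tree_of(newick), TrimPolicy(),
                                            terminal_only=False)
        _, removed2, _ = trim_long_branches(tree_of(relabeled), TrimPolicy(),
                                            terminal_only=False)
        assert sorted(mapping[t] for t in removed1) == sorted(removed2)


class TestIterativeClean:
    def test_fixed_point_with_no_long_branches(self):
        cfg = SimConfig(seed=8, long_branch_fraction=0.0)
        tree, _ = gen_tree_with_outliers(cfg)
        result = iterative_clean_tree(tree, TrimPolicy())
        assert result.removed == []
        assert result.rounds_run == 1
        assert len(result.survivors) == cfg.n_taxa

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_planted_outliers_removed_and_only_them(self, seed):
        cfg = SimConfig(seed=seed)
        tree, truth = gen_tree_with_outliers(cfg)
        result = iterative_clean_tree(tree, TrimPolicy())
        planted = {t for t, v in truth.outlier.items() if v}
        assert set(result.removed) == planted

    def test_removal_log_round_bound(self):
        cfg = SimConfig(seed=1)
        tree, _ = gen_tree_with_outliers(cfg)
        policy = TrimPolicy(rounds=5)
        result = iterative_clean_tree(tree, policy)
        if not result.log.empty:
            assert result.log["round"].max() <= policy.rounds + 1

    def test_sequence_route_with_nj_default_builder(self):
        # 8 clean rows plus one wildly divergent homolog
        rng = np.random.default_rng(3)
        base = "".join(rng.choice(list("ACDEFGHIKL"), size=120))
        rows = []
        for i in range(8):
            row = list(base)
            for pos in rng.choice(120, size=6, replace=False):
                row[pos] = "ACDEFGHIKL"[rng.integers(10)]
            rows.append("".join(row))
        rows.append("".join(rng.choice(list("MNPQRSTVWY"), size=120)))
        msa = Msa([f"s{i}" for i in range(9)], rows)
        result = iterative_clean(msa, TrimPolicy())
        assert "s8" not in result.survivors
        assert set(result.survivors) == {f"s{i}" for i in range(8)}

    def test_too_few_survivors_status(self):
        msa = Msa(list("abc"), ["ACDE", "ACDE", "ACDE"])
        result = iterative_clean(msa, TrimPolicy())
        assert result.status == "too-few-survivors"
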