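"""DEG filtering, ortholog concordance quadrants and Fisher/BH enrichment."""

import numpy as np
import pandas as pd
import pytest

from helpers_oracles import bh_step_up, hypergeom_upper_tail
from nlrmacro.simulate import SimConfig, gen_deg_tables
from nlrmacro.xspecies import (
    bh_adjust,
    concordance,
    deg_overlap,
    filter_degs,
    fisher_pvalue,
    map_orthologs,
    sector_enrichment,
)


def deg_table(rows):
    return pd.DataFrame(rows, columns=["gene", "log2fc", "padj"])


class TestFilterDegs:
    @pytest.mark.parametrize(
        "lfc,padj,expected",
        [
            (2.0, 1e-3, "up"),       # both boundaries inclusive
            (-2.5, 1e-4, "down"),
            (1.9, 1e-9, "none"),     # effect too small
            (3.0, 2e-3, "none"),     # not significant
            (-2.0, 1e-3, "down"),
        ],
    )
    def test_direction_assignment(self, lfc, padj, expected):
        out = filter_degs(deg_table([("g", lfc, padj)]))
        assert out.iloc[0]["direction"] == expected

    def test_strict_mode_excludes_boundary_p(self):
        table = deg_table([("g", 2.5, 1e-3)])
        assert filter_degs(table).iloc[0]["direction"] == "up"
        assert filter_degs(table, strict=True).iloc[0]["direction"] == "none"

    def test_nan_padj_non_significant(self):
        out = filter_degs(deg_table([("g", 5.0, np.nan)]))
        assert out.iloc[0]["direction"] == "none"

    def test_missing_columns_rejected(self):
        with pytest.raises(ValueError, match="missing columns"):
            filter_degs(pd.DataFrame({"gene": ["g"]}))


def orthomap(rows):
    return pd.DataFrame(rows, columns=["gene", "species", "orthogroup"])


class TestMapOrthologs:
    def _degs(self, species, spec):
        return filter_degs(
            deg_table(
                [(g, 3.0 if d == "up" else (-3.0 if d == "down" else 0.5), 1e-5)
                 for g, d in spec]
            )
        )

    def test_concordant_quadrant(self):
        a = self._degs("A", [("a1", "up")])
        b = self._degs("B", [("b1", "up")])
        om = orthomap([("a1", "A", "OGx"), ("b1", "B", "OGx")])
        shared = map_orthologs(a, b, om, "A", "B")
        assert shared.table.iloc[0].tolist() == ["OGx", "up", "up"]

    def test_mixed_directions_flagged(self):
        a = self._degs("A", [("a1", "up"), ("a2", "down")])
        b = self._degs("B", [("b1", "up")])
        om = orthomap([("a1", "A", "OGy"), ("a2", "A", "OGy"), ("b1", "B", "OGy")])
        shared = map_orthologs(a, b, om, "A", "B")
        assert shared.table.iloc[0]["dir_a"] == "mixed"
        assert len(shared.mixed) == 1
        assert concordance(shared).n_mixed == 1

    def test_unmapped_degs_reported(self):
        a = self._degs("A", [("a1", "up"), ("stray", "up")])
        b = self._degs("B", [("b1", "up")])
        om = orthomap([("a1", "A", "OGz"), ("b1", "B", "OGz")])
        shared = map_orthologs(a, b, om, "A", "B")
        assert shared.unmapped_a == ["stray"]

    def test_single_species_degs_excluded(self):
        a = self._degs("A", [("a1", "up")])
        b = filter_degs(deg_table([("b1", 0.1, 0.9)]))
        om = orthomap([("a1", "A", "OG1"), ("b1", "B", "OG1")])
        shared = map_orthologs(a, b, om, "A", "B")
        assert shared.table.empty


class TestConcordance:
    def test_quadrant_arithmetic(self):
        table = pd.DataFrame(
            {
                "orthogroup": [f"OG{i}" for i in range(10)],
                "dir_a": ["up"] * 3 + ["down"] * 3 + ["up"] * 2 + ["down"] * 2,
                "dir_b": ["up"] * 3 + ["down"] * 3 + ["down"] * 2 + ["up"] * 2,
            }
        )
        result = concordance(table)
        assert result.counts == {"up/up": 3, "down/down": 3, "up/down": 2, "down/up": 2}
        assert result.fraction == pytest.approx(0.6)

    def test_all_concordant(self):
        table = pd.DataFrame(
            {"orthogroup": ["1", "2"], "dir_a": ["up", "down"], "dir_b": ["up", "down"]}
        )
        assert concordance(table).fraction == 1.0

    def test_empty_shared_set_warns_nan(self):
        with pytest.warns(UserWarning, match="undefined"):
            result = concordance(pd.DataFrame(columns=["orthogroup", "dir_a", "dir_b"]))
        assert np.isnan(result.fraction)
        assert result.total == 0

    def test_brute_force_recount_on_random_tables(self, rng):
        for _ in range(10):
            n = int(rng.integers(1, 40))
            dirs = rng.choice(["up", "down"], size=(n, 2))
            table = pd.DataFrame(
                {"orthogroup": [str(i) for i in range(n)],
                 "dir_a": dirs[:, 0], "dir_b": dirs[:, 1]}
            )
            result = concordance(table)
            agree = int((dirs[:, 0] == dirs[:, 1]).sum())
            assert result.fraction == pytest.approx(agree / n)
            assert sum(result.counts.values()) == n

    def test_planted_concordance_recovered(self):
        cfg = SimConfig(seed=2)
        deg_a, deg_b, om, truth = gen_deg_tables(cfg)
        shared = map_orthologs(filter_degs(deg_a), filter_degs(deg_b), om, "Mpo", "Nbe")
        result = concordance(shared)
        realized = np.mean([a == b for a, b in truth.direction.values()])
        assert result.total == len(truth.direction)
        assert result.fraction == pytest.approx(realized)


class TestFisherAndBH:
    def test_matches_hypergeometric_tail_oracle(self):
        assert fisher_pvalue(3, 10, 5, 100) == pytest.approx(
            hypergeom_upper_tail(3, 100, 5, 10), abs=1e-12
        )

    def test_empty_margins_give_p_one(self):
        assert fisher_pvalue(0, 10, 0, 100) == pytest.approx(1.0)

    def test_bh_matches_step_up_closed_form(self):
        p = [0.01, 0.02, 0.03, 0.5]
        assert np.allclose(bh_adjust(p), bh_step_up(p))
        assert np.allclose(bh_adjust(p), [0.04, 0.04, 0.04, 0.5])

    def test_bh_monotone_in_rank(self, rng):
        p = rng.random(25)
        adj = bh_adjust(p)
        order = np.argsort(p, kind="stable")
        assert (np.diff(adj[order]) >= -1e-12).all()

    def test_sector_enrichment_table(self):
        universe = {f"g{i}" for i in range(100)}
        sectors = {"up/up": {f"g{i}" for i in range(10)}}
        annotation = {
            "enriched": {f"g{i}" for i in range(8)} | {"g50", "g51"},
            "flat": {f"g{i}" for i in range(40, 80)},
        }
        table = sector_enrichment(sectors, annotation, universe)
        enr = table.set_index("term")
        assert enr.loc["enriched", "p"] < enr.loc["flat", "p"]
        assert enr.loc["enriched", "significant"]
        expected = hypergeom_upper_tail(8, 100, 10, 10)
        assert enr.loc["enriched", "p"] == pytest.approx(expected, abs=1e-12)

    def test_sector_genes_outside_universe_rejected(self):
        with pytest.raises(ValueError, match="outside the universe"):
            sector_enrichment({"s": {"gX"}}, {"t": {"gX"}}, {"g1"})


class TestDegOverlap:
    def test_disjoint_and_identical(self):
        table = deg_overlap({"A": {"g1", "g2"}, "B": {"g3"}})
        lookup = table.set_index("sets")["intersection"]
        assert lookup["A&B"] == 0
        table = deg_overlap({"A": {"g1", "g2"}, "B": {"g1", "g2"}})
        assert table.set_index("sets")["intersection"]["A&B"] == 2

    def test_counts_match_set_algebra(self, rng):
        genes = [f"g{i}" for i in range(50)]
        sets = {
            name: {g for g in genes if rng.random() < 0.4} for name in ("A", "B", "C")
        }
        table = deg_overlap(sets).set_index("sets")
        assert table.loc["A", "intersection"] == len(sets["A"])
        assert table.loc["A&B", "intersection"] == len(sets["A"] & sets["B"])
        assert table.loc["A&B&C", "intersection"] == len(
            sets["A"] & sets["B"] & sets["C"]
        )
        # exclusive regions partition the union
        union = len(sets["A"] | sets["B"] | sets["C"])
        exclusive_total = table["exclusive"].sum() - (
            # inclusion-exclusion: each element counted once in its exact region
            0
        )
        regions = {}
        for g in sets["A"] | sets["B"] | sets["C"]:
            key = "&".join(n for n in ("A", "B", "C") if g in sets[n])
            regions[key] = regions.get(key, 0) + 1
        for key, count in regions.items():
            assert table.loc[key, "exclusive"] == count
        assert sum(regions.values()) == union
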