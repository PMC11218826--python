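"""Cross-species orthologous-DEG concordance and enrichment.

Differentially expressed genes (DEGs) pass |log2FC| >= 2 and adjusted
p <= 1e-3 (boundary inclusive by default; a strict mode uses the
open-interval form some summaries print). Genes map to orthogroups; an
orthogroup shared between two species and DEG in both falls into one of
four directional quadrants (up/up, down/down, up/down, down/up). The
concordance fraction is the share of quadrant pairs moving the same
way. Per-sector functional enrichment uses one-sided Fisher's exact
test (hypergeometric upper tail) with Benjamini-Hochberg correction
applied within each sector.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

QUADRANTS = ("up/up", "down/down", "up/down", "down/up")


def filter_degs(table: pd.DataFrame, lfc_min: float = 2.0, p_max: float = 1e-3,
                strict: bool = False) -> pd.DataFrame:
    """Assign a direction (up/down/none) to every gene in a DEG table.

    Expects columns ``gene, log2fc, padj``. Default thresholds are
    boundary-inclusive (log2fc >= lfc_min, padj <= p_max); ``strict``
    switches the significance side to padj < p_max. Missing or NaN padj
    is treated as non-significant and logged. Returns the table with a
    ``direction`` column; callers keep the full frame as the background
    universe and subset direction != "none" for the DEG set.
    """
    required = {"gene", "log2fc", "padj"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"DEG table missing columns: {sorted(missing)}")
    out = table.copy()
    padj = pd.to_numeric(out["padj"], errors="coerce")
    lfc = pd.to_numeric(out["log2fc"], errors="coerce")
    n_bad = int(padj.isna().sum())
    if n_bad:
        logger.warning("%d genes with missing/NaN padj treated as non-significant", n_bad)
    sig = (padj < p_max) if strict else (padj <= p_max)
    sig = sig.fillna(False) & lfc.notna()
    out["direction"] = np.select(
        [sig & (lfc >= lfc_min), sig & (lfc <= -lfc_min)], ["up", "down"], default="none"
    )
    return out


def _og_directions(degs: pd.DataFrame, orthomap: pd.DataFrame, species: str):
    """Per-orthogroup direction for one species: unanimous, else 'mixed'."""
    genes = orthomap[orthomap["species"] == species]
    deg_only = degs[degs["direction"] != "none"]
    merged = deg_only.merge(genes, on="gene", how="left")
    unmapped = sorted(merged.loc[merged["orthogroup"].isna(), "gene"])
    merged = merged.dropna(subset=["orthogroup"])
    directions = {}
    for og, grp in merged.groupby("orthogroup"):
        dirs = set(grp["direction"])
        directions[og] = dirs.pop() if len(dirs) == 1 else "mixed"
    return directions, unmapped


@dataclass
class SharedOrthogroups:
    """Orthogroups DEG in both species with per-species directions."""

    table: pd.DataFrame                 # orthogroup, dir_a, dir_b
    unmapped_a: list = field(default_factory=list)
    unmapped_b: list = field(default_factory=list)

    @property
    def mixed(self) -> pd.DataFrame:
        t = self.table
        return t[(t["dir_a"] == "mixed") | (t["dir_b"] == "mixed")]


def map_orthologs(degs_a: pd.DataFrame, degs_b: pd.DataFrame, orthomap: pd.DataFrame,
                  species_a: str, species_b: str) -> SharedOrthogroups:
    """Join two species' DEG calls on the orthogroup map.

    Keeps orthogroups holding at least one DEG in each species. The
    per-species orthogroup direction is the unanimous direction of its
    DEG members; conflicting members yield "mixed" (kept in the table,
    excluded from quadrant counting). DEGs absent from the map are
    reported as unmapped.
    """
    for col in ("gene", "species", "orthogroup"):
        if col not in orthomap.columns:
            raise ValueError(f"orthogroup map missing column {col!r}")
    dirs_a, unmapped_a = _og_directions(degs_a, orthomap, species_a)
    dirs_b, unmapped_b = _og_directions(degs_b, orthomap, species_b)
    shared = sorted(set(dirs_a) & set(dirs_b))
    table = pd.DataFrame(
        {
            "orthogroup": shared,
            "dir_a": [dirs_a[o] for o in shared],
            "dir_b": [dirs_b[o] for o in shared],
        }
    )
    return SharedOrthogroups(table=table, unmapped_a=unmapped_a, unmapped_b=unmapped_b)


@dataclass
class ConcordanceResult:
    """Directional quadrant counts over shared orthologous DEGs."""

    counts: dict                        # quadrant -> count
    n_mixed: int
    total: int                          # sum of the four quadrants
    fraction: float                     # (up/up + down/down) / total

    def as_series(self) -> pd.Series:
        return pd.Series({**self.counts, "mixed": self.n_mixed, "total": self.total,
                          "fraction": self.fraction})


def concordance(shared) -> ConcordanceResult:
    """Quadrant counts and the concordant fraction.

    Accepts a :class:`SharedOrthogroups` or its table. Mixed-direction
    orthogroups are excluded from the quadrants and reported separately.
    An empty quadrant sum yields fraction NaN with a warning.
    """
    table = shared.table if isinstance(shared, SharedOrthogroups) else shared
    counts = {q: 0 for q in QUADRANTS}
    n_mixed = 0
    for row in table.itertuples():
        if row.dir_a == "mixed" or row.dir_b == "mixed":
            n_mixed += 1
            continue
        counts[f"{row.dir_a}/{row.dir_b}"] += 1
    total = sum(counts.values())
    if total == 0:
        warnings.warn("no shared orthologous DEGs; concordance undefined")
        fraction = float("nan")
    else:
        fraction = (counts["up/up"] + counts["down/down"]) / total
    return ConcordanceResult(counts=counts, n_mixed=n_mixed, total=total, fraction=fraction)


def fisher_pvalue(k: int, n_set: int, n_term: int, n_universe: int,
                  alternative: str = "greater") -> float:
    """Fisher's exact p for a 2x2 enrichment table.

    *k* term genes in the sector, sector size *n_set*, term size
    *n_term*, universe size *n_universe*. "greater" is the
    over-representation (hypergeometric upper tail) used for
    enrichment; "two-sided" uses the exact conditional test.
    """
    if alternative == "greater":
        return float(stats.hypergeom.sf(k - 1, n_universe, n_term, n_set))
    table = [
        [k, n_term - k],
        [n_set - k, n_universe - n_term - n_set + k],
    ]
    return float(stats.fisher_exact(table, alternative=alternative)[1])


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def sector_enrichment(sectors: dict, annotation: dict, universe,
                      alternative: str = "greater", fdr_max: float = 0.05) -> pd.DataFrame:
    """Fisher/BH term enrichment per sector gene set.

    *sectors* maps sector name -> gene set; *annotation* maps term ->
    gene set; *universe* is the background gene collection (must cover
    every sector gene). BH correction runs within each sector across its
    terms; rows are flagged significant at FDR <= ``fdr_max``. Terms
    with no genes in the universe are skipped and logged.
    """
    universe = set(universe)
    for name, genes in sectors.items():
        stray = set(genes) - universe
        if stray:
            raise ValueError(f"sector {name!r} has genes outside the universe: "
                             f"{sorted(stray)[:5]}")
    rows = []
    for name, genes in sectors.items():
        genes = set(genes)
        sector_rows = []
        for term, members in annotation.items():
            members = set(members) & universe
            if not members:
                logger.warning("term %r has no genes in the universe; skipped", term)
                continue
            k = len(genes & members)
            p = fisher_pvalue(k, len(genes), len(members), len(universe), alternative)
            sector_rows.append(
                {"sector": name, "term": term, "k": k, "term_size": len(members),
                 "sector_size": len(genes), "universe": len(universe), "p": p}
            )
        if not sector_rows:
            continue
        adj = bh_adjust([r["p"] for r in sector_rows])
        for r, q in zip(sector_rows, adj):
            r["fdr"] = float(q)
            r["significant"] = bool(q <= fdr_max)
        rows.extend(sector_rows)
    return pd.DataFrame(
        rows,
        columns=["sector", "term", "k", "term_size", "sector_size", "universe",
                 "p", "fdr", "significant"],
    )


def deg_overlap(deg_sets: dict) -> pd.DataFrame:
    """Venn-style overlap counts for DEG sets of one species.

    Returns one row per non-empty combination of set names with the
    intersection size over that combination and the exclusive count
    (members in exactly those sets).
    """
    from itertools import combinations

    names = list(deg_sets)
    sets = {n: set(s) for n, s in deg_sets.items()}
    rows = []
    for r in range(1, len(names) + 1):
        for combo in combinations(names, r):
            inter = set.intersection(*(sets[n] for n in combo))
            others = set().union(*(sets[n] for n in names if n not in combo)) if len(combo) < len(names) else set()
            rows.append(
                {
                    "sets": "&".join(combo),
                    "intersection": len(inter),
                    "exclusive": len(inter - others),
                }
            )
    return pd.DataFrame(rows)


def quadrant_gene_sets(shared: SharedOrthogroups, degs_a: pd.DataFrame,
                       degs_b: pd.DataFrame, orthomap: pd.DataFrame,
                       species_a: str, species_b: str) -> dict:
    """Genes of both species grouped by their orthogroup's quadrant.

    Convenience for feeding :func:`sector_enrichment` with the four
    concordance sectors.
    """
    og_quadrant = {
        row.orthogroup: f"{row.dir_a}/{row.dir_b}"
        for row in shared.table.itertuples()
        if row.dir_a != "mixed" and row.dir_b != "mixed"
    }
    deg_genes = set(degs_a.loc[degs_a["direction"] != "none", "gene"]) | set(
        degs_b.loc[degs_b["direction"] != "none", "gene"]
    )
    sectors: dict[str, set] = {q: set() for q in QUADRANTS}
    for row in orthomap.itertuples():
        q = og_quadrant.get(row.orthogroup)
        if q is not None and row.gene in deg_genes:
            sectors[q].add(row.gene)
    return sectors
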