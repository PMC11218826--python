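"""Synthetic inputs for the NLR survey pipeline, with planted ground truth.

The generators emulate the statistical structure of the real inputs the
pipeline consumes — proteomes with multi-domain NLR architectures,
NB-ARC homolog trees with long-branch contaminants, all-vs-all
structure-similarity score tables with community structure, and
two-species differential-expression tables over a shared orthogroup map —
and return truth labels so that recovery can be scored exactly.

Every generator is a pure function of :class:`SimConfig` (including its
seed): the same configuration always yields byte-identical output.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd
from scipy import stats

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: NLR subtypes used throughout: TIR-type, CC-type, RPW8-type CC,
#: Cbl-N-homologous CC, hydrolase-type, kinase-type, and minimal
#: NB-ARC-LRR receptors without a recognizable N-terminal domain.
SUBTYPES = ("TIR", "CC", "CC_R", "CC_CblN", "Hyd", "Pkn", "NL")

#: Subtype -> canonical N-terminal domain label planted on the protein.
NTD_DOMAIN = {
    "TIR": "TIR",
    "CC": "CC",
    "CC_R": "RPW8",
    "CC_CblN": "CblN",
    "Hyd": "Hydrolase",
    "Pkn": "Kinase",
}

_DEFAULT_MIX = {
    "TIR": 0.25,
    "CC": 0.25,
    "CC_R": 0.10,
    "CC_CblN": 0.15,
    "Hyd": 0.10,
    "Pkn": 0.05,
    "NL": 0.10,
}

_INTEGRATED_POOL = ("WRKY", "BED", "TRX", "B3", "Jacalin")


class ConfigError(ValueError):
    """Raised when a SimConfig violates its invariants."""


@dataclass
class SimConfig:
    """Parameters of the synthetic study.

    Defaults describe a desk-scale version of a multi-lineage NLR survey:
    a handful of species with ~100 receptor loci each, a 30-tip homolog
    tree with 20% long-branch contaminants, a 100-model structure set
    with 4 planted fold communities (mean similarity 0.8 within / 0.2
    between), and 500 shared orthogroups with 62% planted directional
    concordance between the two species' expression responses.
    """

    seed: int = 0
    # proteome
    n_species: int = 3
    proteins_per_species: int = 100
    architecture_mix: dict = field(default_factory=lambda: dict(_DEFAULT_MIX))
    integrated_fraction: float = 0.10
    ntd_mut_rate: float = 0.15
    # N-terminal motif (synthetic MAEPL-like consensus; the real motif is
    # known only as a sequence logo, so this 17-mer is an invented
    # stand-in with the M-A-E-P-L start and leucine-rich core)
    motif_consensus: str = "MAEPLVAKLGELLVEEV"
    motif_mut_rate: float = 0.10
    # homolog tree
    n_taxa: int = 30
    long_branch_fraction: float = 0.20
    baseline_branch_mean: float = 0.10
    # structure similarity
    n_structures: int = 100
    n_communities: int = 4
    within_mu: float = 0.8
    between_mu: float = 0.2
    sim_sigma: float = 0.05
    # cross-species expression
    n_orthogroups: int = 500
    deg_fraction: float = 0.8
    deg_single_fraction: float = 0.05
    planted_concordance: float = 0.62

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        counts = {
            "n_species": self.n_species,
            "proteins_per_species": self.proteins_per_species,
            "n_taxa": self.n_taxa,
            "n_structures": self.n_structures,
            "n_communities": self.n_communities,
            "n_orthogroups": self.n_orthogroups,
        }
        for name, v in counts.items():
            if not isinstance(v, (int, np.integer)) or v < 1:
                raise ConfigError(f"{name} must be a positive integer, got {v!r}")
        probs = {
            "integrated_fraction": self.integrated_fraction,
            "ntd_mut_rate": self.ntd_mut_rate,
            "motif_mut_rate": self.motif_mut_rate,
            "long_branch_fraction": self.long_branch_fraction,
            "deg_fraction": self.deg_fraction,
            "deg_single_fraction": self.deg_single_fraction,
            "planted_concordance": self.planted_concordance,
            "within_mu": self.within_mu,
            "between_mu": self.between_mu,
        }
        for name, v in probs.items():
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1], got {v!r}")
        if abs(sum(self.architecture_mix.values()) - 1.0) > 1e-9:
            raise ConfigError("architecture_mix must sum to 1")
        unknown = set(self.architecture_mix) - set(SUBTYPES)
        if unknown:
            raise ConfigError(f"unknown subtypes in architecture_mix: {sorted(unknown)}")
        if any(p < 0 for p in self.architecture_mix.values()):
            raise ConfigError("architecture_mix probabilities must be non-negative")
        if self.within_mu <= self.between_mu:
            raise ConfigError("within_mu must exceed between_mu")
        if not self.motif_consensus:
            raise ConfigError("motif_consensus must be non-empty")

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def rng(self, stream: int) -> np.random.Generator:
        """Independent generator for one named random stream."""
        return np.random.default_rng([self.seed, stream])


@dataclass
class TruthLabels:
    """Ground-truth labels attached to generated entities.

    Each generator fills only the fields it is responsible for;
    :func:`simulate_all` merges them. Every generated entity carries
    exactly one label of its kind.
    """

    subtype: dict = field(default_factory=dict)          # protein_id -> subtype
    nlr_id: dict = field(default_factory=dict)           # protein_id -> bool (integrated domain)
    motif_carrier: dict = field(default_factory=dict)    # protein_id -> bool
    outlier: dict = field(default_factory=dict)          # tip label -> bool
    community: dict = field(default_factory=dict)        # structure id -> community int
    direction: dict = field(default_factory=dict)        # orthogroup -> [dir_a, dir_b]

    def merge(self, other: "TruthLabels") -> "TruthLabels":
        for f in dataclasses.fields(self):
            getattr(self, f.name).update(getattr(other, f.name))
        return self

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "TruthLabels":
        return cls(**json.loads(text))


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(AMINO_ACIDS), size=length))


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    """Substitute each position with probability `rate` (never to itself)."""
    out = list(seq)
    hits = np.flatnonzero(rng.random(len(seq)) < rate)
    for i in hits:
        alt = [a for a in AMINO_ACIDS if a != out[i]]
        out[i] = alt[rng.integers(len(alt))]
    return "".join(out)


def plant_motif(seqs, consensus: str, mut_rate: float, seed: int = 0) -> list[str]:
    """Overwrite the first ``len(consensus)`` residues of each sequence with a
    mutated copy of the consensus.

    Each motif position is substituted independently with probability
    ``mut_rate``; the remainder of each sequence is untouched.
    """
    if not consensus:
        raise ValueError("consensus must be non-empty")
    seqs = list(seqs)
    if seqs and min(len(s) for s in seqs) < len(consensus):
        raise ValueError("consensus longer than shortest sequence")
    rng = np.random.default_rng([seed, 17])
    return [_mutate(rng, consensus, mut_rate) + s[len(consensus):] for s in seqs]


# Residue spans (1-based inclusive) of the planted architecture. All
# N-terminal domains end before 200 where the NB-ARC starts, so the
# optional N-side integrated-domain slot (182-198) never overlaps.
_NTD_SPAN = {
    "TIR": (10, 150),
    "CC": (10, 130),
    "RPW8": (10, 130),
    "CblN": (10, 140),
    "Hydrolase": (10, 170),
    "Kinase": (10, 180),
}
_NBARC_SPAN = (200, 500)
_LRR_SPAN = (540, 780)
_PROT_LEN = 800
_ID_N_SPAN = (182, 198)
_ID_C_SPAN = (805, 870)


def gen_proteome(cfg: SimConfig):
    """Generate proteomes with planted domain architectures.

    Returns ``(records, hits, species_map, truth)`` where *records* is a
    list of (protein_id, sequence), *hits* a DataFrame with columns
    ``protein_id, domain, start, end, score`` (1-based inclusive,
    non-overlapping, N-to-C ordered), *species_map* maps protein_id to
    species, and *truth* carries the planted subtype, integrated-domain
    flag and motif-carrier flag per protein.

    Domain regions are mutated copies of per-family ancestor sequences
    (so sequence clustering and distance methods see real family
    structure); linkers are uniform random residues. Proteins of the
    Cbl-N CC subtype carry the N-terminal motif consensus (mutated at
    ``motif_mut_rate``) at position 1.
    """
    cfg.validate()
    rng = cfg.rng(1)
    subtypes = [s for s in SUBTYPES if cfg.architecture_mix.get(s, 0) > 0]
    probs = np.array([cfg.architecture_mix[s] for s in subtypes], dtype=float)
    probs /= probs.sum()

    # family ancestors shared by all proteins of a subtype
    ancestors = {d: _random_seq(rng, e - s + 1) for d, (s, e) in _NTD_SPAN.items()}
    ancestors["NB-ARC"] = _random_seq(rng, _NBARC_SPAN[1] - _NBARC_SPAN[0] + 1)
    ancestors["LRR"] = _random_seq(rng, _LRR_SPAN[1] - _LRR_SPAN[0] + 1)
    id_ancestors = {
        n: _random_seq(rng, _ID_C_SPAN[1] - _ID_C_SPAN[0] + 1) for n in _INTEGRATED_POOL
    }

    records, rows = [], []
    species_map: dict[str, str] = {}
    truth = TruthLabels()
    motif_rng = np.random.default_rng([cfg.seed, 2])

    for si in range(cfg.n_species):
        species = f"sp{si + 1}"
        for pi in range(cfg.proteins_per_species):
            pid = f"{species}_p{pi + 1:04d}"
            subtype = subtypes[rng.choice(len(subtypes), p=probs)]
            has_id = rng.random() < cfg.integrated_fraction
            id_terminus = "N" if (has_id and rng.random() < 0.5) else "C"
            id_name = _INTEGRATED_POOL[rng.integers(len(_INTEGRATED_POOL))]

            length = _PROT_LEN if not (has_id and id_terminus == "C") else _ID_C_SPAN[1] + 5
            seq = list(_random_seq(rng, length))

            def put(dom_seq: str, span: tuple[int, int]):
                s, e = span
                seq[s - 1 : e] = list(dom_seq)

            hits = []
            ntd = NTD_DOMAIN.get(subtype)
            if ntd is not None:
                span = _NTD_SPAN[ntd]
                put(_mutate(rng, ancestors[ntd], cfg.ntd_mut_rate), span)
                hits.append((ntd, span, float(rng.uniform(50, 90))))
            put(_mutate(rng, ancestors["NB-ARC"], cfg.ntd_mut_rate), _NBARC_SPAN)
            hits.append(("NB-ARC", _NBARC_SPAN, float(rng.uniform(80, 120))))
            put(_mutate(rng, ancestors["LRR"], cfg.ntd_mut_rate), _LRR_SPAN)
            hits.append(("LRR", _LRR_SPAN, float(rng.uniform(40, 60))))
            if has_id:
                span = _ID_N_SPAN if id_terminus == "N" else _ID_C_SPAN
                dom = id_ancestors[id_name][: span[1] - span[0] + 1]
                put(_mutate(rng, dom, cfg.ntd_mut_rate), span)
                hits.append((f"OTHER:{id_name}", span, float(rng.uniform(30, 50))))

            seq = "".join(seq)
            is_motif = subtype == "CC_CblN"
            if is_motif:
                seq = _mutate(motif_rng, cfg.motif_consensus, cfg.motif_mut_rate) + seq[
                    len(cfg.motif_consensus) :
                ]

            records.append((pid, seq))
            species_map[pid] = species
            truth.subtype[pid] = subtype
            truth.nlr_id[pid] = bool(has_id)
            truth.motif_carrier[pid] = bool(is_motif)
            for dom, (s, e), score in sorted(hits, key=lambda h: h[1][0]):
                rows.append((pid, dom, s, e, round(score, 2)))

    hits_df = pd.DataFrame(rows, columns=["protein_id", "domain", "start", "end", "score"])
    return records, hits_df, species_map, truth


def gen_tree_with_outliers(cfg: SimConfig):
    """Random bifurcating tree with planted long-branch outlier tips.

    Topology grows by successive random tip attachment. Baseline branch
    lengths are exponential(mean ``baseline_branch_mean``) truncated to
    [1e-3, 0.12] so that no baseline branch — even after degree-2 edge
    merging when neighbouring tips are pruned — can reach the 0.5
    subs/site relative cutoff. Planted outlier tips alternate between
    the absolute regime (length >= 1.0) and the relative regime (length
    in [0.55, 0.9] with all sister branches clamped below length/12, so
    the >= 0.5 and >= 10x-sister predicate holds exactly); a relative
    candidate whose parent is the root or whose sister is itself planted
    falls back to the absolute regime.

    Returns ``(tree, truth)``; truth flags every tip.
    """
    cfg.validate()
    if cfg.n_taxa < 4:
        raise ConfigError("n_taxa must be >= 4")
    rng = cfg.rng(3)
    labels = [f"t{i + 1:03d}" for i in range(cfg.n_taxa)]

    tns = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=tns)

    def leaf(lbl):
        node = dendropy.Node()
        node.taxon = tns.new_taxon(label=lbl)
        return node

    tree.seed_node.add_child(leaf(labels[0]))
    tree.seed_node.add_child(leaf(labels[1]))
    for lbl in labels[2:]:
        candidates = [n for n in tree.preorder_node_iter() if n is not tree.seed_node]
        target = candidates[rng.integers(len(candidates))]
        parent = target.parent_node
        parent.remove_child(target)
        mid = dendropy.Node()
        parent.add_child(mid)
        mid.add_child(target)
        mid.add_child(leaf(lbl))

    def draw_baseline() -> float:
        while True:
            x = rng.exponential(cfg.baseline_branch_mean)
            if x <= 0.12:
                return max(x, 1e-3)

    nodes = [n for n in tree.preorder_node_iter() if n is not tree.seed_node]
    for n in nodes:
        n.edge.length = draw_baseline()

    tips = [n for n in tree.leaf_node_iter()]
    tips.sort(key=lambda n: n.taxon.label)
    k = int(round(cfg.long_branch_fraction * cfg.n_taxa))
    planted_idx = sorted(rng.choice(len(tips), size=k, replace=False))
    planted_nodes = {id(tips[i]) for i in planted_idx}

    truth = TruthLabels(outlier={lbl: False for lbl in labels})
    for j, i in enumerate(planted_idx):
        tip = tips[i]
        want_relative = j % 2 == 1
        parent = tip.parent_node
        sisters = [c for c in parent.child_nodes() if c is not tip]
        relative_ok = (
            want_relative
            and parent is not tree.seed_node
            and not any(id(s) in planted_nodes for s in sisters)
        )
        if relative_ok:
            tip.edge.length = float(rng.uniform(0.55, 0.9))
            for s in sisters:
                s.edge.length = min(s.edge.length, tip.edge.length / 12.0)
        else:
            tip.edge.length = float(1.0 + rng.exponential(0.3))
        truth.outlier[tip.taxon.label] = True

    # planted-signal validity: every planted tip must satisfy the removal
    # predicate under the unrooted (merged degree-2 root) view, where a
    # relative-regime tip can acquire an unclamped sister; any such tip is
    # promoted to the absolute regime
    from nlrmacro.treeclean import TrimPolicy, flag_long_branches

    planted_labels = {t for t, v in truth.outlier.items() if v}
    for _ in range(2):
        flagged = {
            next(iter(f["tips_below"]))
            for f in flag_long_branches(tree, TrimPolicy())
            if f["terminal"]
        }
        unflagged = planted_labels - flagged
        if not unflagged:
            break
        for tip in tree.leaf_node_iter():
            if tip.taxon.label in unflagged:
                tip.edge.length = float(1.0 + rng.exponential(0.3))
    return tree, truth


def gen_tm_matrix(cfg: SimConfig):
    """All-vs-all pairwise normalized structure-similarity scores with
    planted communities.

    Scores are truncated-normal on [0, 1] (sigma ``sim_sigma``) around
    ``within_mu`` for same-community pairs and ``between_mu`` otherwise.
    Returns ``(edges, truth)`` with *edges* a DataFrame
    ``id_a, id_b, score`` over all unordered pairs (self-pairs omitted).
    """
    cfg.validate()
    rng = cfg.rng(4)
    n = cfg.n_structures
    ids = [f"S{i + 1:04d}" for i in range(n)]
    comm = np.array([i * cfg.n_communities // n for i in range(n)])
    ii, jj = np.triu_indices(n, k=1)
    mus = np.where(comm[ii] == comm[jj], cfg.within_mu, cfg.between_mu)
    a = (0.0 - mus) / cfg.sim_sigma
    b = (1.0 - mus) / cfg.sim_sigma
    scores = stats.truncnorm.rvs(a, b, loc=mus, scale=cfg.sim_sigma, random_state=rng)
    edges = pd.DataFrame(
        {
            "id_a": [ids[i] for i in ii],
            "id_b": [ids[j] for j in jj],
            "score": np.round(scores, 6),
        }
    )
    truth = TruthLabels(community={ids[i]: int(comm[i]) for i in range(n)})
    return edges, truth


def gen_deg_tables(cfg: SimConfig):
    """Two-species DEG tables plus orthogroup map with planted concordance.

    Each orthogroup holds one gene per species. A fraction
    ``deg_fraction`` of orthogroups is differentially expressed in both
    species; each such orthogroup is directionally concordant with
    probability ``planted_concordance``. A further 5% per species is DEG
    in that species only, and the rest are background. DEG genes get
    |log2FC| >= 2 with adjusted p log-uniform in [1e-10, 1e-4];
    background genes get |log2FC| < 2 and adjusted p in [1e-2, 1],
    respecting the pipeline's lfc >= 2 / padj <= 1e-3 cutoffs with
    margin.

    Returns ``(deg_a, deg_b, orthomap, truth)``.
    """
    cfg.validate()
    rng = cfg.rng(5)
    n = cfg.n_orthogroups
    ogs = [f"OG{i + 1:05d}" for i in range(n)]
    genes_a = [f"Mp{i + 1:05d}" for i in range(n)]
    genes_b = [f"Nb{i + 1:05d}" for i in range(n)]

    order = rng.permutation(n)
    n_both = int(round(cfg.deg_fraction * n))
    n_single = int(round(cfg.deg_single_fraction * n))
    both = set(order[:n_both])
    only_a = set(order[n_both : n_both + n_single])
    only_b = set(order[n_both + n_single : n_both + 2 * n_single])

    truth = TruthLabels()

    def deg_row(rng, direction):
        lfc = direction * (2.0 + rng.exponential(1.0))
        padj = 10.0 ** rng.uniform(-10, -4)
        return lfc, padj

    def bg_row(rng):
        lfc = float(np.clip(rng.normal(0.0, 0.5), -1.9, 1.9))
        padj = 10.0 ** rng.uniform(-2, 0)
        return lfc, padj

    rows_a, rows_b, map_rows = [], [], []
    for i in range(n):
        map_rows.append((genes_a[i], "Mpo", ogs[i]))
        map_rows.append((genes_b[i], "Nbe", ogs[i]))
        if i in both:
            dir_a = int(rng.choice([-1, 1]))
            dir_b = dir_a if rng.random() < cfg.planted_concordance else -dir_a
            truth.direction[ogs[i]] = [dir_a, dir_b]
            rows_a.append((genes_a[i], *deg_row(rng, dir_a)))
            rows_b.append((genes_b[i], *deg_row(rng, dir_b)))
        elif i in only_a:
            rows_a.append((genes_a[i], *deg_row(rng, int(rng.choice([-1, 1])))))
            rows_b.append((genes_b[i], *bg_row(rng)))
        elif i in only_b:
            rows_a.append((genes_a[i], *bg_row(rng)))
            rows_b.append((genes_b[i], *deg_row(rng, int(rng.choice([-1, 1])))))
        else:
            rows_a.append((genes_a[i], *bg_row(rng)))
            rows_b.append((genes_b[i], *bg_row(rng)))

    cols = ["gene", "log2fc", "padj"]
    deg_a = pd.DataFrame(rows_a, columns=cols)
    deg_b = pd.DataFrame(rows_b, columns=cols)
    orthomap = pd.DataFrame(map_rows, columns=["gene", "species", "orthogroup"])
    return deg_a, deg_b, orthomap, truth


def gen_msa(cfg: SimConfig, records, gap_rate: float = 0.05):
    """Gapped NB-ARC alignment derived from generated proteome records.

    Slices the shared NB-ARC region out of each protein (the regions are
    mutated copies of one ancestor, hence already aligned) and replaces a
    random ``gap_rate`` fraction of characters with gaps to exercise the
    occupancy filter.
    """
    rng = cfg.rng(6)
    s, e = _NBARC_SPAN
    ids, rows = [], []
    for pid, seq in records:
        region = list(seq[s - 1 : e])
        mask = rng.random(len(region)) < gap_rate
        for i in np.flatnonzero(mask):
            region[i] = "-"
        ids.append(pid)
        rows.append("".join(region))
    from nlrmacro.treeclean import Msa

    return Msa(ids, rows)


def gen_annotation_terms(cfg: SimConfig, genes, n_terms: int = 15):
    """Random functional-annotation map (term -> gene set) over a universe."""
    rng = cfg.rng(7)
    genes = list(genes)
    rows = []
    for t in range(n_terms):
        size = int(rng.integers(5, max(6, len(genes) // 10)))
        members = rng.choice(len(genes), size=min(size, len(genes)), replace=False)
        for m in members:
            rows.append((f"T{t + 1:02d}", genes[m]))
    return pd.DataFrame(rows, columns=["term", "gene"])


def simulate_all(cfg: SimConfig, outdir) -> TruthLabels:
    """Generate every synthetic input and write the files the CLI stages read.

    Writes proteome.fa, domain_hits.tsv, species.tsv, ntd.fa,
    motif_alignment.fa, nbarc_alignment.fa, tree.nwk, tm_edges.tsv,
    deg_mpo.tsv, deg_nbe.tsv, orthomap.tsv, terms.tsv and truth.json
    under *outdir*; returns the merged truth labels.
    """
    from nlrmacro import io as nio

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    truth = TruthLabels()

    records, hits, species_map, t1 = gen_proteome(cfg)
    truth.merge(t1)
    nio.write_fasta(records, out / "proteome.fa")
    nio.write_tsv(hits, out / "domain_hits.tsv")
    nio.write_tsv(
        pd.DataFrame(sorted(species_map.items()), columns=["protein_id", "species"]),
        out / "species.tsv",
    )

    # N-terminal-domain regions for sequence clustering
    ntd_records = []
    for pid, seq in records:
        ntd = NTD_DOMAIN.get(t1.subtype[pid])
        if ntd is not None:
            s, e = _NTD_SPAN[ntd]
            ntd_records.append((pid, seq[s - 1 : e]))
    nio.write_fasta(ntd_records, out / "ntd.fa")

    # curated motif alignment: N-terminal slices of motif carriers
    L = len(cfg.motif_consensus)
    motif_records = [
        (pid, seq[:L]) for pid, seq in records if t1.motif_carrier[pid]
    ][:60]
    nio.write_fasta(motif_records, out / "motif_alignment.fa")

    msa = gen_msa(cfg, records[: min(len(records), 80)])
    nio.write_fasta(list(zip(msa.ids, msa.rows)), out / "nbarc_alignment.fa")

    tree, t2 = gen_tree_with_outliers(cfg)
    truth.merge(t2)
    nio.write_newick(tree, out / "tree.nwk")

    edges, t3 = gen_tm_matrix(cfg)
    truth.merge(t3)
    nio.write_tsv(edges, out / "tm_edges.tsv")

    deg_a, deg_b, orthomap, t4 = gen_deg_tables(cfg)
    truth.merge(t4)
    nio.write_tsv(deg_a, out / "deg_mpo.tsv")
    nio.write_tsv(deg_b, out / "deg_nbe.tsv")
    nio.write_tsv(orthomap, out / "orthomap.tsv")
    nio.write_tsv(
        gen_annotation_terms(cfg, list(deg_a["gene"]) + list(deg_b["gene"])),
        out / "terms.tsv",
    )

    (out / "truth.json").write_text(truth.to_json() + "\n")
    return truth
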