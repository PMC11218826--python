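"""NLR architecture classification from per-protein domain-hit tables.

A protein with a full NB-ARC domain is an NLR; one carrying only a
P-loop (a degenerate nucleotide-binding module) is a degenerate NLR;
proteins without either but matching characteristic accessory patterns
(RPW8 alone; TIR or CC alongside a hydrolase; a lone kinase,
MLKL-like) are NLR-associated. The subtype of an (degenerate) NLR is
read from its N-terminal domain: TIR, CC, RPW8-type CC (CC_R),
Cbl-N-type CC (CC_CblN), hydrolase (Hyd) or kinase (Pkn); receptors
with no recognizable N-terminal domain but a C-terminal LRR are minimal
NB-ARC-LRR receptors (NL). Non-canonical domains fused N- or C-terminal
of the NB-ARC are inventoried as integrated domains (NLR-IDs).

Coordinates are 1-based inclusive throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

CANONICAL_DOMAINS = {
    "NB-ARC",
    "P-loop",
    "TIR",
    "CC",
    "RPW8",
    "CblN",
    "Kinase",
    "Hydrolase",
    "LRR",
}

#: canonical N-terminal domain -> receptor subtype
NTD_TO_SUBTYPE = {
    "TIR": "TIR",
    "CC": "CC",
    "RPW8": "CC_R",
    "CblN": "CC_CblN",
    "Hydrolase": "Hyd",
    "Kinase": "Pkn",
}

SUBTYPE_ORDER = ("TIR", "CC", "CC_R", "CC_CblN", "Hyd", "Pkn", "NL", "other")


class DomainDataError(ValueError):
    """Raised on malformed or unrecognized domain-hit input."""


@dataclass(frozen=True)
class DomainHit:
    """One resolved domain interval on a protein (1-based inclusive)."""

    protein_id: str
    domain: str
    start: int
    end: int
    score: float = 0.0

    def __post_init__(self):
        if not (1 <= self.start <= self.end):
            raise DomainDataError(
                f"{self.protein_id}: invalid interval {self.start}-{self.end}"
            )
        if self.domain not in CANONICAL_DOMAINS and not self.domain.startswith("OTHER:"):
            raise DomainDataError(
                f"{self.protein_id}: unknown domain label {self.domain!r} "
                f"(expected one of {sorted(CANONICAL_DOMAINS)} or OTHER:<name>)"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def overlaps(self, other: "DomainHit") -> bool:
        return self.start <= other.end and other.start <= self.end


@dataclass
class NlrAnnotation:
    """Classification result for one protein."""

    protein_id: str
    category: str                      # NLR | degenerate-NLR | NLR-associated | none
    subtype: str | None = None         # defined for NLR / degenerate-NLR
    associated_class: str | None = None  # RPW8 | TX | CC-X | MLKL
    integrated_domains: list = field(default_factory=list)  # [(name, 'N'|'C'), ...] N->C order

    @property
    def is_nlr_id(self) -> bool:
        return bool(self.integrated_domains)


def resolve_overlaps(hits: list[DomainHit]) -> list[DomainHit]:
    """Reduce hits on one protein to a non-overlapping set.

    Priority: higher score, then longer hit, then N-terminal-most.
    Returned hits are sorted by start.
    """
    ranked = sorted(hits, key=lambda h: (-h.score, -h.length, h.start))
    kept: list[DomainHit] = []
    for h in ranked:
        if not any(h.overlaps(k) for k in kept):
            kept.append(h)
    return sorted(kept, key=lambda h: h.start)


def classify(hits, protein_length: int | None = None) -> NlrAnnotation:
    """Classify one protein from its domain hits.

    *hits* may be DomainHit objects or (domain, start, end, score)-like
    mappings/tuples sharing one protein id. Overlapping hits are
    resolved first (higher score wins, ties to the longer then the more
    N-terminal hit).
    """
    hits = [h if isinstance(h, DomainHit) else DomainHit(**h) for h in hits]
    if not hits:
        return NlrAnnotation(protein_id="", category="none")
    pid = hits[0].protein_id
    if any(h.protein_id != pid for h in hits):
        raise DomainDataError("classify() expects hits from a single protein")
    if protein_length is not None and max(h.end for h in hits) > protein_length:
        raise DomainDataError(f"{pid}: hit extends past protein length {protein_length}")

    hits = resolve_overlaps(hits)
    by_dom: dict[str, list[DomainHit]] = {}
    for h in hits:
        by_dom.setdefault(h.domain, []).append(h)

    nbarc = by_dom.get("NB-ARC")
    ploop = by_dom.get("P-loop")

    if nbarc:
        category, anchor = "NLR", min(nbarc, key=lambda h: h.start)
    elif ploop:
        category, anchor = "degenerate-NLR", min(ploop, key=lambda h: h.start)
    else:
        category, anchor = "none", None
        has_hyd = "Hydrolase" in by_dom
        if "RPW8" in by_dom:
            category, assoc = "NLR-associated", "RPW8"
        elif "TIR" in by_dom and has_hyd:
            category, assoc = "NLR-associated", "TX"
        elif "CC" in by_dom and has_hyd:
            category, assoc = "NLR-associated", "CC-X"
        elif "Kinase" in by_dom:
            category, assoc = "NLR-associated", "MLKL"
        return NlrAnnotation(
            protein_id=pid,
            category=category,
            associated_class=assoc if category == "NLR-associated" else None,
        )

    # subtype: best-scoring canonical N-terminal-domain hit entirely
    # N-terminal of the anchor (strictly: hit.end < anchor.start);
    # score ties resolved toward the anchor-proximal hit.
    ntd_hits = [
        h
        for h in hits
        if h.domain in NTD_TO_SUBTYPE and h.end < anchor.start
    ]
    if ntd_hits:
        best = max(ntd_hits, key=lambda h: (h.score, h.end))
        subtype = NTD_TO_SUBTYPE[best.domain]
    elif any(h.domain == "LRR" and h.start > anchor.end for h in hits):
        subtype = "NL"
    else:
        subtype = "other"

    integrated = [
        (h.domain.split(":", 1)[1], "N" if h.end < anchor.start else "C")
        for h in hits
        if h.domain.startswith("OTHER:")
    ]
    return NlrAnnotation(
        protein_id=pid, category=category, subtype=subtype, integrated_domains=integrated
    )


def classify_table(hits_df: pd.DataFrame, protein_lengths: dict | None = None):
    """Classify every protein in a domain-hit table.

    Expects columns ``protein_id, domain, start, end, score``; returns a
    list of NlrAnnotation in first-appearance order of protein ids.
    """
    order = list(dict.fromkeys(hits_df["protein_id"]))
    out = []
    for pid, grp in hits_df.groupby("protein_id", sort=False):
        hits = [
            DomainHit(pid, r.domain, int(r.start), int(r.end), float(r.score))
            for r in grp.itertuples()
        ]
        length = protein_lengths.get(pid) if protein_lengths else None
        out.append(classify(hits, protein_length=length))
    by_id = {a.protein_id: a for a in out}
    return [by_id[p] for p in order]


def annotations_to_table(annotations) -> pd.DataFrame:
    rows = [
        {
            "protein_id": a.protein_id,
            "category": a.category,
            "subtype": a.subtype or "",
            "associated_class": a.associated_class or "",
            "integrated_domains": ";".join(f"{n}@{t}" for n, t in a.integrated_domains),
        }
        for a in annotations
    ]
    return pd.DataFrame(rows)


def inventory(annotations, species_map: dict) -> pd.DataFrame:
    """Per-species receptor inventory.

    One row per species with the total number of NLR-related loci (any
    category other than ``none``), counts per subtype over NLR and
    degenerate-NLR proteins, and the number of NLR-ID proteins (those
    with at least one integrated domain).
    """
    missing = [a.protein_id for a in annotations if a.protein_id not in species_map]
    if missing:
        raise DomainDataError(f"proteins without species assignment: {missing[:5]}")
    species = sorted(set(species_map[a.protein_id] for a in annotations))
    table = {
        sp: {"species": sp, "total": 0, "nlr_id": 0, **{s: 0 for s in SUBTYPE_ORDER}}
        for sp in species
    }
    for a in annotations:
        row = table[species_map[a.protein_id]]
        if a.category == "none":
            continue
        row["total"] += 1
        if a.subtype:
            row[a.subtype] += 1
        if a.is_nlr_id:
            row["nlr_id"] += 1
    cols = ["species", "total", *SUBTYPE_ORDER, "nlr_id"]
    return pd.DataFrame([table[sp] for sp in species], columns=cols)
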