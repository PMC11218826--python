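# nlrmacro

Desk-scale toolkit for macroevolutionary surveys of plant **NLR immune
receptors** (nucleotide-binding domain, leucine-rich-repeat receptors).
Comparative studies of NLRs across divergent plant lineages — from
liverworts and mosses to flowering plants — share a common computational
backbone: classify receptors from their domain architecture, group
their N-terminal "executioner" domains (NTDs) by sequence and by
structure similarity, clean NB-ARC homolog trees of long-branch
artifacts before phylogenetic interpretation, profile short N-terminal
motifs such as MAEPL and MADA, and measure how transcriptional
responses to receptor activation agree between distantly related
species. `nlrmacro` implements that backbone as a tested Python
library with a CLI, plus a synthetic-data generator that produces every
input with known ground truth so each stage's recovery can be scored
exactly.

The heavy upstream steps (AlphaFold2/Foldseek structure comparison,
IQ-TREE maximum likelihood, OrthoFinder orthogroups, DESeq2
differential expression, InterProScan-level domain detection) are
consumed as the plain-text files they produce, not re-implemented.

## The core procedures

* **Architecture classification** — NB-ARC ⇒ NLR; P-loop only ⇒
  degenerate NLR; RPW8 / TIR+hydrolase / CC+hydrolase / lone-kinase
  patterns ⇒ NLR-associated. Subtype = best-scoring canonical NTD
  strictly N-terminal of the NB-ARC (TIR, CC, CC_R, CC_CblN, Hyd, Pkn;
  NB-ARC–LRR without an NTD ⇒ NL). Non-canonical fusions are
  inventoried as integrated domains (NLR-IDs).
* **Sequence grouping** — greedy centroid clustering at 50% identity /
  50% bidirectional coverage over BLOSUM62 global alignments; major
  groups need ≥ 30 loci across ≥ 3 species.
* **Tree cleaning** — up to 13 rounds of align → 10%-occupancy column
  filter → tree → trim, removing branches ≥ 1.0 subs/site (absolute)
  or ≥ 0.5 subs/site and ≥ 10× their sister (relative), with a final
  terminal-only pass. Built-in neighbor joining on p-distances; any
  external tree builder plugs in.
* **Structure network** — graph over pairwise normalized TM-scores with
  edges at ≥ 0.5, Louvain community detection on the weighted graph
  (seeded restarts + local-move refinement; modularity recomputed
  independently), community filters at ≥ 2 and ≥ 20 members, and a
  sequence-vs-structure overlap matrix.
* **Motif profiling** — profile HMM built from a motif alignment
  (≥ 50%-occupancy match columns, pseudocount-smoothed bit-score
  emissions, plan7-style transitions), scored global-in-motif /
  local-in-sequence by Viterbi or forward.
* **Cross-species concordance** — DEGs at |log2FC| ≥ 2 and adjusted
  p ≤ 10⁻³, mapped to orthogroups, counted in directional quadrants
  (up/up, down/down, up/down, down/up) with the concordant fraction,
  and Fisher/Benjamini–Hochberg term enrichment per quadrant sector.

See `docs/methods.md` for the full model descriptions, parameter
defaults, numerical conventions and limitations.

## Worked example

Generate a synthetic survey (2 species here via the library defaults:
3 species × 100 proteins, a 30-tip tree with 20% planted long-branch
outliers, 100 structures in 4 communities, 500 orthogroups at 62%
planted concordance) and run all six stages:

```bash
nlrmacro simulate --out sim --seed 7
nlrmacro classify  --hits sim/domain_hits.tsv --species sim/species.tsv --out cls
nlrmacro cluster   --fasta sim/ntd.fa --species sim/species.tsv --out clu
nlrmacro treeclean --tree sim/tree.nwk --out tc
nlrmacro structnet --edges sim/tm_edges.tsv --og clu/clusters.tsv --out sn --seed 1
nlrmacro motif build --aln sim/motif_alignment.fa --out maepl.json
nlrmacro motif scan  --profile maepl.json --fasta sim/proteome.fa --window 40 --out ms
nlrmacro xspecies  --deg-a sim/deg_mpo.tsv --deg-b sim/deg_nbe.tsv \
                   --ortho sim/orthomap.tsv --anno sim/terms.tsv --out xs
```

which prints:

```
synthetic dataset written to sim
classified 300 proteins -> cls
6 clusters over 265 sequences -> clu
6 removed over 2 rounds (ok); 24 survivors -> tc
Q=0.7500; 4 communities (>= 2 members), 4 major (>= 20) -> sn
profile with 17 match states -> maepl.json
proteome: n=300 mean=-0.30 median=-11.84
shared DEG orthogroups: 400 (mixed 0); concordance 0.598 -> xs
```

Reading the numbers: the 300 synthetic proteins classify into their
planted subtypes (`cls/inventory.tsv` tabulates them per species); the
265 NTD-bearing proteins fall into 6 sequence groups — one per planted
NTD family; tree cleaning removes exactly the 6 planted long-branch
tips and reaches a fixed point in round 2; the similarity network
recovers the 4 planted structure communities at modularity Q = 0.75;
the motif profile has one match state per consensus column, and the
full-proteome scan mean (−0.30 bits, median −11.84) mixes the planted
motif carriers (high positive scores) with background sequences; of
400 orthogroups differentially expressed in both species, 59.8% move
in the same direction — within sampling error of the planted 62%.

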