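# Methods

`nlrmacro` re-implements, at desk scale, the computational core of a
macroevolutionary survey of plant NLR immune receptors: how receptors
are classified from domain architecture, how their N-terminal domains
(NTDs) are grouped by sequence and by structure similarity, how homolog
trees are cleaned of long-branch contamination, how N-terminal motifs
(MAEPL/MADA style) are profiled, and how transcriptional responses are
compared across distantly related species. Heavy external stages —
structure prediction, all-vs-all structure superposition, maximum
likelihood tree inference, orthogroup inference, read mapping and
differential-expression model fitting — are consumed as inputs, exactly
as a practitioner would consume them from AlphaFold2/Foldseek, IQ-TREE,
OrthoFinder or DESeq2 output files.

## Receptor classification (`nlrmacro.classify`)

A protein with a full NB-ARC domain is an NLR; a protein carrying only a
P-loop is a degenerate NLR; with neither, characteristic accessory
patterns define NLR-associated proteins: RPW8 alone (RPW8), TIR plus a
hydrolase (TX), CC plus a hydrolase (CC-X), or a lone kinase (MLKL-like
pseudokinase), applied in that precedence order. The subtype of an
(degenerate) NLR is the best-scoring canonical NTD hit lying entirely
N-terminal of the NB-ARC start (`hit.end < nbarc.start`); score ties
resolve toward the NB-ARC-proximal hit; a receptor without a
recognizable NTD but with an LRR C-terminal of the NB-ARC is a minimal
NB-ARC–LRR receptor (NL), otherwise "other". Hits labelled
`OTHER:<name>` are inventoried as integrated domains with an N/C
terminus flag relative to the NB-ARC.

Coordinates are 1-based inclusive. Overlapping hits are resolved before
classification: higher score wins, ties to the longer hit, then the more
N-terminal one. The precedence of competing canonical NTDs (e.g. both a
CC and an RPW8 hit before one NB-ARC) is not fixed by any published
annotation rule we reproduce; the score-based rule here is this
package's own deterministic choice.

## Sequence grouping (`nlrmacro.cluster`)

NTD sequences are grouped by centroid-greedy clustering at 50% identity
and 50% coverage, a transparent stand-in for the MMseqs2/DeepClust role
in the pipeline. Pairwise alignment is optimal global alignment under
BLOSUM62 with affine gaps; a gap of length L costs 11 + (L − 1)·1
(open 11, extend 1 in Biopython's convention — the convention is part of
this package's contract and its test oracle). Identity is counted over
alignment columns holding residues in *both* sequences; coverage of a
sequence is the fraction of its residues aligned to residues of the
other. Coverage must hold for both sequences by default (the strictest
common mode; the tools' actual coverage mode at "50% coverage" is not
recorded, so a single-sided mode is available by flag). Sequences are
processed longest-first with lexicographic tie-break, and join the first
centroid that satisfies both thresholds. "Major" groups require at
least 30 member loci spanning at least 3 species.

## Homolog-tree cleaning (`nlrmacro.treeclean`)

The cleaning loop repeats, for up to 13 rounds: (re)align → drop
alignment columns with residue occupancy below 10% (boundary
inclusive) → build a tree → remove long branches, stopping early at a
fixed point (a round with no removals); a final extra pass removes
terminal branches only. Two predicates flag a branch, evaluated in one
pass over the round's input tree (cascading effects are deliberately
left to the next round, keeping each pass order-independent):

* **absolute** — length ≥ 1.0 substitutions/site;
* **relative** — length ≥ 0.5 substitutions/site *and* ≥ 10× the
  sister branch.

Trees are treated as unrooted: a degree-2 root is merged first (the
first internal root child is spliced into the root, its stem length
added to the other child's branch — the convention is fixed so results
are reproducible). The sister of a branch is the stem of its sibling
subtree at the parent; at polytomies the *longest* sister is used,
which removes only unambiguous outliers. Flagged terminal branches
delete their tip (degree-2 nodes suppressed, lengths summed, so
tip-to-tip path lengths among survivors are conserved); flagged
internal branches split the tree and keep the larger tip set (ties keep
the side with the lexicographically smallest label). Both rules apply
to internal branches during cleaning rounds and to terminal branches
only in the final pass; the relative rule requires both of its
conditions (the plain reading of the procedure it reproduces).

The default tree builder is neighbor joining (via scikit-bio) on
p-distances that ignore columns gapped in either sequence (pairs with
no shared ungapped column get the maximal distance 1.0); negative NJ
branch length estimates are clamped to zero. ML inference remains
pluggable through the `treebuilder` callable; an existing tree can also
be cleaned directly (`iterative_clean_tree`), in which case each round
restricts the input tree to the surviving taxa.

## Structure-similarity network (`nlrmacro.structnet`)

Pairwise normalized structure-similarity scores (TM-score-like, in
[0, 1]) become an undirected graph with an edge wherever the score is
≥ 0.5 (boundary inclusive; the conventional shared-fold threshold).
Edges keep the score as weight: the upstream method's implementation
accepts weights by default, so weighted modularity is the default here,
with an unweighted mode by flag. Communities are found by Louvain
modularity optimization (networkx), hardened in two ways for
reproducibility and quality: eight seeded restarts, each followed by a
node-level local-move refinement on the unaggregated graph plus a few
seeded perturb-and-refine (iterated local search) steps; the partition
with the highest modularity wins, ties to the earliest restart. The
reported Q is always recomputed by this package's own modularity
function, independent of the optimizer. Resolution is fixed at 1.0
(classic modularity). Communities need ≥ 2 members to be reported and
≥ 20 to be "major"; sequence-group versus structure-community overlap
is a plain contingency matrix over ids present in both assignments,
with one-sided leftovers reported separately.

## N-terminal motif profiles (`nlrmacro.motifprof`)

A profile HMM is built from a curated motif alignment: columns with
≥ 50% residue occupancy (a standard heuristic; the upstream builder's
internal rule is not reproduced) become match states. Match emissions
are pseudocount-smoothed column frequencies,
(c + α·bg)/(n + α) with total pseudocount weight α = 1 distributed by
the background; log-odds are expressed in bits against that background
(uniform by default for tests, a Robinson–Robinson table available).
Transitions follow a plan7-style topology (match/insert/delete, no
I↔D edges; observed I↔D events in the training gap structure are
dropped) and are estimated with Laplace smoothing; insert states emit
at background (zero log-odds).

Scoring is global-in-motif, local-in-sequence: a path must traverse the
model from its first to its last match/delete state but may enter at
any sequence position, and flanking residues cost nothing —
appropriate for short N-terminal motifs inside full-length receptors,
and the reason appending sequence never lowers a best hit. Viterbi
returns the best single-path bit score and its start; forward log-sums
over all paths and entry points and therefore never scores below
Viterbi. Unknown residues are emitted at background (zero log-odds).
Scores are raw bits; no E-value calibration is attempted (the
historical `hmmcalibrate` step has no counterpart here, and scans are
summarized by score distributions, not significance).

## Cross-species concordance (`nlrmacro.xspecies`)

DEGs pass |log2FC| ≥ 2 and adjusted p ≤ 10⁻³. Both thresholds are
boundary-inclusive by default; a strict mode (p < 10⁻³) covers the
open-interval convention some published summaries use, since the two
readings differ exactly on boundary genes. Genes map to orthogroups; an orthogroup's
per-species direction is the unanimous direction of its DEG members,
with conflicts marked "mixed" and excluded from quadrants but reported.
Orthogroups DEG in both species fall into four directional quadrants;
the concordance fraction is (up/up + down/down) over the quadrant
total. Concordance is computed at the orthogroup level by default
(whether published percentages of this kind are orthogroup- or
gene-pair-level is generally ambiguous; the choice is surfaced in the
output). Enrichment per quadrant sector uses the one-sided Fisher exact
test (hypergeometric upper tail; a two-sided mode exists) with
Benjamini–Hochberg correction applied within each sector across terms,
significant at FDR ≤ 0.05.

## Synthetic data (`nlrmacro.simulate`)

The generator produces every input with known truth labels, and its
defaults are the study conditions the tests assume:

* **Proteomes** — 3 species × 100 proteins; subtype mix TIR 0.25,
  CC 0.25, CC_CblN 0.15, CC_R 0.10, Hyd 0.10, NL 0.10, Pkn 0.05; 10%
  of proteins carry an integrated domain at a random terminus. Domain
  regions are mutated copies (15% per-site) of per-family ancestor
  sequences so that clustering and distances see real family structure;
  linkers are uniform random residues (the simplest null background).
  Cbl-N-type proteins carry the N-terminal motif.
* **Motif** — a synthetic MAEPL-like 17-mer consensus
  (`MAEPLVAKLGELLVEEV`; the real motif is published only as a sequence
  logo, so this invented string mirrors its M-A-E-P-L start and
  leucine-rich core), planted at position 1 and mutated at 10% per
  position.
* **Trees** — 30 taxa grown by successive random tip attachment;
  baseline branch lengths exponential (mean 0.1) truncated to
  [10⁻³, 0.12]. The truncation guarantees planted-signal validity:
  untruncated draws occasionally exceed the 0.5 relative cutoff, and
  pruning merges adjacent edges, so up to ~4 merged baseline edges must
  stay below 0.5. 20% of tips are planted outliers, alternating between
  the absolute regime (length ≥ 1.0) and the relative regime (length in
  [0.55, 0.9] with sisters clamped below length/12); relative
  candidates that would lose their clamped sisters under the unrooted
  root-merge are promoted to the absolute regime, and the final tree is
  verified against the actual flagging predicate.
* **Similarity matrices** — 100 structures in 4 planted communities;
  scores truncated-normal on [0, 1], σ = 0.05, mean 0.8 within and 0.2
  between communities (separable but non-degenerate).
* **DEG tables** — 500 orthogroups, one gene per species each; 80% DEG
  in both species, 5% per species DEG in one only; each both-DEG
  orthogroup concordant with probability 0.62. DEG genes draw
  |log2FC| = 2 + Exp(1) and adjusted p log-uniform in [10⁻¹⁰, 10⁻⁴];
  background genes |log2FC| < 1.9 and p in [10⁻², 1], respecting the
  cutoffs with margin.

All generators are pure functions of the configuration including its
seed; identical configurations give byte-identical files.

What the generator does *not* emulate: domain-hit noise (missed or
spurious hits), indels inside domain families, rate heterogeneity and
saturation on trees, similarity-score transitivity violations,
many-to-many orthology, and correlated expression noise. Passing
recovery tests therefore demonstrates correctness of the decision
rules and algorithms under clean planted signal, not robustness to the
measurement error of real annotation pipelines.

## Problem sizes and verification

The test suite checks exact agreement with independent brute-force
oracles wherever enumeration is feasible — branch flagging against a
self-contained newick parser on 200 random trees (≤ 25 tips), Louvain
modularity against exhaustive maximization over all set partitions
(≤ 8 nodes), Viterbi/forward against complete path enumeration
(M ≤ 4, sequences ≤ 8), global alignment against exhaustive alignment
enumeration (≤ 7 residues), Fisher p against direct combinatorial tail
sums (margins ≤ 30), BH against the closed-form step-up — and planted
signal recovery elsewhere (2,000-protein classification, 20-seed
outlier removal, 20-seed planted-partition ARI, 20-seed 62%-concordance
recovery, 400-sequence motif AUROC). `scripts/acceptance.py` recomputes
the same quantities from scratch at those sizes. These sizes keep a
complete run in well under a minute per stage while leaving every
brute-force comparison exact.

## Known limitations

* Neighbor joining on p-distances is a desk-scale substitute for full
  maximum likelihood inference; p-distances saturate for divergent
  sequences, so sequence-route cleaning underestimates long branches
  relative to ML branch lengths. The `treebuilder` hook exists
  precisely so an external ML tool can be plugged in.
* Louvain with restarts and refinement is still a heuristic; exhaustive
  optimality is verified only at sizes where enumeration is possible.
* The greedy clusterer is O(n·k) in alignments and is not meant for
  atlas-scale inputs; it is a transparent reference implementation of
  the thresholds, not a competitor to MMseqs2.
* Profile HMM scores are raw bits and not comparable across profiles of
  different lengths without calibration.
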