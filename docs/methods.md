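# Methods

This note documents the models, conventions and numerical choices behind
`olscontext`, and what the synthetic-data tests do and do not establish
about real genomes.

## Coordinates and genome model

All coordinates are 1-based inclusive (GFF3 convention). A gene's *start
site* is its translation start: the `start` coordinate on the + strand,
the `end` coordinate on the −. The intergenic gap between two
coordinate-adjacent genes is `start(later) − end(earlier) − 1`; it is
negative when annotations overlap. Species identity is supplied by an
explicit file→species map, never guessed from filenames. Only
protein-coding (CDS) features enter OLS prediction by default; the feature
list is configurable because the inclusion of RNA genes is a judgment call
that depends on the annotation source.

## OLS prediction

An OLS is a maximal run of same-strand, coordinate-consecutive genes with
every internal gap ≤ `max_gap` (default 50 nt, the standard
intergenic-distance criterion for prokaryotic operon prediction;
incorporating further features offers little benefit over distance alone
and requires expression data that is rarely available). Design choices:

- **Overlaps chain unconditionally.** A negative gap is the tightest
  possible packing — overlapping transcripts guarantee co-expression — so
  overlap always satisfies the criterion. A gene nested inside another on
  the same strand is treated as coordinate-adjacent with a negative gap
  and logged.
- **Circular replicons.** When a replicon is circular and
  `allow_origin_spanning` is set, the junction between the last and first
  gene is tested too, permitting an origin-spanning OLS. Off by default to
  match the semantics of typical linear annotation files.
- **Transcription order.** Genes in a − strand OLS are stored in
  descending coordinate order, so "head" always means the first gene
  transcribed; gap vectors follow transcription order.

Promoter association: a gene is flagged when at least one strand-matching
motif hit has its center (integer floor of `(start+end)/2`) within
200 nt upstream to 50 nt downstream of the start site, measured in the
gene's reading direction; these windows cover the large majority of
experimentally mapped archaeal transcription start sites. Motif hits with
q-value above 0.001 are dropped at load time.

## Trajectories

Seed families must occur in ≥ 10 species with ≤ 100 total gene copies
(well-represented, but not so paralog-rich that orthology becomes
ambiguous) and have at least one multigene OLS. Within one species, all
OLSs containing a seed copy merge into a single grouping by multiset union
of family labels — paralogs are deliberately not split, to avoid
misassociating paralogous copies across species. A grouping produced by
merging several OLSs has no single transcription order and is therefore
excluded from head/tail/interior classification.

Content collections partition the per-species groupings by exact multiset
equality of family content (copy number matters: {S,A,A} ≠ {S,A}). The
representative grouping of a collection is taken from its
lexicographically first species, for determinism.

Modification events are collection pairs where the larger content equals
the smaller plus exactly one gene instance and both contain ≥ 2 genes.
The unique gene's position in the larger representative decides the kind
(prepend / append / insertion). Direction (gain vs loss) is not inferred;
events are scored from the perspective of gene gain. When the extra
family occurs at several positions the seed-proximal instance is used and
the event flagged ambiguous.

Phylogeny disagreement compares, per collection with ≥ 2 species, the
maximum intra-collection patristic distance against the maximum distance
from members to trajectory species outside the collection, with a margin
of 0.10. Comparing against the *maximum* inter distance is a deliberately
literal implementation of the procedure this package reproduces; the
conventional, stricter variant (minimum inter distance) is available via
`compare="min_inter"`. The topology divergence ratio is undefined (and
reported as absent) for trajectories whose species span zero phylogenetic
distance.

## Dissimilarity metrics

The comparison framework names its metrics but their formulas are design
choices, selected for boundedness, symmetry and agreement with the
qualitative uses they serve; each is isolated behind `MetricConfig` so
alternates can be swapped:

- *gene content*: 1 − multiset Jaccard of family contents;
- *linear gene order*: normalized Kendall-tau distance over shared
  single-copy families, minimized over the second ordering and its
  reversal (an OLS and its reverse complement are the same structure);
  undefined with < 2 shared families;
- *common motifs*: fraction of shared in-scope families whose promoter
  flag differs; scope `all`, `head_only` or `internal_only`;
- *gap (scaled)*: 0.01 × |Δgap| per shared adjacent family pair, averaged
  over pairs; *gap (threshold)*: 1 iff any |Δgap| ≥ 30 nt (inclusive —
  30 nt is the minimum length that can host a basal BRE-TATA promoter
  element, so such a widening can create a new regulatory site);
- amalgamation: weighted sum of components.

A pair for which any component is undefined is dropped rather than
imputed with a maximal value; a query whose matrix contains any undefined
pair yields no context tree (this is why some query sets produce trees
for only a subset of queries).

## Variable-group clustering and Fowlkes–Mallows

Variable-group agglomerative clustering handles ties explicitly: at each
step all clusters connected by inter-cluster dissimilarities within
ε = 1e−9 of the global minimum merge simultaneously, one multifurcating
node per connected tie component, at the minimum's height. ε absorbs
floating-point noise from amalgamation sums. Inter-cluster dissimilarity
is computed from the original leaf matrix (mean over cross leaf pairs for
unweighted-average linkage, maximum for complete), so on tie-free input
the output is node-for-node identical to textbook sequential clustering —
an equivalence the tests verify against an independent implementation on
hundreds of random matrices. Merge heights are asserted monotone during
construction.

The Fowlkes–Mallows index between flat partitions is
`B = T/√(P·Q)` over the block contingency table, with `B = 0` by
convention when either partition is all singletons (`P·Q = 0`). The
*segmentation threshold* is interpreted as a dendrogram cut height
producing the flat partition that is scored (the only way the threshold
is used downstream); an alternative mode cuts to *k* clusters by removing
the k−1 highest merges, since the threshold's name admits either reading.

## Context forest

No canonical tree-to-tree dissimilarity exists for this setting; the one
used here reuses the package's own comparison machinery: restrict both
trees to their shared species S, and take 1 − the mean Fowlkes–Mallows
agreement of the two k-cluster cuts over k = 2..|S|−1. It is bounded in
[0,1], zero iff the trees induce the same partitions at every granularity,
and set to 1 when |S| < 3 (too little shared structure to compare). It
sits behind a small strategy interface.

Grove detection makes "a visibly long separating branch" quantitative: a
grove is a maximal forest subtree with ≥ 3 leaves whose stem length
(parent merge height − subtree height) reaches the 90th percentile of all
stem lengths; both knobs are exposed on the CLI. Forest membership
defaults to trajectories present in every species with clustericity
≥ 0.5.

Chromosomal geometry: the bisect distance between two genes on one
(circular) replicon is the midpoint separation along the shorter arc
divided by half the replicon length — 0 for coincident genes, 1 for
diametrically opposite ones — and pairwise distance profiles histogram
this quantity over all C(n,2) gene pairs.

## Synthetic evolution

The generator emulates the joint structure of the four inputs: strand-
annotated genes grouped into operons/singletons, family labels consistent
across species (ground-truth orthology via inheritance), a bifurcating
species tree with exponential branch lengths, and FIMO-style motif hits
placed 75 nt upstream of promoter-flagged genes (promoters are simulated
as hit records, not sequence — motif scanning is out of scope). Defaults:
8 species, 30 families, operons of 1–5 genes, gene lengths 300–1500 nt,
intra-operon gaps 0–40 nt (below the 50 nt chaining rule), inter-operon
spacers 200–800 nt (above it), promoter probability 0.8 at operon heads /
0.2 internally. Event rates (events per unit branch length) default to
promoter gain+loss 1.0, gap resize 0.24, content gain 0.1, content loss
0.05, reorder 0.002 — preserving the strong empirical rate ordering
promoter ≫ gap ≫ reorder observed for these modification modes. Gap
resizes draw a signed magnitude (default 30–60 nt) and clamp the result
to ≥ −30 nt to avoid pathological overlaps. Every event is recorded in a
truth log whose replay from the root genome reproduces each tip exactly
(a tested invariant).

What the simulator does *not* emulate: nucleotide-level evolution,
horizontal transfer, unannotated genes, annotation errors, multi-replicon
genomes (one replicon per species), or realistic paralog families.
Passing tests therefore demonstrate algorithmic correctness and
recoverability under clean, known-truth conditions — not performance on
real annotation pipelines, where homology clustering noise and gene-call
errors dominate.

## Problem sizes and recovery conditions

Event-recovery checks run 20 independent replicates per event type with
6 species, 12 families (operons of 2–4 genes) and a single active event
rate of 0.2 per unit branch length — about one expected event per
replicate, small enough that multi-hit coincidences (two gains on sibling
branches of one operon, a promoter toggling twice, gap changes that
cancel) stay rare, since each such coincidence hides one event from the
analysis-side detectors. Observed totals are compared to the expected
total with a 3σ Poisson band. Rate-ordering checks use five replicates
with rates 1.0 / 0.24 / 0.002 (promoter / gap / reorder). The oracle
sweeps use 500 random replicons (≤ 12 genes) for OLS prediction, 200
random tie-free matrices for the clustering equivalence, and 200 random
partition pairs for the Fowlkes–Mallows pair-counting identity. The whole
suite runs in a few seconds on one CPU.

## Known limitations

- The exact formulas behind the original interactive tool's named metrics
  are not published alongside it; the formulas here are documented
  design choices, so numeric dissimilarities are not guaranteed to match
  that tool's output even where the qualitative behaviour agrees.
- `cut_k` may return more than k blocks in the presence of
  multifurcations (removing a multifurcating merge releases all its
  children); the forest dissimilarity averages over whatever partitions
  the cuts produce.
- Merged same-species groupings are silently excluded from order-dependent
  computations (event classification, gene-order and scoped motif
  metrics); heavily paralogous families therefore contribute less signal.
- Linear bisect distances can exceed 1 if a replicon is declared linear
  but treated with circular geometry disabled; profiles are intended for
  circular chromosomes.
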