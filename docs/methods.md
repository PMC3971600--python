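# Methods

This note documents the models, parameter choices, numerical conventions and
known limitations of `phylopan`, in the order the pipeline runs.

## Homolog clustering

Families are connected components of a qualifying-pair graph (single
linkage): a pair qualifies when a global, end-gap-free BLOSUM62 alignment
(gap open −11, extend −1) reaches identity ≥ `min_identity` (default 0.40)
and mutual coverage ≥ `min_coverage` (default 0.70).  Conventions that the
thresholds depend on, stated explicitly because alignment tools differ:

* *identity denominator* — residue–residue columns only; columns pairing a
  residue with a gap are excluded;
* *coverage of x* — residue–residue columns ÷ `len(x)`.  A global alignment
  places every residue in some column, so "columns containing a residue of
  x" would always be 1; the residue-pair reading is the one under which a
  70%-length criterion means anything.  The criterion is applied to **both**
  sequences (`min(coverage_a, coverage_b)`), the conservative reading of a
  one-sided "70% of length" rule; it is configurable.
* A pair whose length ratio is below `min_coverage` is skipped without
  aligning — aligned columns can never exceed the shorter length, so the
  bound is exact, not heuristic.

Cluster ids derive from the lexicographically smallest member, making output
order-independent.

## Pangenome distances and markers

The gene-content distance is `d = (A + B − 2S)/(A + B)` over copy-count
vectors, with `S = Σ_c min(x_c, y_c)` so that in-paralogs only count up to
the partner's copy number.  `d` is a metric on count vectors bounded in
[0, 1]; identity of indiscernibles holds because `S` reaches `(A + B)/2`
only for equal vectors (property-tested).

Genome clustering uses scipy hierarchical linkage, default `complete` — the
default of the R heatmap machinery classically used for such displays — with
the method recorded in the result.

Group-specific markers: presence means copy count ≥ 1; a cluster is
A-specific when `presence(A) ≥ presence_frac` and `absence(B) ≥
absence_frac` (defaults 0.9/0.9, inclusive).  Fractions are compared as
exact rationals (`count · q ≥ p · group_size` for a threshold `p/q`), so
boundary cases like 9/10 are deterministic.  Because a published gloss of
the 90/90 rule in terms of genome counts ("at least 11 of 12 / at least 16
of 18") is slightly looser than the fractional rule (16/18 = 88.9%), an
integer-count mode (`min_present_count` / `min_absent_count`) is provided;
the fractional rule is the default and the two are not silently mixed.

## Trait screening

Queries are searched by Smith-Waterman local alignment (BLOSUM62, 11/1) and
scored with a Karlin-Altschul e-value `E = K·m·n·e^{−λS}` (m = query length,
n = database residues).  Defaults λ = 0.267, K = 0.041 are the published
gapped-BLOSUM62 constants for these penalties.  A per-database alternative
(`ReferenceDB.calibrate`) refits (λ, K) from the Gumbel tail of
maximum scores of shuffled queries and stores them with the database; the
published constants remain the default because a small database gives the
shuffle fit little tail data.

Thresholds mirror the screens they implement: butyrate genes use
`E ≤ 1e-30` **and** identity ≥ 0.70; sporulation genes use the e-value
cutoff alone; metagenome reads use `E ≤ 1e-10`.  Relaxing either threshold
can only add hits (tested).  Nucleotide input is screened TBlastN-style:
six-frame translation followed by the same protein search; stop codons
render as `*` and effectively truncate local alignments.  Pseudogene
detection beyond this is out of scope.

## Phylogenetics

*Trimming.*  Column filtering uses per-column Shannon entropy over non-gap
symbols, normalized by log₂ of the alphabet size (4 or 20) so thresholds are
comparable across alphabets; default cutoff 0.7 plus an optional gap-fraction
cutoff.  This is a deliberate simplification of score-matrix-based trimmers:
it keeps the "0.7 entropy" semantics without a BLOSUM30 dependency.

*Distances and trees.*  JC distances are
`d = −((k−1)/k)·ln(1 − p·k/(k−1))` over shared non-gap sites; `p ≥ (k−1)/k`
is capped at `max_distance` (default 5.0) and flagged, as are pairs with no
overlap.  Neighbor joining is delegated to scikit-bio after sorting taxa, so
results are invariant to input row order; additive matrices are recovered
exactly.  Bootstrap support is the fraction of site-resampled NJ replicate
trees containing each split of the full-data tree.

*Likelihoods.*  Felsenstein pruning under the symmetric k-state model
(JC69 for k = 4) with uniform root frequencies; gaps are missing data.  The
model is deliberately simple: the downstream discordance statistics (AU,
SPR) consume any per-site log-likelihood matrix, and externally computed
matrices under richer models can be supplied via `PerSiteScoreMatrix`
(CONSEL-style TSV accepted).

*AU test.*  Multiscale RELL: totals are resampled at relative sizes
{0.5, 0.7, 0.85, 1, 1.2, 1.4, 2} (1,000 replicates each by default); the
bootstrap proportion uses fractional win-splitting on ties so exchangeable
inputs give 0.5 exactly in expectation.  With σ = √(1/r), the model
`Φ⁻¹(1−BP) = d·σ + c/σ` is fit by weighted least squares (delta-method
binomial weights, BPs clipped to [1/2B, 1−1/2B]) and `p = 1 − Φ(d − c)`.
Site columns are put in a canonical sort order before resampling, which
makes the returned p-values exactly invariant to input site order.
All-zero or all-one proportion profiles clamp p to 0/1 with a degenerate
flag.  Under a boundary null (mean-zero per-site score differences) the
measured type-I error at α = 0.05 sits inside the binomial 99% interval
(recomputed by `scripts/acceptance.py`).

*SPR distance.*  Computed on unrooted binary trees.  Up to
`exact_leaf_limit` leaves (default 8) the distance is exact: breadth-first
search over the SPR graph, deduplicating topologies by canonical split set.
A rooted maximum-agreement-forest search minimized over rootings was
considered and rejected: it can overestimate the unrooted distance, and the
test oracle (an independent declarative BFS) computes the unrooted quantity.
Beyond the limit the result carries `exact=False` with certified bounds: an
upper bound from greedy agreement-by-leaf-deletion (if removing k leaves
makes the trees agree, k moves suffice — each deleted leaf can be re-placed
with one SPR), and the trivial lower bound 1.  Note that RF/2 is *not* a
valid lower bound for SPR (one move can change every split), so no RF-based
bound is reported.

*Consensus networks.*  Splits are retained when their occurrence fraction
across gene trees meets the threshold (inclusive; the "similarity cutoff" of
network tools is interpreted as minimum split frequency, the parameter is
exposed).  Pairwise compatibility of the retained system is reported;
layout/drawing is out of scope.

## Trait evolution

Trees are rooted for mapping (root by outgroup via `root_on_outgroup`).
Branches are identified by the tip set below them, so event lists replay on
any copy of the tree; every returned scenario is replay-validated in tests.
Sankoff DP enumerates co-optimal scenarios by backtracking, capped (default
100) with a completeness flag, since co-optimal counts can explode.  The
three named regimes are: Dollo (single gain at the MRCA of positive tips —
placing the gain higher only adds losses — plus one loss per maximal
trait-free subtree), loss-free (one gain per maximal trait-bearing subtree),
and unconstrained Fitch with free root.  When Fitch ambiguity exists the
convention is absence-ancestral unless a root state is supplied.

`lgt_flag` declares a gene a transfer candidate when the AU test rejects the
reference (vertical-inheritance proxy) topology at α (default 0.001,
matching the convention of reporting P < 0.001), reporting the SPR distance
on the shared taxa as a companion statistic.  Donor/direction inference is
explicitly out of scope.

## Metagenome screening

Reads are translated in six frames; the best local hit across the trait and
decoy databases wins, and a read is retained only when that best hit is a
trait gene with `E ≤ 1e-10`.  Score ties break by lexicographic target id,
making the filter order-independent.  Relative abundance defaults to
retained ÷ total reads per sample (configurable denominator, since the
source procedure does not state its normalization).  Habitat pairs are
compared with two-sided Welch's *t* (Welch–Satterthwaite df, scipy
implementation, verified against the closed form) and Bonferroni correction
over the pairs tested; pairs with fewer than two samples per side are
reported not-evaluable rather than guessed.  Taxon-abundance summaries count
a read as classified only when its posterior is strictly above the 0.7
threshold, and use classified reads as the percentage denominator; samples
with zero classified reads are flagged and excluded from summaries.

## Synthetic data: what it emulates, and what it does not

The generator reproduces the statistical structure the analysis assumes at
the scale of the motivating study — ~30 genomes from four habitats (default
weights 0.7 gut / 0.17 rumen / 0.08 oral / 0.05 sediment, assigned as
contiguous blocks in leaf order so habitat-pure clades exist), ~3,500 gene
families with 90% at the root, mean genome sizes near 3,000 genes:

* *Species tree* — Yule pure-birth, ultrametric, seeded; this produces the
  short-internal-branch regime that makes marker-gene trees poorly resolved.
* *Gene content* — per-branch Poisson gain/loss (rate × branch length);
  families in the designated sporulation-analog set multiply their loss rate
  (default 25, ∞ forcing loss) on branches whose descendant tips all belong
  to target habitats, producing ragged, partially penetrant absence
  patterns.  LGT-analog families start absent, enter on one origin branch,
  and then jump into non-carrier lineages at `lgt.rate`, with the donor
  lineage recorded.  Contemporaneity of donors is approximated by preorder
  precedence rather than explicit time slicing.
* *Sequences* — independent random root proteins per family evolved under a
  symmetric 20-state model; the tree is rescaled to height 0.15 by default
  so within-family identity stays far above the 0.40 clustering threshold
  while cross-family identity sits at the 1/20 random baseline.  On an LGT
  branch the recipient copies the donor lineage's current sequence, making
  gene trees discordant.  Paralogs (1 + Poisson(0.05) copies per tip) share
  one sequence.  No indels, rate variation, codon bias, or realistic
  substitution matrices — clustering and discordance thresholds, not
  sequence realism, are under test.  Nucleotide genes are reverse-translated
  with uniform synonymous codons.
* *Metagenomes* — reads uniform over (gene, start) pairs of habitat genomes,
  independent per-base substitution errors, plus a Binomial background of
  uniform random sequence.  No quality-score model, chimeras, or abundance
  skew.

Consequently, passing recovery tests demonstrates correctness of the
pipeline's logic under its own assumptions (clusters = families, markers =
planted loss set, loss scenarios = planted events, LGT flags = planted
discordance) — not robustness to real-data artifacts such as domain
shuffling, fragmented assemblies or annotation error.

## Problem sizes and determinism

Tests and the acceptance script run deliberately scaled-down studies chosen
to exercise every code path while keeping the whole suite in the minutes
range: recovery uses 10 genomes × 24 families (≈ 215 genes, ≈ 23,000
pairwise alignments), exact-SPR oracles use 6–7 leaves where the full
topology space (105 / 945 trees) is enumerable, LGT power/size use 200
replicates of 400-site alignments on 8 taxa, and calibrations use 500–1,000
null replicates.  The full study scale (30 genomes, 3,500 families) is
exercised for gene content only, where it is cheap.  Every stochastic step
takes an explicit integer seed and is bit-reproducible; FASTQ output is
byte-identical across reruns of the same seed.
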