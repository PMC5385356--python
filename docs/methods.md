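# Methods

This note records the models, conventions and design choices behind
`consmotif`, in the order the pipeline applies them.

## Problem setting

Given a set of orthologous protein-coding ORFs for one gene — typically one
sequence per species, spanning deep divergences — the pipeline asks: which
short stretches of the protein ("linear motifs") are under the strongest
combined residue conservation and purifying selection?  All answers are
reported in the coordinates of a single reference ortholog (by convention
the human sequence, numbered 1..L on the full protein), so that positions
are directly comparable across analyses and species sets.

## Reference-anchored codon alignment

Instead of a progressive multiple alignment, every query is aligned
pairwise to the reference: translated proteins are globally aligned with
affine gaps (BLOSUM62, gap open −11, gap extend −1, via Biopython's
`PairwiseAligner`), and the protein alignment is back-threaded onto the
underlying codons, which preserves reading frame by construction.  The
resulting star alignment has exactly one column per reference codon
position:

* query codons *inserted* relative to the reference have no reference
  coordinate and are dropped (counted per sequence in
  `CodonAlignment.dropped_insertions`);
* reference positions *deleted* in a query appear as the gap codon `---`.

This is a deliberate method substitution for a progressive MSA: every
downstream statistic is a per-reference-position quantity, and insertions
relative to the reference are never consumed.  The cost is that
alignment quality between two non-reference sequences is only as good as
their independent alignments to the reference; for ortholog sets anchored
on a well-annotated reference this is the standard trade-off of star
alignment.  Rows are ordered reference-first, then lexicographically, so
the matrix is independent of input order.  On highly diverged pairs the
optimal protein alignment may introduce compensating gap pairs even for
equal-length sequences; these are handled like any other indel.

The accounting statistic `codons_analyzed = n_rows × n_positions` counts
every codon-column cell examined, gap cells included.

## Per-site selection estimation (counting method)

Selective pressure per site is estimated by a Nei–Gojobori-style counting
procedure applied column by column:

* **Expected sites.** For a sense codon, each of the nine single-nucleotide
  neighbors contributes 1/3 of a site, classified synonymous or
  nonsynonymous under the standard genetic code; mutations creating stop
  codons are excluded from both tallies (so S + N ≤ 3).
* **Pairwise differences.** For two codons differing at k positions, the k!
  orderings of single-base steps are enumerated; pathways through a stop
  codon are excluded (with a fallback to all pathways if none survive, stop
  steps counted as nonsynonymous).  sd and nd are the pathway-averaged
  synonymous and nonsynonymous difference counts.
* **Per-site summary.** Over all unordered pairs of non-gap codons at a
  position, per-pair proportions pN = nd/N̄ and pS = sd/S̄ (N̄, S̄ the
  pair-averaged expected sites) are clamped into [0, 1] and averaged into
  dN and dS; d = dN − dS.

The clamp matters at single-codon scale: a single synonymous
third-position difference can give sd/S̄ ≈ 1.4, and no multiple-hit (log)
correction is applied because log corrections are numerically unstable on
3-nt windows.  Clamping per pair rather than per site keeps the per-pair
proportions interpretable and, empirically, gives a lower-variance d.

The standardized score is z = (mean(d) − d_i)/sd(d) over the scored
positions of the gene (population SD), so stronger purifying selection
(more negative d) yields larger positive z; by construction mean(z) = 0
and sd(z) = 1.  Positions with fewer than `min_pairs` (default 3)
comparable pairs are left unscored (z = NaN).  This all-pairs counting
estimator deliberately replaces likelihood codon models: it is
deterministic, order-independent and adequate at desk scale; tree-aware
ancestral counting would reduce the pseudo-replication of pairwise
comparisons and is a natural extension.

A structural limitation worth stating: a perfectly invariant site has
d = 0, which the standardization cannot distinguish from neutral sites
whose d averages 0.  Invariant sites are instead captured by the residue
conservation component below — the two components are complementary, not
redundant.

## The combined 0–2 conservation score

Each scored position receives `score = c + p` with

* c = (m − 1)/(n − 1), where m is the modal residue count among the n
  non-gap residues: 1 exactly at 100% identity, 0 exactly when all
  residues differ;
* p = clamp(z/2, 0, 1): 1 exactly at z ≥ 2 ("more than 2 SDs above the
  mean" purifying selection), 0 at or below the gene mean, linear between.
  Unscored positions contribute p = 0 (conservative).

The endpoint conditions therefore characterize the extremes exactly:
score = 2 iff (100% identity and z ≥ 2); score = 0 iff (all distinct and
z ≤ 0).  Only these endpoints are externally fixed; the additive
continuous form between them is the simplest score matching both, and a
categorical {0, 1, 2} variant (count of endpoint conditions met) is
available via `site_scores(..., categorical=True)`.  Positions with more
than half the rows gapped are reported but flagged `low_support`; positions
with fewer than two residues score 0 and are flagged.

## Sliding-window motif discovery

Scores are averaged over every full window of w = 21 codons (step 1, no
partial edge windows).  Motifs are selected greedily: the highest-mean
window first, then the best window not overlapping any already-selected
one, until k motifs or exhaustion; ties break leftmost.  The motif count k
is a user parameter, not a detection threshold — the method ranks windows,
it does not test them.  Reported coordinates are window start/end in
reference numbering.

## Phylogenies

Distances are TN93 (Tamura–Nei 1993): purine transitions, pyrimidine
transitions and transversions with empirical base frequencies pooled over
each sequence pair, computed on the nucleotide view of the codon alignment
with gap-containing sites excluded pairwise.  A non-positive logarithm
argument (saturation) returns a configurable cap (default 5.0
substitutions/site) with a warning rather than aborting the matrix.  With
equal base frequencies and balanced transition classes TN93 reduces to
K2P, and further to JC69 when transitions are half the transversions —
both limits are asserted in the test suite to 1e-9.

Trees are built with Saitou–Nei neighbor joining; Q-matrix ties break at
the lowest index pair and negative branch-length estimates are clamped to
zero (deficit logged), so results are deterministic.  Bootstrap supports
resample codon columns with replacement (default 500 replicates, seeded);
each internal bipartition of the point tree is annotated with its
percentage among surviving replicates, and a replicate whose distance
matrix is uncomputable is dropped (hard error if more than 10% drop).
Newick output writes supports as internal node labels and branch lengths
with 6 significant digits.

## Cross-group conservation

For a protein alignment partitioned into G organism groups, a group is
*conserved* at a position when all its non-gap residues are identical
(strict identity; a similarity-class mode is intentionally not the
default) and at least `min_group_coverage` (default 0.5) of the group is
non-gap — a mostly-gapped group cannot count as conserved.  Positions are
binned by the exact number of conserved groups; for G = 5 the bands carry
the conventional colors red (all 5), green (exactly 4), cyan (exactly 3),
gray (exactly 2).  Band percentages are computed over the total alignment
length and rounded to one decimal; the "conserved in at least one
grouping" total is reported both as the sum of rounded band percents (the
arithmetic used in the motivating report) and as the exact unrounded
union, which can differ in the last decimal.

## The simulator

The generator produces the statistical structure the analysis assumes, so
every stage is testable without downloads.  Sequences evolve along a tree
(balanced, or a Kingman-coalescent shape, scaled to a total length in
expected substitutions per nucleotide site) under a continuous-time codon
process: single-nucleotide neighbor moves with rate
(kappa for transitions, 1 for transversions) × (ω at the site if
nonsynonymous, a synonymous scale if synonymous), stop states forbidden.
Rates are normalised so branch lengths share the unit of the TN93
distances downstream.  Simulation is an exact per-site Gillespie jump
process; the root sequence is uniform over sense codons; everything
derives from one seed and the same config is byte-reproducible.

Planted "motifs" set ω ≈ 0 (default 0.02) *and* scale the synonymous rate
by 0.1, so motif columns stay near-identical at codon and residue level —
emulating a fully conserved linear motif.  Groups are assigned by clade
(contiguous subtrees), making within-group conservation phylogenetically
realistic.

What the simulator does **not** emulate: indels (the alignment stage is
tested with constructed indel cases instead), rate heterogeneity beyond
per-site ω, base-composition drift, isoform or paralog mixture, and
alignment error from manual curation.  Passing recovery tests therefore
demonstrates that the estimators and the score behave as designed under
the assumed generative model, not that real ortholog sets are this clean.

## Standard study conditions and what they show

The motif-recovery experiment uses 24 taxa, 200 codons, total tree length
2, neutral background (ω = 1), one planted 21-codon conserved block, 50
replicates — sizes chosen to represent a mid-sized vertebrate ortholog set
while keeping a full Monte-Carlo run in seconds.  Under these conditions
the rank-1 window overlaps the planted block (Jaccard ≥ 0.5) in roughly
nine of ten replicates; the binding check in the test suite runs the
experiment on a fixed seed list.  The margin is real but not enormous —
under a neutral background the z-component contributes pure noise
(≈ +0.2 mean score outside the motif), which is the main cost of the
additive score form.

## Numerical and degenerate-input conventions

* Coordinates are 1-based inclusive throughout, on the reference protein.
* Sequence validation: upper-casing, U→T, ambiguity codes reject the
  record (not masked), trailing stop stripped, internal stop rejects.
* If every scored position has identical d (sd = 0), all z are set to 0.
* TN93 terms whose frequency coefficient is 0 contribute 0.
* All randomness (simulation, bootstrap, recovery) flows from explicit
  integer seeds; no global RNG state is used.

## Known limitations

* Pairwise counting over-counts shared ancestry; z is a within-gene
  ranking device, not a calibrated test statistic.
* Star alignment cannot recover alignments between two non-reference
  sequences better than their reference anchoring allows.
* The bootstrap assumes codon columns are exchangeable; planted-motif
  structure violates this mildly.
* The category/percentage machinery takes the input alignment as given;
  column masking of hypervariable regions is the caller's responsibility.
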