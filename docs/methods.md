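# Methods

## The pipeline model

The method targets amplicons whose read pairs do not overlap, so each
sequenced fragment is represented as an ordered pair of segments
(forward read R1, reverse read R2) with an unsequenced middle. All
within-pipeline comparisons respect that structure: identity between two
paired units is pooled over independent R1-vs-R1 and R2-vs-R2 alignments,
(matches₁ + matches₂)/(columns₁ + columns₂), so no alignment can cross
the junction. Stitched representatives (R1 + 8 Ns + reverse-complemented
R2) exist only for taxonomy and tree building, where N-containing
words/k-mers are skipped and the spacer is therefore inert; downstream
code must never rely on the spacer's length.

Stage order: QC → paired-backbone clustering (de novo chimera removal,
optional reference screen) → orphan-R1 mapping → clustering of the
unmapped remainder → stitching → classification → non-bacteria and
singleton filtering → tree → table. Three modes share this code path:
`hybrid` (full), `paired-only` (orphans discarded) and `r1-only` (R2
ignored entirely); the comparison of the three on the same input is the
package's central experiment.

### Quality control

Trimmomatic-style, in a fixed order chosen to match that tool's
documented semantics for the steps used: LEADING (strip 5' bases with
quality < 3), TRAILING (same from the 3' end), SLIDINGWINDOW (scan
5'→3' with a 4-base window; cut immediately before the first window with
mean quality < 15; evaluated only where a full window fits; reads
shorter than the window skip the step), MINLEN (trimmed length ≥ 75% of
the *original* length). One simplification relative to Trimmomatic is
deliberate: after the window cut we do not additionally strip trailing
bases below the threshold — cut-before-first-failing-window only, which
is deterministic and covered by tests. Reads containing N after trimming
are rejected. Survivors are truncated to 250 (R1) / 200 (R2) bp;
a read shorter than its truncation length fails, which is what converts
decayed R2s into orphaned pairs. R2-only failures orphan the pair
(the R1 continues single-end); R1 failures drop the pair — the pipeline
is R1-anchored and never uses orphan R2s.

### Clustering

Dereplication keys on the (R1, R2) pair, not R1 alone; units sort by
size descending with lexicographic tie-break, making the clustering
input — and hence the whole run — independent of file order. Greedy
centroid clustering processes units in that order: join the best
centroid at identity ≥ 0.97, ties to the more abundant centroid then
founding order; otherwise check for chimerism; otherwise found a new
centroid. Centroids are never re-centered. The 0.97 radius is the
field's convention for species-proxy OTUs and is configurable. After
every run all centroid pairs are asserted to be below the radius.

Alignment is ends-free (semi-global) with affine gaps: match +1,
mismatch −2, gap open −10, extend −1 (first gapped base costs
open+extend). The heavy gap costs reflect a substitution-dominated
platform. Identity is matches over internal columns; terminal gap runs
are free and excluded, which is what lets a trimmed orphan (≥ 75% of its
original length) map cleanly onto a 250 bp centroid segment.

Two numerical consequences of the ends-free formulation are handled
explicitly:

- *Degenerate overlaps.* A dovetail alignment of two unrelated sequences
  can collapse to a short perfect overlap with identity 1. Radius and
  mapping decisions therefore require the alignment to cover ≥ 80% of
  the shorter segment (`pair_identity_covered`); otherwise the pair is
  treated as no hit. Genuine homologs at ≥ 90% identity always pass this
  bar; the uncovered identity remains available as `pair_identity`.
- *Fast path.* When two segments have equal length (the common case
  after truncation) the pipeline scores them by direct positionwise
  comparison instead of the full dynamic program. Under
  substitution-only divergence the gapless alignment is the optimal
  alignment, so this is exact there; `PipelineParams(fast_identity=False)`
  forces the DP everywhere. Library-level functions default to the DP.

### Chimera detection

Two-parent model with a single crossover. Candidate parents are up to 8
centroids at identity ≥ 0.90 to the query (parents are always at least
as abundant as the query because of processing order). Match profiles
are computed per segment and concatenated in *genome orientation*
(forward segment, then the reverse segment's profile reversed): in that
coordinate system a chimeric molecule is always a prefix-from-A /
suffix-from-B pattern, even when the crossover falls inside the reverse
read (where read orientation would split it into three blocks). All
ordered parent pairs and crossover positions are scanned by prefix sums;
the query is chimeric iff the best spliced model reaches 0.99 identity
and beats the best single parent by ≥ 0.01. The same model drives the
optional reference screen, with parents drawn from a user-supplied
full-length reference FASTA instead of centroids. The margin rule has a
geometric consequence worth knowing: a splice whose crossover sits
within ~10% of either end is arithmetically within 1% of a pure parent
and is absorbed into that parent's cluster rather than flagged — it
never reaches the detector, because it passes the clustering radius.
Thresholds (0.90 / 0.99 / 0.01 / 8 parents) are exposed in the API.

### Taxonomy

8-mer naive Bayes with bootstrap confidence. Training counts, per genus,
the number of reference sequences containing each word;
P(w|g) = (n(w,g) + Pr(w)) / (N(g) + 1) with word prior
Pr(w) = (sequences containing w + 0.5)/(total + 1). Genus priors are
uniform (training sets are genus-imbalanced). Classification extracts
all N-free words, takes the full-word-set argmax as the point estimate,
then draws ⌈words/8⌉ words with replacement in each of 100 replicates;
per-rank confidence is the fraction of replicate winners agreeing with
the point estimate at that rank (monotone non-increasing with depth by
construction), and the call is assigned down to the deepest rank with
confidence ≥ 0.8. Each classify call derives its RNG stream from
(seed, sequence id), so per-OTU results are order-independent. OTUs not
confidently Bacteria at kingdom — including UNCLASSIFIED — are removed,
as are OTUs whose total count across all samples is 1 (configurable).
There is no structural-alignment screen: non-bacterial filtering is
delegated entirely to the classifier's kingdom call, a documented design
decision.

### Tree

OTU representatives are mixed-length, so the tree is built from k-mer
set distances, d(a,b) = 1 − |Kₐ∩K_b| / min(|Kₐ|,|K_b|) with k = 6 and
N-containing k-mers skipped — insensitive to end gaps and the spacer by
construction — followed by canonical neighbor joining (Saitou–Nei Q,
deterministic label-order tie-breaks, negative pendant branches clipped
to 0 with the deficit moved to the sibling so additive matrices are
still recovered exactly; the property suite verifies exact recovery to
1e-9 on random additive matrices). This alignment-free stand-in replaces
structural alignment + approximate-ML tree building on purpose:
deterministic, dependency-free, and adequate for UniFrac at this scale.
A user-built Newick tree can be supplied instead wherever a tree is
consumed. Trees are midpoint-rooted before UniFrac.

## Evaluation statistics

- Subsampling is multivariate-hypergeometric (without replacement),
  seeded; samples below depth are dropped with a warning.
- Bray-Curtis with the 0/0 → 0 convention; unweighted and
  (normalized) weighted UniFrac computed by vectorized per-branch
  bookkeeping and cross-checked against scikit-bio in the test suite.
- Mantel: Spearman by default over upper triangles, permutation of one
  matrix's labels jointly on rows and columns,
  p = (1 + #{r_perm ≥ r_obs})/(1 + n_perm). The bootstrap SE resamples
  *samples* with replacement and recomputes r on the induced submatrix,
  excluding self-pairs of duplicated samples (whose distances are
  structurally zero in both matrices).
- One-way random-effects ICC with the unbalanced-adjusted mean group
  size k₀; the raw estimate is returned unclipped, groups with a single
  replicate are excluded, and the implementation is cross-checked
  against both a from-scratch ANOVA oracle and pingouin's ICC(1,1).
- Prevalence filters use strict inequality ("more than" x% of samples);
  both readings are defensible and strict is the documented choice.
- Per-genus Spearman correlations are computed on relative abundances
  (depth-invariant); a genus absent from one table is scored against a
  zero vector and reported as 0. Genus collapsing pools OTUs
  unclassified at genus into `unclassified_<deepest assigned rank>`
  bins, preserving the grand total; the bin mass is the
  unclassified-at-genus read fraction.

## The synthetic study generator

The generator reproduces the statistical structure of a
technical-replicate gold-standard experiment, not any particular
sequencing run:

- **References**: one random 694 nt ancestor, each of 20 species mutated
  at 5% of sites, pairwise divergence verified ≥ 5% by brute force with
  bounded redraws. Lineages are hierarchical (species pair into genera,
  genera into families, all Bacteria) so taxonomy tests have structure.
- **Communities**: per subject, species abundances ∝ exp(N(0, 1.5²)),
  giving realistic long-tailed profiles; technical replicates share the
  subject vector *exactly*, so replicate variation downstream is pure
  multinomial read sampling and ICC targets are well defined.
- **Reads**: 8000 pairs per sample by default (the suite and the
  acceptance script run at 800 for desk-scale turnaround; every check is
  a property, not a magnitude, and is insensitive to this scaling). R1 is
  the first 250 bases, R2 the reverse complement of the last 200.
  Per-cycle PHRED means interpolate linearly (R1: 36→30, R2: 34→16.8,
  jitter sd 3) and bases substitute with probability 10^(−Q/10). The R2
  profile was calibrated once so that default QC passes ~60-65% of R2s —
  about half the R2 loss rate that motivates the method in real data —
  and ~100% of R1s; these are characterizations, not targets.
- **Chimeras**: 1% of molecules are two-distinct-parent splices at a
  uniform crossover — matching the detector's model by design; harder
  chimera structures are out of scope.
- **R2 retention**: `degrade_r2` keeps exactly ⌊retain·n⌋ reverse reads
  per sample (uniform, seeded), emulating datasets with 25/50/75/100% of
  good-quality R2s.

What the generator does *not* emulate — indels, PCR bias,
platform-specific error motifs, length variation, contaminants with
foreign taxonomy — bounds what green tests mean: they validate the
algorithmic claims (read recovery, backbone stability, chimera model,
statistic definitions) under a substitution-only error model, not
performance on any particular instrument's quirks.

## Numerical and reproducibility choices

- One global seed per run; stage streams are derived (simulation uses
  fixed stream offsets; classification derives per-sequence streams from
  (seed, id)), so identical configs are byte-identical — asserted by
  test on every saved artifact.
- Greedy clustering refuses unsorted input rather than sorting silently:
  the processing order is part of the algorithm.
- Mantel's permutation p has a floor of 1/(n_perm+1); the self-comparison
  p equals that floor only when the label set is large enough that the
  identity permutation is not redrawn by chance.
- Degenerate inputs: empty reads FAIL_SHORT; an empty backbone maps
  nothing (valid); all-zero sample pairs get Bray-Curtis 0; a constant
  vector gets Spearman 0; fewer than 2 usable ICC groups is an error.

## Known limitations

- The substitution-only alignment fast path is exact only for
  substitution-only divergence; data with real indels should run with
  `fast_identity=False` (the DP handles indels throughout).
- Identity from ends-free alignment is undefined for unrelated
  sequences; the 80% coverage floor is a pragmatic guard, not a
  similarity model.
- The classifier assigns at genus level at best (no species calls), and
  its confidence is agreement with the point estimate, which can be
  overconfident when reference genera are sparse.
- The k-mer/NJ tree is a topology-plausible stand-in, not a
  phylogenetic estimate; branch lengths are k-mer distances, and UniFrac
  values should be compared between runs of this pipeline, not across
  tree-building methods.
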