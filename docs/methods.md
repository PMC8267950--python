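# Methods

This note records the models implemented by `mifish`, the parameter
defaults and why they were chosen, and the numerical conventions where
the underlying procedure leaves room for interpretation.

## Per-nucleus ploidy and gain/loss annotation

Each nucleus's ploidy is an integer inferred from its own signal
counts. The rule, in order:

1. **Anchor.** The candidate ploidy is the median of the centromere
   probe counts (CCP4, CCP10). A panel without centromere probes falls
   back to the median of the gene counts.
2. **Amplification exclusion.** Gene probes counting more than twice
   the candidate are treated as amplified and left out, so a 20-copy
   *HER2* cluster cannot drag a diploid nucleus's average up.
3. **Pooled mean.** The ploidy is the mean of the centromere counts
   plus the retained gene counts, rounded half-up to an integer.
   (`include_centromeres_in_mean=False` restricts the mean to the
   retained gene probes; the default includes the centromeres because
   they are the designated references.)

Rounding is half-*up*, not banker's: a pooled mean of 2.5 becomes 3.
Exact integer arithmetic is used throughout so no binary-float artifact
can flip a boundary case. If every gene probe is excluded the
centromere median alone decides; a nucleus with no usable probes is an
error.

This rule reproduces the two extreme worked cases: the uniformly
diploid vector annotates as 2, and the pattern `8-4-4-4-3-2-4-5`
(median 4, nothing excluded, mean 4.25) annotates as tetraploid.

Gains and losses are then the strict trichotomy against that nucleus's
own ploidy: count > ploidy is a gain, < is a loss, = is neutral. The
per-nucleus baseline makes the calls invariant under whole-genome
doubling: a uniformly tetraploid nucleus is neutral everywhere.

## Sample summaries

- **Average ploidy** is the mean of the per-nucleus integer ploidies,
  rounded half-up to one decimal *before* the diploid/aneuploid
  comparison; the cutoff is 2.2 (2.0 and 2.1 are diploid). The
  one-decimal rounding matters only in a narrow band around the cutoff
  and mirrors how the cutoff was calibrated against image cytometry.
- **Instability index** `I = N·100/n` counts distinct signal patterns
  over the full 10-probe vector by default
  (`pattern_universe="genes"` restricts to the 8 gene probes). The full
  vector is the default because the index is defined on "signal
  patterns observed", without restriction.
- **CNA calls** use the fraction of nuclei carrying a gain (loss) of
  each gene relative to their own ploidy: called at ≥ 0.15, *major* at
  ≥ 0.85, both thresholds inclusive. When both directions clear the
  floor (possible in mixed-ploidy populations) the more frequent
  direction is reported, ties going to the gain; both fractions are
  always retained alongside the call.
- **Amplification** is strict: mean gene count > 2 × sample ploidy,
  where the sample ploidy for this test is the modal per-nucleus
  ploidy (ties broken toward the smaller mode). A mean of exactly twice
  the ploidy is not amplified.
- The **major clone** is the most frequent signal pattern; ties are
  broken toward the lexicographically smallest vector, making every
  summary deterministic.

## Clone graphs

Nuclei are grouped by gain/loss pattern, a deliberately coarser key
than the raw counts: patterns differing only in the magnitude of the
same imbalance are one clone. Two clones are connected when exactly one
gene differs by one step, i.e. neutral↔gain or neutral↔loss; a switch
from loss to gain passes through neutral and is two steps, so no edge.
Edges point from the clone with fewer aberrant genes to the one with
more, which makes the graph a DAG whose sources are the least aberrant
clones. Sub-threshold clones are kept in the data model; display
truncation is a rendering concern.

## Copy-number phylogenies

Observed gene-probe patterns are connected into a rooted tree starting
from the diploid state `(2,…,2)` under a unit-cost event model:

- a **single-probe step** changes one coordinate by ±1 and costs 1;
- a **WGD edge** doubles every coordinate and costs 1;
- a coordinate at 0 is **absorbing** by default — a fully lost locus
  cannot be regained, and WGD keeps it at 0
  (`absorbing_zero=False` lifts this);
- unobserved intermediate patterns are inserted as **transit nodes**
  with multiplicity 0.

`total_events` is the edge count and `tree_depth` the longest
root-to-leaf path. Counting a WGD as one event (not one per probe) is a
modelling choice: the tree objective is the number of evolutionary
events, and a WGD is a single mitotic accident.

**Heuristic.** The builder greedily attaches the unattached pattern
with the smallest event distance to any node already in the tree (ties:
earlier-inserted anchor, then lexicographically smaller pattern).
Pairwise event distances allow up to two interleaved WGD rounds and are
computed coordinate-separably, since unit steps commute. Two
refinements close most of the gap to optimality at no cost in
determinism: pure-step paths detour through the coordinate-wise median
of (anchor, target, nearest remaining pattern) — the median lies
between anchor and target in every coordinate, so the detour is free
and creates shared branch points — and for up to five non-root patterns
all insertion orders are enumerated and the cheapest tree kept.
Transit-path coordinates are stepped fully in panel order; this fixes
node identity but not the event count.

**Exact oracle.** For instances with ≤ 3 observed patterns, ≤ 4 probes
and counts ≤ 6, `steiner_oracle` computes the true minimum by solving
the minimum Steiner arborescence on the directed copy-number lattice
(unit-step and WGD edges, absorbing zero): with at most three terminals
the optimum has at most two branch points, and each topology is scored
with Dijkstra searches (scipy's C implementation), including a
virtual-source pass that locates the second branch point in one sweep.
The lattice extends to twice the largest observed count so
WGD-overshoot-then-loss routes are considered. On 100 random ≤3-pattern
instances the heuristic matched the oracle in 95 and never went below
it; the acceptance suite re-measures this (threshold ≥ 90%).

## Mutual exclusivity and co-occurrence

Alteration events (CNA calls, mutations) form a samples × events 0/1
matrix. The null model preserves every row and column sum via
checkerboard switching: sample a 2×2 submatrix, flip it when it is a
checkerboard. Draws are taken every `10 × (number of ones)` attempted
switches (a standard thinning heuristic for fixed-margin binary-matrix
chains), after an equally long burn-in. The observed statistic for a
pair is the number of samples altered in both events; co-occurrence is
its upper tail, exclusivity its lower tail; Benjamini–Hochberg
adjustment is applied across pairs per direction. All chain work runs
in a numba-compiled kernel (~2×10⁷ switch attempts/s), and results are
reproducible given the seed.

**Tie handling.** The overlap statistic is integer-valued and the null
conditions on all margins, so the classical closed-tail estimator
`(1 + #{null ≥ obs})/(1 + B)` is markedly conservative on small
matrices: its measured attained size at α = 0.05 over 40×6 matrices
with random margins was ≈ 0.02, and a hypergeometric bound shows no
margin configuration at 40 samples brings it near nominal. The default
estimator therefore splits the null mass tied at the observed value
between the two tails with a single seeded uniform draw per pair — the
randomized permutation p-value, which is exactly sized for discrete
statistics — giving a measured attained size of ≈ 0.04–0.05 while still
never returning 0, and keeping the two tails complementary
(`p_co + p_ex = 1 + 1/(1+B)`). `tie_break="conservative"` restores the
classical estimator for users who prefer validity over power.

Group comparisons (`compare_groups`) delegate to scipy: two-sided
t-test, Fisher exact, chi-square.

## Variant filter cascade

Eleven hard-filter criteria remove artifacts and germline variants from
pre-annotated calls; all criteria are evaluated on every record (no
short-circuit) so the audit table shows each rule that fired. Readings
fixed here where the wording allows more than one:

- **Two-tier MAPQ (8/9).** Variants with ≥ 100 COSMIC cases or on a
  breast-cancer hotspot gene (*TP53*, *PIK3CA*, *GATA3*, *MAP3K1*,
  *KMT2C*) face only the MAPQ < 40 tier; all other variants face
  MAPQ < 55. The trusted branch is exempt from the stricter tier.
- **Cross-sample recurrence (10).** A variant present in more than one
  sample *and* below 100 COSMIC cases is removed (a recurrent private
  variant is more likely artifact than hotspot); the per-variant sample
  count is recomputed over the whole table, keyed by
  chrom/pos/ref/alt, making verdicts order-independent.
- **Zero-COSMIC moderate impact (11).** A variant with no COSMIC case
  whose dbNSFP impact is only "moderate" is removed.
- The ≤ 5% allele-fraction boundary (2) is inclusive, as written.

The COSMIC trust threshold (default 100) is exposed; raising it can
only shrink the kept set (trusted records migrate to the stricter MAPQ
tier), a monotonicity the tests sweep.

Absent annotations are an error, never a silent pass.

## DNA-histogram classification

A histogram of per-cell DNA content (c units; 2c = diploid) is
classified *aneuploid* when a stem line lies outside both the 2c ± 0.25
and 4c ± 0.25 windows, or when strictly more than 10 cells measure
above 5c; otherwise *diploid*. Stem lines are local maxima of the
Gaussian-smoothed counts (bandwidth 0.1 c, evaluated on a 0.01 c grid)
with prominence ≥ 2.5% of the total cell count (converted to curve
units through the kernel's peak factor). The original procedure is a
visual call; the smoothing bandwidth, prominence floor and window
half-width are this implementation's numeric equivalents, all exposed
as parameters. The ±0.25 c window covers staining variation while
still separating a 3c stem line; fewer than 1214 cells triggers a
warning (the smallest set the rule was applied to in practice), not a
rejection.

## Synthetic data

`simulate_sample` emulates the statistical structure the analyses
assume: a clone tree grown from a founder by single-probe ±1 events
(absorbing zero respected), Dirichlet(1) clone frequencies with a
forced dominant clone ≥ 0.3 assigned in descending order (the founder
is the major clone), centromere counts tracking the founder ploidy, and
independent per-probe miscount noise of ±1 with probability 0.02 —
a rate at which single-clone samples land at the low-end instability
indices (~2–8) seen in genomically stable tumors, since
P(intact 10-probe vector) = 0.98¹⁰ ≈ 0.82. Founders: `diploid` (all 2),
`wgd_tetraploid` (all 4), `hypodiploid` (centromeres and over half the
loci at one copy).

What it does **not** model: spatial tissue structure, selection,
hybridization-efficiency differences between probes, segmentation
errors correlated within a nucleus, or doublets. Passing recovery tests
therefore show the estimators are correct under independent symmetric
enumeration noise, not that they are robust to every real-data failure
mode.

Note on parameter recovery: under miscount noise the major-clone
fraction read off the full signal-pattern table is biased low by design
— pattern dispersal is exactly what the instability index measures — so
fraction-recovery checks run at zero noise (where the estimate is the
realized binomial draw), while ploidy-class recovery runs at the
default noise. `simulate_variant_table` plants an exact pass count and
cycles every filter criterion; `simulate_histogram` mixes Gaussian stem
lines with a debris floor and, for aneuploid samples, an off-modal stem
line plus a >5c tail.

## Problem sizes in the test suite

The statistical acceptance checks use: 100 random instances for the
tree-vs-oracle comparison (≤ 3 patterns, ≤ 4 probes, counts ≤ 6); 1000
simulated 40×6 matrices at 2000 permutations each for type-I
calibration; 200 simulated samples of 250 nuclei for parameter
recovery; a 100-record variant fixture. The full suite runs in about
two minutes on one CPU, the calibration accounting for most of it.

## Known limitations

- The tree builder is a heuristic; on dense high-instability samples
  (dozens of observed patterns) the event count is an upper bound with
  no optimality certificate (the exact oracle is limited to toy sizes).
- The exclusivity test is pairwise only; it does not search for larger
  mutually exclusive modules.
- Ploidy annotation assumes the centromere probes are honest references
  (`centromere_tracks_ploidy` in the generator); centromere-specific
  aneuploidies (e.g. an isolated chromosome-4 loss) bias the anchor.
- Histogram classification pools the two diploid histogram types; it
  does not reproduce the full four-type grading.
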