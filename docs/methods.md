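# Methods

## Dating model

A miRNA's age is estimated from the phylogenetic distribution of its
relatives. Records from a miRBase-style annotation table are partitioned
into ortho-groups, by default by normalized name stem: the species prefix
is stripped, case is folded, mature-arm suffixes (`-5p`/`-3p`) are removed,
and a trailing numeric copy suffix is stripped only when the resulting stem
collides with another record of the same species (so `hsa-mir-194-1` and
`hsa-mir-194-2` merge, but a lone `mir-125-1`-style gene name is left
alone; the bare family token never counts as a copy stem). Grouping by
shared family identifier is available as an alternative mode, since
name-based and family-based homology bracket the plausible definitions of
"evolutionarily related records" for this kind of catalog.

Each ortho-group is one binary character on a rooted species tree. Under
Dollo parsimony (one gain, arbitrarily many losses) the gain placement
minimizing the number of loss events is exactly the MRCA of the present
leaves: placing the gain on any ancestor of the MRCA adds at least one
all-absent subtree, i.e. at least one extra loss. The package therefore
computes the MRCA directly, and the test suite verifies the equivalence
against a brute-force enumeration of every candidate gain node on
thousands of random trees.

Because unobserved losses (or missing annotations in under-studied
genomes) can only pull the MRCA toward the present, the reported age is a
**lower bound** on the true age. Both ends of the origin branch are
emitted: `age_my` (the MRCA node, used everywhere downstream) and
`parent_age_my` (the older end, for transparency). A character present in
a single species dates to that terminal branch and gets age 0. Ages below
100 MY are classed *young*; the boundary value itself is *old* (the young
class is strict).

## Calibration

The tree carries no branch lengths of its own; node ages come from a
calibration table keyed by internal-node label or by a leaf pair naming an
MRCA. When a node has an estimate flagged `expert` that value is used
(mean of expert values if several); otherwise the arithmetic mean of the
published estimates. Leaves are 0 by definition. Internal nodes with no
calibration receive the midpoint of their nearest calibrated ancestor and
oldest calibrated descendant — interpolated nodes never serve as
calibrations for deeper nodes, so a chain of uncalibrated nodes collapses
onto one midpoint rather than drifting. A parent calibrated younger than
its child aborts with an error naming the pair; equal parent/child ages
are tolerated (they arise legitimately from interpolation).

## Statistics

* **Rank tests.** All Mann–Whitney comparisons use mid-ranks with
  tie-corrected variances. For small tie-free samples (both groups ≤ 8)
  the exact null enumeration is used; otherwise the normal approximation
  without continuity correction, which keeps the plain test numerically
  identical to the one-stratum reduction of the stratified test.
* **Stratified (van Elteren) test.** Per informative stratum the group-1
  rank sum is centered at its null mean; contributions are combined with
  weights 1/(n_s + 1) and standardized by the summed weighted
  tie-corrected variances. Strata containing only one group are dropped
  with a log entry. The implementation is validated against exact
  within-stratum permutation enumeration on small instances.
* **Correlations.** Spearman's rho via mid-ranks with the t-approximation
  p-value. A constant input vector yields a flagged (undefined) result
  rather than a silent NaN. Correlations of age with disease counts
  include zero-association miRNAs at count 0; a flag restricts to
  disease-associated miRNAs as a robustness variant.
* **Per-disease enrichment.** Each disease's member ages are compared with
  non-members by a two-sided Mann–Whitney test (a variant compares against
  the full background including members, since either reading of
  "background of all miRNAs" is defensible). Raw p-values against a 0.01
  threshold reproduce the conventional counting; Benjamini–Hochberg
  adjusted values are always emitted alongside. Diseases with fewer than
  two aged members are skipped.
* **Disease collapsing.** Cancer merging collapses every term matching a
  configurable regex (carcinoma|cancer|leukemia|lymphoma|tumor|neoplasm|
  blastoma|sarcoma|melanoma) into one entry. MeSH collapsing truncates
  dot-delimited tree numbers to a chosen level and unions the miRNA sets;
  multi-path diseases contribute to every truncated label, and diseases
  without a path are kept uncollapsed with a warning.
* **Target-age permutation test.** The statistic is the mean over miRNAs
  of the fraction of their targets strictly older than the miRNA (ties
  count as not-older). The null shuffles which intact target set is paired
  with which miRNA age, so both marginal age distributions are preserved
  while the pairing is broken. Empirical p = (r + 1)/(n_perm + 1) with
  10,000 shuffles by default; the +1 correction keeps p strictly positive.
* **Jaccard profiles.** Binary disease/target/tissue vectors over a fixed
  label universe; pairs where both vectors are empty are undefined and
  excluded with a log count. Family analyses keep families with more than
  four members; pair populations are within-family, between-family, and
  singleton–singleton, compared by Mann–Whitney and, within matching age
  strata, by the stratified test. Age strata default to origin-node bins,
  with numeric-age quantile bins as the alternative.
* **Expression breadth.** Replicate columns are consolidated per tissue; a
  miRNA is present in a tissue if any replicate has expression > 0
  (default) or if the replicate mean exceeds a threshold. Breadth is the
  number of present tissues.

## Genomic context

All coordinates are BED-convention 0-based half-open; touching intervals
never overlap. Lookup uses per-chromosome interval trees and agrees with a
quadratic scan by construction (tested). Intron membership uses the
precursor midpoint by default — robust for precursors straddling splice
boundaries — with any-overlap and full-containment rules selectable.
TE and TFBS flags use any positive overlap (a minimum-fraction threshold
is available). The per-miRNA conservation score is the
overlap-length-weighted mean of element scores (maximum as alternative),
missing when no element overlaps. Strand is ignored by default.

## Synthetic data

The generator produces every input the pipeline reads, with the monotone
age-effect structure the analysis is designed to detect, and records its
ground truth. Defaults describe the study conditions: 25 species on an
800 MY ultrametric tree, 500 human-containing miRNA characters, loss rate
0.02 expected events per branch (losses are rare under the Dollo
assumption), 50 diseases (40% cancer-named, with MeSH-style paths),
disease counts Poisson with λ(age) = 0.5 + 0.02·age, 2000 genes with
gamma(2, 600) ages (mean 1200 MY, far older than the miRNAs, as for
protein-coding genes), target counts Poisson(2 + 0.03·age) drawn with a
0.92 bias toward genes older than the miRNA, 20 tissues × 3 replicates
with logistic-in-age presence, 30 families whose members share a base
profile at retention 0.9, and interval tracks in which TE overlap is
planted preferentially on young miRNAs (odds 4) and TFBS on old ones
(odds 4), with conservation scores trending upward in age. Sizes were
chosen so the full pipeline completes in seconds on one CPU.

Character gains are uniform over the ancestors of the focal species, so
planted ages are roughly uniform over node depths; the generator does not
reproduce the strong young-skew of real miRNA catalogs, nor annotation
ascertainment bias across species, sequence-level homology, or dependence
between the disease/target/tissue channels beyond their shared age driver.
Passing tests therefore demonstrate that the estimators and tests recover
planted structure of the assumed form and stay calibrated under the
corresponding nulls — not that real catalogs satisfy those generative
assumptions.

With losses disabled the pipeline recovers every planted age exactly
(characters are exactly the gain node's leaf set and the MRCA inverts
that); with losses enabled the estimate is verifiably never older than
the planted age.

## Numerical and design choices

* Tie-breaks in the brute-force Dollo oracle go to the most recent node;
  the MRCA result is provably unique, so this guard is never exercised.
* Permutation and simulation seeds are explicit everywhere; all outputs
  are byte-reproducible given the seed, and set-derived collections are
  sorted before writing or sampling so results do not depend on hash
  randomization.
* The pipeline writes outputs atomically (temp file + rename), so an
  interrupted stage never leaves truncated tables.
* Species present in annotations but absent from the tree or calibration
  are dropped from presence profiles with a logged count.
* The grouping mode, presence rule, intron rule, conservation reduction,
  enrichment background, and age-strata definition are all recorded in the
  config hash carried in every output header.

## Known limitations

* Name-based orthology inherits whatever inconsistencies the annotation
  namespace contains; no sequence-level verification is attempted.
* Ages are lower bounds; sparse annotation in non-focal species biases
  characters young, and nothing in the method can correct for that.
* The van Elteren normal approximation is asymptotic; for very small or
  heavily tied strata the exact-enumeration comparison in the test suite
  bounds, but does not remove, the discreteness error.
* The per-miRNA conservation reduction and the intron-membership rule are
  explicit substitutes for conventions that differ between published
  analyses; both are configurable and logged.
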