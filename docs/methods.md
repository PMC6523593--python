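# Methods

This note documents the models, estimators, defaults and numerical
conventions implemented in `walnutsnp`, and what the synthetic-data tests
do and do not demonstrate about real data.

## Synthetic study design

The generator (`walnutsnp.simulate`) emulates a walnut breeding-program
genotyping study: a small, highly heterozygous founder panel, full-sib
families from controlled crosses, occasional open pollination, genotyping
error and missingness, and a historical pedigree ledger with occasional
mislabelling.

* **Founders.** `n_founders = 27` unrelated individuals. Each site draws a
  true minor allele frequency; the minor allele is assigned to REF or ALT
  with probability 1/2 and dosages are Binomial(2, p) per sample
  (Hardy-Weinberg, no inbreeding). The default MAF law is uniform on
  [0.05, b] with b ≈ 0.269 solved numerically so the expected
  heterozygosity 2pq equals `target_het = 0.26`, the mean observed
  heterozygosity of the real discovery panel. Any `uniform(a,b)`,
  `beta(a,b)` (scaled to [0, 0.5]) or `fixed(p)` law can be substituted.
* **Sites.** `n_sites` SNPs spread over `n_scaffolds` scaffolds (default
  20 × 5 Mb) at uniform random distinct positions. Sites are unlinked:
  there is no recombination map, so LD between nearby sites is sampling
  noise only. This is deliberate — LD pruning and tagSNP selection are
  exercised for their contracts (bounds, maximality, determinism), not for
  realistic haplotype structure.
* **Crosses.** A `CrossPlan` lists (dam, sire, n) entries, processed in
  order so later crosses may use earlier offspring (multi-generation
  pedigrees). Each offspring receives one Mendelian allele draw per parent
  per site. `OPEN` sires are drawn uniformly from a candidate list
  (default: all founders except the dam); no pollen-cloud model is
  attempted. The truth graph records the realised sire and flags the
  offspring, so the exported recorded pedigree blanks it as a real ledger
  would.
* **Error model.** Genotype errors are symmetric code flips: a called
  dosage is replaced by one of the other two codes with probability
  `geno_error_rate` (default 0.01), then set missing with `missing_rate`
  (default 0.01). The symmetric flip exercises both false-heterozygote and
  false-homozygote failure modes; real array error is cluster-driven and
  not symmetric, which the tests do not capture. Mislabelling replaces a
  recorded parent entry with probability `mislabel_rate` (default 0.02) by
  a wrong id drawn uniformly from the panel, excluding the child and both
  true parents — a "mislabel" naming a true parent is undetectable in
  principle and therefore not a useful error to inject. The error and
  mislabel rates are plausible knobs, not measured values.
* **Annotations.** Filter inputs (QUAL, MQ, DP, DP4, flanking-variant
  flags, 16-mer counts, probe-conversion scores, effect classes) are
  generated directly rather than derived from sequence: the filters are
  predicates on annotations, and no reference genome is in scope. Baseline
  values pass every predicate; a configurable fraction of sites per rule
  is overwritten with failing values and recorded in truth columns, so
  filter behaviour can be scored exactly. AC/AN are computed from the
  simulated genotypes.

All randomness flows from explicit integer seeds through
`numpy.random.default_rng`; identical configuration implies bit-identical
output.

## Site filtering

Two stages, each a conjunction of predicates with configurable thresholds
(defaults are the published design values; comparators follow the printed
boundary semantics exactly, e.g. QUAL equal to 60 fails, AC/AN equal to
0.05 passes):

1. quality: QUAL ≤ 60; MQ ≤ 20; DP < 200 or > 4580; strand rule;
   sum(DP4)/DP < 0.75; AC/AN < 0.05 or > 0.95;
2. array candidacy: indel; more than two alleles; predicted variants in
   both 35-bp flanks; 16-mer count > 300; P-convert ≤ 0.6 for both probe
   orientations.

The strand rule's published description is self-contradictory (it removes
sites whose four DP4 components all exceed 1, i.e. the well-supported
ones). The default here removes a site unless both alleles are seen more
than once on both strands, consistent with standard strand-bias practice;
the literal reading is available via `strand_mode="literal"`. The depth
bounds are applied to the multi-sample aggregate DP.

Reports attribute every failed rule per site, while summary counts use
first-failing-rule attribution so the per-rule counts partition the
removals. Filtering is idempotent, and relaxing any single threshold can
only grow the survivor set (property-tested).

## Panel selection

* HIGH_MOD_EFF: sites with effect class HIGH or MODERATE.
* ALL_HOM: no heterozygous founder call and at most 3 missing (the source
  texts disagree between "less than three" and "no more than three"
  missing; ≤ 3 is the default and both are selectable, as are
  either-allele vs alternate-only homozygosity).
* INFP tagSNPs: scaffolds are tiled with non-overlapping 10-kb windows
  from position 1 (focal point = midpoint, final partial window kept —
  focal-point placement is otherwise unconstrained and this choice has no
  free parameters). Within a window, all-heterozygous, all-homozygous and
  > 6-missing sites are dropped; remaining candidates are visited in
  descending-MAF order (tie: ascending position) and kept iff r² with
  every kept site is < 0.81 (a pair exactly at the threshold is "too
  correlated"). The greedy order is a declared convention; the output is
  a maximal valid set regardless of order.
* Assembly: union with reason priority HIGH_MOD_EFF > ALL_HOM > INFP;
  A/T and C/G sites cost two probes. If a target size or probe budget is
  exceeded, only INFP sites are trimmed, round-robin across windows,
  lowest MAF first within a window; an unreachable target is reported as
  an explicit shortfall.

r² is the squared Pearson correlation of dosage vectors over jointly
called samples; pairs with fewer than two joint calls or zero variance
carry no LD information and never exclude a site.

## Relatedness

Prefilters before estimation (defaults as published): drop samples with
call rate < 0.97; drop sites with missing rate > 0.2 or MAF < 0.05;
LD-prune greedily in position order within 50-kb sliding windows at
r² ≤ 0.25 (window step = one site; in-window order is position order —
the published description does not fix these and this matches common
practice). IBS0 and kinship are computed on the same pruned set, with the
jointly-called site count as the IBS0 denominator.

The KING-robust between-family estimator is implemented from
genotype-pair counts (see README for the formula); it is the estimator
the named algorithm computes and needs no allele frequencies. The
all-pairs path is vectorised through indicator-matrix products and agrees
with the scalar path to float32 accumulation error (~1e-5 on k), which is
far below the classification granularity; the scalar path is exact
integer counting.

## Pedigree reconstruction

Classification: DUPLICATE if k > 0.45; else first-degree if k ≥ 0.16,
split into PO (IBS0 ≤ 0.03) and FS (IBS0 > 0.03); else OTHER. These
defaults are the published calibrated values. `calibrate_thresholds`
re-derives them from recorded relationships: the first-degree bound as
the 2.5th percentile (lower bound of the central 95% interval) of kinship
over known PO+FS pairs, and the PO IBS0 bound as the maximum IBS0 over
known PO pairs that already pass the first-degree bound — the restriction
keeps mislabelled records (kinship ≈ 0) from inflating it.

A deliberate consequence of percentile calibration is that ~1% of true PO
pairs fall below the calibrated kinship bound (the pooled 2.5% tail is
shared between PO and the wider-tailed FS distribution). Reconstruction
therefore defaults to the published thresholds; calibration is the tool
for transferring the method to panels with different ancestry or marker
content.

Assignment per sample: duplicates are first collapsed onto the
highest-call-rate representative (tie: lexicographic id). Candidate
parents are PO-classified partners from an earlier generation; PO pairs
whose relative generation is unknown or equal are sent to a review list
rather than oriented by guesswork. Generations come from supplied
metadata (cross years) when available, else from the recorded pedigree's
implied depth. Recorded parents are confirmed iff they are PO-classified
candidates and pass the duo Mendelian test (< 5%); failures become
`recorded_rejected`. Among passing candidates, the trio with the lowest
inconsistency rate is accepted if below 5%, else the best duo; ties break
by rate then IBS0. Edge provenance distinguishes `recorded_confirmed`,
`corrected` (replacement for a rejected record in the same slot) and
`new`; candidates beyond two parents are flagged for review, never
silently dropped.

Note a structural limitation the synthetic tests expose: the duo
Mendelian test cannot reject a full sib posing as a parent (a sib duo's
inconsistency rate equals its IBS0, well under 5%), and on a low-MAF
panel FS IBS0 (~0.017 here) sits below the published 0.03 PO bound. Sib
impostors are instead excluded by generation metadata (same generation ⇒
unorientable) or, when calibration is used, by the tighter calibrated
IBS0 bound. On real array data with more intermediate-frequency markers,
FS IBS0 sits above 0.03 and the published bound separates the classes
directly.

## Diversity statistics

* Per-site MAF, observed heterozygosity and missing rate from non-missing
  dosages; set means are unweighted; all-missing sites are excluded from
  means and counted.
* F_IS per family (≥ 5 members): 1 − mean(Ho)/mean(He) over the family's
  polymorphic sites, He = 2p(1−p) from family allele frequencies. Note a
  sib family has an inherent heterozygote excess against its own allele
  frequencies (an Aa×aa site alone gives F_IS = −1/3), so family values
  are structurally negative; a random-mating HWE sample gives |F_IS| <
  0.02 at 10⁴ sites.
* Robust sets: PHR sites, and NMH/OTV/AAvar/ABvar/BBvar sites, with zero
  Mendelian errors over all accepted trios and duos. With no trios the
  condition is vacuous and the full class sets are returned with a
  warning. Adding trios can only shrink the sets.
* PCA: dosages centred by 2p and scaled by sqrt(2p(1−p)) (the standard
  allele-frequency normalisation for SNP PCA), missing entries
  mean-imputed, eigendecomposition of the sample covariance; variance
  proportions are reported over the full spectrum and sum to 1.
* UPGMA on allele-sharing distance 1 − IBS (per-site shared-allele
  proportion 1 − |a−b|/2, averaged over jointly called sites; the
  distance choice is a declared convention — the published analysis names
  only "genetic distance"). The agglomeration is the naive O(n³)
  size-weighted average-linkage merge with ties broken by the
  lexicographically smallest cluster label for determinism; merge height
  is half the cluster distance, so trees are ultrametric to float
  precision, and branch lengths are serialised with shortest round-trip
  float repr. scipy's average linkage serves as an independent oracle in
  the tests.

## Problem sizes and what the tests show

Acceptance-level runs use the study-scale conditions: 27 founders, 10⁴
sites (≈ 9×10³ after prefilters), 100 replicates for kinship recovery,
and 25 families × 22 offspring (+10 open-pollinated) for reconstruction —
about 550 offspring and 1,120 true parent-child edges per run. At these
sizes the package recovers kinship means within ±0.005 of expectation,
reconstructs error-free pedigrees exactly, and with 1% genotyping error
and 2% dam mislabelling attains 100% PO classification recall, flags
every injected mislabel and recovers every true parent.

These results validate the estimators and the decision logic, not array
chemistry: the simulator has no cluster-calling artefacts, no
ascertainment bias, no linkage, and HWE founders. Quantities that depend
on those realities (class conversion rates, real-panel PCA percentages)
are taken from the published validation counts as data, and the
arithmetic over them is recomputed, not asserted.
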