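# Methods

## Scope and data model

The package analyses three readouts of a TaqMan-style marker study of
the *RRAS2* gene in breast cancer: endpoint allelic-discrimination
fluorescence (one VIC/FAM pair per sample), qPCR cycle thresholds for
genomic targets (*RRAS2*, reference *COX8A*) and expression targets
(*RRAS2*, normalizer *PUM1*), and per-sample metadata (cohort, plate,
clinical attributes). Cohorts are healthy blood donors, blood from
breast-cancer patients, and breast tumors, plus a small set of anchor
normal tissue samples re-run on every expression plate.

No patient-level dataset of this design is publicly available, so the
synthetic generator is a first-class component: it produces all input
tables with known ground truth, and the test suite validates each
estimator by parameter recovery against that truth.

## Genotyping

Signals are mapped to polar coordinates, θ = atan2(FAM, VIC) in degrees
and distance d = √(VIC²+FAM²). θ depends only on the allele ratio and is
invariant to any common positive gain; d is proportional to total
template, making it a copy-number proxy. Optional no-template background
subtraction floors signals at zero; a sample that is zero in both
channels is uncallable and excluded from clustering.

Calls come from clustering θ into k=3 groups, labelled GG < GC < CC by
ascending center. The production clusterer is **exact 1-D k-means**:
optimal 1-D clusters are contiguous on the sorted axis, so dynamic
programming over contiguous partitions (O(n²k)) finds the global
optimum deterministically, with ties broken toward earlier boundaries.
We chose this over the classical quantile-initialized Lloyd iteration
(also provided, and tested for its monotone objective) because a local
search cannot guarantee the exhaustive-search equivalence we require of
the caller; determinism and optimality remove the initialization as a
degree of freedom. A fixed-threshold mode (gates in degrees) mirrors
manual instrument gating.

Two guards make degenerate data explicit rather than arbitrary: cluster
centers closer than `min_separation` (default 5°) are merged and each
survivor labelled by the canonical θ band containing it (GG [0°,30°),
GC [30°,60°), CC [60°,90°]), so a missing genotype class is reported
empty; and calls closer than `no_call_margin` (default 2°) to a cluster
boundary become NO_CALL, mirroring instrument "undetermined" calls.

## Copy number

Replicate Ct values are averaged per (sample, gene) after dropping
undetermined wells; a replicate range above 1.0 cycle raises a QC flag,
and a sample with no determined replicate is excluded with a log entry.
The relative genomic abundance is R = E^(Ct_COX8A − Ct_RRAS2) with
efficiency E = 2 by default (configurable; assay efficiencies are not
calibrated here). Anchoring divides every R by the healthy-cohort
**median**; the median rather than the mean is used because the
amplified tail is one-sided, and the anchored healthy median is 1 by
construction (bit-exact for odd cohort sizes; within one ulp for even
sizes, where the median averages two normalized values). Estimated
copies are 2·R_norm, and category thresholds are inclusive: ratio ≥ 1.5
is a gain, ≥ 2.0 an amplification, so the ≥1.5 fraction contains the
≥2.0 one.

Cohort-level distance-to-origin comparisons use two-sided Wilcoxon
rank-sum tests against the healthy cohort: the distance distribution is
heavy-tailed by construction (a diploid bulk plus an amplified tail), so
ranks are preferred over a Gaussian model; the one-way ANOVA F across
cohorts is reported alongside for comparability with variance-based
analyses. An optional median ± k·MAD filter (off by default) stands in
for iterative robust outlier exclusion.

## Expression

Comparative-Ct quantification: q = E^(−ΔCt), ΔCt = Ct_target −
Ct_normalizer, fold-change = q / mean(q over anchor samples), so the
anchor mean is exactly 1. Anchor aggregation uses the **arithmetic**
mean of the linear-scale q (fold-changes are reported relative to a
mean expression level); a geometric-mean mode is available for
log-symmetric designs. Per-plate anchoring is the default: any additive
Ct shift shared by the genes on a plate cancels exactly in ΔCt and in
the plate-local anchor mean. Plates without anchors are excluded with an
error report rather than silently falling back to a global anchor. The
overexpression call is strict (fold > 1).

Luciferase reporter wells are background-subtracted per channel using
the mean of non-transfected wells (0 if absent); wells whose renilla
signal does not exceed background are excluded, numerators are floored
at a small epsilon, and the allele effect is the ratio of mean
C-construct to mean G-construct activity.

## Association statistics

Allele frequency q_C = (2n_CC + n_GC)/2n with s.e. √(pq/2n). The
Hardy–Weinberg test is exact: conditional on the observed allele
counts, the heterozygote count has a known discrete distribution, and
the two-sided p sums the probabilities of all configurations no more
likely than the observed one. The case–control test is Fisher's exact
on the 2×2 of GG vs CC homozygotes (heterozygotes dropped, matching the
homozygote-contrast design; a 2×3 chi-square over all genotypes is also
provided). Both tests are computed in exact integer arithmetic
(binomial coefficients over a common denominator), so probability ties
are resolved exactly and the p-values agree with brute-force
enumeration to the last bit; the odds ratio takes a 0.5 continuity
correction, flagged, when a cell is zero. The dose–expression analysis
reports per-genotype mean ± s.e.m., a first-principles one-way ANOVA
(between/within sums of squares; all-equal data yields F = 0 and p = 1,
zero within-group variance with distinct means yields F = ∞ and an
underflowed p of 0.0, reported as computed), Spearman rank correlation
of C-allele dose (0/1/2) with expression, and Tukey-adjusted pairwise
contrasts. No correction is applied across the small set of top-level
tests; each is reported per-test.

## Synthetic cohort generator

Defaults are the study conditions: cohort sizes 234/200/449 (+10
anchors), C-allele frequency 0.30 (healthy) vs 0.45 (patients/tumors),
exact Hardy–Weinberg proportions unless `hwe_deviation` inflates the CC
class, 20% copy gains (ratio uniform on [1.5, 2.0)) and 10%
amplifications (uniform on [2.0, 2.5]) among patient-derived samples,
triplicate wells on 5 plates.

* **Fluorescence**: signal = gain × allele templates × amount × noise,
  with a shared lognormal per-sample DNA amount (CV 0.20) and
  independent lognormal per-channel noise (CV 0.10). Lognormal
  (multiplicative) noise keeps signals positive and preserves the
  gain-invariance of θ. Copy gains preserve allelic composition by
  default (a CC sample with 4 copies contributes 4 C templates); an
  allele-specific switch routes extra copies to the C allele instead,
  since which of the two happens in vivo is not established.
* **Ct model**: Ct = c₀ − log₂(template)/log₂(E) + plate + ε, with one
  additive N(0, 0.5) shift per plate shared by all genes on it (the
  run-to-run threshold shifts ΔCt is designed to cancel) and N(0, 0.1)
  per-well noise. c₀ (26 genomic, 30 expression) only places Ct values
  in the realistic 18–35 range.
* **Expression**: tumor log2 fold-change = base + dose·(#C alleles) +
  σ·z with dose effect 0.5 per C allele; base 0.62 and σ 2.29 are
  calibrated once so the simulated tumor cohort reproduces the reported
  cohort-level summary of this assay class (median fold ≈ 2.1, ≈ 68%
  of tumors above fold 1). Blood and anchor samples sit at fold 1.

All randomness flows from a single seed through named substreams, so
(config, seed) reproduces every table byte for byte.

What the generator does **not** emulate: full amplification curves
(only endpoint/Ct summaries), allele-specific probe cross-talk,
PCR-efficiency differences between targets, plate-position effects,
sample contamination or degradation, and somatic mosaicism. Passing
recovery tests therefore shows the estimators are correct under the
stated generative model, not that they are robust to every artifact of
real instruments; the plate-shift, gain-invariance and scale-invariance
properties are exact guarantees that transfer to real data, while
accuracy figures (e.g. call accuracy at 10% noise) are model-relative.

## Numerical and design choices

* Exact integer arithmetic in both exact tests; p-values capped at 1.
* The DP clusterer breaks SSE ties (< 1e-15) toward earlier split
  points; Lloyd stops on center convergence (allclose).
* Anchoring is idempotent and scale-invariant; re-anchoring normalized
  ratios is a no-op.
* Degenerate inputs: empty cohorts yield zero count rows, not errors;
  comparisons on cohorts with fewer than 2 samples are skipped with a
  warning; configuration errors name the offending field.
* Pipeline reports contain no timestamps; provenance is (package
  version, config hash, seed), keeping repeat runs byte-identical.
* Problem sizes in the tests and the acceptance run use the study-sized
  cohort (883 samples) or smaller, which is ample for the recovery
  tolerances asserted; power and type-I checks use 200 and 2000
  replicates respectively, sized to keep Monte-Carlo error well inside
  the asserted margins.

## Known limitations

* Efficiency E is assumed shared by target and reference; no
  standard-curve calibration.
* Whole-chromosome-11 amplification is invisible to the *RRAS2*/*COX8A*
  ratio (both genes sit on chromosome 11); the distance readout is the
  only (coarse) guard.
* The exact HWE test is conservative at small n, as exact conditional
  tests are; its type-I error is verified ≤ 0.06 at nominal 0.05 in the
  suite.
* The 2° NO_CALL margin and 5° minimum cluster separation are
  instrument-motivated defaults, not fitted quantities.
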