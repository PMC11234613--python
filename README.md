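# rras2kit

Desk-side analysis of the genetic markers that associate the unmutated
*RRAS2* gene with breast cancer: the rs8570 single-nucleotide
polymorphism (a G→C substitution at position +124 of the *RRAS2* mRNA
3'UTR), *RRAS2* genomic copy gains, and *RRAS2* mRNA overexpression. It
is written for molecular-epidemiology and cancer-genetics groups who run
TaqMan-style endpoint genotyping and qPCR panels on patient cohorts and
want a reproducible, scriptable path from raw well readouts to cohort
statistics. Because no patient-level dataset of this kind is publicly
deposited, the package ships a synthetic cohort generator with ground
truth, so every estimator can be validated by parameter recovery.

## What it computes

**Genotyping from endpoint fluorescence.** Each sample's dual-probe
endpoint signals (VIC reporter for the G allele on *x*, FAM reporter for
the C allele on *y*) are mapped to polar coordinates

&nbsp;&nbsp;θ = atan2(FAM, VIC) (degrees), d = √(VIC² + FAM²),

where θ encodes the allele ratio (GG ≈ 0°, GC ≈ 45°, CC ≈ 90°) and d
the total amplifiable template. Genotypes are called by exact 1-D
*k*-means on θ (dynamic programming over contiguous partitions of the
sorted angles — deterministic and globally optimal), with a
fixed-threshold gate as an alternative and a NO_CALL margin around
cluster boundaries.

**Copy number.** The genomic qPCR ratio R = E^(Ct_COX8A − Ct_RRAS2)
(*COX8A*, a stable single-copy housekeeping gene near the chromosome 11
centromere, is the reference; E is the amplification efficiency,
default 2) is anchored so the healthy-blood cohort's median is 1 —
those samples are assumed diploid — giving estimated copies
2·R/median(R_healthy). Samples are categorized as copy **gain**
(normalized ratio ≥ 1.5) or **amplified** (≥ 2.0). The
distance-to-origin d provides a model-free cross-check, compared across
cohorts by rank-sum tests.

**Expression.** Comparative-Ct quantification q = E^(−ΔCt) with
ΔCt = Ct_RRAS2 − Ct_PUM1, referred to the mean of a fixed set of
anchor normal tissue samples carried on every plate (anchor mean ≡ 1);
a sample with fold-change > 1 *overexpresses* *RRAS2*. Per-plate
anchoring cancels additive run-to-run Ct shifts exactly. The
dual-luciferase allele-reporter ratio (background-subtracted
firefly/renilla, C-allele construct over G-allele construct) is also
provided.

**Association statistics.** Allele frequencies with binomial standard
errors; an exact Hardy–Weinberg test (conditional on allele counts,
two-sided by probability ordering, computed in exact integer
arithmetic); the case–control Fisher exact test on GG vs CC homozygotes
(heterozygotes dropped; exact integer arithmetic, so p-values match full
enumeration identically); and genotype-dose versus expression
association (first-principles one-way ANOVA, Spearman trend of C-allele
dose, Tukey pairwise contrasts).

## Worked example

Simulate the study-shaped cohort (234 healthy blood donors, 200 patient
blood samples, 449 tumors; C-allele frequency 0.30 healthy vs 0.45
patients; 20% copy gains and 10% amplifications among patient samples)
and run every stage:

```bash
python analysis/01_simulate_cohort.py --seed 1
python analysis/02_call_genotypes.py
python analysis/03_copy_number.py
python analysis/04_expression.py
python analysis/05_association_stats.py
```

Selected output at seed 1:

```
cluster centers (deg): [0.0, 45.0, 90.0]
call accuracy vs truth: 100.00% (883 called)

normalized RRAS2/COX8A ratio medians:
healthy_blood    1.000
patient_blood    1.025
tumor            1.033

gain/amplification fractions:
       cohort   n  pct_gain_or_higher  pct_amplified
healthy_blood 234                 0.0            0.0
patient_blood 200                25.0            8.5
        tumor 449                28.1           10.0

anchor-set mean relative expression: 1.000000 (1 by construction)
tumor median fold-change: 2.21
tumor pct_overexpressed: 69.9

GG vs CC homozygotes, tumor vs healthy blood: OR = 5.09, Fisher exact p = 6.04e-10
```

Reading it: the three θ clusters land on the canonical genotype angles
and every call matches the simulated truth; anchoring fixes the healthy
ratio median at exactly 1, so the patient/tumor medians slightly above
1 and the ~28%/10% gain/amplification fractions read directly as excess
*RRAS2* copies; the anchor normal set reads fold 1 by construction and
about 70% of tumors overexpress *RRAS2* (median fold ≈ 2.2); and CC
homozygotes are strongly enriched in tumors relative to healthy blood
(odds ratio ≈ 5).

The same stages are available as a CLI (`rras2kit simulate | genotype |
copynumber | expression | stats | validate | run-all`) and as library
functions for user CSVs (documented column schemas in
`src/rras2kit/io.py`).

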