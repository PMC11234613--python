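"""Synthetic marker-study cohorts with ground truth.

Generates the three tables the analysis consumes — endpoint VIC/FAM
fluorescence, qPCR Ct values and sample metadata — under a configurable
generative model, plus a truth table for parameter-recovery testing.

Generative model
----------------
* Genotypes per cohort are drawn from Hardy-Weinberg proportions
  (p^2, 2pq, q^2) of the cohort's C-allele frequency, with the CC
  frequency optionally inflated by ``(1 + hwe_deviation)`` and the triple
  renormalized.
* Genomic copies: healthy samples carry the diploid baseline; patient
  blood and tumor samples carry a copy *gain* (ratio uniform in
  [1.5, 2.0)) with probability ``frac_gain`` and an *amplification*
  (ratio uniform in [2.0, 2.5]) with probability ``frac_amplified``.
* Expression: tumor samples have a log2 fold-change
  ``base + dose_effect * (#C alleles) + sd * z`` relative to normal
  tissue; blood samples and the anchor normals sit at fold 1.
* Endpoint fluorescence is linear in allele template copies with a
  shared lognormal per-sample DNA-amount factor and per-channel
  lognormal noise, so signals stay positive and the angle theta is
  gain-invariant.
* Ct values follow ``c0 - log2(template)/log2(E) + plate + eps`` with an
  additive per-plate shift shared by every gene on the plate (so that
  delta-Ct normalization cancels it) and i.i.d. Gaussian per-well noise.

All randomness flows from ``config.seed`` through named substreams, so a
given (config, seed) reproduces the tables byte for byte.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from rras2kit.config import (
    C_DOSE,
    COHORTS,
    GENOTYPES,
    HEALTHY,
    PATIENT_BLOOD,
    TUMOR,
    CohortConfig,
    ConfigError,
)

ANCHOR = "anchor_normal"

ASSAYS = ("genomic_RRAS2", "genomic_COX8A", "expr_RRAS2", "expr_normalizer")

# fixed substream indices so each table is reproducible in isolation
_STREAMS = {
    "genotypes": 0,
    "fluorescence": 1,
    "plate_effects": 2,
    "genomic_RRAS2": 3,
    "genomic_COX8A": 4,
    "expr_RRAS2": 5,
    "expr_normalizer": 6,
    "metadata": 7,
}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(_STREAMS[stream],)))


def _lognormal_factor(rng: np.random.Generator, cv: float, size: int) -> np.ndarray:
    """Unit-mean lognormal multiplier with the given coefficient of variation."""
    if cv == 0:
        return np.ones(size)
    sigma = np.sqrt(np.log1p(cv * cv))
    return rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma, size=size)


def _plate_ids(n: int, start: int, plate_count: int) -> list[str]:
    return [f"P{(start + i) % plate_count + 1:02d}" for i in range(n)]


def simulate_genotypes(config: CohortConfig) -> pd.DataFrame:
    """Draw ground-truth genotype, copy number and expression fold per sample.

    Returns a truth table with columns ``sample_id, cohort, true_genotype,
    true_copies, true_expr_fold, plate_id``. The anchor normals (re-run on
    every plate for expression anchoring) are appended with cohort
    ``anchor_normal``, diploid copies and expression fold exactly 1.
    """
    config.validate()
    rng = _rng(config.seed, "genotypes")

    rows = []
    offset = 0
    specs = [
        (HEALTHY, "H", config.n_healthy, config.allele_freq_C_healthy),
        (PATIENT_BLOOD, "B", config.n_patient_blood, config.allele_freq_C_tumor),
        (TUMOR, "T", config.n_tumor, config.allele_freq_C_tumor),
        (ANCHOR, "N", config.n_anchor, config.allele_freq_C_healthy),
    ]
    for cohort, prefix, n, freq_c in specs:
        freqs = config.genotype_frequencies(freq_c)
        p = np.array([freqs[g] for g in GENOTYPES])
        genotypes = rng.choice(len(GENOTYPES), size=n, p=p)
        baseline = config.copies_per_group.get(cohort, 2.0)

        if cohort in (PATIENT_BLOOD, TUMOR):
            cat = rng.choice(
                3,
                size=n,
                p=[1 - config.frac_gain - config.frac_amplified,
                   config.frac_gain, config.frac_amplified],
            )
            ratio = np.ones(n)
            ratio[cat == 1] = rng.uniform(1.5, 2.0, size=int((cat == 1).sum()))
            ratio[cat == 2] = rng.uniform(2.0, 2.5, size=int((cat == 2).sum()))
        else:
            ratio = np.ones(n)
        copies = baseline * ratio

        if cohort == TUMOR:
            dose = np.array([C_DOSE[GENOTYPES[g]] for g in genotypes], dtype=float)
            z = rng.standard_normal(n) if config.expr_biological_sd > 0 else np.zeros(n)
            log2fc = (
                config.expr_log2fc_base
                + config.expr_log2fc_by_genotype * dose
                + config.expr_biological_sd * z
            )
            expr_fold = np.exp2(log2fc)
        else:
            expr_fold = np.ones(n)

        plates = _plate_ids(n, offset, config.plate_count)
        for i in range(n):
            rows.append(
                {
                    "sample_id": f"{prefix}{i + 1:04d}",
                    "cohort": cohort,
                    "true_genotype": GENOTYPES[genotypes[i]],
                    "true_copies": copies[i],
                    "true_expr_fold": expr_fold[i],
                    "plate_id": plates[i],
                }
            )
        offset += n

    return pd.DataFrame(rows)


def _allele_templates(truth: pd.DataFrame, allele_specific: bool) -> tuple[np.ndarray, np.ndarray]:
    """Per-sample G- and C-allele template copy numbers."""
    dose_c = truth["true_genotype"].map(C_DOSE).to_numpy(dtype=float)
    dose_g = 2.0 - dose_c
    copies = truth["true_copies"].to_numpy(dtype=float)
    if allele_specific:
        # extra copies beyond the diploid pair go to the C allele when present
        extra = copies - 2.0
        has_c = dose_c > 0
        c_t = dose_c + np.where(has_c, extra, 0.0)
        g_t = dose_g + np.where(~has_c, extra, 0.0)
    else:
        # proportional: gains preserve the allelic composition
        g_t = copies * dose_g / 2.0
        c_t = copies * dose_c / 2.0
    return g_t, c_t


def simulate_fluorescence(truth: pd.DataFrame, config: CohortConfig) -> pd.DataFrame:
    """Endpoint VIC (allele G) / FAM (allele C) signals for each sample.

    ``signal = gain * allele_templates * amount * noise`` with a shared
    lognormal DNA-amount factor per sample and independent lognormal noise
    per channel. Anchor normals are excluded (they are expression-only).
    """
    if truth.empty:
        raise ValueError("truth table is empty")
    config.validate()
    truth = truth[truth["cohort"] != ANCHOR].reset_index(drop=True)
    rng = _rng(config.seed, "fluorescence")
    n = len(truth)

    g_t, c_t = _allele_templates(truth, config.allele_specific_amplification)
    amount = _lognormal_factor(rng, config.template_amount_cv, n)
    noise_v = _lognormal_factor(rng, config.fluor_noise_cv, n)
    noise_f = _lognormal_factor(rng, config.fluor_noise_cv, n)
    gain = config.fluor_gain_per_allele_copy

    return pd.DataFrame(
        {
            "sample_id": truth["sample_id"],
            "cohort": truth["cohort"],
            "vic": gain * g_t * amount * noise_v,
            "fam": gain * c_t * amount * noise_f,
        }
    )


def _plate_effects(config: CohortConfig) -> dict[str, float]:
    rng = _rng(config.seed, "plate_effects")
    shifts = rng.normal(0.0, config.plate_effect_sd, size=config.plate_count)
    return {f"P{i + 1:02d}": shifts[i] for i in range(config.plate_count)}


def simulate_ct(truth: pd.DataFrame, config: CohortConfig, assay: str) -> pd.DataFrame:
    """Replicate Ct values for one assay over the given (sample, plate) rows.

    ``assay`` is one of ``genomic_RRAS2``, ``genomic_COX8A``, ``expr_RRAS2``,
    ``expr_normalizer``. The template amount is the sample's true genomic
    copies, the fixed diploid reference (2), or the expression baseline
    scaled by the true fold-change; the normalizer is genotype-independent.
    """
    if assay not in ASSAYS:
        raise ValueError(f"unknown assay {assay!r}; expected one of {ASSAYS}")
    if truth.empty:
        raise ValueError("truth table is empty")
    config.validate()
    if config.efficiency <= 1:
        raise ConfigError("efficiency must be > 1")

    if assay == "genomic_RRAS2":
        template = truth["true_copies"].to_numpy(dtype=float)
        c0, gene = config.ct_baseline_genomic, config.genomic_target
    elif assay == "genomic_COX8A":
        template = np.full(len(truth), 2.0)
        c0, gene = config.ct_baseline_genomic, config.genomic_reference
    elif assay == "expr_RRAS2":
        template = config.expression_baseline_template * truth["true_expr_fold"].to_numpy(dtype=float)
        c0, gene = config.ct_baseline_expression, config.expression_target
    else:
        template = np.full(len(truth), config.expression_baseline_template)
        c0, gene = config.ct_baseline_expression, config.expression_normalizer

    rng = _rng(config.seed, assay)
    plate_shift = _plate_effects(config)
    base_ct = c0 - np.log2(template) / np.log2(config.efficiency)
    base_ct = base_ct + truth["plate_id"].map(plate_shift).to_numpy(dtype=float)

    frames = []
    for rep in range(1, config.replicates + 1):
        eps = rng.normal(0.0, config.ct_noise_sd, size=len(truth)) if config.ct_noise_sd > 0 else 0.0
        frames.append(
            pd.DataFrame(
                {
                    "sample_id": truth["sample_id"].to_numpy(),
                    "gene": gene,
                    "plate_id": truth["plate_id"].to_numpy(),
                    "replicate": rep,
                    "ct": base_ct + eps,
                }
            )
        )
    out = pd.concat(frames, ignore_index=True)
    return out.sort_values(["sample_id", "plate_id", "replicate"], kind="stable").reset_index(drop=True)


def _metadata(truth: pd.DataFrame, config: CohortConfig) -> pd.DataFrame:
    """Sample metadata with light clinical attributes for grouping demos."""
    rng = _rng(config.seed, "metadata")
    n = len(truth)
    age = np.clip(np.round(rng.normal(58, 12, size=n)), 25, 95).astype(int)
    subtypes = np.array(["Luminal A", "Luminal B", "HER2+", "TNBC"])
    subtype = np.where(
        truth["cohort"].to_numpy() == TUMOR,
        rng.choice(subtypes, size=n, p=[0.45, 0.25, 0.12, 0.18]),
        "NA",
    )
    return pd.DataFrame(
        {
            "sample_id": truth["sample_id"],
            "cohort": truth["cohort"],
            "plate_id": truth["plate_id"],
            "age": age,
            "molecular_subtype": subtype,
        }
    )


def simulate_cohort(config: CohortConfig, outdir=None) -> dict[str, pd.DataFrame]:
    """Generate the full table set: truth, fluorescence, Ct tables, metadata.

    The expression Ct table re-runs the anchor normal samples on every
    plate (mirroring a consistent per-plate normalization set), so that
    per-plate anchoring is always possible downstream. If ``outdir`` is
    given, each table is also written as ``<name>.csv``.
    """
    truth = simulate_genotypes(config)
    fluor = simulate_fluorescence(truth, config)

    genomic_truth = truth[truth["cohort"] != ANCHOR].reset_index(drop=True)
    ct_genomic = pd.concat(
        [
            simulate_ct(genomic_truth, config, "genomic_RRAS2"),
            simulate_ct(genomic_truth, config, "genomic_COX8A"),
        ],
        ignore_index=True,
    )

    # expression plating: cohort samples on their own plate, anchors on all
    cohort_rows = truth[truth["cohort"] != ANCHOR]
    anchors = truth[truth["cohort"] == ANCHOR]
    plated = [cohort_rows]
    for plate in sorted(cohort_rows["plate_id"].unique()):
        rerun = anchors.copy()
        rerun["plate_id"] = plate
        plated.append(rerun)
    expr_truth = pd.concat(plated, ignore_index=True)
    ct_expression = pd.concat(
        [
            simulate_ct(expr_truth, config, "expr_RRAS2"),
            simulate_ct(expr_truth, config, "expr_normalizer"),
        ],
        ignore_index=True,
    )

    metadata = _metadata(truth, config)
    tables = {
        "truth": truth,
        "fluorescence": fluor,
        "ct_genomic": ct_genomic,
        "ct_expression": ct_expression,
        "metadata": metadata,
    }
    if outdir is not None:
        from pathlib import Path

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name, df in tables.items():
            df.to_csv(outdir / f"{name}.csv", index=False)
    return tables


def anchor_sample_ids(config: CohortConfig) -> list[str]:
    """IDs of the anchor normal samples the generator emits."""
    return [f"N{i + 1:04d}" for i in range(config.n_anchor)]
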