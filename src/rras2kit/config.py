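"""Configuration objects for the synthetic cohort generator and pipeline."""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml

HEALTHY = "healthy_blood"
PATIENT_BLOOD = "patient_blood"
TUMOR = "tumor"
COHORTS = (HEALTHY, PATIENT_BLOOD, TUMOR)

GENOTYPES = ("GG", "GC", "CC")

#: number of C alleles carried by each diploid genotype
C_DOSE = {"GG": 0, "GC": 1, "CC": 2}


class ConfigError(ValueError):
    """Raised when a configuration field is invalid; names the field."""


@dataclass
class CohortConfig:
    """Parameters of the simulated marker study.

    The defaults emulate the cohorts of the published study: 234 healthy
    capillary-blood donors, 200 blood samples from breast-cancer patients
    and 449 breast tumors, with a C-allele frequency of 0.30 in the healthy
    population and 0.45 in the patient/tumor population, one fifth of
    patient-derived samples carrying an RRAS2 copy gain (ratio in
    [1.5, 2.0)) and one tenth an amplification (ratio >= 2.0).
    """

    # cohort sizes
    n_healthy: int = 234
    n_patient_blood: int = 200
    n_tumor: int = 449

    # genotype frequencies
    allele_freq_C_healthy: float = 0.30
    allele_freq_C_tumor: float = 0.45
    #: multiplicative inflation of the CC homozygote frequency (0 = exact HWE)
    hwe_deviation: float = 0.0

    # genomic copy number
    copies_per_group: dict = field(
        default_factory=lambda: {HEALTHY: 2.0, PATIENT_BLOOD: 2.0, TUMOR: 2.0}
    )
    frac_gain: float = 0.20
    frac_amplified: float = 0.10
    #: if True, copies beyond the diploid pair are assigned to the C allele
    #: (when present) instead of preserving the allelic composition
    allele_specific_amplification: bool = False

    # expression model (log2 scale)
    expr_log2fc_by_genotype: float = 0.5
    #: baseline tumor/patient log2 shift on top of the genotype dose effect
    expr_log2fc_base: float = 0.62
    #: biological dispersion (s.d. of log2 expression fold) in tumor samples
    expr_biological_sd: float = 2.29

    # plate / qPCR noise
    plate_count: int = 5
    plate_effect_sd: float = 0.5
    ct_noise_sd: float = 0.1
    replicates: int = 3
    efficiency: float = 2.0
    #: Ct of one template copy at efficiency 2 (cosmetic; keeps Ct in range)
    ct_baseline_genomic: float = 26.0
    ct_baseline_expression: float = 30.0
    #: arbitrary template units of the expression normalizer / unit fold-change
    expression_baseline_template: float = 50.0

    # fluorescence model
    fluor_gain_per_allele_copy: float = 1000.0
    fluor_noise_cv: float = 0.10
    template_amount_cv: float = 0.20

    # anchor ("tumor-adjacent normal") samples re-run on every plate
    n_anchor: int = 10

    seed: int = 0

    # gene labels used in the emitted Ct tables
    genomic_target: str = "RRAS2"
    genomic_reference: str = "COX8A"
    expression_target: str = "RRAS2"
    expression_normalizer: str = "PUM1"

    def validate(self) -> "CohortConfig":
        for name in ("n_healthy", "n_patient_blood", "n_tumor", "n_anchor"):
            if int(getattr(self, name)) < 0:
                raise ConfigError(f"{name} must be >= 0")
        for name in ("allele_freq_C_healthy", "allele_freq_C_tumor"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1]")
        for name in (
            "hwe_deviation",
            "plate_effect_sd",
            "ct_noise_sd",
            "fluor_noise_cv",
            "template_amount_cv",
            "expr_biological_sd",
        ):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if not 0 <= self.frac_gain <= 1 or not 0 <= self.frac_amplified <= 1:
            raise ConfigError("frac_gain/frac_amplified must be in [0, 1]")
        if self.frac_gain + self.frac_amplified > 1:
            raise ConfigError("frac_gain + frac_amplified must be <= 1")
        if self.efficiency <= 1:
            raise ConfigError("efficiency must be > 1")
        if self.plate_count < 1:
            raise ConfigError("plate_count must be >= 1")
        if self.replicates < 1:
            raise ConfigError("replicates must be >= 1")
        for cohort in COHORTS:
            if self.copies_per_group.get(cohort, 2.0) <= 0:
                raise ConfigError(f"copies_per_group[{cohort}] must be > 0")
        return self

    def genotype_frequencies(self, allele_freq_C: float) -> dict:
        """Hardy-Weinberg genotype frequencies with optional CC inflation.

        The CC frequency q^2 is multiplied by (1 + hwe_deviation) and the
        triple renormalized to sum to one.
        """
        q = allele_freq_C
        p = 1.0 - q
        raw = {"GG": p * p, "GC": 2 * p * q, "CC": q * q * (1.0 + self.hwe_deviation)}
        total = sum(raw.values())
        return {g: v / total for g, v in raw.items()}

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "CohortConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config fields: {sorted(unknown)}")
        return cls(**d).validate()

    @classmethod
    def from_file(cls, path: str | Path) -> "CohortConfig":
        """Load from YAML or JSON (decided by extension, YAML by default)."""
        path = Path(path)
        text = path.read_text()
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        if not isinstance(data, dict):
            raise ConfigError(f"config file {path} does not contain a mapping")
        return cls.from_dict(data)
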