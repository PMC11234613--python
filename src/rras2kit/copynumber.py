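"""RRAS2 genomic copy-number inference from qPCR and endpoint distance.

Two complementary readouts:

* the distance to the origin of the endpoint (VIC, FAM) point, a
  model-free proxy of amplifiable template compared across cohorts;
* the RRAS2/COX8A genomic qPCR ratio ``E^(Ct_ref - Ct_target)``,
  anchored so that the healthy-blood cohort's median ratio equals 1
  (assumed diploid: 2 copies of each gene per cell). Estimated copies
  are ``2 * normalized ratio``; samples are categorized as *gain*
  (ratio >= 1.5) or *amplified* (ratio >= 2.0), both bounds inclusive.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats as sps

CATEGORY_NORMAL = "normal"
CATEGORY_GAIN = "gain"
CATEGORY_AMPLIFIED = "amplified"

GAIN_THRESHOLD = 1.5
AMPLIFIED_THRESHOLD = 2.0


def aggregate_replicates(
    ct_table: pd.DataFrame,
    max_range: float = 1.0,
    by: tuple[str, ...] = ("sample_id", "gene"),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Mean Ct over determined replicates per (sample, gene).

    Ct values that are NaN (or the string ``"undetermined"`` in raw CSVs,
    coerced to NaN by the readers) are dropped; a (sample, gene) whose
    determined replicates span more than ``max_range`` cycles is flagged;
    one with no determined replicate at all is excluded and listed in the
    second return value.
    """
    required = set(by) | {"ct"}
    missing = required - set(ct_table.columns)
    if missing:
        raise ValueError(f"Ct table missing columns: {sorted(missing)}")
    df = ct_table.copy()
    df["ct"] = pd.to_numeric(df["ct"], errors="coerce")
    det = df["ct"].notna()
    if ((df.loc[det, "ct"] <= 0) | (df.loc[det, "ct"] > 45)).any():
        raise ValueError("determined Ct values must lie in (0, 45]")

    keys = list(by)
    grouped = df.groupby(keys, sort=True)["ct"]
    agg = grouped.agg(
        ct_mean="mean",
        ct_sd="std",
        n_determined="count",
        ct_range=lambda s: (s.max() - s.min()) if s.notna().any() else np.nan,
    ).reset_index()
    if "plate_id" in df.columns and "plate_id" not in keys:
        plates = df.groupby(keys, sort=True)["plate_id"].first().reset_index()
        agg = agg.merge(plates, on=keys)
    agg["range_flag"] = agg["ct_range"] > max_range

    excluded = agg[agg["n_determined"] == 0][keys].reset_index(drop=True)
    if len(excluded):
        warnings.warn(
            f"{len(excluded)} (sample, gene) group(s) with all replicates undetermined excluded"
        )
    agg = agg[agg["n_determined"] > 0].reset_index(drop=True)
    return agg, excluded


def raw_copy_ratio(
    mean_ct: pd.DataFrame,
    target: str = "RRAS2",
    reference: str = "COX8A",
    efficiency: float = 2.0,
) -> tuple[pd.DataFrame, list[str]]:
    """Per-sample relative abundance ``E^(Ct_reference - Ct_target)``.

    One cycle earlier on the target at efficiency 2 means twice the
    template. Samples lacking either gene are excluded and their IDs
    returned.
    """
    if efficiency <= 1:
        raise ValueError("efficiency must be > 1")
    wide = mean_ct.pivot_table(index="sample_id", columns="gene", values="ct_mean")
    for gene in (target, reference):
        if gene not in wide.columns:
            raise ValueError(f"gene {gene!r} absent from the Ct table")
    complete = wide[[target, reference]].dropna()
    excluded = sorted(set(wide.index) - set(complete.index))
    if excluded:
        warnings.warn(f"{len(excluded)} sample(s) missing a gene excluded: {excluded[:5]}...")
    out = pd.DataFrame(
        {
            "sample_id": complete.index,
            "raw_ratio": np.power(efficiency, complete[reference] - complete[target]).to_numpy(),
        }
    ).reset_index(drop=True)
    return out, excluded


def anchor_to_diploid(
    ratios: pd.DataFrame,
    reference_cohort: str = "healthy_blood",
    gain_threshold: float = GAIN_THRESHOLD,
    amplified_threshold: float = AMPLIFIED_THRESHOLD,
) -> pd.DataFrame:
    """Normalize raw ratios so the reference cohort's median is exactly 1.

    The healthy-blood cohort is assumed diploid (2 copies of RRAS2 and of
    COX8A per cell), so after anchoring ``est_copies = 2 * norm_ratio``.
    Anchoring is idempotent and invariant to any global scale factor.
    """
    required = {"sample_id", "cohort", "raw_ratio"}
    missing = required - set(ratios.columns)
    if missing:
        raise ValueError(f"ratio table missing columns: {sorted(missing)}")
    ref = ratios.loc[ratios["cohort"] == reference_cohort, "raw_ratio"]
    if ref.empty:
        raise ValueError(f"reference cohort {reference_cohort!r} is empty")
    anchor = float(ref.median())
    out = ratios.copy()
    out["norm_ratio"] = out["raw_ratio"] / anchor
    out["est_copies"] = 2.0 * out["norm_ratio"]
    out["category"] = np.select(
        [out["norm_ratio"] >= amplified_threshold, out["norm_ratio"] >= gain_threshold],
        [CATEGORY_AMPLIFIED, CATEGORY_GAIN],
        default=CATEGORY_NORMAL,
    )
    return out


def classify_amplification(
    records: pd.DataFrame,
    gain_threshold: float = GAIN_THRESHOLD,
    amplified_threshold: float = AMPLIFIED_THRESHOLD,
) -> pd.DataFrame:
    """Per-cohort fractions of samples with ratio >= 1.5 and >= 2.0.

    Both thresholds are inclusive; the >=1.5 fraction therefore contains
    the >=2.0 one.
    """
    if "norm_ratio" not in records.columns:
        raise ValueError("records must be anchored first (missing norm_ratio)")
    rows = []
    for cohort, sub in records.groupby("cohort", sort=True):
        n = len(sub)
        rows.append(
            {
                "cohort": cohort,
                "n": n,
                "frac_gain_or_higher": float((sub["norm_ratio"] >= gain_threshold).mean()),
                "frac_amplified": float((sub["norm_ratio"] >= amplified_threshold).mean()),
                "pct_gain_or_higher": 100.0 * float((sub["norm_ratio"] >= gain_threshold).mean()),
                "pct_amplified": 100.0 * float((sub["norm_ratio"] >= amplified_threshold).mean()),
            }
        )
    return pd.DataFrame(rows)


def distance_abundance_summary(
    polar: pd.DataFrame,
    reference_cohort: str = "healthy_blood",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-cohort distance-to-origin distribution and rank-sum comparisons.

    Distance to the origin grows with the amount of amplifiable template,
    so a cohort-level shift flags higher genomic RRAS2 abundance. Each
    non-reference cohort is compared to the reference with a two-sided
    Wilcoxon rank-sum (Mann-Whitney) test; distance distributions are
    heavy-tailed by construction, so ranks are preferred over a Gaussian
    model. The one-way ANOVA F across all cohorts is reported alongside.
    """
    df = polar[polar["callable"]] if "callable" in polar.columns else polar
    if "cohort" not in df.columns:
        raise ValueError("polar table lacks a 'cohort' column")
    summary_rows = []
    for cohort, sub in df.groupby("cohort", sort=True):
        d = sub["distance"].dropna()
        summary_rows.append(
            {
                "cohort": cohort,
                "n": len(d),
                "median": float(d.median()),
                "mean": float(d.mean()),
                "p10": float(d.quantile(0.10)),
                "p90": float(d.quantile(0.90)),
            }
        )
    summary = pd.DataFrame(summary_rows)

    ref = df.loc[df["cohort"] == reference_cohort, "distance"].dropna()
    if ref.empty:
        raise ValueError(f"reference cohort {reference_cohort!r} is empty")
    comp_rows = []
    groups_for_anova = []
    for cohort, sub in df.groupby("cohort", sort=True):
        d = sub["distance"].dropna()
        if len(d) >= 2:
            groups_for_anova.append(d.to_numpy())
        if cohort == reference_cohort:
            continue
        if len(d) < 2 or len(ref) < 2:
            warnings.warn(f"cohort {cohort!r} has <2 samples; comparison skipped")
            continue
        u, p = sps.mannwhitneyu(d, ref, alternative="two-sided")
        comp_rows.append(
            {
                "cohort": cohort,
                "reference": reference_cohort,
                "n": len(d),
                "median_ratio_vs_ref": float(d.median() / ref.median()),
                "rank_sum_U": float(u),
                "p_value": float(p),
            }
        )
    comparisons = pd.DataFrame(comp_rows)
    if len(groups_for_anova) >= 2:
        f, p = sps.f_oneway(*groups_for_anova)
        comparisons.attrs["anova_F"] = float(f)
        comparisons.attrs["anova_p"] = float(p)
    return summary, comparisons


def mad_outlier_filter(values: pd.Series, k: float = 5.0) -> pd.Series:
    """Boolean mask of values within median +/- k*MAD (robust outlier gate).

    Optional coarse stand-in for iterative robust-regression outlier
    removal; off by default everywhere.
    """
    med = values.median()
    mad = (values - med).abs().median()
    if mad == 0:
        return pd.Series(True, index=values.index)
    return (values - med).abs() <= k * mad
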