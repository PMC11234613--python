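"""Replicate aggregation, copy ratios, diploid anchoring and categories."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

from rras2kit.copynumber import (
    aggregate_replicates,
    anchor_to_diploid,
    classify_amplification,
    distance_abundance_summary,
    raw_copy_ratio,
)
from rras2kit.genotyping import polar_transform
from rras2kit.synthetic import simulate_cohort, simulate_genotypes, simulate_ct


def _ct(rows):
    return pd.DataFrame(rows, columns=["sample_id", "gene", "plate_id", "replicate", "ct"])


def test_replicate_mean_and_range_flag():
    table = _ct(
        [("a", "RRAS2", "P01", i, v) for i, v in enumerate((24.9, 25.0, 25.1), 1)]
        + [("b", "RRAS2", "P01", i, v) for i, v in enumerate((24.0, 26.0), 1)]
    )
    agg, excluded = aggregate_replicates(table)
    a = agg[agg["sample_id"] == "a"].iloc[0]
    b = agg[agg["sample_id"] == "b"].iloc[0]
    assert a["ct_mean"] == pytest.approx(25.0) and not a["range_flag"]
    assert b["ct_mean"] == pytest.approx(25.0) and b["range_flag"]
    assert excluded.empty


def test_undetermined_replicates_dropped_or_excluded():
    table = _ct(
        [("a", "RRAS2", "P01", 1, 24.0), ("a", "RRAS2", "P01", 2, np.nan),
         ("a", "RRAS2", "P01", 3, 25.0),
         ("b", "RRAS2", "P01", 1, np.nan), ("b", "RRAS2", "P01", 2, np.nan)]
    )
    with pytest.warns(UserWarning, match="undetermined"):
        agg, excluded = aggregate_replicates(table)
    assert agg["sample_id"].tolist() == ["a"]
    assert agg.iloc[0]["ct_mean"] == pytest.approx(24.5)  # mean of the two determined
    assert excluded["sample_id"].tolist() == ["b"]


def test_ct_out_of_range_rejected():
    with pytest.raises(ValueError, match="45"):
        aggregate_replicates(_ct([("a", "RRAS2", "P01", 1, 46.0)]))


def _mean_ct(pairs):
    # pairs: (sample, ct_rras2, ct_cox8a)
    rows = []
    for s, t, r in pairs:
        rows.append({"sample_id": s, "gene": "RRAS2", "ct_mean": t})
        rows.append({"sample_id": s, "gene": "COX8A", "ct_mean": r})
    return pd.DataFrame(rows)


def test_raw_ratio_equal_cts_give_one_and_one_cycle_gives_two():
    ratios, _ = raw_copy_ratio(_mean_ct([("a", 25.0, 25.0), ("b", 24.0, 25.0)]))
    assert ratios.set_index("sample_id").loc["a", "raw_ratio"] == pytest.approx(1.0)
    assert ratios.set_index("sample_id").loc["b", "raw_ratio"] == pytest.approx(2.0)


def test_raw_ratio_monotone_in_both_cts():
    base, _ = raw_copy_ratio(_mean_ct([("a", 25.0, 25.0)]))
    lower_target, _ = raw_copy_ratio(_mean_ct([("a", 24.5, 25.0)]))
    higher_ref, _ = raw_copy_ratio(_mean_ct([("a", 25.0, 25.5)]))
    assert lower_target["raw_ratio"].iloc[0] > base["raw_ratio"].iloc[0]
    assert higher_ref["raw_ratio"].iloc[0] > base["raw_ratio"].iloc[0]


def test_missing_gene_excludes_sample_with_log():
    mean_ct = pd.concat(
        [_mean_ct([("a", 25.0, 25.0)]),
         pd.DataFrame([{"sample_id": "b", "gene": "RRAS2", "ct_mean": 24.0}])]
    )
    with pytest.warns(UserWarning, match="missing a gene"):
        ratios, excluded = raw_copy_ratio(mean_ct)
    assert excluded == ["b"]
    assert ratios["sample_id"].tolist() == ["a"]


def _ratio_df(values, cohort="healthy_blood"):
    return pd.DataFrame(
        {"sample_id": [f"{cohort[0]}{i}" for i in range(len(values))],
         "cohort": cohort, "raw_ratio": values}
    )


def test_anchoring_sets_reference_median_to_exactly_one():
    anchored = anchor_to_diploid(_ratio_df([0.8, 1.0, 1.2]))
    assert anchored["norm_ratio"].median() == 1.0
    assert anchored["est_copies"].tolist() == pytest.approx([1.6, 2.0, 2.4])


@settings(derandomize=True, max_examples=30)
@given(scale=hst.floats(0.01, 100.0))
def test_anchoring_is_scale_invariant_and_idempotent(scale):
    base = _ratio_df([0.7, 0.9, 1.0, 1.1, 1.6])
    scaled = base.assign(raw_ratio=base["raw_ratio"] * scale)
    a1 = anchor_to_diploid(base)
    a2 = anchor_to_diploid(scaled)
    assert np.allclose(a1["norm_ratio"], a2["norm_ratio"])
    again = anchor_to_diploid(a1.assign(raw_ratio=a1["norm_ratio"]))
    assert np.allclose(again["norm_ratio"], a1["norm_ratio"])


def test_empty_reference_cohort_rejected():
    with pytest.raises(ValueError, match="reference cohort"):
        anchor_to_diploid(_ratio_df([1.0, 2.0], cohort="tumor"))


def test_category_boundaries_inclusive():
    df = pd.concat([_ratio_df([1.0]), _ratio_df([1.49, 1.50, 2.00], cohort="tumor")])
    anchored = anchor_to_diploid(df)
    cats = anchored[anchored["cohort"] == "tumor"]["category"].tolist()
    assert cats == ["normal", "gain", "amplified"]


def test_fraction_counting():
    df = pd.concat([_ratio_df([1.0]), _ratio_df([1.0] * 8 + [1.6, 2.1], cohort="tumor")])
    fr = classify_amplification(anchor_to_diploid(df))
    tumor = fr[fr["cohort"] == "tumor"].iloc[0]
    assert tumor["frac_gain_or_higher"] == pytest.approx(0.2)
    assert tumor["frac_amplified"] == pytest.approx(0.1)


def test_fractions_weakly_monotone_in_thresholds():
    df = pd.concat([_ratio_df([1.0]), _ratio_df(list(np.linspace(0.8, 2.6, 40)), cohort="tumor")])
    anchored = anchor_to_diploid(df)
    lo = classify_amplification(anchored, gain_threshold=1.3, amplified_threshold=1.8)
    hi = classify_amplification(anchored, gain_threshold=1.6, amplified_threshold=2.2)
    for col in ("frac_gain_or_higher", "frac_amplified"):
        assert (hi[col] <= lo[col] + 1e-12).all()


def test_zero_noise_recovers_true_copies_exactly(noise_free_config):
    truth = simulate_genotypes(noise_free_config)
    truth = truth[truth["cohort"] != "anchor_normal"].reset_index(drop=True)
    ct = pd.concat(
        [simulate_ct(truth, noise_free_config, "genomic_RRAS2"),
         simulate_ct(truth, noise_free_config, "genomic_COX8A")]
    )
    agg, _ = aggregate_replicates(ct)
    ratios, _ = raw_copy_ratio(agg)
    ratios = ratios.merge(truth[["sample_id", "cohort", "true_copies"]], on="sample_id")
    anchored = anchor_to_diploid(ratios)
    assert np.allclose(anchored["est_copies"], anchored["true_copies"], atol=1e-9)


def test_true_copies_three_gives_raw_ratio_1_5(noise_free_config):
    truth = simulate_genotypes(noise_free_config).head(6).copy()
    truth["true_copies"] = 3.0
    ct = pd.concat(
        [simulate_ct(truth, noise_free_config, "genomic_RRAS2"),
         simulate_ct(truth, noise_free_config, "genomic_COX8A")]
    )
    agg, _ = aggregate_replicates(ct)
    ratios, _ = raw_copy_ratio(agg)
    assert np.allclose(ratios["raw_ratio"], 1.5)


# ---------------------------------------------------------------------------
# distance comparison
# ---------------------------------------------------------------------------

def _polar(distances, cohort):
    rad = np.radians(45.0)
    pairs = [(d * np.cos(rad), d * np.sin(rad)) for d in distances]
    df = pd.DataFrame(
        [{"sample_id": f"{cohort}{i}", "cohort": cohort, "vic": v, "fam": f}
         for i, (v, f) in enumerate(pairs)]
    )
    return polar_transform(df)


def test_identical_cohorts_give_maximal_p_and_equal_medians():
    d = [1.0, 1.1, 1.2, 1.3, 1.4]
    polar = pd.concat([_polar(d, "healthy_blood"), _polar(d, "tumor")])
    summary, comparisons = distance_abundance_summary(polar)
    meds = summary.set_index("cohort")["median"]
    assert meds["tumor"] == pytest.approx(meds["healthy_blood"])
    assert comparisons.iloc[0]["p_value"] > 0.9


def test_doubled_distances_double_the_median():
    d = np.array([1.0, 1.5, 2.0, 2.5])
    polar = pd.concat([_polar(d, "healthy_blood"), _polar(2 * d, "tumor")])
    summary, _ = distance_abundance_summary(polar)
    meds = summary.set_index("cohort")["median"]
    assert meds["tumor"] == pytest.approx(2 * meds["healthy_blood"])


def test_tiny_cohort_comparison_skipped_with_warning():
    polar = pd.concat([_polar([1.0, 1.1, 1.2], "healthy_blood"), _polar([5.0], "tumor")])
    with pytest.warns(UserWarning, match="skipped"):
        _, comparisons = distance_abundance_summary(polar)
    assert comparisons.empty


def test_higher_copy_cohort_has_longer_median_distance():
    """Tumor cohorts simulated with copy gains sit farther from the origin."""
    wins = 0
    n_rep = 20
    from rras2kit.config import CohortConfig

    for rep in range(n_rep):
        cfg = CohortConfig(
            n_healthy=40, n_patient_blood=0, n_tumor=40, n_anchor=0,
            copies_per_group={"healthy_blood": 2.0, "patient_blood": 2.0, "tumor": 3.0},
            frac_gain=0.0, frac_amplified=0.0, seed=100 + rep,
        )
        tables = simulate_cohort(cfg)
        polar = polar_transform(tables["fluorescence"])
        summary, _ = distance_abundance_summary(polar)
        meds = summary.set_index("cohort")["median"]
        wins += meds["tumor"] > meds["healthy_blood"]
    assert wins >= int(0.95 * n_rep)
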