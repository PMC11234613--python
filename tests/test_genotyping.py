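"""Polar transform geometry and theta clustering."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

from rras2kit.genotyping import (
    NO_CALL,
    cluster_genotypes,
    genotype_counts,
    kmeans_1d,
    lloyd_kmeans_1d,
    polar_transform,
)
from tests.oracles import best_contiguous_three_partition


def _points(pairs, cohort="healthy_blood"):
    return pd.DataFrame(
        [{"sample_id": f"S{i}", "cohort": cohort, "vic": v, "fam": f} for i, (v, f) in enumerate(pairs)]
    )


def test_polar_transform_known_geometry():
    out = polar_transform(_points([(1, 0), (0, 1), (3, 4)]))
    assert out["theta_deg"].tolist() == pytest.approx([0.0, 90.0, np.degrees(np.arctan2(4, 3))])
    assert out["theta_deg"].iloc[2] == pytest.approx(53.130, abs=1e-3)
    assert out["distance"].tolist() == pytest.approx([1.0, 1.0, 5.0])


def test_background_subtraction_floors_at_zero_and_flags_uncallable():
    with pytest.warns(UserWarning, match="uncallable"):
        out = polar_transform(_points([(5, 3), (1, 1)]), background=(2, 2))
    assert out["callable"].tolist() == [True, False]
    assert out["theta_deg"].iloc[0] == pytest.approx(np.degrees(np.arctan2(1, 3)))
    assert np.isnan(out["theta_deg"].iloc[1])


def test_negative_signal_rejected():
    with pytest.raises(ValueError, match="nonnegative"):
        polar_transform(_points([(-1, 2)]))


def test_missing_column_named_in_error():
    with pytest.raises(ValueError, match="fam"):
        polar_transform(pd.DataFrame({"sample_id": ["a"], "vic": [1.0]}))


@settings(derandomize=True, max_examples=50)
@given(
    vic=hst.floats(0.01, 1e5),
    fam=hst.floats(0.01, 1e5),
    scale=hst.floats(1e-3, 1e3),
)
def test_theta_gain_invariant_distance_linear(vic, fam, scale):
    """theta is invariant under common positive rescaling; distance scales."""
    base = polar_transform(_points([(vic, fam)]))
    scaled = polar_transform(_points([(vic * scale, fam * scale)]))
    assert scaled["theta_deg"].iloc[0] == pytest.approx(base["theta_deg"].iloc[0], abs=1e-9)
    assert scaled["distance"].iloc[0] == pytest.approx(base["distance"].iloc[0] * scale, rel=1e-12)


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------

def _polar_from_theta(thetas):
    # unit-distance points at the given angles
    rad = np.radians(np.asarray(thetas, dtype=float))
    return polar_transform(_points(list(zip(np.cos(rad), np.sin(rad)))))


def test_well_separated_triplets_call_all_three_genotypes():
    polar = _polar_from_theta([5, 6, 7, 44, 45, 46, 84, 85, 86])
    calls, report = cluster_genotypes(polar)
    assert calls["genotype"].tolist() == ["GG"] * 3 + ["GC"] * 3 + ["CC"] * 3
    assert report.empty_genotypes == []


def test_degenerate_single_cluster_reports_gc_only_with_warning():
    polar = _polar_from_theta([44.2, 44.6, 45.0, 45.4, 45.8])
    with pytest.warns(UserWarning, match="empty"):
        calls, report = cluster_genotypes(polar)
    assert set(calls["genotype"]) == {"GC"}
    assert sorted(report.empty_genotypes) == ["CC", "GG"]


def test_too_few_callable_points_rejected():
    polar = _polar_from_theta([10, 80])
    with pytest.raises(ValueError, match="callable"):
        cluster_genotypes(polar)


def test_threshold_mode_uses_fixed_gates():
    polar = _polar_from_theta([10, 40, 80])
    calls, _ = cluster_genotypes(polar, method="threshold", thresholds=(30, 60))
    assert calls["genotype"].tolist() == ["GG", "GC", "CC"]


def test_low_margin_points_become_no_call():
    # threshold mode: 29 deg is within 2 deg of the 30-deg gate
    polar = _polar_from_theta([5, 29, 45, 85])
    calls, _ = cluster_genotypes(polar, method="threshold", thresholds=(30, 60), no_call_margin=2.0)
    assert calls["genotype"].tolist() == ["GG", NO_CALL, "GC", "CC"]

    # kmeans mode: every call sits at least the margin away from a boundary
    polar = _polar_from_theta([5, 6, 7, 24, 44, 45, 46, 84, 85, 86])
    calls, report = cluster_genotypes(polar, no_call_margin=2.0)
    called = calls[calls["genotype"] != NO_CALL]
    assert (called["margin"] >= 2.0).all()


def test_kmeans_matches_exhaustive_contiguous_partition_oracle():
    """Exact 1-D k-means equals brute-force search over 3-partitions (n<=12)."""
    rng = np.random.default_rng(42)
    for _ in range(60):
        n = rng.integers(3, 13)
        theta = rng.uniform(0, 90, size=n)
        centers, labels = kmeans_1d(theta, 3)
        sse_impl = sum(
            ((theta[labels == c] - theta[labels == c].mean()) ** 2).sum()
            for c in range(3) if (labels == c).any()
        )
        sse_oracle, _ = best_contiguous_three_partition(theta)
        assert sse_impl == pytest.approx(sse_oracle, abs=1e-9)


def test_lloyd_objective_never_increases():
    rng = np.random.default_rng(0)
    theta = np.concatenate([rng.normal(10, 3, 40), rng.normal(45, 3, 40), rng.normal(80, 3, 40)])
    _, _, history = lloyd_kmeans_1d(theta, 3)
    assert all(b <= a + 1e-9 for a, b in zip(history, history[1:]))


def test_calls_invariant_under_gain_change_and_reordering():
    rng = np.random.default_rng(1)
    rad = np.radians(np.concatenate([rng.normal(8, 2, 20), rng.normal(45, 2, 20), rng.normal(82, 2, 20)]))
    d = rng.uniform(0.5, 2.0, len(rad))
    pairs = list(zip(d * np.cos(rad), d * np.sin(rad)))
    base, _ = cluster_genotypes(polar_transform(_points(pairs)))

    scaled, _ = cluster_genotypes(polar_transform(_points([(v * 7.3, f * 7.3) for v, f in pairs])))
    assert scaled["genotype"].tolist() == base["genotype"].tolist()

    perm = np.random.default_rng(2).permutation(len(pairs))
    shuffled, _ = cluster_genotypes(polar_transform(_points([pairs[i] for i in perm])))
    by_theta_base = base.sort_values("theta_deg")["genotype"].tolist()
    by_theta_shuf = shuffled.sort_values("theta_deg")["genotype"].tolist()
    assert by_theta_base == by_theta_shuf


# ---------------------------------------------------------------------------
# counting
# ---------------------------------------------------------------------------

def test_genotype_counts_pure_gg():
    calls = pd.DataFrame({"sample_id": [f"S{i}" for i in range(10)],
                          "genotype": ["GG"] * 10, "cohort": ["healthy_blood"] * 10})
    counts = genotype_counts(calls)
    row = counts.iloc[0]
    assert (row["n_GG"], row["n_GC"], row["n_CC"]) == (10, 0, 0)
    assert (row["pct_GG"], row["pct_GC"], row["pct_CC"]) == (100.0, 0.0, 0.0)


def test_empty_cohort_yields_zero_row_not_error():
    calls = pd.DataFrame({"sample_id": ["a"], "genotype": ["GG"], "cohort": ["tumor"]})
    counts = genotype_counts(calls, expected_cohorts=["tumor", "healthy_blood"])
    healthy = counts[counts["cohort"] == "healthy_blood"].iloc[0]
    assert healthy["n_called"] == 0 and healthy["pct_GG"] == 0.0


def test_unknown_cohort_label_rejected():
    calls = pd.DataFrame({"sample_id": ["a"], "genotype": ["GG"], "cohort": ["plasma"]})
    with pytest.raises(ValueError, match="unknown cohort"):
        genotype_counts(calls, expected_cohorts=["tumor"])


def test_no_call_tallied_separately():
    calls = pd.DataFrame({"sample_id": ["a", "b", "c"],
                          "genotype": ["GG", NO_CALL, "CC"], "cohort": ["tumor"] * 3})
    row = genotype_counts(calls).iloc[0]
    assert row["n_NO_CALL"] == 1 and row["n_called"] == 2
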