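"""Population-genetic and association statistics for the rs8570 marker.

Implements allele-frequency estimation, an exact Hardy-Weinberg test, the
GG-vs-CC case-control Fisher exact test, and the genotype-dose versus
expression association.

Both exact tests are computed in exact integer arithmetic: the two-sided
p-value is the total probability of outcomes no more likely than the one
observed, and probability comparisons are made on integer numerators over
a common denominator, so ties are resolved exactly rather than to
floating-point tolerance.
"""

from __future__ import annotations

import math
import warnings
from math import comb

import numpy as np
import pandas as pd
from scipy import stats as sps

from rras2kit.config import C_DOSE


def allele_frequencies(n_gg: int, n_gc: int, n_cc: int) -> dict:
    """G/C allele frequencies with the binomial standard error.

    ``q_C = (2 n_CC + n_GC) / 2n``; s.e. = sqrt(p q / 2n) treating the 2n
    alleles as independent draws.
    """
    for name, v in (("n_gg", n_gg), ("n_gc", n_gc), ("n_cc", n_cc)):
        if v < 0:
            raise ValueError(f"{name} must be >= 0")
    n = n_gg + n_gc + n_cc
    if n == 0:
        raise ValueError("empty genotype table")
    q = (2 * n_cc + n_gc) / (2 * n)
    p = 1.0 - q
    return {
        "n": n,
        "p_G": p,
        "q_C": q,
        "se": math.sqrt(p * q / (2 * n)),
    }


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test
# ---------------------------------------------------------------------------

def _hwe_weight(n: int, n_c_alleles: int, h: int) -> int:
    """Integer weight proportional to P(heterozygotes = h | n, allele count).

    Conditional on the allele counts, the probability of h heterozygotes
    is proportional to the multinomial coefficient times 2^h.
    """
    c = (n_c_alleles - h) // 2
    g = n - h - c
    return comb(n, g) * comb(n - g, h) * (1 << h)


def hwe_exact_test(n_gg: int, n_gc: int, n_cc: int) -> dict:
    """Exact test of Hardy-Weinberg proportions.

    Conditional on the observed allele counts, sums the probabilities of
    every heterozygote count whose probability does not exceed that of the
    observed configuration (two-sided by probability ordering). Also
    reports the HWE-expected genotype counts and the 1-df chi-square.
    """
    n = n_gg + n_gc + n_cc
    if n < 1:
        raise ValueError("empty genotype table")
    n_c = 2 * n_cc + n_gc

    h_min = n_c % 2
    h_max = min(n_c, 2 * n - n_c)
    support = range(h_min, h_max + 1, 2)
    weights = {h: _hwe_weight(n, n_c, h) for h in support}
    total = sum(weights.values())
    w_obs = weights[n_gc]
    p_exact = sum(w for w in weights.values() if w <= w_obs) / total

    q = n_c / (2 * n)
    p = 1.0 - q
    expected = {"GG": n * p * p, "GC": 2 * n * p * q, "CC": n * q * q}
    chi2 = 0.0
    for obs, exp in ((n_gg, expected["GG"]), (n_gc, expected["GC"]), (n_cc, expected["CC"])):
        if exp > 0:
            chi2 += (obs - exp) ** 2 / exp
    chi2_p = float(sps.chi2.sf(chi2, df=1)) if chi2 > 0 else 1.0

    return {
        "test": "HWE exact",
        "n": n,
        "observed": {"GG": n_gg, "GC": n_gc, "CC": n_cc},
        "expected": expected,
        "p_value": min(p_exact, 1.0),
        "chi2": chi2,
        "chi2_p": chi2_p,
    }


# ---------------------------------------------------------------------------
# Fisher exact test (GG vs CC homozygotes)
# ---------------------------------------------------------------------------

def _fisher_two_sided_exact(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p for [[a, b], [c, d]] in exact integer arithmetic.

    Conditional on all margins, cell ``a`` is hypergeometric; the p-value
    sums P(table) over tables whose probability is at most the observed
    table's, compared exactly on integer numerators.
    """
    r1, r2, c1 = a + b, c + d, a + c
    lo, hi = max(0, c1 - r2), min(r1, c1)
    num = {k: comb(r1, k) * comb(r2, c1 - k) for k in range(lo, hi + 1)}
    total = sum(num.values())
    w_obs = num[a]
    return sum(w for w in num.values() if w <= w_obs) / total


def fisher_gg_cc(case_counts: tuple[int, int], control_counts: tuple[int, int]) -> dict:
    """Case-control Fisher exact test on GG vs CC homozygotes.

    Heterozygotes are dropped; the 2x2 table is (rows: case, control;
    columns: CC, GG). The odds ratio is
    ``(CC_case * GG_control) / (GG_case * CC_control)``, with a 0.5
    continuity correction (flagged) when any cell is zero.

    Parameters are ``(n_GG, n_CC)`` per group.
    """
    gg_case, cc_case = case_counts
    gg_ctrl, cc_ctrl = control_counts
    cells = (gg_case, cc_case, gg_ctrl, cc_ctrl)
    if any(v < 0 for v in cells):
        raise ValueError("counts must be >= 0")
    if sum(cells) == 0:
        raise ValueError("all four cells are zero")
    if gg_case + cc_case == 0 or gg_ctrl + cc_ctrl == 0:
        raise ValueError("each group needs at least one homozygote")

    p = _fisher_two_sided_exact(cc_case, gg_case, cc_ctrl, gg_ctrl)

    continuity = any(v == 0 for v in cells)
    if continuity:
        cc_case_, gg_case_, cc_ctrl_, gg_ctrl_ = (v + 0.5 for v in (cc_case, gg_case, cc_ctrl, gg_ctrl))
    else:
        cc_case_, gg_case_, cc_ctrl_, gg_ctrl_ = cc_case, gg_case, cc_ctrl, gg_ctrl
    odds_ratio = (cc_case_ * gg_ctrl_) / (gg_case_ * cc_ctrl_)

    return {
        "test": "Fisher exact GG vs CC",
        "table": {"case": {"GG": gg_case, "CC": cc_case}, "control": {"GG": gg_ctrl, "CC": cc_ctrl}},
        "odds_ratio": odds_ratio,
        "continuity_corrected": continuity,
        "p_value": min(p, 1.0),
    }


def genotype_test_2x3(case_counts: tuple[int, int, int], control_counts: tuple[int, int, int]) -> dict:
    """Chi-square test over the full 2x3 genotype contingency table."""
    table = np.array([case_counts, control_counts], dtype=float)
    chi2, p, dof, expected = sps.chi2_contingency(table)
    return {
        "test": "chi-square 2x3 genotype",
        "chi2": float(chi2),
        "dof": int(dof),
        "p_value": float(p),
        "expected": expected.tolist(),
    }


# ---------------------------------------------------------------------------
# genotype-dose vs expression
# ---------------------------------------------------------------------------

def one_way_anova(groups: list[np.ndarray]) -> dict:
    """One-way ANOVA from the between/within sum-of-squares decomposition."""
    groups = [np.asarray(g, dtype=float) for g in groups if len(g) > 0]
    if len(groups) < 2:
        raise ValueError("ANOVA needs at least two groups")
    all_vals = np.concatenate(groups)
    grand = all_vals.mean()
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df_between = len(groups) - 1
    df_within = len(all_vals) - len(groups)
    if df_within <= 0:
        raise ValueError("ANOVA needs more observations than groups")
    if ss_within == 0.0:
        if ss_between == 0.0:
            return {"F": 0.0, "p_value": 1.0, "ss_between": 0.0, "ss_within": 0.0,
                    "df_between": df_between, "df_within": df_within}
        return {"F": float("inf"), "p_value": 0.0, "ss_between": float(ss_between),
                "ss_within": 0.0, "df_between": df_between, "df_within": df_within}
    f = (ss_between / df_between) / (ss_within / df_within)
    return {
        "F": float(f),
        "p_value": float(sps.f.sf(f, df_between, df_within)),
        "ss_between": float(ss_between),
        "ss_within": float(ss_within),
        "df_between": df_between,
        "df_within": df_within,
    }


def genotype_expression_association(
    calls: pd.DataFrame,
    expression_records: pd.DataFrame,
    tukey: bool = True,
) -> dict:
    """Does expression rise with the C-allele dose?

    Joins genotype calls with relative-expression records, summarizes
    expression per genotype (mean +/- s.e.m.), runs a one-way ANOVA
    (first-principles sums of squares) across genotype groups, the
    Spearman rank correlation of C-allele dose (0/1/2) with expression,
    and optionally Tukey-adjusted pairwise contrasts.
    """
    merged = calls.merge(expression_records, on="sample_id")
    merged = merged[merged["genotype"].isin(C_DOSE)]
    if merged.empty:
        raise ValueError("no called sample with an expression record")

    groups, summaries = [], []
    for genotype in ("GG", "GC", "CC"):
        vals = merged.loc[merged["genotype"] == genotype, "rel_expr"].to_numpy(dtype=float)
        if len(vals) < 2:
            if len(vals) > 0:
                warnings.warn(f"genotype group {genotype} has <2 samples; dropped from ANOVA")
            elif genotype in merged["genotype"].values:
                pass
            else:
                warnings.warn(f"genotype group {genotype} absent; dropped")
            continue
        groups.append(vals)
        summaries.append(
            {
                "genotype": genotype,
                "n": len(vals),
                "mean": float(vals.mean()),
                "sem": float(vals.std(ddof=1) / math.sqrt(len(vals))),
            }
        )
    if len(groups) < 2:
        raise ValueError("need at least two genotype groups with >=2 samples")

    anova = one_way_anova(groups)

    dose = merged["genotype"].map(C_DOSE).to_numpy(dtype=float)
    expr = merged["rel_expr"].to_numpy(dtype=float)
    if np.ptp(dose) == 0 or np.ptp(expr) == 0:
        rho, rho_p = 0.0, 1.0
    else:
        rho, rho_p = sps.spearmanr(dose, expr)
        rho, rho_p = float(rho), float(rho_p)

    result = {
        "per_genotype": summaries,
        "anova": anova,
        "dose_rank_correlation": {"rho": rho, "p_value": rho_p},
    }
    if tukey and len(groups) >= 2 and anova["ss_within"] > 0:
        from statsmodels.stats.multicomp import pairwise_tukeyhsd

        kept = {s["genotype"] for s in summaries}
        sub = merged[merged["genotype"].isin(kept)]
        res = pairwise_tukeyhsd(sub["rel_expr"].to_numpy(dtype=float), sub["genotype"].to_numpy())
        result["tukey"] = [
            {
                "group1": str(r[0]),
                "group2": str(r[1]),
                "meandiff": float(r[2]),
                "p_adj": float(r[3]),
                "reject": bool(r[6]),
            }
            for r in res.summary().data[1:]
        ]
    return result
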