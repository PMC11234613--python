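"""Endpoint allelic discrimination: polar transform and genotype clustering.

A TaqMan-style genotyping assay reports, per sample, the endpoint
fluorescence of two allele-specific probes: VIC for the G allele (x axis)
and FAM for the C allele (y axis). Each sample's point is summarized in
polar coordinates: the angle theta to the x axis encodes the allele ratio
(GG near 0 degrees, GC near 45, CC near 90) and the distance to the
origin the total amplifiable template, a copy-number proxy.

Genotypes are called by clustering theta into three groups. The default
clusterer is exact 1-D k-means: because optimal 1-D clusters are
contiguous on the sorted axis, the global optimum is found by dynamic
programming over contiguous partitions — fully deterministic and
independent of initialization. A quantile-initialized Lloyd iteration and
a fixed-threshold gate are also provided.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

GENOTYPE_BY_RANK = ("GG", "GC", "CC")
NO_CALL = "NO_CALL"

#: canonical theta bands used to label clusters when fewer than 3 survive
_CANONICAL_BANDS = ((0.0, 30.0, "GG"), (30.0, 60.0, "GC"), (60.0, 90.01, "CC"))


def polar_transform(points: pd.DataFrame, background: tuple[float, float] | None = None) -> pd.DataFrame:
    """Convert (vic, fam) endpoint signals to polar coordinates.

    Parameters
    ----------
    points
        DataFrame with columns ``sample_id, vic, fam`` (extra columns such
        as ``cohort`` are carried through).
    background
        Optional ``(vic0, fam0)`` no-template background, subtracted and
        floored at zero before the transform.

    Returns
    -------
    DataFrame with added columns ``theta_deg`` (angle to the VIC axis, in
    [0, 90]), ``distance`` (Euclidean distance to the origin) and
    ``callable`` (False where both signals are zero after subtraction;
    such samples get NaN coordinates and are excluded from clustering).
    """
    required = {"sample_id", "vic", "fam"}
    missing = required - set(points.columns)
    if missing:
        raise ValueError(f"fluorescence table missing columns: {sorted(missing)}")
    out = points.copy()
    vic = out["vic"].to_numpy(dtype=float)
    fam = out["fam"].to_numpy(dtype=float)
    if (vic < 0).any() or (fam < 0).any():
        raise ValueError("fluorescence signals must be nonnegative")
    if background is not None:
        vic = np.maximum(vic - background[0], 0.0)
        fam = np.maximum(fam - background[1], 0.0)
    callable_ = (vic > 0) | (fam > 0)
    theta = np.degrees(np.arctan2(fam, vic))
    dist = np.hypot(vic, fam)
    out["theta_deg"] = np.where(callable_, theta, np.nan)
    out["distance"] = np.where(callable_, dist, np.nan)
    out["callable"] = callable_
    n_uncallable = int((~callable_).sum())
    if n_uncallable:
        warnings.warn(f"{n_uncallable} sample(s) uncallable (zero signal in both channels)")
    return out


# ---------------------------------------------------------------------------
# 1-D k-means
# ---------------------------------------------------------------------------

def kmeans_1d(values: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Globally optimal 1-D k-means by dynamic programming.

    Optimal clusters of 1-D k-means are contiguous intervals of the sorted
    values, so an O(n^2 k) DP over contiguous partitions finds the exact
    optimum. Returns ``(centers, labels)`` with centers ascending and
    labels in the original order. Ties between equal-cost partitions break
    toward earlier boundaries, deterministically.
    """
    values = np.asarray(values, dtype=float)
    n = len(values)
    if n < k:
        raise ValueError(f"need at least k={k} points, got {n}")
    order = np.argsort(values, kind="stable")
    x = values[order]

    # prefix sums for O(1) interval SSE
    ps = np.concatenate([[0.0], np.cumsum(x)])
    ps2 = np.concatenate([[0.0], np.cumsum(x * x)])

    def sse(i: int, j: int) -> float:
        # SSE of x[i:j]
        s, s2, m = ps[j] - ps[i], ps2[j] - ps2[i], j - i
        return max(s2 - s * s / m, 0.0)

    INF = float("inf")
    cost = np.full((k + 1, n + 1), INF)
    split = np.zeros((k + 1, n + 1), dtype=int)
    cost[0, 0] = 0.0
    for c in range(1, k + 1):
        for j in range(c, n + 1):
            best, best_i = INF, c - 1
            for i in range(c - 1, j):
                v = cost[c - 1, i] + sse(i, j)
                if v < best - 1e-15:
                    best, best_i = v, i
            cost[c, j] = best
            split[c, j] = best_i

    # backtrack boundaries
    bounds = [n]
    j = n
    for c in range(k, 0, -1):
        j = split[c, j]
        bounds.append(j)
    bounds = bounds[::-1]

    labels_sorted = np.empty(n, dtype=int)
    centers = np.empty(k)
    for c in range(k):
        i, j = bounds[c], bounds[c + 1]
        labels_sorted[i:j] = c
        centers[c] = x[i:j].mean()
    labels = np.empty(n, dtype=int)
    labels[order] = labels_sorted
    return centers, labels


def lloyd_kmeans_1d(
    values: np.ndarray,
    k: int = 3,
    init_quantiles: tuple[float, ...] = (0.1, 0.5, 0.9),
    max_iter: int = 200,
) -> tuple[np.ndarray, np.ndarray, list[float]]:
    """Quantile-initialized Lloyd iteration on one dimension.

    Returns ``(centers, labels, objective_history)``; the objective (total
    within-cluster SSE) is non-increasing across iterations. Provided as
    the classical reference algorithm; :func:`kmeans_1d` is the production
    path because it is globally optimal.
    """
    values = np.asarray(values, dtype=float)
    if len(values) < k:
        raise ValueError(f"need at least k={k} points, got {len(values)}")
    centers = np.quantile(values, init_quantiles[:k])
    history: list[float] = []
    labels = np.zeros(len(values), dtype=int)
    for _ in range(max_iter):
        d = np.abs(values[:, None] - centers[None, :])
        labels = d.argmin(axis=1)
        history.append(float((d[np.arange(len(values)), labels] ** 2).sum()))
        new = centers.copy()
        for c in range(k):
            if (labels == c).any():
                new[c] = values[labels == c].mean()
        if np.allclose(new, centers):
            break
        centers = new
    order = np.argsort(centers, kind="stable")
    remap = np.empty(k, dtype=int)
    remap[order] = np.arange(k)
    return centers[order], remap[labels], history


# ---------------------------------------------------------------------------
# genotype calling
# ---------------------------------------------------------------------------

@dataclass
class ClusterReport:
    """What the clusterer did: surviving centers and empty classes."""

    centers_deg: list[float]
    genotype_of_cluster: list[str]
    empty_genotypes: list[str]
    n_uncallable: int
    boundaries_deg: list[float]


def _label_clusters(centers: np.ndarray, min_separation: float) -> tuple[np.ndarray, list[str], list[str]]:
    """Merge centers closer than ``min_separation`` and map to genotypes.

    With three surviving clusters the mapping is by theta rank
    (GG < GC < CC). When clusters merge, each survivor is labelled by the
    canonical theta band containing its center, so the squeezed-out
    genotype class is reported empty rather than split arbitrarily.
    """
    merged = [[c] for c in centers]
    changed = True
    while changed and len(merged) > 1:
        changed = False
        for i in range(len(merged) - 1):
            if abs(np.mean(merged[i + 1]) - np.mean(merged[i])) < min_separation:
                merged[i] = merged[i] + merged.pop(i + 1)
                changed = True
                break
    final_centers = np.array([np.mean(g) for g in merged])

    if len(final_centers) == len(centers) == 3:
        names = list(GENOTYPE_BY_RANK)
    else:
        names = []
        for c in final_centers:
            band = next(name for lo, hi, name in _CANONICAL_BANDS if lo <= c < hi)
            while band in names:  # collision: push to the next rank
                idx = GENOTYPE_BY_RANK.index(band) + 1
                if idx >= 3:
                    break
                band = GENOTYPE_BY_RANK[idx]
            names.append(band)
    empty = [g for g in GENOTYPE_BY_RANK if g not in names]
    if empty:
        warnings.warn(
            f"cluster centers {np.round(final_centers, 2).tolist()} closer than "
            f"{min_separation} deg; genotype class(es) {empty} reported empty"
        )
    return final_centers, names, empty


def cluster_genotypes(
    polar: pd.DataFrame,
    k: int = 3,
    method: str = "kmeans",
    thresholds: tuple[float, float] | None = None,
    init_quantiles: tuple[float, ...] = (0.1, 0.5, 0.9),
    min_separation: float = 5.0,
    no_call_margin: float = 2.0,
) -> tuple[pd.DataFrame, ClusterReport]:
    """Call GG/GC/CC genotypes from the theta angle.

    Parameters
    ----------
    polar
        Output of :func:`polar_transform` (needs ``theta_deg, callable``).
    method
        ``"kmeans"`` (exact DP, default), ``"lloyd"`` (quantile-initialized
        Lloyd) or ``"threshold"`` (fixed gates; requires ``thresholds``).
    thresholds
        ``(t1, t2)`` in degrees for threshold mode: theta < t1 -> GG,
        t1 <= theta < t2 -> GC, else CC.
    min_separation
        Minimum distance between adjacent cluster centers (degrees); closer
        centers are merged and the squeezed-out class reported empty.
    no_call_margin
        Calls closer than this (degrees) to a cluster boundary become
        NO_CALL, mirroring instrument "undetermined" gates.

    Returns
    -------
    (calls, report)
        ``calls`` has columns ``sample_id, genotype, cluster_index,
        margin, theta_deg`` (+ carried columns); uncallable samples are
        NO_CALL with NaN margin.
    """
    df = polar.copy()
    mask = df["callable"].to_numpy(dtype=bool)
    theta = df.loc[mask, "theta_deg"].to_numpy(dtype=float)

    if method == "threshold":
        if thresholds is None:
            raise ValueError("threshold mode requires thresholds=(t1, t2)")
        t1, t2 = thresholds
        if not 0 <= t1 < t2 <= 90:
            raise ValueError("thresholds must satisfy 0 <= t1 < t2 <= 90")
        boundaries = np.array([t1, t2])
        labels = np.digitize(theta, boundaries)
        names = list(GENOTYPE_BY_RANK)
        centers = np.array([
            theta[labels == c].mean() if (labels == c).any() else np.nan for c in range(3)
        ])
        empty = [names[c] for c in range(3) if not (labels == c).any()]
    elif method in ("kmeans", "lloyd"):
        if mask.sum() < k:
            raise ValueError(f"need at least {k} callable points, got {int(mask.sum())}")
        if method == "kmeans":
            centers, labels = kmeans_1d(theta, k)
        else:
            centers, labels, _ = lloyd_kmeans_1d(theta, k, init_quantiles)
        centers, names, empty = _label_clusters(centers, min_separation)
        if len(centers) < k:
            # reassign to surviving centers
            labels = np.abs(theta[:, None] - centers[None, :]).argmin(axis=1)
        boundaries = (centers[:-1] + centers[1:]) / 2.0 if len(centers) > 1 else np.array([])
    else:
        raise ValueError(f"unknown method {method!r}")

    if len(boundaries):
        margin = np.abs(theta[:, None] - boundaries[None, :]).min(axis=1)
    else:
        margin = np.full(len(theta), np.inf)

    genotype = np.array([names[c] for c in labels], dtype=object)
    genotype[margin < no_call_margin] = NO_CALL

    df["genotype"] = NO_CALL
    df["cluster_index"] = -1
    df["margin"] = np.nan
    df.loc[mask, "genotype"] = genotype
    df.loc[mask, "cluster_index"] = labels
    df.loc[mask, "margin"] = margin

    report = ClusterReport(
        centers_deg=[float(c) for c in centers],
        genotype_of_cluster=list(names),
        empty_genotypes=list(empty),
        n_uncallable=int((~mask).sum()),
        boundaries_deg=[float(b) for b in np.atleast_1d(boundaries)],
    )
    cols = ["sample_id", "genotype", "cluster_index", "margin", "theta_deg", "distance"]
    extra = [c for c in df.columns if c not in cols and c not in ("vic", "fam", "callable")]
    return df[cols + extra], report


def genotype_counts(
    calls: pd.DataFrame,
    by_cohort: bool = True,
    expected_cohorts: list[str] | None = None,
) -> pd.DataFrame:
    """Contingency of GG/GC/CC (and NO_CALL) counts and within-group percent.

    ``expected_cohorts``, when given, defines the universe of cohort
    labels: unknown labels raise, absent cohorts yield zero rows.
    """
    if calls.empty:
        raise ValueError("calls table is empty")
    group_col = "cohort" if by_cohort else None
    if group_col and group_col not in calls.columns:
        raise ValueError("calls table lacks a 'cohort' column")

    if group_col:
        labels = list(pd.unique(calls[group_col]))
        if expected_cohorts is not None:
            unknown = sorted(set(labels) - set(expected_cohorts))
            if unknown:
                raise ValueError(f"unknown cohort label(s): {unknown}")
            labels = list(expected_cohorts)
        groups = [(lab, calls[calls[group_col] == lab]) for lab in labels]
    else:
        groups = [("all", calls)]

    rows = []
    for lab, sub in groups:
        counts = sub["genotype"].value_counts()
        n_gg, n_gc, n_cc = (int(counts.get(g, 0)) for g in GENOTYPE_BY_RANK)
        n_nc = int(counts.get(NO_CALL, 0))
        called = n_gg + n_gc + n_cc
        row = {"cohort": lab, "n_GG": n_gg, "n_GC": n_gc, "n_CC": n_cc,
               "n_NO_CALL": n_nc, "n_called": called}
        for g, n in zip(GENOTYPE_BY_RANK, (n_gg, n_gc, n_cc)):
            row[f"pct_{g}"] = 100.0 * n / called if called else 0.0
        rows.append(row)
    return pd.DataFrame(rows)
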