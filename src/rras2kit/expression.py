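"""Plate-anchored relative mRNA quantification and luciferase ratios.

Relative expression follows the comparative-Ct model: per sample,
``q = E^(-dCt)`` with ``dCt = Ct_target - Ct_normalizer``; fold-change is
``q`` divided by the mean ``q`` of a fixed set of anchor normal samples,
so the anchor mean reads exactly 1 and a sample with fold > 1
*overexpresses* the target. Because every run carries the anchor set,
per-plate anchoring cancels any additive Ct shift shared by the genes on
a plate.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from rras2kit.copynumber import aggregate_replicates


def relative_expression(
    ct_table: pd.DataFrame,
    anchor_sample_ids: list[str],
    target: str = "RRAS2",
    normalizer: str = "PUM1",
    efficiency: float = 2.0,
    per_plate: bool = True,
    anchor_agg: str = "arithmetic",
    max_range: float = 1.0,
) -> tuple[pd.DataFrame, dict]:
    """Fold-change of target expression vs the anchor normal set.

    Parameters
    ----------
    ct_table
        Long Ct table (``sample_id, gene, plate_id, replicate, ct``); the
        anchor samples may recur on several plates (one record per
        (sample, plate) is emitted for them).
    anchor_sample_ids
        The consistent normal-sample set whose mean expression defines
        fold 1. In per-plate mode every plate must carry at least one.
    anchor_agg
        ``"arithmetic"`` mean of linear-scale quantities (default) or
        ``"geometric"``.

    Returns
    -------
    (records, report)
        ``records``: one row per (sample, plate) with ``delta_ct,
        rel_expr, overexpressed, is_anchor``. ``report`` lists excluded
        samples/plates.
    """
    if efficiency <= 1:
        raise ValueError("efficiency must be > 1")
    if anchor_agg not in ("arithmetic", "geometric"):
        raise ValueError("anchor_agg must be 'arithmetic' or 'geometric'")
    anchor_set = set(anchor_sample_ids)
    if not anchor_set:
        raise ValueError("anchor_sample_ids is empty")

    by = ("sample_id", "gene", "plate_id") if "plate_id" in ct_table.columns else ("sample_id", "gene")
    agg, excluded_undetermined = aggregate_replicates(ct_table, max_range=max_range, by=by)
    index_cols = [c for c in ("sample_id", "plate_id") if c in agg.columns]
    wide = agg.pivot_table(index=index_cols, columns="gene", values="ct_mean")
    for gene in (target, normalizer):
        if gene not in wide.columns:
            raise ValueError(f"gene {gene!r} absent from the Ct table")
    missing_norm = wide[wide[normalizer].isna() | wide[target].isna()]
    if len(missing_norm):
        warnings.warn(f"{len(missing_norm)} sample(s) lacking target or normalizer excluded")
    wide = wide.dropna(subset=[target, normalizer]).reset_index()
    if "plate_id" not in wide.columns:
        wide["plate_id"] = "ALL"

    wide["delta_ct"] = wide[target] - wide[normalizer]
    wide["q"] = np.power(efficiency, -wide["delta_ct"])
    wide["is_anchor"] = wide["sample_id"].isin(anchor_set)

    excluded_plates: list[str] = []
    frames = []
    if per_plate:
        for plate, sub in wide.groupby("plate_id", sort=True):
            anchors = sub[sub["is_anchor"]]
            if anchors.empty:
                excluded_plates.append(str(plate))
                continue
            frames.append(_normalize(sub, anchors, anchor_agg))
        if excluded_plates:
            warnings.warn(
                f"plate(s) without anchor samples excluded: {excluded_plates}"
            )
        if not frames:
            raise ValueError("no plate carries an anchor sample")
    else:
        anchors = wide[wide["is_anchor"]]
        if anchors.empty:
            raise ValueError("no anchor sample present in the Ct table")
        frames.append(_normalize(wide, anchors, anchor_agg))

    records = pd.concat(frames, ignore_index=True)
    records["overexpressed"] = records["rel_expr"] > 1.0  # strict: fold exactly 1 is not over
    cols = ["sample_id", "plate_id", "delta_ct", "rel_expr", "overexpressed", "is_anchor"]
    report = {
        "excluded_undetermined": excluded_undetermined.to_dict("records"),
        "excluded_plates_no_anchor": excluded_plates,
        "n_records": int(len(records)),
    }
    return records[cols], report


def _normalize(sub: pd.DataFrame, anchors: pd.DataFrame, anchor_agg: str) -> pd.DataFrame:
    out = sub.copy()
    if anchor_agg == "arithmetic":
        ref = anchors["q"].mean()
    else:
        ref = np.exp(np.log(anchors["q"]).mean())
    out["rel_expr"] = out["q"] / ref
    return out


def overexpression_fraction(records: pd.DataFrame, by: str | None = None) -> pd.DataFrame:
    """Fraction of samples with fold-change strictly above 1, per group.

    Anchor records are excluded (they define fold 1, not the cohort).
    """
    if records.empty:
        raise ValueError("records table is empty")
    df = records[~records["is_anchor"]] if "is_anchor" in records.columns else records
    groups = df.groupby(by, sort=True) if by else [("all", df)]
    rows = []
    for label, sub in groups:
        n = len(sub)
        n_over = int((sub["rel_expr"] > 1.0).sum())
        rows.append(
            {
                "group": label,
                "n": n,
                "n_overexpressed": n_over,
                "fraction_overexpressed": n_over / n if n else 0.0,
                "pct_overexpressed": 100.0 * n_over / n if n else 0.0,
            }
        )
    return pd.DataFrame(rows)


def luciferase_allele_ratio(
    wells: pd.DataFrame,
    construct_num: str = "UTR_C",
    construct_den: str = "UTR_G",
    epsilon: float = 1e-12,
) -> dict:
    """Background-subtracted firefly/renilla activity per construct.

    Non-transfected wells (``construct == "none"``) define the background
    of each luminescence channel (0 if absent). Per well,
    ``activity = (firefly - bg_f) / (renilla - bg_r)``; wells whose
    renilla signal does not exceed background are excluded. Reports mean
    +/- s.e.m. per construct and the C/G allele ratio of means.
    """
    required = {"construct", "firefly", "renilla"}
    missing = required - set(wells.columns)
    if missing:
        raise ValueError(f"luciferase table missing columns: {sorted(missing)}")
    if (wells[["firefly", "renilla"]] < 0).any().any():
        raise ValueError("luminescence signals must be nonnegative")

    bg = wells[wells["construct"] == "none"]
    bg_f = float(bg["firefly"].mean()) if len(bg) else 0.0
    bg_r = float(bg["renilla"].mean()) if len(bg) else 0.0

    per_construct: dict[str, dict] = {}
    excluded = 0
    for construct, sub in wells[wells["construct"] != "none"].groupby("construct", sort=True):
        renilla = sub["renilla"] - bg_r
        ok = renilla > 0
        excluded += int((~ok).sum())
        firefly = np.maximum(sub.loc[ok, "firefly"] - bg_f, epsilon)
        activity = firefly / np.maximum(renilla[ok], epsilon)
        if activity.empty:
            raise ValueError(f"construct {construct!r} has no usable well")
        per_construct[str(construct)] = {
            "n": int(len(activity)),
            "mean": float(activity.mean()),
            "sem": float(activity.std(ddof=1) / np.sqrt(len(activity))) if len(activity) > 1 else 0.0,
        }
    if excluded:
        warnings.warn(f"{excluded} well(s) with renilla at or below background excluded")

    result = {"background": {"firefly": bg_f, "renilla": bg_r}, "constructs": per_construct}
    if construct_num in per_construct and construct_den in per_construct:
        result["allele_ratio"] = per_construct[construct_num]["mean"] / per_construct[construct_den]["mean"]
        result["allele_ratio_label"] = f"{construct_num}/{construct_den}"
    return result
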