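"""End-to-end orchestration: simulate/read -> genotype -> CNV -> expression -> stats.

The pipeline runs either on a simulated cohort (a :class:`CohortConfig`)
or on user CSVs, and writes the calls, copy-ratio and expression tables
plus a consolidated JSON report. Every number in the report traces back
to rows of the emitted CSVs; excluded samples are counted per stage, and
(config, seed) fully determines every output byte (no timestamps).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from rras2kit import copynumber as cn
from rras2kit import expression as ex
from rras2kit import genotyping as gt
from rras2kit import io as rio
from rras2kit import stats as st
from rras2kit import synthetic as syn
from rras2kit.config import COHORTS, HEALTHY, PATIENT_BLOOD, TUMOR, CohortConfig, ConfigError


@dataclass
class RunConfig:
    """One reproducible pipeline run.

    Exactly one of ``simulation`` (a CohortConfig) or ``inputs`` (paths to
    fluorescence/ct_genomic/ct_expression/metadata CSVs) must be set.
    """

    simulation: Optional[CohortConfig] = None
    inputs: Optional[dict] = None  # keys: fluorescence, ct_genomic, ct_expression, metadata
    anchor_sample_ids: Optional[list] = None
    outdir: Optional[str] = None

    clustering_method: str = "kmeans"
    thresholds: Optional[tuple] = None
    no_call_margin: float = 2.0
    efficiency: float = 2.0
    per_plate_anchoring: bool = True
    reference_cohort: str = HEALTHY
    case_cohort: str = TUMOR
    seed: int = 0

    def validate(self) -> "RunConfig":
        if (self.simulation is None) == (self.inputs is None):
            raise ConfigError("exactly one of {simulation, inputs} must be set")
        if self.simulation is not None:
            self.simulation.validate()
            if self.anchor_sample_ids is None:
                self.anchor_sample_ids = syn.anchor_sample_ids(self.simulation)
        elif not self.anchor_sample_ids:
            raise ConfigError("anchor_sample_ids is required in file mode")
        return self


def validate_inputs(paths: dict) -> dict:
    """Schema report for a set of input CSVs plus cross-file ID checks.

    Raises :class:`rras2kit.io.DataError` on the first violation; returns
    a per-file summary (columns, row counts) and the cross-file check
    outcome otherwise.
    """
    report = {}
    readers = {
        "fluorescence": rio.read_fluorescence,
        "ct_genomic": rio.read_ct,
        "ct_expression": rio.read_ct,
        "metadata": rio.read_metadata,
    }
    tables = {}
    for key, reader in readers.items():
        if key not in paths:
            raise rio.DataError(f"missing input table: {key}")
        df = reader(paths[key])
        tables[key] = df
        report[key] = {"path": str(paths[key]), "n_rows": int(len(df)), "columns": list(df.columns)}

    meta_ids = set(tables["metadata"]["sample_id"])
    for key in ("fluorescence", "ct_genomic", "ct_expression"):
        missing = sorted(set(tables[key]["sample_id"]) - meta_ids)
        if missing:
            raise rio.DataError(
                f"{key}: {len(missing)} sample_id(s) absent from metadata: {missing[:10]}"
            )
    report["cross_file_ids"] = "ok"
    return report


def _json_sanitize(obj):
    if isinstance(obj, dict):
        return {str(k): _json_sanitize(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_json_sanitize(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.bool_):
        return bool(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def _config_hash(run: RunConfig) -> str:
    payload = {
        "simulation": run.simulation.to_dict() if run.simulation else None,
        "inputs": {k: str(v) for k, v in (run.inputs or {}).items()} or None,
        "options": {
            "clustering_method": run.clustering_method,
            "thresholds": run.thresholds,
            "no_call_margin": run.no_call_margin,
            "efficiency": run.efficiency,
            "per_plate_anchoring": run.per_plate_anchoring,
            "reference_cohort": run.reference_cohort,
            "case_cohort": run.case_cohort,
            "seed": run.seed,
        },
    }
    return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:16]


def run_pipeline(run: RunConfig) -> dict:
    """Execute all stages and return the consolidated report.

    When ``run.outdir`` is set, writes ``calls.csv``, ``copy_ratio.csv``,
    ``expression.csv``, ``stats.json`` and ``report.json`` there (plus the
    simulated input tables in simulation mode).
    """
    run.validate()
    outdir = Path(run.outdir) if run.outdir else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)

    # ---- stage 0: inputs -------------------------------------------------
    if run.simulation is not None:
        cfg = dataclasses.replace(run.simulation, seed=run.seed)
        tables = syn.simulate_cohort(cfg, outdir=outdir / "simulated" if outdir else None)
        truth = tables["truth"]
    else:
        validate_inputs(run.inputs)
        tables = {
            "fluorescence": rio.read_fluorescence(run.inputs["fluorescence"]),
            "ct_genomic": rio.read_ct(run.inputs["ct_genomic"]),
            "ct_expression": rio.read_ct(run.inputs["ct_expression"]),
            "metadata": rio.read_metadata(run.inputs["metadata"]),
        }
        truth = None

    metadata = tables["metadata"]
    accounting = {"n_input_samples": int(metadata["sample_id"].nunique())}

    # ---- stage 1: genotyping --------------------------------------------
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        polar = gt.polar_transform(tables["fluorescence"])
        calls, cluster_report = gt.cluster_genotypes(
            polar,
            method=run.clustering_method,
            thresholds=run.thresholds,
            no_call_margin=run.no_call_margin,
        )
    counts = gt.genotype_counts(calls, by_cohort=True)
    accounting["genotyping"] = {
        "n_samples": int(len(calls)),
        "n_uncallable": cluster_report.n_uncallable,
        "n_no_call": int((calls["genotype"] == gt.NO_CALL).sum()),
    }

    # ---- stage 2: copy number -------------------------------------------
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        agg, excl_ct = cn.aggregate_replicates(tables["ct_genomic"])
        ratios, excl_genes = cn.raw_copy_ratio(agg, efficiency=run.efficiency)
        ratios = ratios.merge(metadata[["sample_id", "cohort"]], on="sample_id")
        anchored = cn.anchor_to_diploid(ratios, reference_cohort=run.reference_cohort)
        fractions = cn.classify_amplification(anchored)
        dist_summary, dist_comparisons = cn.distance_abundance_summary(
            polar, reference_cohort=run.reference_cohort
        )
    accounting["copy_number"] = {
        "n_samples": int(len(anchored)),
        "n_excluded_undetermined": int(len(excl_ct)),
        "n_excluded_missing_gene": len(excl_genes),
    }

    # ---- stage 3: expression --------------------------------------------
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        expr_records, expr_report = ex.relative_expression(
            tables["ct_expression"],
            anchor_sample_ids=run.anchor_sample_ids,
            efficiency=run.efficiency,
            per_plate=run.per_plate_anchoring,
        )
    expr_with_meta = expr_records.merge(metadata[["sample_id", "cohort"]], on="sample_id", how="left")
    overexpr = ex.overexpression_fraction(expr_with_meta, by="cohort")
    tumor_expr = expr_with_meta[expr_with_meta["cohort"] == run.case_cohort]
    overall_overexpr = (
        ex.overexpression_fraction(tumor_expr) if len(tumor_expr) else ex.overexpression_fraction(expr_with_meta)
    )
    accounting["expression"] = {
        "n_records": int(len(expr_records)),
        "excluded_plates_no_anchor": expr_report["excluded_plates_no_anchor"],
    }

    # ---- stage 4: statistics --------------------------------------------
    stats_block: dict = {"per_cohort": {}}
    for _, row in counts.iterrows():
        cohort = row["cohort"]
        n_gg, n_gc, n_cc = int(row["n_GG"]), int(row["n_GC"]), int(row["n_CC"])
        if n_gg + n_gc + n_cc == 0:
            continue
        stats_block["per_cohort"][cohort] = {
            "allele_frequencies": st.allele_frequencies(n_gg, n_gc, n_cc),
            "hwe": st.hwe_exact_test(n_gg, n_gc, n_cc),
        }

    def _counts(cohort):
        row = counts[counts["cohort"] == cohort]
        if row.empty:
            return None
        r = row.iloc[0]
        return int(r["n_GG"]), int(r["n_GC"]), int(r["n_CC"])

    case, ctrl = _counts(run.case_cohort), _counts(run.reference_cohort)
    if case and ctrl and (case[0] + case[2]) > 0 and (ctrl[0] + ctrl[2]) > 0:
        stats_block["fisher_gg_cc"] = st.fisher_gg_cc((case[0], case[2]), (ctrl[0], ctrl[2]))
        stats_block["genotype_2x3"] = st.genotype_test_2x3(case, ctrl)

    assoc = None
    if len(tumor_expr) >= 6:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                assoc = st.genotype_expression_association(calls, tumor_expr)
        except ValueError:
            assoc = None
    stats_block["genotype_expression"] = assoc

    # ---- recovery metrics (simulation mode only) -------------------------
    recovery = None
    if truth is not None:
        merged = calls.merge(truth[["sample_id", "true_genotype", "true_copies"]], on="sample_id")
        called = merged[merged["genotype"] != gt.NO_CALL]
        acc = float((called["genotype"] == called["true_genotype"]).mean()) if len(called) else 0.0
        cnv = anchored.merge(truth[["sample_id", "true_copies"]], on="sample_id")
        rmse = float(np.sqrt(((cnv["est_copies"] - cnv["true_copies"]) ** 2).mean()))
        recovery = {
            "genotype_call_accuracy": acc,
            "n_called": int(len(called)),
            "est_copies_rmse": rmse,
        }

    from rras2kit import __version__ as _version  # deferred: avoids import cycle

    report = {
        "provenance": {
            "package_version": _version,
            "config_hash": _config_hash(run),
            "seed": run.seed,
            "mode": "simulation" if run.simulation is not None else "files",
        },
        "accounting": accounting,
        "genotype_counts": counts.to_dict("records"),
        "cluster_report": dataclasses.asdict(cluster_report),
        "copy_number": {
            "fractions": fractions.to_dict("records"),
            "distance_summary": dist_summary.to_dict("records"),
            "distance_comparisons": dist_comparisons.to_dict("records"),
            "anova_F": dist_comparisons.attrs.get("anova_F"),
            "anova_p": dist_comparisons.attrs.get("anova_p"),
        },
        "expression": {
            "overexpression_by_cohort": overexpr.to_dict("records"),
            "overexpression_case": overall_overexpr.to_dict("records"),
        },
        "stats": stats_block,
        "recovery": recovery,
    }
    report = _json_sanitize(report)

    if outdir:
        calls.to_csv(outdir / "calls.csv", index=False)
        anchored.to_csv(outdir / "copy_ratio.csv", index=False)
        expr_with_meta.to_csv(outdir / "expression.csv", index=False)
        (outdir / "stats.json").write_text(json.dumps(_json_sanitize(stats_block), indent=2, sort_keys=True))
        (outdir / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    return report
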