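"""CSV readers and schema validation for the pipeline's interchange files.

The interchange format is plain CSV with documented headers:

* fluorescence: ``sample_id, cohort, vic, fam``
* Ct (long):    ``sample_id, gene, plate_id, replicate, ct``
  (``ct`` may be the string ``undetermined``, read as missing)
* metadata:     ``sample_id, cohort`` plus free-form columns
* luciferase:   ``construct, firefly, renilla``

A reader shim for wide "plate layout" exports (one row per sample,
columns ``<gene>_<replicate>``) is also provided.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd


class DataError(ValueError):
    """Raised for malformed input data; message names column/row."""


SCHEMAS = {
    "fluorescence": {"required": ["sample_id", "cohort", "vic", "fam"], "unique_id": True},
    "ct": {"required": ["sample_id", "gene", "plate_id", "replicate", "ct"], "unique_id": False},
    "metadata": {"required": ["sample_id", "cohort"], "unique_id": True},
    "luciferase": {"required": ["construct", "firefly", "renilla"], "unique_id": False},
}


def _read_csv(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise DataError(f"file not found: {path}")
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise DataError(f"{path}: file is empty (no rows)") from None
    if df.empty:
        raise DataError(f"{path}: file has a header but no rows")
    return df


def check_schema(df: pd.DataFrame, kind: str, name: str = "") -> None:
    schema = SCHEMAS[kind]
    missing = [c for c in schema["required"] if c not in df.columns]
    if missing:
        raise DataError(f"{name or kind}: missing column(s) {missing}")
    if schema["unique_id"]:
        dupes = df.loc[df["sample_id"].duplicated(), "sample_id"].unique().tolist()
        if dupes:
            raise DataError(f"{name or kind}: duplicate sample_id values {dupes[:10]}")


def read_fluorescence(path: str | Path) -> pd.DataFrame:
    df = _read_csv(path)
    check_schema(df, "fluorescence", str(path))
    for col in ("vic", "fam"):
        df[col] = pd.to_numeric(df[col], errors="raise")
    return df


def read_ct(path: str | Path) -> pd.DataFrame:
    """Long Ct table; ``undetermined`` (any case) becomes NaN."""
    df = _read_csv(path)
    check_schema(df, "ct", str(path))
    df["ct"] = pd.to_numeric(
        df["ct"].astype(str).str.strip().replace(
            {"undetermined": None, "Undetermined": None, "UNDETERMINED": None, "nan": None, "": None}
        ),
        errors="coerce",
    )
    return df


def read_metadata(path: str | Path) -> pd.DataFrame:
    df = _read_csv(path)
    check_schema(df, "metadata", str(path))
    return df


def read_luciferase(path: str | Path) -> pd.DataFrame:
    df = _read_csv(path)
    check_schema(df, "luciferase", str(path))
    for col in ("firefly", "renilla"):
        df[col] = pd.to_numeric(df[col], errors="raise")
    return df


def read_plate_layout(path: str | Path, plate_id: str = "P01") -> pd.DataFrame:
    """Wide plate-layout export -> long Ct table.

    Expects ``sample_id`` plus columns named ``<gene>_<replicate>``
    (e.g. ``RRAS2_1, RRAS2_2, COX8A_1``); an optional ``plate_id``
    column overrides the default.
    """
    df = _read_csv(path)
    if "sample_id" not in df.columns:
        raise DataError(f"{path}: missing column(s) ['sample_id']")
    has_plate = "plate_id" in df.columns
    value_cols = [c for c in df.columns if c not in ("sample_id", "plate_id")]
    bad = [c for c in value_cols if "_" not in c or not c.rsplit("_", 1)[1].isdigit()]
    if bad:
        raise DataError(f"{path}: plate-layout columns must look like GENE_<rep>; got {bad}")
    long = df.melt(
        id_vars=["sample_id"] + (["plate_id"] if has_plate else []),
        value_vars=value_cols,
        var_name="gene_rep",
        value_name="ct",
    )
    parts = long["gene_rep"].str.rsplit("_", n=1, expand=True)
    long["gene"] = parts[0]
    long["replicate"] = parts[1].astype(int)
    if not has_plate:
        long["plate_id"] = plate_id
    long["ct"] = pd.to_numeric(
        long["ct"].astype(str).str.strip().replace({"undetermined": None, "Undetermined": None}),
        errors="coerce",
    )
    return long[["sample_id", "gene", "plate_id", "replicate", "ct"]]
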