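"""Readers/writers for cell tables and the run manifest."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd

from spatialtma.errors import SchemaError

REQUIRED_COLUMNS = ("cell_id", "sample_id", "x_um", "y_um", "nuclear_area_um2")


def read_cell_table(path, markers: list[str] | None = None) -> pd.DataFrame:
    """Read and validate a cell table (CSV or Parquet by extension).

    Required columns: cell_id, sample_id, x_um, y_um, nuclear_area_um2, plus
    any requested marker columns. Unknown columns pass through untouched.
    Raises :class:`SchemaError` naming missing columns; rows with
    non-numeric coordinates are reported.
    """
    path = Path(path)
    if path.suffix in (".parquet", ".pq"):
        table = pd.read_parquet(path)
    else:
        table = pd.read_csv(path)
    required = list(REQUIRED_COLUMNS) + list(markers or [])
    missing = [c for c in required if c not in table.columns]
    if missing:
        raise SchemaError(f"cell table missing required columns: {missing}", missing)
    numeric = ["x_um", "y_um", "nuclear_area_um2"] + list(markers or [])
    bad_rows: dict[str, list[int]] = {}
    for col in numeric:
        coerced = pd.to_numeric(table[col], errors="coerce")
        bad = table.index[coerced.isna() & table[col].notna()]
        if len(bad):
            bad_rows[col] = list(bad[:20])
        table[col] = coerced
    if bad_rows:
        raise SchemaError(f"non-numeric values in columns (first rows shown): {bad_rows}")
    if table["cell_id"].duplicated().any():
        raise SchemaError("cell_id values are not unique")
    return table


def write_cell_table(table: pd.DataFrame, path) -> None:
    path = Path(path)
    if path.suffix in (".parquet", ".pq"):
        table.to_parquet(path, index=False)
    else:
        table.to_csv(path, index=False)


def read_clinical_table(path) -> pd.DataFrame:
    table = pd.read_csv(path)
    missing = [c for c in ("sample_id", "response") if c not in table.columns]
    if missing:
        raise SchemaError(f"clinical table missing columns: {missing}", missing)
    return table


def file_sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(manifest: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)


def read_manifest(path) -> dict:
    with open(path) as fh:
        return json.load(fh)
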