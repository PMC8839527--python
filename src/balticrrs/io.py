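"""Station-table and coefficient-file I/O.

The canonical exchange format for station data is a UTF-8 CSV with a
fixed, unit-suffixed header (decimal point, empty cells for missing
values).  Column order::

    station_id,
    chl_a_mg_m3, sum_c_mg_m3, spm_g_m3, spm_inorg_g_m3, a_cdom_400_m1,
    then per band b in {420, 488, 555, 620}:
        aph_b, ad_b, acdom_b, bbp_b        [1/m]
        lu_b, ed_b, eu_b                   [relative energy units]
        rrs_b                              [1/sr]

Coefficient sets are JSON files with per-band blocks (see
:mod:`balticrrs.coefficients`).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .bands import BANDS
from .coefficients import ModelCoefficients


def constituent_columns() -> list[str]:
    return ["chl_a_mg_m3", "sum_c_mg_m3", "spm_g_m3", "spm_inorg_g_m3", "a_cdom_400_m1"]


def iop_columns() -> list[str]:
    return [f"{q}_{b}" for b in BANDS for q in ("aph", "ad", "acdom", "bbp")]


def radiometry_columns(include_eu: bool = True) -> list[str]:
    quantities = ("lu", "ed", "eu") if include_eu else ("lu", "ed")
    return [f"{q}_{b}" for b in BANDS for q in quantities]


def rrs_columns() -> list[str]:
    return [f"rrs_{b}" for b in BANDS]


def station_columns() -> list[str]:
    """The full ordered station-CSV header."""
    cols = ["station_id"] + constituent_columns()
    for b in BANDS:
        cols += [f"{q}_{b}" for q in ("aph", "ad", "acdom", "bbp")]
        cols += [f"{q}_{b}" for q in ("lu", "ed", "eu")]
        cols += [f"rrs_{b}"]
    return cols


class StationSchemaError(ValueError):
    """Raised when a station table violates the CSV schema or invariants."""


def validate_station_table(table: pd.DataFrame, required: list[str] | None = None) -> pd.DataFrame:
    """Check schema and physical invariants of a station table.

    Rows violating invariants raise :class:`StationSchemaError` with the
    offending row labels.  ``required`` defaults to the constituent
    columns; measured columns are validated when present.
    """
    required = constituent_columns() if required is None else required
    missing = [c for c in required if c not in table.columns]
    if missing:
        raise StationSchemaError(f"missing required column(s): {missing}")
    num = table[[c for c in table.columns if c != "station_id"]]
    for col in num.columns:
        values = pd.to_numeric(num[col], errors="coerce")
        bad = num[col].notna() & values.isna()
        if bad.any():
            raise StationSchemaError(
                f"column {col!r}: malformed numbers in row(s) {list(table.index[bad])}")
    if {"spm_g_m3", "spm_inorg_g_m3"} <= set(table.columns):
        bad = table["spm_inorg_g_m3"] > table["spm_g_m3"]
        if bad.any():
            raise StationSchemaError(
                f"spm_inorg exceeds spm in row(s) {list(table.index[bad])}")
    nonneg = [c for c in constituent_columns() + iop_columns() if c in table.columns]
    for col in nonneg:
        bad = table[col] < 0
        if bad.any():
            raise StationSchemaError(
                f"column {col!r}: negative values in row(s) {list(table.index[bad])}")
    if {"sum_c_mg_m3", "chl_a_mg_m3"} <= set(table.columns):
        bad = (table["sum_c_mg_m3"] > 0) & (table["chl_a_mg_m3"] == 0)
        if bad.any():
            raise StationSchemaError(
                f"sum_c > 0 with chl_a = 0 in row(s) {list(table.index[bad])}")
    return table


def read_station_csv(path: str | Path) -> pd.DataFrame:
    """Read and validate a station CSV.

    The header must contain at least the five constituent columns; the
    remaining schema columns are optional but validated when present.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        table = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise StationSchemaError(f"{path}: empty file") from exc
    unknown = [c for c in table.columns if c not in station_columns()]
    if unknown:
        raise StationSchemaError(f"{path}: unknown column(s) {unknown}")
    return validate_station_table(table)


def write_station_csv(table: pd.DataFrame, path: str | Path) -> None:
    """Write a station table in canonical column order (full precision)."""
    cols = [c for c in station_columns() if c in table.columns]
    table[cols].to_csv(path, index=False)


def write_coefficients(coefficients: ModelCoefficients, path: str | Path) -> None:
    """Write a coefficient set as JSON (all four bands required)."""
    coefficients.save(path)


def read_coefficients(path: str | Path) -> ModelCoefficients:
    return ModelCoefficients.load(path)
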