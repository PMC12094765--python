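"""Readers, writers and validators for the tabular interchange formats.

All files use one canonical CSV dialect: UTF-8, comma separator, header
row, "." decimal point. Areas are written as integers when integral so a
read→write→read cycle is byte-stable. Blank cells in study tables are
explicit missing values (NaN), never zeros.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any, Mapping

import pandas as pd
import yaml

from .catalogs import DEFAULT_LULC, LULCCatalog, SERVICES


class SchemaError(ValueError):
    """A required column is absent or mis-typed."""


class ValidationError(ValueError):
    """Rows violate a content invariant (codes, signs, duplicate keys)."""


AREA_COLUMNS = ["region", "year", "lulc", "area_ha"]


def _require_columns(df: pd.DataFrame, cols: list[str], what: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{what}: missing column(s) {missing}")


def validate_area_panel(df: pd.DataFrame, catalog: LULCCatalog | None = None) -> pd.DataFrame:
    """Validate a long-format area panel (region, year, lulc, area_ha)."""
    catalog = catalog or DEFAULT_LULC
    _require_columns(df, AREA_COLUMNS, "area panel")
    df = df[AREA_COLUMNS].copy()
    df["year"] = df["year"].astype(int)
    df["area_ha"] = pd.to_numeric(df["area_ha"])

    unknown = df.index[~df["lulc"].isin(catalog.types)]
    if len(unknown):
        rows = ", ".join(str(i) for i in unknown[:10])
        raise ValidationError(f"unknown LULC code(s) at row(s) {rows}")
    bad = df.index[~df["area_ha"].ge(0) | ~df["area_ha"].apply(pd.notna)]
    if len(bad):
        rec = df.loc[bad[0]]
        raise ValidationError(
            f"non-finite or negative area at row {bad[0]}: "
            f"({rec.region}, {rec.year}, {rec.lulc}) = {rec.area_ha}"
        )
    dup = df.duplicated(subset=["region", "year", "lulc"])
    if dup.any():
        raise ValidationError(f"duplicate (region, year, lulc) key at row {dup.idxmax()}")
    return df


def read_area_panel(path: str | Path, catalog: LULCCatalog | None = None) -> pd.DataFrame:
    return validate_area_panel(pd.read_csv(path), catalog)


def write_area_panel(df: pd.DataFrame, path: str | Path) -> None:
    out = validate_area_panel(df)
    a = out["area_ha"]
    if (a == a.round()).all():
        out["area_ha"] = a.astype("int64")
    out.to_csv(path, index=False)


def read_ef_matrix(path: str | Path) -> pd.DataFrame:
    """Read an equivalent-factor matrix (rows = lulc, columns = services)."""
    df = pd.read_csv(path)
    _require_columns(df, ["lulc"] + list(SERVICES), "EF matrix")
    df = df.set_index("lulc")[list(SERVICES)].astype(float)
    return validate_ef_matrix(df)


def validate_ef_matrix(df: pd.DataFrame, catalog: LULCCatalog | None = None) -> pd.DataFrame:
    catalog = catalog or DEFAULT_LULC
    missing_rows = [t for t in catalog.types if t not in df.index]
    if missing_rows:
        raise ValidationError(f"EF matrix missing row(s) {missing_rows}")
    missing_cols = [s for s in SERVICES if s not in df.columns]
    if missing_cols:
        raise SchemaError(f"EF matrix missing service column(s) {missing_cols}")
    df = df.loc[list(catalog.types), list(SERVICES)]
    if df.isna().any().any():
        raise ValidationError("EF matrix has missing cells")
    return df


def write_ef_matrix(df: pd.DataFrame, path: str | Path) -> None:
    validate_ef_matrix(df).rename_axis("lulc").to_csv(path)


def read_study_table(path: str | Path) -> pd.DataFrame:
    """Read a literature study table (rows = study, service columns, blanks = missing)."""
    df = pd.read_csv(path)
    _require_columns(df, ["study"] + list(SERVICES), "study table")
    return df.set_index("study")[list(SERVICES)].astype(float)


def write_study_table(df: pd.DataFrame, path: str | Path) -> None:
    df.rename_axis("study").to_csv(path)


def read_s_factors(path: str | Path) -> pd.Series:
    """Read spatiotemporal adjustment factors as a (region, year)-indexed series."""
    df = pd.read_csv(path)
    _require_columns(df, ["region", "year", "s"], "S-factor table")
    df["year"] = df["year"].astype(int)
    s = df.set_index(["region", "year"])["s"].astype(float)
    if (s <= 0).any() or s.isna().any():
        raise ValidationError("S factors must be finite and positive")
    return s


def write_s_factors(s: pd.Series, path: str | Path) -> None:
    s.rename("s").rename_axis(["region", "year"]).reset_index().to_csv(path, index=False)


def read_driver_panel(path: str | Path) -> pd.DataFrame:
    """Read a driver panel keyed by (region, year) with responses and predictors."""
    df = pd.read_csv(path)
    _require_columns(df, ["region", "year"], "driver panel")
    df["year"] = df["year"].astype(int)
    return df


def read_config(path: str | Path) -> dict[str, Any]:
    """Read a YAML or JSON run configuration."""
    text = Path(path).read_text()
    if str(path).endswith(".json"):
        return json.loads(text)
    cfg = yaml.safe_load(text)
    if not isinstance(cfg, Mapping):
        raise SchemaError("config must be a mapping")
    return dict(cfg)
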