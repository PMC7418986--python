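"""CSV/XLSX readers and writers for the pipeline's interchange tables.

CSV is the canonical interchange format.  An XLSX reader is provided for
study-style workbooks that carry one sheet per table; sheet names are mapped
through a user-editable dictionary rather than hard-coded.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import pandas as pd

from .harvest_records import validate_age_harvest

YEARLY_COLUMNS = ("year", "onsite", "phone", "nuisance_kills")
FOOD_COLUMNS = ("year", "species", "respondent", "abundance", "production")

#: default workbook sheet -> table mapping for XLSX input
DEFAULT_SHEET_MAP: Mapping[str, str] = {
    "age_harvest": "age_harvest",
    "yearly": "yearly",
    "food_survey": "food_survey",
}


def _require_columns(df: pd.DataFrame, cols, name: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    extra = [c for c in df.columns if c not in cols]
    if missing:
        raise ValueError(f"{name}: missing columns {missing} (extra: {extra})")


def _check_year_contiguous(years: pd.Series, name: str) -> None:
    ys = sorted(set(int(y) for y in years))
    gaps = [y for y in range(ys[0], ys[-1] + 1) if y not in ys]
    if gaps:
        raise ValueError(f"{name}: year gap at {gaps}")


def read_age_harvest(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, ("year", "sex", "age", "count"), "age_harvest")
    validate_age_harvest(df)
    _check_year_contiguous(df["year"], "age_harvest")
    return df


def read_yearly(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, YEARLY_COLUMNS, "yearly")
    if (df["onsite"].dropna() < 0).any() or (df["phone"].dropna() < 0).any():
        bad = df[(df["onsite"] < 0) | (df["phone"] < 0)].iloc[0]
        raise ValueError(f"yearly: negative count in year {int(bad['year'])}")
    _check_year_contiguous(df["year"], "yearly")
    return df


def read_food_survey(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, FOOD_COLUMNS, "food_survey")
    return df


def read_workbook(
    path: str | Path, sheet_map: Mapping[str, str] | None = None
) -> dict[str, pd.DataFrame]:
    """Read a one-sheet-per-table XLSX workbook into validated frames."""
    sheet_map = dict(sheet_map or DEFAULT_SHEET_MAP)
    out: dict[str, pd.DataFrame] = {}
    with pd.ExcelFile(path) as book:
        for table, sheet in sheet_map.items():
            if sheet not in book.sheet_names:
                raise ValueError(f"workbook has no sheet '{sheet}' for table {table}")
            out[table] = book.parse(sheet)
    if "age_harvest" in out:
        validate_age_harvest(out["age_harvest"])
    if "yearly" in out:
        _require_columns(out["yearly"], YEARLY_COLUMNS, "yearly")
    if "food_survey" in out:
        _require_columns(out["food_survey"], FOOD_COLUMNS, "food_survey")
    return out


def write_csv(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    return path
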