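"""Cohort CSV schema, parsing and staging helpers.

The cohort file is a plain RFC-4180 CSV (UTF-8, "." decimal) with one row
per infant.  Velocities are stored in cm/s, matching the staging bins; a
reader flag accepts m/s input (``lpa_units="ms"``) because published tables
disagree on the unit.  Gestational age is accepted as decimal weeks or as
"weeks+days" text (27+3 -> 27.4286).  Missing values are empty cells, never
sentinel numbers.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from .errors import CohortFormatError, SchemaError
from .hemodynamics import DAO_DIRECTIONS, EchoExam
from .staging import StagingScheme, compute_score, model5_scheme

__all__ = [
    "SCHEMA_COLUMNS",
    "REQUIRED_COLUMNS",
    "read_cohort",
    "write_cohort",
    "parse_gestational_age",
    "exam_from_row",
    "score_cohort",
]

SCHEMA_COLUMNS = [
    "infant_id",
    "group",
    "ga_weeks",
    "birth_weight_g",
    "apgar5",
    "cord_ph",
    "advanced_resuscitation",
    "td_mm",
    "vmax_vmin",
    "lpa_cms",
    "dao_direction",
    "la_ao",
    "lvo_mlkgmin",
    "svc_mlkgmin",
    "ea_ratio",
    "pda_score",
    "postnatal_age_h",
]

#: pda_score is recomputed when absent; everything else must be present.
REQUIRED_COLUMNS = [c for c in SCHEMA_COLUMNS if c != "pda_score"]

_GROUPS = ("CM", "IBT", "unknown")
_NUMERIC = [
    "birth_weight_g",
    "apgar5",
    "cord_ph",
    "td_mm",
    "vmax_vmin",
    "lpa_cms",
    "la_ao",
    "lvo_mlkgmin",
    "svc_mlkgmin",
    "ea_ratio",
    "pda_score",
    "postnatal_age_h",
]


def parse_gestational_age(value: Union[str, float]) -> float:
    """Decimal weeks from a number or 'weeks+days' text (27+3 -> 27.4286)."""
    if isinstance(value, (int, float)) and not isinstance(value, bool):
        return float(value)
    text = str(value).strip()
    if "+" in text:
        weeks_s, days_s = text.split("+", 1)
        weeks, days = float(weeks_s), float(days_s)
        if not 0 <= days < 7:
            raise CohortFormatError(f"days part of gestational age must be 0-6: {text!r}")
        return weeks + days / 7.0
    return float(text)


def read_cohort(path: Union[str, Path], lpa_units: str = "cms") -> pd.DataFrame:
    """Read and validate a cohort CSV.

    Header must contain every required schema column (extra columns are
    preserved untouched); categorical cells are case-normalized.  A
    malformed header raises :class:`SchemaError` listing the missing
    columns, an unparseable cell :class:`CohortFormatError` with its line
    number.
    """
    if lpa_units not in ("cms", "ms"):
        raise SchemaError(f"lpa_units must be 'cms' or 'ms', got {lpa_units!r}")
    path = Path(path)
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in REQUIRED_COLUMNS if c not in raw.columns]
    if missing:
        raise SchemaError(f"cohort file {path.name} is missing columns: {missing}")
    df = raw.copy()

    def _cell_error(column: str, idx: int, value: str) -> CohortFormatError:
        # +2: header line plus 1-based indexing
        return CohortFormatError(
            f"{path.name} line {idx + 2}: cannot parse {column}={value!r}"
        )

    ids = df["infant_id"].str.strip()
    if ids.duplicated().any():
        dup = ids[ids.duplicated()].iloc[0]
        raise CohortFormatError(f"duplicate infant_id {dup!r}")
    df["infant_id"] = ids

    group = df["group"].str.strip()
    norm = group.str.upper().where(group.str.upper().isin(("CM", "IBT")), group.str.lower())
    bad = ~norm.isin(_GROUPS)
    if bad.any():
        idx = int(np.flatnonzero(bad)[0])
        raise _cell_error("group", idx, group.iloc[idx])
    df["group"] = norm

    ga = []
    for idx, cell in enumerate(df["ga_weeks"]):
        cell = cell.strip()
        if cell == "":
            ga.append(np.nan)
            continue
        try:
            ga.append(parse_gestational_age(cell))
        except (ValueError, CohortFormatError):
            raise _cell_error("ga_weeks", idx, cell) from None
    df["ga_weeks"] = ga

    for col in _NUMERIC + ["advanced_resuscitation"]:
        if col not in df.columns:
            continue
        out = []
        for idx, cell in enumerate(df[col]):
            cell = cell.strip()
            if cell == "":
                out.append(np.nan)
                continue
            try:
                out.append(float(cell))
            except ValueError:
                raise _cell_error(col, idx, cell) from None
        df[col] = out

    dao = df["dao_direction"].str.strip().str.lower()
    bad = ~(dao.isin(DAO_DIRECTIONS) | (dao == ""))
    if bad.any():
        idx = int(np.flatnonzero(bad)[0])
        raise _cell_error("dao_direction", idx, df["dao_direction"].iloc[idx])
    df["dao_direction"] = dao.replace("", np.nan)

    if lpa_units == "ms":
        df["lpa_cms"] = df["lpa_cms"] * 100.0
    if "pda_score" not in df.columns:
        df["pda_score"] = np.nan
    return df


def write_cohort(cohort: pd.DataFrame, path: Union[str, Path]) -> None:
    """Write a cohort CSV (missing values as empty cells)."""
    cohort.to_csv(path, index=False, na_rep="")


def exam_from_row(row: Union[pd.Series, dict]) -> EchoExam:
    """Build the staged subset of an :class:`EchoExam` from a cohort row."""
    def get(key):
        v = row.get(key, None)
        if v is None or (isinstance(v, float) and math.isnan(v)):
            return None
        return v

    return EchoExam(
        transductal_diameter=get("td_mm"),
        ductal_vmax_vmin_ratio=get("vmax_vmin"),
        lpa_diastolic_velocity=get("lpa_cms"),
        dao_flow_direction=get("dao_direction"),
        la_ao_ratio=get("la_ao"),
        postnatal_age=get("postnatal_age_h"),
    )


def score_cohort(
    cohort: pd.DataFrame,
    scheme: Optional[StagingScheme] = None,
    overwrite: bool = False,
) -> pd.DataFrame:
    """Return a copy with ``pda_score`` filled from the staging scheme.

    Rows that already carry a score are kept unless ``overwrite`` is set, so
    rescoring a scored cohort is a no-op.
    """
    scheme = scheme or model5_scheme()
    out = cohort.copy()
    if "pda_score" not in out.columns:
        out["pda_score"] = np.nan
    for idx in out.index:
        if not overwrite and not pd.isna(out.at[idx, "pda_score"]):
            continue
        out.at[idx, "pda_score"] = compute_score(exam_from_row(out.loc[idx]), scheme).total
    out["pda_score"] = out["pda_score"].astype(float)
    return out
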