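"""Cohort file I/O: one canonical delimited-text schema.

Canonical columns: ``id, age_years, sex {F,M}, black {0,1}, height_cm,
weight_kg, scr_umol_l`` (or ``scr_mg_dl``), ``scys_mg_l, valine_umol_l,
myo_inositol_umol_l, mgfr_ml_min_173, tracer``.  Exactly one creatinine
column may be present; mg/dL is converted to µmol/L on read.  Unknown
columns are preserved.  Comma or tab delimiters are auto-detected.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .equations import UMOL_PER_MG_DL

__all__ = ["CohortSchemaError", "read_cohort", "write_cohort"]

MANDATORY = ("id", "age_years", "sex")
MARKER_COLUMNS = ("scys_mg_l", "valine_umol_l", "myo_inositol_umol_l")


class CohortSchemaError(ValueError):
    pass


def read_cohort(path, require_mgfr: bool = False) -> pd.DataFrame:
    """Read and validate a cohort file; creatinine normalized to µmol/L.

    Marker columns may be absent (equations needing them fail later with a
    named missing-marker error).  Row-level problems are collected and
    reported together with 1-based data line numbers.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=None, engine="python")

    missing = [c for c in MANDATORY if c not in df.columns]
    if require_mgfr and "mgfr_ml_min_173" not in df.columns:
        missing.append("mgfr_ml_min_173")
    if missing:
        raise CohortSchemaError(f"{path.name}: missing mandatory columns: {missing}")
    has_umol = "scr_umol_l" in df.columns
    has_mgdl = "scr_mg_dl" in df.columns
    if has_umol and has_mgdl:
        raise CohortSchemaError(
            f"{path.name}: both scr_umol_l and scr_mg_dl present; keep exactly one")
    if has_mgdl:
        df = df.rename(columns={"scr_mg_dl": "scr_umol_l"})
        df["scr_umol_l"] = df["scr_umol_l"] * UMOL_PER_MG_DL

    problems: list[str] = []
    sex_norm = df["sex"].astype(str).str.strip().str.upper()
    bad_sex = ~sex_norm.isin(["F", "M", "FEMALE", "MALE"])
    for i in df.index[bad_sex]:
        problems.append(f"line {i + 1}: unrecognized sex {df.at[i, 'sex']!r}")
    df["sex"] = sex_norm.str[0]

    for col in ("age_years", "height_cm", "weight_kg", "scr_umol_l",
                "mgfr_ml_min_173", *MARKER_COLUMNS):
        if col not in df.columns:
            continue
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.notna() & ~(vals > 0)
        for i in df.index[bad]:
            problems.append(f"line {i + 1}: non-positive {col} = {df.at[i, col]}")
        df[col] = vals
    if problems:
        raise CohortSchemaError(f"{path.name}: " + "; ".join(problems))
    if "black" in df.columns:
        df["black"] = df["black"].fillna(0).astype(int)
    return df


def write_cohort(df: pd.DataFrame, path, sep: str = ",") -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep=sep, index=False)
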