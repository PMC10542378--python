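"""Cohort-table reading, validation and writing.

The on-disk cohort format is a CSV/TSV with one row per participant:
``id, age, sex (F/M), pet_scanner (A/H), mri_scanner (T/V)``, genotypes, and
the seven regional BP_ND columns (plain decimals, unitless; left/right
hemispheres are assumed already volume-weight averaged upstream). Genotypes
are accepted either carrier-coded (0/1 columns named ``httlpr, rs6295,
rs7333412, rs1137070, rs6265``) or raw (columns ``rs6265, httlpr, httlpr_snp,
rs6295, rs7333412, rs1137070`` holding allele strings such as ``L/S``), in
which case they are recoded on read. Continuous covariates are mean-centered
on read (column ``age_c``).
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .genotypes import recode_genotype_table
from .simulate import REGIONS, VARIANTS

__all__ = ["read_cohort", "write_cohort", "validate_cohort"]

_SEX_CODES = {"F": 0, "M": 1}
_PET_CODES = {"A": 0, "H": 1}
_MRI_CODES = {"T": 0, "V": 1}


def _decode(series: pd.Series, codes: dict, column: str) -> pd.Series:
    s = series
    if s.dtype == object:
        mapped = s.astype(str).str.strip().str.upper().map(codes)
        if mapped.isna().any():
            bad = sorted(set(s[mapped.isna()].astype(str)))
            raise ValueError(f"illegal codes {bad} in column {column!r}")
        return mapped.astype(int)
    vals = set(pd.unique(s.dropna()))
    if not vals <= {0, 1}:
        raise ValueError(f"column {column!r} must be coded {sorted(codes)} or 0/1")
    return s.astype(int)


def validate_cohort(df: pd.DataFrame) -> pd.DataFrame:
    """Validate and normalize an in-memory cohort table (codes to 0/1,
    genotypes carrier-coded, ``age_c`` added)."""
    df = df.copy()
    base = ["id", "age", "sex", "pet_scanner", "mri_scanner"]
    missing = [c for c in base + list(REGIONS) if c not in df.columns]
    if missing:
        raise ValueError(f"cohort table is missing required columns: {missing}")
    if df["id"].duplicated().any():
        dup = df.loc[df["id"].duplicated(), "id"].tolist()
        raise ValueError(f"duplicate participant ids: {dup}")

    has_carrier = all(v in df.columns for v in VARIANTS)
    raw_cols = ["rs6265", "httlpr", "httlpr_snp", "rs6295", "rs7333412", "rs1137070"]
    looks_raw = "httlpr_snp" in df.columns or (
        has_carrier and df[list(VARIANTS)].dtypes.eq(object).any()
    )
    if looks_raw:
        raw = df[[c for c in raw_cols if c in df.columns]]
        coded = recode_genotype_table(raw)
        for v in VARIANTS:
            df[v] = coded[v]
    elif not has_carrier:
        raise ValueError(
            f"cohort table needs carrier columns {list(VARIANTS)} or a raw "
            "genotype block including 'httlpr_snp'"
        )
    for v in VARIANTS:
        vals = set(pd.unique(df[v]))
        if not vals <= {0, 1}:
            raise ValueError(f"carrier column {v!r} must be 0/1, found {sorted(vals)}")

    df["sex"] = _decode(df["sex"], _SEX_CODES, "sex")
    df["pet_scanner"] = _decode(df["pet_scanner"], _PET_CODES, "pet_scanner")
    df["mri_scanner"] = _decode(df["mri_scanner"], _MRI_CODES, "mri_scanner")

    check_cols = base + list(VARIANTS) + list(REGIONS)
    if len(df) and df[check_cols].isna().any().any():
        bad = df[check_cols].columns[df[check_cols].isna().any()].tolist()
        raise ValueError(f"missing values in columns {bad}")
    import numpy as np

    for r in REGIONS:
        df[r] = df[r].astype(float)
        if len(df) and not np.isfinite(df[r].to_numpy()).all():
            raise ValueError(f"non-finite BP_ND values in region {r!r}")
    df["age"] = df["age"].astype(float)
    df["age_c"] = df["age"] - df["age"].mean() if len(df) else df["age"]
    return df


def read_cohort(path) -> pd.DataFrame:
    """Read and validate a cohort CSV/TSV."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    df = pd.read_csv(path, sep=sep, float_precision="round_trip")
    return validate_cohort(df)


def write_cohort(df: pd.DataFrame, path) -> None:
    """Write a cohort table with file-level codings (F/M, A/H, T/V)."""
    path = Path(path)
    out = df.copy()
    if len(out):
        out["sex"] = out["sex"].map({0: "F", 1: "M"})
        out["pet_scanner"] = out["pet_scanner"].map({0: "A", 1: "H"})
        out["mri_scanner"] = out["mri_scanner"].map({0: "T", 1: "V"})
    out = out.drop(columns=[c for c in ("age_c",) if c in out.columns])
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    out.to_csv(path, sep=sep, index=False)
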