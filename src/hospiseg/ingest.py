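"""Reading, validating, merging and de-suppressing the input tables.

The beneficiary summary table carries hospital-level Medicare
fee-for-service counts for five race/ethnicity groups; cells below the
privacy threshold (11 in the public release) arrive suppressed (empty).
Suppressed cells are resolved by residual division: the gap between the
hospital total and the sum of the disclosed group counts is split
equally among the suppressed groups.  The result conserves the hospital
total exactly and may be non-integer.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from hospiseg.definitions import (
    CROSSWALK_COLUMNS,
    GROUPS,
    IPBS_COLUMNS,
    RATINGS_COLUMNS,
    STRUCTURAL_BASE_COLUMNS,
)

logger = logging.getLogger(__name__)

_ABS_TOL = 1e-6  # slack for float round-trip of integer counts


def _read_csv_checked(path: str | Path, required: tuple[str, ...]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, dtype={"hospital_id": str})
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path.name}: missing required columns {missing}")
    if df["hospital_id"].duplicated().any():
        dups = df.loc[df["hospital_id"].duplicated(), "hospital_id"].tolist()
        raise ValueError(f"{path.name}: duplicate hospital_id {dups}")
    return df


def _parse_numeric(df: pd.DataFrame, col: str, name: str) -> pd.Series:
    """Coerce a column to numeric; empty cells become NaN (suppressed),
    anything else non-numeric is a parse error naming the row."""
    raw = df[col]
    out = pd.to_numeric(raw, errors="coerce")
    bad = out.isna() & raw.notna() & (raw.astype(str).str.strip() != "")
    if bad.any():
        i = int(np.flatnonzero(bad.to_numpy())[0])
        raise ValueError(
            f"{name}: malformed numeric value {raw.iloc[i]!r} in column {col!r}, row {i}"
        )
    return out


def read_ipbs_like(path: str | Path) -> pd.DataFrame:
    """Read a beneficiary-summary-style table.

    Returns one row per hospital with float group columns where NaN marks
    a suppressed cell.  Validates: unique ids, nonnegative counts, sum of
    disclosed group counts <= total, dual <= total.
    """
    df = _read_csv_checked(path, IPBS_COLUMNS)
    name = Path(path).name
    for col in IPBS_COLUMNS[1:]:
        df[col] = _parse_numeric(df, col, name)
    if df["total"].isna().any() or df["dual"].isna().any():
        raise ValueError(f"{name}: total and dual must not be missing")
    numeric = df[list(IPBS_COLUMNS[1:])]
    if (numeric < 0).any().any():
        raise ValueError(f"{name}: negative counts are not allowed")
    known = df[list(GROUPS)].fillna(0).sum(axis=1)
    over = known > df["total"] + _ABS_TOL
    if over.any():
        ids = df.loc[over, "hospital_id"].tolist()
        raise ValueError(f"{name}: disclosed group counts exceed total for {ids}")
    if (df["dual"] > df["total"] + _ABS_TOL).any():
        ids = df.loc[df["dual"] > df["total"] + _ABS_TOL, "hospital_id"].tolist()
        raise ValueError(f"{name}: dual enrollment exceeds total for {ids}")
    return df


def read_crosswalk(path: str | Path) -> pd.DataFrame:
    df = _read_csv_checked(path, CROSSWALK_COLUMNS)
    for col in ("county", "hrr", "hsa"):
        if df[col].isna().any() or (df[col].astype(str).str.strip() == "").any():
            raise ValueError(f"{Path(path).name}: empty {col} assignment")
    return df


def read_ratings(path: str | Path) -> pd.DataFrame:
    df = _read_csv_checked(path, RATINGS_COLUMNS)
    stars = _parse_numeric(df, "stars", Path(path).name)
    if ((stars < 0) | (stars > 5)).any():
        raise ValueError(f"{Path(path).name}: star ratings must be on the 0-5 scale")
    if (stars == 0).any():
        logger.warning("star rating of 0 present (public ratings are usually 1-5)")
    df["stars"] = stars
    return df


def read_structural(path: str | Path) -> pd.DataFrame:
    df = _read_csv_checked(path, STRUCTURAL_BASE_COLUMNS)
    name = Path(path).name
    for col in ("beds", "icu_beds", "total_expenses", "discharges_total",
                "discharges_medicaid", "discharges_uninsured"):
        df[col] = _parse_numeric(df, col, name)
        if df[col].isna().any() or (df[col] < 0).any():
            raise ValueError(f"{name}: column {col!r} must be complete and nonnegative")
    return df


def impute_suppressed(records: pd.DataFrame) -> pd.DataFrame:
    """Resolve suppressed group cells by equal division of the residual.

    Each missing group receives ``(total - sum(known)) / n_missing``;
    disclosed cells are unchanged.  Adds one boolean ``imputed_<group>``
    column per group.  Idempotent; conserves hospital totals exactly.

    Raises if the residual is negative while cells are missing (data
    inconsistent with the suppression model), or if no cells are missing
    but the disclosed counts do not add up to the total.
    """
    out = records.copy()
    counts = out[list(GROUPS)].to_numpy(dtype=float)
    totals = out["total"].to_numpy(dtype=float)
    miss = np.isnan(counts)
    n_missing = miss.sum(axis=1)
    residual = totals - np.nansum(counts, axis=1)

    bad = (n_missing > 0) & (residual < -_ABS_TOL)
    if bad.any():
        ids = out.loc[bad, "hospital_id"].tolist()
        raise ValueError(f"negative residual with suppressed cells for {ids}")
    incomplete = (n_missing == 0) & (np.abs(residual) > _ABS_TOL)
    if incomplete.any():
        ids = out.loc[incomplete, "hospital_id"].tolist()
        raise ValueError(f"group counts do not sum to total (no suppressed cells) for {ids}")

    with np.errstate(invalid="ignore", divide="ignore"):
        fill = np.where(n_missing > 0, np.maximum(residual, 0.0) / np.maximum(n_missing, 1), 0.0)
    counts[miss] = np.broadcast_to(fill[:, None], counts.shape)[miss]
    out[list(GROUPS)] = counts
    for j, g in enumerate(GROUPS):
        out[f"imputed_{g}"] = miss[:, j]
    return out


def merge_sources(
    ipbs: pd.DataFrame,
    crosswalk: pd.DataFrame,
    ratings: pd.DataFrame,
    structural: pd.DataFrame,
) -> pd.DataFrame:
    """Inner-join beneficiary, crosswalk and structural tables on
    hospital_id; left-join ratings (a hospital may be unrated).

    Hospitals with zero beneficiaries are dropped with a warning (their
    composition is undefined).  Logs the number of hospitals dropped per
    source; raises if nothing survives.
    """
    n0 = len(ipbs)
    zero = ipbs["total"] <= 0
    if zero.any():
        logger.warning("dropping %d hospital(s) with zero beneficiaries", int(zero.sum()))
        ipbs = ipbs[~zero]

    ids = set(ipbs["hospital_id"]) & set(crosswalk["hospital_id"]) & set(structural["hospital_id"])
    for name, tbl in (("ipbs", ipbs), ("crosswalk", crosswalk), ("structural", structural)):
        dropped = len(tbl) - tbl["hospital_id"].isin(ids).sum()
        logger.info("merge: %d hospital(s) from %s not in all sources", int(dropped), name)
    merged = (
        ipbs.merge(crosswalk, on="hospital_id", how="inner")
        .merge(structural, on="hospital_id", how="inner")
        .merge(ratings[["hospital_id", "stars"]], on="hospital_id", how="left")
    )
    if merged.empty:
        raise ValueError("no hospitals present in all sources")
    merged["rating_missing"] = merged["stars"].isna()
    logger.info("merge: %d of %d hospitals retained", len(merged), n0)
    return merged.reset_index(drop=True)


def load_inputs(in_dir: str | Path) -> dict[str, pd.DataFrame]:
    """Read the four tables from a directory with the canonical file names."""
    d = Path(in_dir)
    return {
        "ipbs": read_ipbs_like(d / "ipbs.csv"),
        "crosswalk": read_crosswalk(d / "crosswalk.csv"),
        "ratings": read_ratings(d / "ratings.csv"),
        "structural": read_structural(d / "structural.csv"),
    }
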