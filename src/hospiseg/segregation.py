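"""Dissimilarity index of hospital patient composition within geographies.

For a race/ethnicity group x in a geographic area G containing hospitals
i = 1..n, with p_i patients in hospital i, P = sum p_i, m_i the group's
share in hospital i and M its share in the whole area, the dissimilarity
index is

    DI_x = sum_i  p_i * |m_i - M| / (2 * P * M * (1 - M))

DI is 0 when every hospital mirrors the area composition and 1 under
complete separation; it equals the classic two-group form
(1/2) * sum_i |x_i/X - y_i/Y| where x_i are the group counts and y_i the
complement counts, and is interpretable as the share of the group that
would have to change hospitals for perfect evenness.  It is undefined
when the area share M is 0 or 1 (group absent or universal); such units
are flagged and excluded from summaries rather than counted as zero.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from hospiseg.definitions import GROUPS, LEVELS, MINORITY, REPORTED_GROUPS

#: numpy quantile interpolation used for all IQRs (type-7, linear).
QUANTILE_METHOD = "linear"


def composition(records: pd.DataFrame) -> pd.DataFrame:
    """Per-hospital group shares from an imputed count table.

    Adds ``share_<group>`` columns for the five groups plus
    ``share_minority`` (= 1 - NHW share).  Requires positive totals.
    """
    if (records["total"] <= 0).any():
        bad = records.loc[records["total"] <= 0, "hospital_id"].tolist()
        raise ValueError(f"composition undefined for zero-total hospitals {bad}")
    out = records.copy()
    for g in GROUPS:
        out[f"share_{g}"] = out[g] / out["total"]
    out[f"share_{MINORITY}"] = 1.0 - out["share_nhw"]
    return out


def dissimilarity_index(p, m) -> float:
    """Weighted dissimilarity index for one area.

    Parameters
    ----------
    p : array-like
        Patient totals per hospital (all > 0).
    m : array-like
        Group share per hospital, in [0, 1].

    Returns
    -------
    float
        DI in [0, 1], or NaN when the area share M is 0 or 1
        (mathematically undefined, not an error).
    """
    p = np.asarray(p, dtype=float)
    m = np.asarray(m, dtype=float)
    if p.shape != m.shape or p.ndim != 1 or p.size == 0:
        raise ValueError("p and m must be equal-length 1-d arrays")
    if np.any(p <= 0):
        raise ValueError("hospital patient totals must be positive")
    if np.any((m < 0) | (m > 1)):
        raise ValueError("group shares must lie in [0, 1]")
    # Idempotent double-complement projection: after it, a share vector
    # and its complement (1 - m) are exact floating-point mirrors, so
    # the canonical flip below makes DI(m) == DI(1 - m) bit-exactly.
    m = 1.0 - (1.0 - m)
    P = p.sum()
    M = float((p * m).sum() / P)
    if M <= 0.0 or M >= 1.0:
        return math.nan
    if p.size == 1 or np.all(m == m[0]):
        return 0.0  # every hospital mirrors the area: perfectly even
    if M > 0.5:
        # evaluate on the smaller-share side (complement symmetry)
        m = 1.0 - m
        M = float((p * m).sum() / P)
    return float((p * np.abs(m - M)).sum() / (2.0 * P * M * (1.0 - M)))


def classic_di_oracle(x, y) -> float:
    """Classic two-group dissimilarity: (1/2) * sum |x_i/X - y_i/Y|.

    Independent closed form used to validate the weighted formula;
    x are group counts per hospital, y the complement counts.
    NaN when either margin is zero.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    X, Y = x.sum(), y.sum()
    if X <= 0 or Y <= 0:
        return math.nan
    return float(0.5 * np.abs(x / X - y / Y).sum())


def _group_share_column(group: str) -> str:
    if group not in REPORTED_GROUPS and group not in GROUPS:
        raise ValueError(f"unknown group {group!r}")
    return f"share_{group}"


def di_by_level(
    analytic: pd.DataFrame,
    level: str,
    groups: tuple[str, ...] = REPORTED_GROUPS,
) -> pd.DataFrame:
    """Dissimilarity index per (geographic unit, group) at one level.

    ``analytic`` must carry ``total``, the ``share_*`` columns (see
    :func:`composition`) and, for sub-region levels, the crosswalk
    column named after the level.  The region level treats the whole
    table as a single unit.

    Returns a tidy frame: level, unit_id, group, di, n_hospitals, P, M,
    defined.
    """
    if level not in LEVELS:
        raise ValueError(f"unknown level {level!r}; expected one of {LEVELS}")
    if level == "region":
        unit_ids = pd.Series(["region"] * len(analytic), index=analytic.index)
    else:
        if level not in analytic.columns:
            raise ValueError(f"analytic table lacks a {level!r} column")
        unit_ids = analytic[level]
        if unit_ids.isna().any():
            raise ValueError(f"hospitals without a {level} assignment")

    rows = []
    for unit, sub in analytic.groupby(unit_ids, sort=True):
        p = sub["total"].to_numpy(dtype=float)
        P = float(p.sum())
        for g in groups:
            m = sub[_group_share_column(g)].to_numpy(dtype=float)
            M = float((p * m).sum() / P)
            di = dissimilarity_index(p, m)
            rows.append(
                {
                    "level": level,
                    "unit_id": unit,
                    "group": g,
                    "di": di,
                    "n_hospitals": len(sub),
                    "P": P,
                    "M": M,
                    "defined": not math.isnan(di),
                }
            )
    return pd.DataFrame(rows)


def summarize_level(
    results: pd.DataFrame,
    min_hospitals_per_unit: int = 1,
) -> pd.DataFrame:
    """Median and IQR of DI across units, per (level, group).

    Units with undefined DI (area share 0 or 1) or fewer than
    ``min_hospitals_per_unit`` hospitals are excluded and counted in
    ``n_units_excluded``.  IQR endpoints use linear-interpolation
    (type-7) quantiles.  Raises if every unit of some (level, group) is
    excluded.
    """
    if results.empty:
        raise ValueError("no DI results to summarize")
    rows = []
    for (level, group), sub in results.groupby(["level", "group"], sort=False):
        ok = sub["defined"] & (sub["n_hospitals"] >= min_hospitals_per_unit)
        used = sub.loc[ok, "di"].to_numpy(dtype=float)
        if used.size == 0:
            raise ValueError(f"all units excluded for level={level!r} group={group!r}")
        lo, med, hi = np.quantile(used, [0.25, 0.5, 0.75], method=QUANTILE_METHOD)
        rows.append(
            {
                "level": level,
                "group": group,
                "median_di": float(med),
                "iqr_low": float(lo),
                "iqr_high": float(hi),
                "n_units_used": int(used.size),
                "n_units_excluded": int((~ok).sum()),
            }
        )
    return pd.DataFrame(rows)
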