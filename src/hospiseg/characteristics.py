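"""Derived hospital structural and quality measures.

Eight characteristics per hospital: overall quality star rating (passed
through, possibly missing), ICU beds as a percentage of total general
beds, total expenses per bed, two composite service counts (7 essential
professional services; 9 essential diagnostic/treatment/imaging items),
percent of beneficiaries dually enrolled in Medicare and Medicaid,
ownership category, and safety-net status (top quartile of hospitals by
percent of discharges that are Medicaid or uninsured).
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd

from hospiseg.definitions import DIAGNOSTIC_SERVICES, PROFESSIONAL_SERVICES

#: quantile used for the safety-net cut (linear interpolation, type-7);
#: hospitals at or above the threshold are flagged (inclusive ties).
SAFETY_NET_QUANTILE = 0.75


def _count_indicators(indicators: Mapping[str, object], keys: tuple[str, ...]) -> int:
    total = 0
    for k in keys:
        v = indicators.get(k, 0)
        if isinstance(v, (bool, np.bool_)):
            total += int(v)
        elif isinstance(v, (int, np.integer)) and v in (0, 1):
            total += int(v)
        else:
            raise ValueError(f"indicator {k!r} must be boolean/0-1, got {v!r}")
    return total


def count_essential_professional(indicators: Mapping[str, object]) -> int:
    """Number offered among the 7 essential professional services.

    Absent keys count as not offered; keys outside the canonical seven
    are ignored.
    """
    return _count_indicators(indicators, PROFESSIONAL_SERVICES)


def count_essential_diagnostic(indicators: Mapping[str, object]) -> int:
    """Number offered among the 9 essential diagnostic/treatment/imaging items."""
    return _count_indicators(indicators, DIAGNOSTIC_SERVICES)


def flag_safety_net(discharges: pd.DataFrame) -> pd.DataFrame:
    """Rank hospitals by percent Medicaid/uninsured discharges and flag
    the top quartile.

    Requires ``hospital_id``, ``discharges_total``, ``discharges_medicaid``
    and ``discharges_uninsured`` columns with positive totals.  Returns a
    frame with ``pct``, dense ``rank`` (1 = highest pct) and ``flagged``;
    the threshold (type-7 75th percentile, ties flagged inclusively) is
    stored in ``.attrs["threshold"]``.
    """
    zero = discharges["discharges_total"] <= 0
    if zero.any():
        ids = discharges.loc[zero, "hospital_id"].tolist()
        raise ValueError(f"zero total discharges for {ids}")
    pct = 100.0 * (
        discharges["discharges_medicaid"] + discharges["discharges_uninsured"]
    ) / discharges["discharges_total"]
    threshold = float(np.quantile(pct.to_numpy(dtype=float), SAFETY_NET_QUANTILE))
    out = pd.DataFrame(
        {
            "hospital_id": discharges["hospital_id"],
            "pct_medicaid_uninsured_discharges": pct,
            "rank": pct.rank(ascending=False, method="dense").astype(int),
            "flagged": pct >= threshold,
        }
    ).reset_index(drop=True)
    out.attrs["threshold"] = threshold
    out.attrs["quantile_method"] = "linear (type 7), ties flagged inclusively (>= threshold)"
    return out


def derive_characteristics(
    structural: pd.DataFrame,
    analytic: pd.DataFrame,
) -> pd.DataFrame:
    """Build the per-hospital characteristics table.

    ``structural`` is the raw survey table (beds, expenses, service
    indicators, ownership, discharges); ``analytic`` supplies
    ``total``, ``dual`` and, when present, ``stars``.  Pure function of
    its inputs.
    """
    merged = structural.merge(
        analytic[["hospital_id", "total", "dual"]
                 + (["stars"] if "stars" in analytic.columns else [])],
        on="hospital_id",
        how="inner",
    )
    if (merged["beds"] <= 0).any():
        ids = merged.loc[merged["beds"] <= 0, "hospital_id"].tolist()
        raise ValueError(f"hospitals with zero beds: {ids}")
    if (merged["dual"] > merged["total"]).any():
        ids = merged.loc[merged["dual"] > merged["total"], "hospital_id"].tolist()
        raise ValueError(f"dual enrollment exceeds beneficiary total for {ids}")

    svc_cols = {c: c.removeprefix("svc_") for c in merged.columns if c.startswith("svc_")}
    indicator_rows = [
        {name: int(row[col]) for col, name in svc_cols.items()}
        for _, row in merged.iterrows()
    ]
    out = pd.DataFrame(
        {
            "hospital_id": merged["hospital_id"],
            "star_rating": merged["stars"] if "stars" in merged.columns else np.nan,
            "icu_pct": 100.0 * merged["icu_beds"] / merged["beds"],
            "expense_per_bed": merged["total_expenses"] / merged["beds"],
            "n_essential_prof": [count_essential_professional(r) for r in indicator_rows],
            "n_essential_diag": [count_essential_diagnostic(r) for r in indicator_rows],
            "dual_pct": 100.0 * merged["dual"] / merged["total"],
            "ownership": merged["ownership"],
        }
    )
    sn = flag_safety_net(merged)
    out = out.merge(
        sn[["hospital_id", "flagged"]].rename(columns={"flagged": "safety_net"}),
        on="hospital_id",
        how="left",
    )
    out.attrs["safety_net_threshold"] = sn.attrs["threshold"]
    return out
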