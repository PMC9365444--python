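"""Rank-based association analysis.

Spearman rank correlations between hospital race/ethnicity composition
and hospital characteristics (pairwise-complete over missing values),
composition cross-correlations, and Wilcoxon rank-sum comparisons of
compositions/characteristics across hospital strata (safety-net status,
ownership).

Spearman p-values use the t approximation with n-2 degrees of freedom;
rank-sum p-values are exact for small untied samples (as in R's
``wilcox.test``) and otherwise use the tie-corrected normal
approximation with continuity correction.  Both statistics handle ties
by average ranks.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
import pandas as pd
from scipy import stats

from hospiseg.definitions import REPORTED_GROUPS

#: numeric characteristics entering correlation / comparison tables
NUMERIC_CHARACTERISTICS = (
    "star_rating",
    "icu_pct",
    "expense_per_bed",
    "n_essential_prof",
    "n_essential_diag",
    "dual_pct",
)


@dataclasses.dataclass(frozen=True)
class CorrelationResult:
    var_x: str
    var_y: str
    rho: float          # NaN when undefined (constant input)
    p_value: float
    n_pairs: int

    @property
    def defined(self) -> bool:
        return not math.isnan(self.rho)


@dataclasses.dataclass(frozen=True)
class RankSumResult:
    variable: str
    group_a: str
    group_b: str
    n_a: int
    n_b: int
    statistic: float    # rank sum of group a (average ranks for ties)
    p_value: float


def spearman(x, y, var_x: str = "x", var_y: str = "y") -> CorrelationResult:
    """Spearman rank correlation with pairwise deletion of missing values.

    Average ranks for ties; two-sided p from the t approximation with
    n-2 df.  A constant vector yields an undefined (NaN) rho rather
    than an error.  Requires >= 3 complete pairs.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-d vectors")
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    n = int(x.size)
    if n < 3:
        raise ValueError(f"need at least 3 complete pairs, got {n}")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return CorrelationResult(var_x, var_y, math.nan, math.nan, n)
    rho, p = stats.spearmanr(x, y)
    return CorrelationResult(var_x, var_y, float(rho), float(p), n)


def rank_sum_test(a, b, variable: str = "", group_a: str = "a", group_b: str = "b") -> RankSumResult:
    """Wilcoxon rank-sum (Mann-Whitney) test of two independent samples.

    Reports the rank sum of the first sample (average ranks for ties)
    and a two-sided p-value: exact enumeration when either sample has
    at most 8 untied observations (the small-sample default of R's
    ``wilcox.test``), otherwise the tie-corrected normal approximation
    with continuity correction.  With fewer than 4 observations combined
    the p-value is NaN.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")
    n_a, n_b = int(a.size), int(b.size)
    u1, p = stats.mannwhitneyu(a, b, alternative="two-sided", method="auto",
                               use_continuity=True)
    w_a = float(u1) + n_a * (n_a + 1) / 2.0
    if n_a + n_b < 4:
        p = math.nan
    return RankSumResult(variable, group_a, group_b, n_a, n_b, w_a, float(p))


def _share_cols(groups=REPORTED_GROUPS) -> list[str]:
    return [f"share_{g}" for g in groups]


def _merge_chars(analytic: pd.DataFrame, characteristics: pd.DataFrame) -> pd.DataFrame:
    # characteristics wins on any column both tables carry (e.g. ownership)
    overlap = [c for c in analytic.columns if c != "hospital_id" and c in characteristics.columns]
    return analytic.drop(columns=overlap).merge(characteristics, on="hospital_id", how="inner")


def composition_correlation_matrix(analytic: pd.DataFrame) -> list[CorrelationResult]:
    """All pairwise Spearman correlations among the five reported group
    shares (NHW, NHB, Hispanic, API/AIAN, minority) across hospitals.

    Because minority share = 1 - NHW share by construction, the
    (NHW, minority) entry is exactly -1 on any dataset.
    """
    if len(analytic) < 3:
        raise ValueError("need at least 3 hospitals")
    cols = _share_cols()
    out = []
    for i, cx in enumerate(cols):
        for cy in cols[i + 1:]:
            out.append(
                spearman(analytic[cx], analytic[cy],
                         var_x=cx.removeprefix("share_"), var_y=cy.removeprefix("share_"))
            )
    return out


def characteristic_correlations(
    analytic: pd.DataFrame,
    characteristics: pd.DataFrame,
) -> list[CorrelationResult]:
    """Spearman correlation of each group share with each numeric
    characteristic; missing characteristic values (e.g. unrated
    hospitals) are dropped pairwise, so n varies per pair."""
    merged = _merge_chars(analytic, characteristics)
    out = []
    for g in REPORTED_GROUPS:
        for c in NUMERIC_CHARACTERISTICS:
            out.append(
                spearman(merged[f"share_{g}"], merged[c], var_x=g, var_y=c)
            )
    return out


def group_comparisons(
    analytic: pd.DataFrame,
    characteristics: pd.DataFrame,
    by: str,
) -> list[RankSumResult]:
    """Rank-sum comparison of every composition share and numeric
    characteristic across the two strata of ``by`` (``safety_net`` or
    ``ownership``)."""
    if by not in ("safety_net", "ownership"):
        raise ValueError(f"unknown stratifier {by!r}")
    merged = _merge_chars(analytic, characteristics)
    if by == "safety_net":
        mask = merged["safety_net"].astype(bool)
        label_a, label_b = "safety_net", "non_safety_net"
    else:
        mask = merged["ownership"] == "nonfederal_government"
        label_a, label_b = "nonfederal_government", "nonprofit"
    if not mask.any():
        raise ValueError(f"stratum {label_a!r} is empty")
    if mask.all():
        raise ValueError(f"stratum {label_b!r} is empty")

    variables = _share_cols() + list(NUMERIC_CHARACTERISTICS)
    out = []
    for v in variables:
        a = merged.loc[mask, v]
        b = merged.loc[~mask, v]
        name = v.removeprefix("share_") + ("_share" if v.startswith("share_") else "")
        out.append(rank_sum_test(a, b, variable=name, group_a=label_a, group_b=label_b))
    return out


def correlations_to_frame(results: list[CorrelationResult]) -> pd.DataFrame:
    return pd.DataFrame([dataclasses.asdict(r) for r in results])


def rank_sums_to_frame(results: list[RankSumResult]) -> pd.DataFrame:
    return pd.DataFrame([dataclasses.asdict(r) for r in results])


def benjamini_hochberg(p_values) -> np.ndarray:
    """Optional BH-adjusted p-values (off by default in all outputs)."""
    p = np.asarray(p_values, dtype=float)
    n = p.size
    order = np.argsort(p)
    adj = np.empty(n)
    adj[order] = np.minimum.accumulate((p[order] * n / np.arange(1, n + 1))[::-1])[::-1]
    return np.minimum(adj, 1.0)
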