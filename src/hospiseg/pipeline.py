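"""End-to-end analysis pipeline over the four input tables.

Stages: read + merge (inner join on hospital id, ratings optional) ->
residual-division imputation of suppressed cells -> per-hospital group
shares -> dissimilarity indices at each geographic level with
median/IQR summaries -> derived hospital characteristics -> rank-based
association tables.

Outputs are the study-shaped tables:

* T1 — per-county mean (SD) of composition and characteristics, plus
  counts of safety-net / ownership categories;
* T2 — median (IQR) dissimilarity index by geographic level and group;
* T3 — Spearman correlations among group shares across hospitals;
* T4 — Spearman correlations of group shares with structure/quality
  measures (pairwise-complete n per cell);
* F2 — per-group distribution quantiles (median, IQR) across hospitals;

plus tidy per-unit DI results and machine-readable run metadata
(conventions, exclusions, per-stage counts).  All user-facing shares and
DI values are percentages; internal values are fractions.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from hospiseg.association import (
    _merge_chars,
    composition_correlation_matrix,
    characteristic_correlations,
    correlations_to_frame,
    group_comparisons,
    rank_sums_to_frame,
)
from hospiseg.characteristics import derive_characteristics
from hospiseg.definitions import LEVELS, REPORTED_GROUPS
from hospiseg.ingest import impute_suppressed, load_inputs, merge_sources
from hospiseg.segregation import composition, di_by_level, summarize_level

logger = logging.getLogger(__name__)


def _table1(analytic: pd.DataFrame, chars: pd.DataFrame) -> pd.DataFrame:
    """Per-county mean (SD) of compositions (as percent) and numeric
    characteristics, with counts of safety-net and ownership categories."""
    merged = _merge_chars(analytic, chars)
    rows = []
    numeric = {
        **{f"share_{g}": f"pct_{g}" for g in REPORTED_GROUPS},
        "star_rating": "star_rating",
        "icu_pct": "icu_pct",
        "expense_per_bed": "expense_per_bed",
        "n_essential_prof": "n_essential_prof",
        "n_essential_diag": "n_essential_diag",
        "dual_pct": "dual_pct",
    }
    for county, sub in merged.groupby("county", sort=True):
        for col, name in numeric.items():
            vals = sub[col].astype(float)
            scale = 100.0 if col.startswith("share_") else 1.0
            rows.append(
                {
                    "county": county,
                    "n_hospitals": len(sub),
                    "variable": name,
                    "statistic": "mean (sd)",
                    "mean": scale * vals.mean(),
                    "sd": scale * vals.std(ddof=1) if len(sub) > 1 else 0.0,
                }
            )
        for name, flag in (
            ("safety_net", sub["safety_net"].astype(bool)),
            ("nonfederal_government", sub["ownership"] == "nonfederal_government"),
            ("nonprofit", sub["ownership"] == "nonprofit"),
        ):
            rows.append(
                {
                    "county": county,
                    "n_hospitals": len(sub),
                    "variable": name,
                    "statistic": "n (pct)",
                    "mean": int(flag.sum()),
                    "sd": 100.0 * flag.mean(),
                }
            )
    return pd.DataFrame(rows)


def _figure2(analytic: pd.DataFrame) -> pd.DataFrame:
    """Across-hospital distribution of each group share: median and IQR
    (type-7 quantiles), in percent."""
    rows = []
    for g in REPORTED_GROUPS:
        vals = analytic[f"share_{g}"].to_numpy(dtype=float)
        lo, med, hi = np.quantile(vals, [0.25, 0.5, 0.75])
        rows.append(
            {
                "group": g,
                "median_pct": 100.0 * med,
                "iqr_low_pct": 100.0 * lo,
                "iqr_high_pct": 100.0 * hi,
                "n_hospitals": vals.size,
            }
        )
    return pd.DataFrame(rows)


@dataclasses.dataclass
class PipelineResult:
    analytic: pd.DataFrame
    characteristics: pd.DataFrame
    di_results: pd.DataFrame
    tables: dict[str, pd.DataFrame]   # T1, T2, T3, T4, F2
    metadata: dict


def run_pipeline(
    in_dir: str | Path,
    out_dir: str | Path | None = None,
    levels: tuple[str, ...] = LEVELS,
    min_hospitals_per_unit: int = 1,
) -> PipelineResult:
    """Run the full analysis on a directory holding the four input CSVs.

    When ``out_dir`` is given, writes the five tables, the tidy DI
    results, the analytic table and JSON run metadata there.
    """
    inputs = load_inputs(in_dir)
    logger.info("stage ingest: %d hospitals in beneficiary table", len(inputs["ipbs"]))

    merged = merge_sources(
        inputs["ipbs"], inputs["crosswalk"], inputs["ratings"], inputs["structural"]
    )
    imputed = impute_suppressed(merged)
    analytic = composition(imputed)
    logger.info("stage composition: %d hospitals analytic", len(analytic))

    di_frames = [di_by_level(analytic, level) for level in levels]
    di_results = pd.concat(di_frames, ignore_index=True)
    di_summary = summarize_level(di_results, min_hospitals_per_unit)
    logger.info("stage segregation: %d unit-group DI values", len(di_results))

    chars = derive_characteristics(inputs["structural"], analytic)
    logger.info("stage characteristics: %d hospitals", len(chars))

    t3 = correlations_to_frame(composition_correlation_matrix(analytic))
    t4 = correlations_to_frame(characteristic_correlations(analytic, chars))
    comparisons = []
    for by in ("safety_net", "ownership"):
        try:
            comparisons.append(rank_sums_to_frame(group_comparisons(analytic, chars, by)))
        except ValueError as exc:  # a degenerate stratum: skip with a log line
            logger.warning("stage association: comparison by %s skipped (%s)", by, exc)
    comparisons_df = (
        pd.concat(comparisons, ignore_index=True) if comparisons else pd.DataFrame()
    )

    t2 = di_summary.copy()
    t2["median_di_pct"] = 100.0 * t2["median_di"]
    t2["iqr_low_pct"] = 100.0 * t2["iqr_low"]
    t2["iqr_high_pct"] = 100.0 * t2["iqr_high"]
    t2 = t2[
        ["level", "group", "median_di_pct", "iqr_low_pct", "iqr_high_pct",
         "n_units_used", "n_units_excluded"]
    ]

    tables = {
        "T1": _table1(analytic, chars),
        "T2": t2,
        "T3": t3,
        "T4": t4,
        "F2": _figure2(analytic),
        "comparisons": comparisons_df,
    }

    from hospiseg import __version__  # deferred: avoids import cycle

    metadata = {
        "package_version": __version__,
        "n_hospitals": int(len(analytic)),
        "n_imputed_cells": int(analytic[[f"imputed_{g}" for g in
                                         ("nhw", "nhb", "hispanic", "api_aian", "other")]]
                               .to_numpy().sum()),
        "levels": list(levels),
        "min_hospitals_per_unit": int(min_hospitals_per_unit),
        "conventions": {
            "quantiles": "linear interpolation (type 7)",
            "di_scale": "tables report percent; internal values are fractions",
            "undefined_di": "units with area share 0 or 1 excluded from summaries",
            "spearman_p": "t approximation, n-2 df, average ranks",
            "rank_sum_p": "exact for small untied samples; otherwise normal "
                          "approximation with tie and continuity corrections",
            "table1_dispersion": "mean (SD); counts as n (pct)",
            "multiple_testing": "unadjusted p-values",
        },
        "di_exclusions": {
            f"{r.level}/{r.group}": int(r.n_units_excluded)
            for r in di_summary.itertuples()
            if r.n_units_excluded
        },
    }

    result = PipelineResult(
        analytic=analytic,
        characteristics=chars,
        di_results=di_results,
        tables=tables,
        metadata=metadata,
    )
    if out_dir is not None:
        _write_outputs(result, out_dir)
    return result


def _write_outputs(result: PipelineResult, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    di = result.di_results.copy()
    di["di_pct"] = 100.0 * di["di"]
    di["M_pct"] = 100.0 * di["M"]
    di[["level", "unit_id", "group", "di_pct", "n_hospitals", "P", "M_pct", "defined"]].to_csv(
        out / "di_results.csv", index=False
    )
    result.tables["T2"].to_csv(out / "di_summary.csv", index=False)
    result.tables["T1"].to_csv(out / "table1_county_characteristics.csv", index=False)
    result.tables["T3"].to_csv(out / "table3_composition_correlations.csv", index=False)
    result.tables["T4"].to_csv(out / "table4_characteristic_correlations.csv", index=False)
    result.tables["F2"].to_csv(out / "fig2_composition_distribution.csv", index=False)
    if not result.tables["comparisons"].empty:
        result.tables["comparisons"].to_csv(out / "group_comparisons.csv", index=False)
    result.analytic.to_csv(out / "analytic.csv", index=False)
    result.characteristics.to_csv(out / "characteristics.csv", index=False)
    with open(out / "run_metadata.json", "w") as fh:
        json.dump(result.metadata, fh, indent=2, sort_keys=True)
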