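"""Synthetic hospital-system generator.

Emulates the statistical structure of the four inputs the analysis
consumes — a hospital-by-race beneficiary count table with small-cell
suppression, a hospital->geography crosswalk (county / HRR / HSA), a
star-rating table, and a structural survey table — so every downstream
stage can be exercised without any external data.

Model
-----
Geography is a nested hierarchy: counties contain HSAs, HSAs contain
hospitals; counties map onto HRRs via ``hrr_grouping``.  Compositions are
Dirichlet-multinomial:

* each county's mean composition is drawn from a Dirichlet centred on
  ``region_group_means`` with spread controlled by ``county_dispersion``
  (larger value => more between-county spread);
* each hospital's composition is drawn from a Dirichlet centred on its
  county mean with total concentration ``hospital_concentration`` — the
  segregation knob: small values give polarised hospitals within a
  geography (high dissimilarity), large values give near-identical
  hospitals (dissimilarity -> 0);
* integer group counts are multinomial draws of each hospital's total.

Hospital totals are log-normal with a floor, so small hospitals exist
and small-cell suppression (< ``suppression_threshold``) occurs
naturally in small groups.  Star ratings are a discretised noisy
monotone transform of minority share with slope ``rating_link_strength``
(<= 0); dual Medicare/Medicaid enrollment and the Medicaid/uninsured
discharge mix rise with minority share at slope ``dual_link_strength``
(>= 0).  Structural capacity measures (beds, ICU beds, expenses, service
lines) are generated independently of composition.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from hospiseg.definitions import (
    ALL_SERVICES,
    DIAGNOSTIC_SERVICES,
    GROUPS,
    PROFESSIONAL_SERVICES,
)

# Region mean composition: the four named groups scaled to sum to 99%
# (NHW-heavy metropolitan mix) plus a 1% residual "other" group.
DEFAULT_REGION_MEANS = (0.670, 0.152, 0.131, 0.037, 0.010)


def default_hrr_grouping(n_counties: int) -> dict[str, str]:
    """Round-robin assignment of counties to ~2/3 as many HRRs.

    Mirrors the real geography where regional referral markets span one
    or two counties (e.g. 9 counties grouped into 6 HRRs).
    """
    n_hrrs = max(1, round(2 * n_counties / 3))
    return {f"cty{i:02d}": f"hrr{i % n_hrrs:02d}" for i in range(n_counties)}


class SyntheticConfig(BaseModel):
    """Parameters of the synthetic hospital system.

    Defaults emulate the scale of a nine-county metropolitan study
    region: 36 HSAs, 6 HRRs, 72 hospitals, a few thousand Medicare
    fee-for-service beneficiaries per hospital.
    """

    model_config = ConfigDict(frozen=True)

    n_counties: int = Field(default=9, ge=1)
    hsas_per_county: int = Field(default=4, ge=1)
    hospitals_per_hsa: int = Field(default=2, ge=1)
    hrr_grouping: dict[str, str] | None = None
    hospital_size_log_mean: float = 8.0
    hospital_size_log_sd: float = Field(default=1.0, gt=0)
    region_group_means: tuple[float, float, float, float, float] = DEFAULT_REGION_MEANS
    county_dispersion: float = Field(default=0.12, gt=0)
    hospital_concentration: float = Field(default=2.0, gt=0)
    rating_link_strength: float = Field(default=-3.0, le=0)
    dual_link_strength: float = Field(default=4.0, ge=0)
    rating_missing_frac: float = Field(default=0.2, ge=0, le=1)
    suppression_threshold: int = Field(default=11, ge=0)
    allow_crosscutting: bool = False
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "SyntheticConfig":
        total = float(sum(self.region_group_means))
        if abs(total - 1.0) > 1e-12:
            raise ValueError(f"region_group_means must sum to 1, got {total!r}")
        if any(s < 0 for s in self.region_group_means):
            raise ValueError("region_group_means must be nonnegative")
        if self.hrr_grouping is not None:
            expected = {f"cty{i:02d}" for i in range(self.n_counties)}
            if set(self.hrr_grouping) != expected:
                raise ValueError(
                    "hrr_grouping must map exactly the generated county ids "
                    f"{sorted(expected)}; got {sorted(self.hrr_grouping)}"
                )
        return self

    @property
    def n_hospitals(self) -> int:
        return self.n_counties * self.hsas_per_county * self.hospitals_per_hsa

    def resolved_hrr_grouping(self) -> dict[str, str]:
        if self.hrr_grouping is not None:
            return dict(self.hrr_grouping)
        return default_hrr_grouping(self.n_counties)


@dataclasses.dataclass
class SyntheticRegion:
    """One generated hospital system: the four masked input tables plus
    the unmasked truth retained for test oracles."""

    ipbs: pd.DataFrame          # hospital_id,total,<5 groups with NaN where suppressed>,dual
    crosswalk: pd.DataFrame     # hospital_id,county,hrr,hsa
    ratings: pd.DataFrame       # hospital_id,stars (only rated hospitals)
    structural: pd.DataFrame    # hospital_id,beds,...,svc_* indicators
    truth: dict                 # {"counts": unmasked df, "county_means": df,
                                #  "hospital_shares": df, "config": SyntheticConfig}


def apply_suppression(truth_counts: pd.DataFrame, threshold: int) -> pd.DataFrame:
    """Mask small cells: every group count strictly below ``threshold``
    becomes missing (NaN); totals and cells >= threshold are untouched.

    ``truth_counts`` must carry the five group columns; other columns
    pass through unchanged.
    """
    if threshold < 0:
        raise ValueError("threshold must be nonnegative")
    group_cols = [g for g in GROUPS if g in truth_counts.columns]
    vals = truth_counts[group_cols].to_numpy()
    if np.any(vals < 0):
        raise ValueError("group counts must be nonnegative")
    masked = truth_counts.copy()
    masked[group_cols] = masked[group_cols].astype(float).where(
        truth_counts[group_cols] >= threshold
    )
    return masked


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def generate_region(config: SyntheticConfig) -> SyntheticRegion:
    """Draw one synthetic hospital system. Deterministic given the seed."""
    rng = np.random.default_rng(config.seed)
    hrr_map = config.resolved_hrr_grouping()

    counties = [f"cty{i:02d}" for i in range(config.n_counties)]

    # --- hierarchy: HSAs nest in counties; hospitals allocated randomly
    # across a county's HSAs with at least one per HSA, so single-hospital
    # HSAs occur (as they do in real local hospital markets).
    rows = []
    hosp_idx = 0
    for county in counties:
        hsas = [f"hsa_{county}_{j}" for j in range(config.hsas_per_county)]
        n_hosp_county = config.hsas_per_county * config.hospitals_per_hsa
        extra = n_hosp_county - len(hsas)
        alloc = np.ones(len(hsas), dtype=int)
        if extra > 0:
            alloc += rng.multinomial(extra, np.full(len(hsas), 1.0 / len(hsas)))
        for hsa, k in zip(hsas, alloc):
            for _ in range(k):
                rows.append(
                    {
                        "hospital_id": f"hosp{hosp_idx:03d}",
                        "county": county,
                        "hrr": hrr_map[county],
                        "hsa": hsa,
                    }
                )
                hosp_idx += 1
    crosswalk = pd.DataFrame(rows, columns=["hospital_id", "county", "hrr", "hsa"])
    if config.allow_crosscutting:
        # Reassign HRRs independently of county, to exercise downstream
        # code on a partition that does not nest in the others.
        hrr_ids = sorted(set(hrr_map.values()))
        crosswalk["hrr"] = rng.choice(hrr_ids, size=len(crosswalk))
    n_hospitals = len(crosswalk)

    # --- hospital sizes: log-normal, floored so shares are defined and
    # suppression bites in small hospitals.
    totals = np.exp(
        rng.normal(config.hospital_size_log_mean, config.hospital_size_log_sd, n_hospitals)
    )
    totals = np.maximum(30, np.round(totals)).astype(int)

    # --- compositions: county Dirichlet around the region mean, hospital
    # Dirichlet around the county mean.  Alphas floored away from zero
    # (numpy requires alpha > 0); near-zero group means still yield
    # near-zero counts.
    region_means = np.asarray(config.region_group_means, dtype=float)
    county_alpha = np.maximum(region_means / config.county_dispersion, 1e-6)
    county_means = rng.dirichlet(county_alpha, size=config.n_counties)
    county_means = np.maximum(county_means, 1e-4)
    county_means /= county_means.sum(axis=1, keepdims=True)
    county_mean_df = pd.DataFrame(county_means, index=counties, columns=list(GROUPS))

    county_of = crosswalk["county"].to_numpy()
    county_idx = np.array([counties.index(c) for c in county_of])
    hosp_alpha = np.maximum(
        config.hospital_concentration * county_means[county_idx], 1e-9
    )
    shares = np.vstack([rng.dirichlet(a) for a in hosp_alpha])
    counts = np.vstack([rng.multinomial(t, s) for t, s in zip(totals, shares)])

    truth_counts = pd.DataFrame(counts, columns=list(GROUPS))
    truth_counts.insert(0, "total", totals)
    truth_counts.insert(0, "hospital_id", crosswalk["hospital_id"].to_numpy())

    minority_share = 1.0 - counts[:, 0] / totals

    # --- dual Medicare/Medicaid enrollment: logistic in minority share.
    dual_logit = -2.0 + config.dual_link_strength * minority_share + rng.normal(0, 0.3, n_hospitals)
    dual = rng.binomial(totals, _sigmoid(dual_logit))
    truth_counts["dual"] = dual

    # --- star ratings: noisy monotone latent in minority share, rounded
    # to the 0-5 integer scale; a fraction missing completely at random.
    minority_region_mean = 1.0 - region_means[0]
    latent = (
        3.0
        + config.rating_link_strength * (minority_share - minority_region_mean)
        + rng.normal(0, 1.0, n_hospitals)
    )
    stars = np.clip(np.round(latent), 0, 5).astype(int)
    rated = rng.random(n_hospitals) >= config.rating_missing_frac
    ratings = pd.DataFrame(
        {"hospital_id": crosswalk["hospital_id"][rated], "stars": stars[rated]}
    ).reset_index(drop=True)

    # --- structural table: capacity measures independent of composition;
    # discharge payer mix linked to minority share (so safety-net status
    # correlates with composition); ownership mildly linked.
    beds = np.maximum(10, np.round(totals / rng.uniform(8.0, 15.0, n_hospitals))).astype(int)
    icu_beds = rng.binomial(beds, 0.14)
    expenses = np.round(beds * rng.lognormal(np.log(9e5), 0.35, n_hospitals)).astype(np.int64)
    svc = {}
    for s in PROFESSIONAL_SERVICES:
        svc[f"svc_{s}"] = rng.binomial(1, 0.85, n_hospitals)
    for s in DIAGNOSTIC_SERVICES:
        svc[f"svc_{s}"] = rng.binomial(1, 0.72, n_hospitals)
    own_p = _sigmoid(-2.2 + 2.0 * minority_share)
    ownership = np.where(
        rng.random(n_hospitals) < own_p, "nonfederal_government", "nonprofit"
    )
    discharges_total = np.round(totals * rng.uniform(1.2, 2.0, n_hospitals)).astype(int)
    mu_share = 0.6 * _sigmoid(
        -2.0 + config.dual_link_strength * minority_share + rng.normal(0, 0.3, n_hospitals)
    )
    discharges_medicaid = rng.binomial(discharges_total, 0.8 * mu_share)
    discharges_uninsured = rng.binomial(discharges_total, 0.2 * mu_share)
    structural = pd.DataFrame(
        {
            "hospital_id": crosswalk["hospital_id"],
            "beds": beds,
            "icu_beds": icu_beds,
            "total_expenses": expenses,
            "ownership": ownership,
            "discharges_total": discharges_total,
            "discharges_medicaid": discharges_medicaid,
            "discharges_uninsured": discharges_uninsured,
            **svc,
        }
    )

    ipbs = apply_suppression(truth_counts, config.suppression_threshold)

    truth = {
        "counts": truth_counts,
        "county_means": county_mean_df,
        "hospital_shares": pd.DataFrame(
            shares, columns=list(GROUPS), index=crosswalk["hospital_id"]
        ),
        "config": config,
    }
    return SyntheticRegion(
        ipbs=ipbs, crosswalk=crosswalk, ratings=ratings, structural=structural, truth=truth
    )


def write_region(region: SyntheticRegion, out_dir: str | Path) -> None:
    """Write the four input CSVs (suppressed cells as empty strings), the
    generator config as YAML, and the unmasked table under ``truth/``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ipbs = region.ipbs.copy()
    # Suppressed cells -> empty string; intact cells back to integers.
    for g in GROUPS:
        ipbs[g] = ipbs[g].map(lambda v: "" if pd.isna(v) else str(int(v)))
    ipbs.to_csv(out / "ipbs.csv", index=False)
    region.crosswalk.to_csv(out / "crosswalk.csv", index=False)
    region.ratings.to_csv(out / "ratings.csv", index=False)
    region.structural.to_csv(out / "structural.csv", index=False)
    cfg: SyntheticConfig = region.truth["config"]
    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump(cfg.model_dump(), fh, sort_keys=True)
    truth_dir = out / "truth"
    truth_dir.mkdir(exist_ok=True)
    region.truth["counts"].to_csv(truth_dir / "counts.csv", index=False)
    region.truth["county_means"].to_csv(truth_dir / "county_means.csv", index_label="county")
    region.truth["hospital_shares"].to_csv(truth_dir / "hospital_shares.csv")


def load_config(path: str | Path) -> SyntheticConfig:
    with open(path) as fh:
        raw: Mapping = yaml.safe_load(fh) or {}
    if raw.get("region_group_means") is not None:
        raw = dict(raw)
        raw["region_group_means"] = tuple(raw["region_group_means"])
    return SyntheticConfig(**raw)
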