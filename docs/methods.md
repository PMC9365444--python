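# Methods

## The measure

`hospiseg` quantifies how unevenly a race/ethnicity group is distributed
across the hospitals of a geographic area, using the dissimilarity index
(DI), the classical evenness measure from demographic segregation
research.  For a group *x* in an area *G* with hospitals *i = 1..n*,
patient totals *p_i* (area total *P*), group shares *m_i* (area share
*M*):

    DI_x = Σ_i  p_i |m_i − M| / (2 P M (1 − M))

DI = 0 when every hospital mirrors the area composition; DI = 1 under
complete separation.  It equals the textbook two-group form
½ Σ |x_i/X − y_i/Y| on the group counts *x_i* and their complements
*y_i = p_i − x_i* (the package carries both forms; their algebraic
identity is asserted in tests to 1e-10 on random instances).  A DI of
0.40 is read as: 40% of the group's patients would need to change
hospitals to make the area perfectly integrated.

The index is computed for non-Hispanic White (NHW), non-Hispanic Black
(NHB), Hispanic, API/AIAN and the combined minority (non-NHW) group,
within four nested levels: the whole region, counties, hospital referral
regions (HRRs) and hospital service areas (HSAs).  Comparing levels
exposes the modifiable-areal-unit effect: segregation measured within
small local markets is mechanically smaller than region-wide
segregation.

### Properties relied on

* **Bounds**: DI ∈ [0, 1] whenever M ∈ (0, 1).
* **Complement symmetry**: DI of a group equals DI of its complement,
  so DI(NHW) = DI(minority) always.
* **Scale invariance**: multiplying all patient counts by a constant
  leaves DI unchanged.
* **Degeneracies**: a single-hospital unit has DI = 0 (the hospital *is*
  the area); a unit where the group is absent (M = 0) or universal
  (M = 1) has an *undefined* DI — such units are flagged and excluded
  from summaries rather than counted as zeros, which would bias medians
  downward.

### Numerical choices

Shares pass through the idempotent projection `m → 1 − (1 − m)` and the
index is evaluated on the smaller-share side (complementing when
M > ½).  This costs at most one ulp per share and makes complement
symmetry hold *bit-exactly*, not just to rounding error — without it,
DI(m) and DI(1 − m) can differ in the last ulp because the
floating-point complement is not an involution.  Perfectly even and
single-hospital units short-circuit to exactly 0.  All quantile
summaries (DI medians/IQRs, safety-net threshold, composition
distributions) use linear-interpolation (type-7) quantiles; the
convention is recorded in run metadata.

## Suppression and imputation

Public hospital-by-race beneficiary tables suppress cells below 11 to
protect privacy.  Suppressed cells are resolved by residual division:
the hospital total minus the sum of disclosed group counts, divided
equally among the suppressed groups.  This conserves hospital totals
exactly (asserted to 1e-9), may produce non-integer counts (accepted
downstream — shares tolerate reals), and bounds each cell's error below
the suppression threshold, since every suppressed true cell and every
equal split of their sum is below it.  A negative residual is a hard
error, not clamped: the inputs would then contradict the suppression
model, and silent clamping would hide corrupted data.  Imputation runs
after the four-way merge of the input tables.

## Hospital characteristics

Eight measures per hospital: star rating (0–5, passed through from the
quality table; missing ratings stay missing), ICU beds as % of total
general beds, total expenses per bed, counts of 7 essential professional
services and of 9 essential diagnostic/treatment/imaging items
(indicator sums over fixed canonical item lists; unrelated indicators
ignored), % of beneficiaries dually enrolled in Medicare and Medicaid
(a socioeconomic-disadvantage proxy), ownership, and safety-net status.
Safety-net = top quartile of hospitals by % of discharges that are
Medicaid or uninsured, computed with type-7 percentiles and inclusive
tie handling (every hospital at or above the threshold is flagged).
Note that agencies applying this definition on a national pool will flag
a different (often larger) share of any particular region's hospitals
than the within-sample quartile used here.

## Association stage

Spearman rank correlations (average ranks for ties; two-sided p from the
t approximation with n − 2 df) relate hospital composition to
characteristics, with pairwise-complete deletion so each pair reports
its own n.  Wilcoxon rank-sum tests compare compositions and
characteristics across safety-net status and ownership strata; p-values
are exact by enumeration when a sample has ≤ 8 untied observations
(matching R's `wilcox.test` small-sample default) and otherwise use the
tie-corrected normal approximation with continuity correction.  Exact
enumeration oracles in the test suite bound the approximation error
(≤ 0.05 for the Spearman t form at n = 6, verified exhaustively).
Because minority share is defined as 1 − NHW share, their rank
correlation is −1 on any dataset; this structural identity doubles as an
end-to-end wiring check.  P-values are reported unadjusted; a
Benjamini–Hochberg helper exists but is off by default.

## Synthetic-data generator

The generator emulates the statistical structure of the four inputs —
not any real region's demography.  Geography is a nested hierarchy
(default 9 counties × 4 HSAs × 2 hospitals = 72 hospitals, 36 HSAs, 6
HRRs via a county→HRR grouping: the closest integer grid to a
9-county / 37-HSA / 6-HRR / 84-hospital metropolitan study region).
Hospitals are allocated randomly across a county's HSAs with at least
one each, so single-hospital HSAs arise as they do in real local
markets.  An `allow_crosscutting` flag reassigns HRRs independently of
county to exercise the partition-agnostic DI code.

* **Compositions**: county means ~ Dirichlet centred on the region mix
  (default 67/15.2/13.1/3.7/1% for NHW/NHB/Hispanic/API-AIAN/other; the
  residual "other" held at 1%), with spread set by `county_dispersion`
  (alpha = mean/dispersion, so larger is more dispersed; default 0.12
  gives county NHW means ranging over tens of points).  Hospital shares
  ~ Dirichlet centred on the county mean with total concentration
  `hospital_concentration` — the segregation knob.  The default of 2.0
  reproduces a realistic across-hospital NHW spread (IQR spanning tens
  of points); integer counts are multinomial draws of log-normal
  hospital totals (default log-mean 8, log-sd 1, floor 30), so
  small-cell suppression arises naturally.
* **Quality link**: star rating = round(3 + slope·(minority share −
  region mean) + N(0,1)) clipped to 0–5, slope `rating_link_strength`
  ≤ 0 (default −3, giving ρ ≈ −0.5 at n ≈ 70); 20% of ratings missing
  completely at random.
* **Disadvantage link**: dual-enrollment and Medicaid/uninsured
  discharge proportions are logistic in minority share with slope
  `dual_link_strength` (default 4, giving ρ ≈ 0.9), so safety-net
  status correlates with composition.  Ownership is mildly linked the
  same way.  Structural capacity (beds, ICU beds ≈ 14% of beds,
  expenses ≈ $0.9M/bed, service lines) is generated independently of
  composition.

### What the generator does not emulate

A single Dirichlet concentration cannot match both the wide spread of
large groups and the tight, never-zero shares of small groups: with the
default knob, rare groups (API/AIAN, other) collapse to near-zero shares
in many hospitals, making the synthetic region more segregated overall
(region DI ≈ 0.6) than a typical real metropolitan hospital system
(≈ 0.3–0.4) and producing undefined DIs for rare groups in some small
units (correctly flagged and excluded).  There is no spatial geometry,
no hospital closures/mergers, and no claim of demographic realism for
any real region.  Passing tests therefore demonstrate correctness of
the measures, the suppression/imputation mechanics and the recovery of
planted composition–quality links — not that real-data estimates will
take any particular value.

## Problem sizes in tests

Property tests run on 10⁴ random DI instances and 1,000
oracle-equivalence instances; null calibration uses 2,000 generator
draws of a 24-hospital system; link recovery uses 200 draws at 84
hospitals; the concentration sweep covers 5 knob values × 5 seeds at the
default 72-hospital scale.  The whole suite runs in well under a minute
on one CPU.

## Known limitations

* The safety-net quartile is within-sample; regional flag counts will
  not match national-pool definitions.
* DI is the only segregation measure implemented (no exposure,
  isolation, entropy or spatially weighted variants).
* Unit-level DI medians are unweighted across units; patient-weighted
  summaries are not offered.
* The imputation rule assumes suppressed cells are genuinely below the
  threshold; inconsistent inputs abort rather than repair.
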