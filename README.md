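# hospiseg

Hospital-based racial and ethnic segregation analysis for Medicare-style
hospital data.

Racial and ethnic minority patients are often concentrated in a subset
of a region's hospitals, and those hospitals can differ systematically
in resources and quality.  `hospiseg` is a pipeline for quantifying that
phenomenon from hospital-level public data: it ingests a
hospital-by-race beneficiary count table (with the small-cell
suppression typical of public releases), a hospital→geography crosswalk
(county, hospital referral region, hospital service area), a quality
star-rating table and a structural survey table; measures segregation
with the dissimilarity index at four nested geographic levels; derives
eight hospital structural/quality characteristics; and tests their
association with patient composition using rank-based statistics.  It
is written for health-services and disparities researchers who want the
whole chain — suppression handling included — reproducible and tested.

## The measure

For race/ethnicity group *x* in area *G* with hospitals *i = 1..n*
(patient totals *p_i*, area total *P*, group shares *m_i*, area share
*M*), the dissimilarity index is

```
DI_x = Σ_i  p_i |m_i − M| / (2 P M (1 − M))
```

DI ranges from 0 (every hospital mirrors the area) to 1 (complete
separation) and is read as the share of the group's patients who would
have to change hospitals for perfect evenness.  It is computed for NHW,
NHB, Hispanic, API/AIAN and the combined minority (non-NHW) group at the
region, county, HRR and HSA levels, and summarized as median (IQR)
across the units of each level.  Suppressed count cells (< 11) are
resolved by residual division: the gap between the hospital total and
the disclosed cells, split equally among the suppressed ones.
Associations are measured with Spearman rank correlations and Wilcoxon
rank-sum tests.  See `docs/methods.md` for conventions and numerical
details.

A synthetic-data generator (`hospiseg synth`) emulates all four input
tables — nested geography, Dirichlet-multinomial compositions with a
tunable segregation knob, natural small-cell suppression, and planted
composition–quality links — so the full pipeline runs and is testable
without downloading anything.

## Worked example

Generate a synthetic 72-hospital region (9 counties, 36 HSAs, 6 HRRs)
and run the full analysis:

```
hospiseg synth --out demo/in --seed 1
hospiseg run --in demo/in --out demo/out
```

or equivalently in Python:

```python
import hospiseg as hs
from hospiseg.synthetic import write_region
from hospiseg.pipeline import run_pipeline

write_region(hs.generate_region(hs.SyntheticConfig(seed=1)), "demo/in")
result = run_pipeline("demo/in", "demo/out")
print(result.tables["T2"])   # DI median (IQR) by level and group
```

Selected output for this seed — NHW dissimilarity (in percent) by
geographic level, from `demo/out/di_summary.csv`:

| level  | median DI % | IQR %       | units used |
|--------|-------------|-------------|------------|
| region | 54.0        | —           | 1          |
| county | 57.2        | 35.9–61.4   | 9          |
| hrr    | 56.7        | 39.0–61.9   | 6          |
| hsa    | 10.3        | 0.0–46.4    | 36         |

Region-wide, 54% of NHW (equivalently, minority) patients would need to
change hospitals for perfect integration; within the small local
markets (HSAs) the measured unevenness is much lower — the
modifiable-areal-unit effect.  The association tables for the same run
show the planted links recovered: Spearman ρ between minority share and
star rating −0.61 (n = 63 rated hospitals), between minority share and
dual Medicare/Medicaid enrollment +0.92, and ρ(NHW, minority) = −1.00
exactly, as forced by minority = 1 − NHW.  Outputs land as CSV tables
(county summaries, DI per unit and per level, correlation and
comparison tables, composition quantiles) plus `run_metadata.json`
recording seeds, conventions and exclusions.

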