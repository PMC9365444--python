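"""Shared vocabulary: race/ethnicity groups, geographic levels, service items.

Race/ethnicity groups follow the enhanced (RTI-style) Medicare coding:
non-Hispanic White (NHW), non-Hispanic Black (NHB), Hispanic,
Asian/Pacific Islander + Alaskan Native/American Indian (API/AIAN), and a
small residual "other".  The combined "minority" group is everything that
is not NHW (NHB + Hispanic + API/AIAN + other).
"""

# Columns of the beneficiary count table, in canonical order.
GROUPS = ("nhw", "nhb", "hispanic", "api_aian", "other")

# Groups reported in user-facing tables: the four named groups plus the
# combined minority (non-NHW) group; "other" is folded into minority and
# never reported alone.
REPORTED_GROUPS = ("nhw", "nhb", "hispanic", "api_aian", "minority")

MINORITY = "minority"

# Geographic levels, coarsest to finest.  "region" is the whole study
# area as a single unit; the rest come from the hospital->geography
# crosswalk (county, hospital referral region, hospital service area).
LEVELS = ("region", "county", "hrr", "hsa")

# The 7 essential professional services counted into one composite score.
PROFESSIONAL_SERVICES = (
    "emergency_department",
    "adult_cardiology",
    "neurological",
    "oncology",
    "orthopedic",
    "psychiatric_child_adolescent",
    "palliative_care",
)

# The 9 essential diagnostic / treatment / imaging items.
DIAGNOSTIC_SERVICES = (
    "cath_diagnostic",
    "cath_interventional",
    "cardiac_electrophysiology",
    "hemodialysis",
    "optical_colonoscopy",
    "endoscopic_ultrasound",
    "ct_scanner",
    "mri",
    "ultrasound",
)

ALL_SERVICES = PROFESSIONAL_SERVICES + DIAGNOSTIC_SERVICES

# CSV schemas consumed by ingest.
IPBS_COLUMNS = ("hospital_id", "total", "nhw", "nhb", "hispanic", "api_aian", "other", "dual")
CROSSWALK_COLUMNS = ("hospital_id", "county", "hrr", "hsa")
RATINGS_COLUMNS = ("hospital_id", "stars")
STRUCTURAL_BASE_COLUMNS = (
    "hospital_id",
    "beds",
    "icu_beds",
    "total_expenses",
    "ownership",
    "discharges_total",
    "discharges_medicaid",
    "discharges_uninsured",
)
STRUCTURAL_COLUMNS = STRUCTURAL_BASE_COLUMNS + tuple(f"svc_{s}" for s in ALL_SERVICES)

OWNERSHIP_CATEGORIES = ("nonfederal_government", "nonprofit")
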