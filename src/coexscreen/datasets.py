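"""Bundled example data: the 36-patient lung adenocarcinoma cohort.

Published per-patient clinical values for a surgical lung adenocarcinoma
cohort stratified by EGFR mutation status (Ex19del n=9, L858R n=9, neither
n=18): sex, age in years, tumour size on CT in mm, and maximal pathological
size in mm.  Used as a worked example for the covariate group comparison.
"""

from __future__ import annotations

import pandas as pd

from .io import TraitDesign

# sample, sex, age_years, ct_size_mm, path_size_mm, status
_COHORT = [
    ("Patient01", "F", 58, 18, 20, "EX19DEL"),
    ("Patient02", "F", 75, 46, 40, "EX19DEL"),
    ("Patient03", "F", 72, 52, 39, "EX19DEL"),
    ("Patient04", "F", 72, 13, 20, "EX19DEL"),
    ("Patient05", "M", 74, 18, 17, "EX19DEL"),
    ("Patient06", "M", 71, 26, 51, "EX19DEL"),
    ("Patient07", "F", 71, 27, 28, "EX19DEL"),
    ("Patient08", "F", 40, 26, 14, "EX19DEL"),
    ("Patient09", "F", 70, 24, 22, "EX19DEL"),
    ("Patient10", "M", 72, 18, 7, "L858R"),
    ("Patient11", "F", 76, 43, 25, "L858R"),
    ("Patient12", "M", 71, 42, 37, "L858R"),
    ("Patient13", "M", 73, 46, 30, "L858R"),
    ("Patient14", "F", 64, 26, 18, "L858R"),
    ("Patient15", "M", 64, 27, 30, "L858R"),
    ("Patient16", "F", 69, 45, 32, "L858R"),
    ("Patient17", "F", 76, 22, 15, "L858R"),
    ("Patient18", "M", 73, 33, 35, "L858R"),
    ("Patient19", "M", 69, 15, 12, "NONE"),
    ("Patient20", "F", 80, 54, 45, "NONE"),
    ("Patient21", "M", 73, 42, 30, "NONE"),
    ("Patient22", "M", 72, 36, 22, "NONE"),
    ("Patient23", "M", 63, 14, 11, "NONE"),
    ("Patient24", "M", 66, 18, 9, "NONE"),
    ("Patient25", "F", 69, 7, 8, "NONE"),
    ("Patient26", "M", 55, 12, 20, "NONE"),
    ("Patient27", "M", 82, 25, 15, "NONE"),
    ("Patient28", "F", 70, 45, 45, "NONE"),
    ("Patient29", "M", 74, 18, 15, "NONE"),
    ("Patient30", "F", 62, 19, 22, "NONE"),
    ("Patient31", "M", 65, 31, 30, "NONE"),
    ("Patient32", "M", 68, 26, 23, "NONE"),
    ("Patient33", "M", 63, 34, 27, "NONE"),
    ("Patient34", "M", 60, 28, 21, "NONE"),
    ("Patient35", "F", 22, 17, 20, "NONE"),
    ("Patient36", "M", 70, 28, 25, "NONE"),
]


def egfr_cohort() -> pd.DataFrame:
    """The cohort as a DataFrame (sample, sex, age, tumour sizes, status)."""
    return pd.DataFrame(
        _COHORT,
        columns=["sample_id", "sex", "age_years", "ct_size_mm", "path_size_mm", "status"],
    )


def egfr_cohort_traits() -> TraitDesign:
    """The cohort as a TraitDesign with age and tumour sizes as covariates."""
    df = egfr_cohort()
    cov = df[["age_years", "ct_size_mm", "path_size_mm"]].astype(float)
    return TraitDesign(list(df["sample_id"]), list(df["status"]), cov)
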