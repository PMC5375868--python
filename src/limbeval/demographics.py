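"""Reference demographics of an 18-subject hemiparetic stroke cohort.

The table below records the published demographic and clinical profile of a
representative post-stroke cohort with substantial upper-limb hemiparesis
(Brunnstrom stage 3 or later): sex, height (cm), weight (kg), paretic side,
age (years), days since onset, upper-extremity Fugl-Meyer total (0-66) and
Brunnstrom stage.  It anchors the synthetic-cohort generator to realistic
ages, sexes and clinical-score ranges, and supports cohort-level summary
statistics.
"""

from __future__ import annotations

import pandas as pd

_COLUMNS = (
    "sex",
    "height_cm",
    "weight_kg",
    "paretic_side",
    "age",
    "onset_days",
    "fmue",
    "brunnstrom",
)

_STROKE_ROWS = (
    ("M", 175, 71, "left", 72, 40, 50, 4),
    ("F", 159, 48, "right", 52, 33, 58, 5),
    ("M", 181, 81, "right", 50, 11, 59, 5),
    ("M", 162, 65, "right", 58, 21, 40, 4),
    ("F", 173, 66, "right", 53, 366, 37, 4),
    ("M", 176, 75, "right", 30, 457, 25, 4),
    ("M", 168, 68, "right", 61, 68, 48, 4),
    ("F", 162, 49, "left", 75, 48, 40, 5),
    ("M", 176, 71, "left", 46, 49, 41, 3),
    ("M", 170, 68, "left", 69, 10, 10, 3),
    ("F", 165, 55, "left", 50, 36, 21, 3),
    ("F", 158, 49, "left", 50, 51, 48, 5),
    ("M", 175, 72, "right", 51, 78, 24, 3),
    ("F", 155, 45, "right", 81, 81, 51, 5),
    ("M", 178, 72, "left", 44, 225, 38, 3),
    ("F", 163, 66, "left", 51, 584, 35, 4),
    ("M", 169, 73, "left", 59, 40, 57, 5),
    ("M", 175, 72, "left", 43, 71, 45, 4),
)


def stroke_reference_cohort() -> pd.DataFrame:
    """The reference stroke cohort as a DataFrame (one row per subject)."""
    return pd.DataFrame(list(_STROKE_ROWS), columns=list(_COLUMNS))


def cohort_summary() -> dict:
    """Summary statistics of the reference cohort (means, counts)."""
    df = stroke_reference_cohort()
    return {
        "n": len(df),
        "mean_age": float(df["age"].mean()),
        "n_female": int((df["sex"] == "F").sum()),
        "n_male": int((df["sex"] == "M").sum()),
        "mean_fmue": float(df["fmue"].mean()),
        "age_range": (int(df["age"].min()), int(df["age"].max())),
    }
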