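"""Published patient-characteristics table of the crossover study.

Twenty ICU patients ready to wean, as printed in the study report this
pipeline's cohort calibration targets.  Used to validate the summary
conventions (median and 1st-3rd quartiles by linear interpolation) against
the printed medians.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["study_patients"]

_ROWS = [
    # patient, age, sex, bmi, saps2, ett_id
    (1, 64, "female", 20, 67, 7.0),
    (2, 60, "female", 30, 31, 7.0),
    (3, 64, "male", 30, 35, 7.5),
    (4, 55, "female", 13, 34, 7.0),
    (5, 59, "male", 23, 31, 8.0),
    (6, 70, "male", 29, 63, 8.0),
    (7, 62, "male", 36, 43, 8.0),
    (8, 62, "female", 23, 52, 7.5),
    (9, 78, "male", 30, 67, 7.5),
    (10, 71, "male", 25, 53, 8.0),
    (11, 79, "male", 28, 50, 8.0),
    (12, 64, "male", 31, 84, 7.5),
    (13, 47, "male", 23, 46, 7.5),
    (14, 68, "male", 28, 66, 7.5),
    (15, 40, "female", 29, 40, 7.5),
    (16, 59, "male", 25, 59, 7.5),
    (17, 60, "male", 42, 35, 8.5),
    (18, 66, "male", 24, 57, 8.5),
    (19, 19, "male", 33, 37, 8.0),
    (20, 63, "male", 22, 67, 8.5),
]


def study_patients() -> pd.DataFrame:
    """The 20 published patient rows (age, sex, BMI, SAPS II, ETT ID)."""
    return pd.DataFrame(
        _ROWS, columns=["patient", "age", "sex", "bmi", "saps2", "ett_id"])
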