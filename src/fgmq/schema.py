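"""Harmonized microdata schema shared by every pipeline stage.

One row is one respondent: either a woman aged 15-49 answering about
herself (``module="women"``, self-report) or a daughter aged 0-14 whose
mother answered for her (``module="daughters"``, proxy report).

In-memory representation
------------------------
Records travel as a :class:`pandas.DataFrame` with the CSV schema columns.
``age_at_fgm`` is a float column where ``NaN`` means *missing*; the
approximate "during infancy" answer is carried in the companion boolean
column ``age_at_fgm_approx`` (the CSV serializes it as the token
``INFANCY`` in the ``age_at_fgm`` field).  Pooling adds ``weight_denorm``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

#: exact CSV column order of the harmonized schema
COLUMNS = [
    "survey_id",
    "module",
    "current_age",
    "birth_cohort",
    "fgm_status",
    "age_at_fgm",
    "education",
    "dob_complete",
    "stratum_id",
    "cluster_id",
    "weight_norm",
]

#: token used in the age_at_fgm CSV field for the approximate infancy answer
APPROX_INFANCY = "INFANCY"

#: CSV tokens read as missing (written back as the empty string)
MISSING_TOKENS = ("", "NA")

MODULES = ("women", "daughters")
COHORTS = ("1960s", "1970s", "1980s", "1990s", "2000s", "2010s", "post2020", "missing")
FGM_STATUS = ("yes", "no", "missing")
EDUCATION = ("none", "primary", "secondary", "higher", "other", "missing")
DOB = ("complete", "imputed")

#: eligible current-age range per module (inclusive)
AGE_RANGE = {"women": (15, 49), "daughters": (0, 14)}

#: internal flag column marking the infancy sentinel
APPROX_COL = "age_at_fgm_approx"


def weight_column(records: pd.DataFrame) -> str:
    """Preferred analysis weight: denormalized if pooling has run, else normalized."""
    return "weight_denorm" if "weight_denorm" in records.columns else "weight_norm"


def cohort_from_birth_year(birth_year) -> pd.Series:
    """Bin birth years into the decade cohorts used throughout the analysis."""
    y = pd.Series(np.asarray(birth_year))
    out = pd.Series("missing", index=y.index, dtype=object)
    out[(y >= 1960) & (y < 1970)] = "1960s"
    out[(y >= 1970) & (y < 1980)] = "1970s"
    out[(y >= 1980) & (y < 1990)] = "1980s"
    out[(y >= 1990) & (y < 2000)] = "1990s"
    out[(y >= 2000) & (y < 2010)] = "2000s"
    out[(y >= 2010) & (y < 2020)] = "2010s"
    out[y >= 2020] = "post2020"
    return out


def age_reported(records: pd.DataFrame) -> pd.Series:
    """Boolean mask: age at FGM was reported (a number or the infancy answer).

    Completeness analyses count the approximate infancy answer as reported;
    only a truly absent value is incomplete.
    """
    numeric = records["age_at_fgm"].notna()
    if APPROX_COL in records.columns:
        return numeric | records[APPROX_COL].fillna(False).astype(bool)
    return numeric


class SchemaError(ValueError):
    """Raised when a file or frame violates the harmonized schema."""
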