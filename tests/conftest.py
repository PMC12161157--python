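import numpy as np
import pandas as pd
import pytest

from fgmq.schema import APPROX_COL, COLUMNS

_DEFAULT = {
    "survey_id": "SV1",
    "module": "women",
    "current_age": 30,
    "birth_cohort": "1980s",
    "fgm_status": "yes",
    "age_at_fgm": 4.0,
    APPROX_COL: False,
    "education": "none",
    "dob_complete": "imputed",
    "stratum_id": "SV1-h0",
    "cluster_id": "SV1-h0-c0",
    "weight_norm": 1.0,
}

ORDER = COLUMNS[:6] + [APPROX_COL] + COLUMNS[6:]


def make_records(rows):
    """Build a validated-layout records frame from partial row dicts."""
    full = []
    for row in rows:
        r = dict(_DEFAULT)
        r.update(row)
        full.append(r)
    df = pd.DataFrame(full, columns=ORDER)
    df["age_at_fgm"] = df["age_at_fgm"].astype(float)
    df["current_age"] = df["current_age"].astype(int)
    df["weight_norm"] = df["weight_norm"].astype(float)
    df[APPROX_COL] = df[APPROX_COL].astype(bool)
    return df


@pytest.fixture
def record_factory():
    return make_records


@pytest.fixture
def rng():
    return np.random.default_rng(20251001)
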