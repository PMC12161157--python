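"""Reading and writing harmonized respondent microdata and result tables.

The ingestion boundary is a comma-separated file with the exact header of
:data:`fgmq.schema.COLUMNS`.  Every row either becomes a validated record or
is rejected with a line-numbered diagnostic; the caller always gets both the
accepted records and the rejection report, so no row disappears silently.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .schema import (
    AGE_RANGE,
    APPROX_COL,
    APPROX_INFANCY,
    COHORTS,
    COLUMNS,
    DOB,
    EDUCATION,
    FGM_STATUS,
    MISSING_TOKENS,
    MODULES,
    SchemaError,
)

_FLOAT_FMT = "%.12g"  # round-trips weights to 12 significant digits


def _is_missing(s: pd.Series) -> pd.Series:
    return s.isin(MISSING_TOKENS)


def read_microdata(
    path,
    schema_version: str = "1",
    weights_raw: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read a harmonized microdata CSV.

    Parameters
    ----------
    path
        CSV file with header exactly matching the harmonized schema.
    schema_version
        Schema label; only ``"1"`` exists.
    weights_raw
        If True, ``weight_norm`` is stored in the DHS six-implied-decimals
        integer convention and is divided by 10**6 on read.

    Returns
    -------
    (records, rejects)
        ``records``: validated frame (``age_at_fgm`` float with NaN missing,
        plus boolean ``age_at_fgm_approx``).  ``rejects``: one row per
        rejected input row with columns ``line`` (1-based file line) and
        ``reason``.

    Raises
    ------
    SchemaError
        On an unknown or absent column, an unsupported schema version, or a
        violated cluster/stratum nesting.
    """
    if schema_version != "1":
        raise SchemaError(f"unknown schema_version {schema_version!r}")
    raw = pd.read_csv(path, dtype=str, keep_default_na=False, skipinitialspace=True)
    unknown = [c for c in raw.columns if c not in COLUMNS]
    if unknown:
        raise SchemaError(f"unknown column {unknown[0]!r}")
    absent = [c for c in COLUMNS if c not in raw.columns]
    if absent:
        raise SchemaError(f"missing column {absent[0]!r}")
    raw = raw[COLUMNS]
    return validate_records(raw, weights_raw=weights_raw)


def validate_records(
    raw: pd.DataFrame, weights_raw: bool = False
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Validate a string-typed frame row by row; split into accepted/rejected."""
    n = len(raw)
    reason = pd.Series("", index=raw.index, dtype=object)

    def flag(mask, why):
        new = mask & (reason == "")
        reason[new] = why

    flag(~raw["module"].isin(MODULES), "unknown module")
    cur_age = pd.to_numeric(raw["current_age"], errors="coerce")
    flag(cur_age.isna() | (cur_age != cur_age.round()), "current_age not an integer")
    for mod, (lo, hi) in AGE_RANGE.items():
        bad = (raw["module"] == mod) & ~((cur_age >= lo) & (cur_age <= hi))
        flag(bad, "age outside module range")

    cohort = raw["birth_cohort"].where(~_is_missing(raw["birth_cohort"]), "missing")
    flag(~cohort.isin(COHORTS), "unknown birth_cohort")
    fgm = raw["fgm_status"].where(~_is_missing(raw["fgm_status"]), "missing")
    flag(~fgm.isin(FGM_STATUS), "unknown fgm_status")

    afgm_str = raw["age_at_fgm"]
    afgm_missing = _is_missing(afgm_str)
    afgm_approx = afgm_str == APPROX_INFANCY
    afgm_num = pd.to_numeric(
        afgm_str.where(~(afgm_missing | afgm_approx), "0"), errors="coerce"
    )
    flag(afgm_num.isna() | (afgm_num != afgm_num.round()), "age_at_fgm not an integer")
    flag(~afgm_missing & ~afgm_approx & (afgm_num < 0), "age_at_fgm negative")
    flag(
        ~afgm_missing & (fgm != "yes"),
        "age_at_fgm without fgm_status=yes",
    )

    edu = raw["education"].where(~_is_missing(raw["education"]), "missing")
    flag(~edu.isin(EDUCATION), "unknown education")
    flag(~raw["dob_complete"].isin(DOB), "unknown dob_complete")

    w = pd.to_numeric(raw["weight_norm"], errors="coerce")
    if weights_raw:
        w = w / 1e6
    flag(w.isna() | ~(w > 0), "weight_norm not positive")
    flag(_is_missing(raw["survey_id"]), "missing survey_id")
    flag(_is_missing(raw["stratum_id"]) | _is_missing(raw["cluster_id"]), "missing design id")

    rejected = reason != ""
    rejects = pd.DataFrame(
        {"line": (raw.index[rejected] + 2).astype(int), "reason": reason[rejected]}
    ).reset_index(drop=True)

    keep = raw[~rejected]
    records = pd.DataFrame(
        {
            "survey_id": keep["survey_id"].astype(str),
            "module": keep["module"].astype(str),
            "current_age": cur_age[~rejected].astype(int),
            "birth_cohort": cohort[~rejected].astype(str),
            "fgm_status": fgm[~rejected].astype(str),
            "age_at_fgm": afgm_num[~rejected].where(
                ~(afgm_missing | afgm_approx)[~rejected], np.nan
            ),
            APPROX_COL: afgm_approx[~rejected].astype(bool),
            "education": edu[~rejected].astype(str),
            "dob_complete": keep["dob_complete"].astype(str),
            "stratum_id": keep["stratum_id"].astype(str),
            "cluster_id": keep["cluster_id"].astype(str),
            "weight_norm": w[~rejected].astype(float),
        }
    ).reset_index(drop=True)

    # cluster ids must be nested in strata, strata in surveys
    nest = records.drop_duplicates(["survey_id", "stratum_id", "cluster_id"])
    dup = nest.duplicated(["survey_id", "cluster_id"])
    if dup.any():
        cid = nest.loc[dup, "cluster_id"].iloc[0]
        raise SchemaError(f"cluster {cid!r} appears in more than one stratum")

    assert len(records) + len(rejects) == n
    return records, rejects


def write_microdata(records: pd.DataFrame, path) -> str:
    """Write records back to the harmonized CSV (inverse of :func:`read_microdata`).

    Extra columns such as ``weight_denorm`` are appended after the schema
    columns so pooled/preprocessed intermediates survive a round trip.
    """
    if len(records) == 0:
        raise ValueError("empty table")
    out = records.copy()
    age = out["age_at_fgm"]
    ser = age.map(lambda v: "" if pd.isna(v) else str(int(v)))
    if APPROX_COL in out.columns:
        ser = ser.where(~out[APPROX_COL].astype(bool), APPROX_INFANCY)
        out = out.drop(columns=[APPROX_COL])
    out["age_at_fgm"] = ser
    extra = [c for c in out.columns if c not in COLUMNS]
    out = out[COLUMNS + extra]
    out.to_csv(path, index=False, float_format=_FLOAT_FMT)
    return str(path)


def read_microdata_any(path) -> pd.DataFrame:
    """Read a microdata CSV that may carry extra pipeline columns.

    Used for pipeline intermediates (pooled or redistributed data); rows are
    assumed already validated and none are rejected.
    """
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    extra = [c for c in raw.columns if c not in COLUMNS]
    records, rejects = validate_records(raw[COLUMNS].reset_index(drop=True))
    if len(rejects):
        raise SchemaError(
            f"invalid intermediate file {path}: line {rejects['line'].iloc[0]} "
            f"{rejects['reason'].iloc[0]}"
        )
    for c in extra:
        records[c] = pd.to_numeric(raw[c], errors="coerce").to_numpy()
    return records


def write_table(table: pd.DataFrame, path) -> str:
    """Write a result table to CSV with a header and stable ordering.

    Rejects empty tables; numeric values round-trip to 12 significant digits.
    """
    if table is None or len(table) == 0:
        raise ValueError("empty table")
    table.to_csv(path, index=False, float_format=_FLOAT_FMT)
    return str(path)


def survey_metadata(records: pd.DataFrame) -> pd.DataFrame:
    """Per-survey module availability and sample sizes.

    Not every wave carries both modules (series include women-only and
    daughters-only waves); downstream stages consult this to know which
    contrasts a wave can contribute to.
    """
    rows = []
    for s, sub in records.groupby("survey_id", sort=True):
        n_women = int((sub["module"] == "women").sum())
        n_daughters = int((sub["module"] == "daughters").sum())
        rows.append({
            "survey_id": s,
            "has_women_module": n_women > 0,
            "has_daughters_module": n_daughters > 0,
            "n_women": n_women,
            "n_daughters": n_daughters,
        })
    return pd.DataFrame(rows)


def read_population_totals(path) -> pd.DataFrame:
    """Read per-survey eligible population totals.

    CSV columns: ``survey_id``, ``eligible_population`` and optionally
    ``module`` for totals split by survey module.
    """
    df = pd.read_csv(path, dtype={"survey_id": str})
    need = {"survey_id", "eligible_population"}
    if not need.issubset(df.columns):
        raise SchemaError("totals file needs columns survey_id, eligible_population")
    if (df["eligible_population"] <= 0).any():
        raise SchemaError("eligible_population must be positive")
    return df
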