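"""Weighted medians of age at FGM by cohort and composition tables.

The weighted median convention is the *lower* median on integer ages: the
smallest value whose cumulative weight reaches half of the total weight.
With equal weights this is the ordinary lower median, matching the integer
granularity of the reported ages.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .schema import COHORTS, age_reported, weight_column


def round_half_away(x):
    """Round half away from zero (the convention of printed survey tables)."""
    x = np.asarray(x, dtype=float)
    return np.sign(x) * np.floor(np.abs(x) + 0.5)


def percent(numerator, denominator) -> float:
    """Integer percentage, half away from zero; NaN for a zero denominator."""
    if denominator == 0:
        return float("nan")
    return float(round_half_away(100.0 * numerator / denominator))


def weighted_median(values, weights=None):
    """Smallest value whose cumulative weight reaches half the total weight.

    NaN values are ignored; returns NaN on an empty input.  Raises on
    non-positive weights.
    """
    v = np.asarray(values, dtype=float)
    w = np.ones_like(v) if weights is None else np.asarray(weights, dtype=float)
    keep = ~np.isnan(v)
    v, w = v[keep], w[keep]
    if v.size == 0:
        return float("nan")
    if (w <= 0).any():
        raise ValueError("weights must be positive")
    order = np.argsort(v, kind="stable")
    v, w = v[order], w[order]
    cum = np.cumsum(w)
    half = cum[-1] / 2.0
    return float(v[np.searchsorted(cum, half, side="left")])


_SCOPES = ("both", "women", "daughters")


def median_table(records: pd.DataFrame, weighted: bool = True) -> pd.DataFrame:
    """Median age at FGM per birth cohort for each module and both pooled.

    One row per cohort present in the data, with NaN medians for cohorts
    that have no FGM-positive mass in a scope (e.g. cohorts observed only
    as daughters have no women's-module median).
    """
    sub = records[(records["fgm_status"] == "yes") & records["age_at_fgm"].notna()]
    w = sub[weight_column(sub)] if weighted else pd.Series(1.0, index=sub.index)
    cohorts = [c for c in COHORTS if c in set(records["birth_cohort"])]
    rows = []
    for cohort in cohorts:
        row = {"birth_cohort": cohort}
        for scope in _SCOPES:
            m = sub["birth_cohort"] == cohort
            if scope != "both":
                m &= sub["module"] == scope
            row[f"median_{scope}"] = weighted_median(sub.loc[m, "age_at_fgm"], w[m])
        rows.append(row)
    return pd.DataFrame(rows)


def _fgm_band(age: float) -> str:
    if np.isnan(age):
        return "missing"
    if age < 1:
        return "<1"
    if age <= 5:
        return "1-5"
    if age <= 10:
        return "6-10"
    if age <= 15:
        return "11-15"
    return ">15"


_BAND_ORDER = ["<1", "1-5", "6-10", "11-15", ">15", "infancy", "missing"]


def table_frequency_by_survey(records: pd.DataFrame) -> pd.DataFrame:
    """Unweighted FGM frequency by survey and module, with a pooled total row.

    Columns: survey_id, scope, n_obs, n_fgm, pct_fgm (integer percent).
    Surveys lacking a module get NaN cells for that scope.
    """
    rows = []
    surveys = sorted(set(records["survey_id"])) + ["total"]
    for s in surveys:
        sub = records if s == "total" else records[records["survey_id"] == s]
        for scope in _SCOPES:
            part = sub if scope == "both" else sub[sub["module"] == scope]
            n = len(part)
            if n == 0 and scope != "both":
                rows.append({"survey_id": s, "scope": scope, "n_obs": np.nan,
                             "n_fgm": np.nan, "pct_fgm": np.nan})
                continue
            k = int((part["fgm_status"] == "yes").sum())
            rows.append({"survey_id": s, "scope": scope, "n_obs": n,
                         "n_fgm": k, "pct_fgm": percent(k, n)})
    return pd.DataFrame(rows)


def table_education_dob(records: pd.DataFrame) -> pd.DataFrame:
    """Unweighted composition by women's education and DoB completeness."""
    n = len(records)
    rows = []
    for level in ["none", "primary", "secondary", "higher", "other", "missing"]:
        k = int((records["education"] == level).sum())
        rows.append({"variable": "education", "level": level, "n": k, "pct": percent(k, n)})
    for level in ["complete", "imputed"]:
        k = int((records["dob_complete"] == level).sum())
        rows.append({"variable": "dob_complete", "level": level, "n": k, "pct": percent(k, n)})
    return pd.DataFrame(rows)


def table_cohorts(records: pd.DataFrame) -> pd.DataFrame:
    """Unweighted counts per birth cohort split by module, with percent of total."""
    n = len(records)
    rows = []
    for cohort in COHORTS:
        mask = records["birth_cohort"] == cohort
        if not mask.any():
            continue
        nw = int((mask & (records["module"] == "women")).sum())
        nd = int((mask & (records["module"] == "daughters")).sum())
        rows.append({"birth_cohort": cohort, "n_women": nw, "n_daughters": nd,
                     "pct_total": percent(nw + nd, n)})
    out = pd.DataFrame(rows)
    out.loc[len(out)] = {
        "birth_cohort": "total",
        "n_women": int((records["module"] == "women").sum()),
        "n_daughters": int((records["module"] == "daughters").sum()),
        "pct_total": 100.0,
    }
    return out


def table_age_bands(records: pd.DataFrame) -> pd.DataFrame:
    """Counts of FGM-positive records per age-at-FGM band and module.

    Ages are completed years, so "<1" is age 0.  Counts are unweighted row
    counts (use raw or stochastically-redistributed records); an unresolved
    infancy sentinel is tabulated in its own band.
    """
    sub = records[records["fgm_status"] == "yes"].copy()
    band = sub["age_at_fgm"].map(_fgm_band)
    if "age_at_fgm_approx" in sub.columns:
        band = band.where(~sub["age_at_fgm_approx"].astype(bool), "infancy")
    sub["band"] = band
    rows = []
    for module in ("women", "daughters"):
        part = sub[sub["module"] == module]
        n = len(part)
        for b in _BAND_ORDER:
            k = int((part["band"] == b).sum())
            if b == "infancy" and k == 0:
                continue
            rows.append({"module": module, "band": b, "n": k, "pct": percent(k, n)})
    return pd.DataFrame(rows)


def composition_tables(records: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """All unweighted composition tables keyed table1..table4 (+ table6 medians)."""
    return {
        "table1": table_frequency_by_survey(records),
        "table2": table_education_dob(records),
        "table3": table_cohorts(records),
        "table4": table_age_bands(records),
        "table6": median_table(records),
    }
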