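"""Data-quality metrics: completeness of age reporting and age heaping.

Completeness
    Among FGM-positive respondents, the share whose age at FGM is missing,
    profiled by current age, survey module, or survey.  The self-/proxy-
    report contrast shows up as a jump in this profile between ages 14
    (daughters, proxy) and 15 (women, self).

Age heaping
    Preference for round ages (multiples of 5) signals approximate recall.
    Because classical digit-preference indices (Whipple, Myers) need ages
    >= 10, heaping at the young ages relevant here is measured per target
    age a in {5, 10, 15} as

        ratio(a) = C(a) / [ (C(a-1) + C(a+1)) / 2 ]

    where C(x) is the (weighted) count of FGM at age x: the observed count
    against the count expected under a smooth, locally linear transition
    from the adjacent ages.  A ratio of 1 means no heaping; the ratio is
    exactly 1 for any age distribution linear across {a-1, a, a+1} and is
    invariant to rescaling the weights.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .schema import AGE_RANGE, age_reported, weight_column

_GROUPERS = {
    "age": ["current_age"],
    "module": ["module"],
    "age×module": ["module", "current_age"],
    "survey×module": ["survey_id", "module"],
}
# ASCII aliases for the group_by keys
_GROUPERS["age_x_module"] = _GROUPERS["age×module"]
_GROUPERS["survey_x_module"] = _GROUPERS["survey×module"]


def completeness_profile(
    records: pd.DataFrame,
    group_by: str = "age_x_module",
    weighted: bool = True,
    extra_group_by: list[str] | None = None,
) -> pd.DataFrame:
    """Weighted share of FGM-positive records with missing age at FGM, per group.

    Returns one row per group with columns ``n_fgm_yes`` (weighted mass),
    ``n_missing_age`` (weighted mass), ``share_missing_age`` (NaN and
    ``flag="no_fgm_mass"`` when the group has no FGM-positive mass).
    """
    if group_by not in _GROUPERS:
        raise ValueError(f"unknown group_by {group_by!r}")
    keys = _GROUPERS[group_by] + (extra_group_by or [])
    df = records.copy()
    w = df[weight_column(df)].to_numpy() if weighted else np.ones(len(df))
    yes = (df["fgm_status"] == "yes").to_numpy()
    missing = yes & ~age_reported(df).to_numpy()
    df["_wyes"] = np.where(yes, w, 0.0)
    df["_wmiss"] = np.where(missing, w, 0.0)
    out = (
        df.groupby(keys, sort=True, dropna=False)
        .agg(n_fgm_yes=("_wyes", "sum"), n_missing_age=("_wmiss", "sum"))
        .reset_index()
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        out["share_missing_age"] = np.where(
            out["n_fgm_yes"] > 0, out["n_missing_age"] / out["n_fgm_yes"], np.nan
        )
    out["flag"] = np.where(out["n_fgm_yes"] > 0, "", "no_fgm_mass")
    return out


def weighted_age_counts(
    records: pd.DataFrame, by: list[str] | None = None, weighted: bool = True
) -> pd.DataFrame:
    """Weighted count of FGM-positive records per reported age at FGM."""
    df = records[(records["fgm_status"] == "yes") & records["age_at_fgm"].notna()].copy()
    df["age"] = df["age_at_fgm"].astype(int)
    w = df[weight_column(df)] if weighted else pd.Series(1.0, index=df.index)
    df["_w"] = w
    keys = (by or []) + ["age"]
    return df.groupby(keys, sort=True).agg(count=("_w", "sum")).reset_index()


def heaping_index(
    records: pd.DataFrame,
    target_ages=(5, 10, 15),
    by_module: bool = True,
    weighted: bool = True,
    extra_group_by: list[str] | None = None,
) -> pd.DataFrame:
    """Smooth-transition heaping ratios at the target ages.

    One row per (group, target age) with observed and expected weighted
    counts and their ratio.  The daughters' module never reports age 15
    (its respondents are under 15).  Ratios with zero expected but positive
    observed mass are +inf and flagged; groups with no mass anywhere in
    {a-1, a, a+1} are flagged ``empty`` with ratio NaN.
    """
    for a in target_ages:
        if a - 1 < 0:
            raise ValueError("target age must be >= 1 (needs a lower adjacent age)")
    by = (["module"] if by_module else []) + (extra_group_by or [])
    counts = weighted_age_counts(records, by=by, weighted=weighted)
    groups = counts[by].drop_duplicates().itertuples(index=False) if by else [()]
    rows = []
    for g in groups:
        key = tuple(g)
        sub = counts
        for col, val in zip(by, key):
            sub = sub[sub[col] == val]
        cmap = dict(zip(sub["age"], sub["count"]))
        if by_module:
            mod = key[by.index("module")]
            max_age = AGE_RANGE[mod][1]
        else:
            max_age = None
        for a in target_ages:
            if max_age is not None and a + 1 > max_age:
                continue
            obs = cmap.get(a, 0.0)
            exp = (cmap.get(a - 1, 0.0) + cmap.get(a + 1, 0.0)) / 2.0
            if exp > 0:
                ratio, flag = obs / exp, ""
            elif obs > 0:
                ratio, flag = np.inf, "zero_expected"
            else:
                ratio, flag = np.nan, "empty"
            rows.append(dict(zip(by, key)) | {
                "age": a, "observed": obs, "expected": exp, "ratio": ratio, "flag": flag,
            })
    return pd.DataFrame(rows, columns=by + ["age", "observed", "expected", "ratio", "flag"])
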