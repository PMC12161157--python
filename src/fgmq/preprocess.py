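"""Record exclusion and redistribution of approximate "infancy" ages.

Two cleaning steps run between pooling and analysis, in this order:

1. *Exclusion*: a reported age at FGM later than the respondent's current
   age is internally inconsistent; such records are dropped and audited.
2. *Redistribution*: women often answer "during infancy" instead of an
   exact age.  Those answers are kept, not discarded: each one is spread
   over ages 0..K (default K=5) according to the distribution of precise
   answers in that age range given by women of the same survey (the
   *anchor distribution*).  Deterministic fractional mode splits the record
   into weighted copies; stochastic mode draws a single age per record.
   Both conserve the total weighted count of FGM-positive records.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .schema import APPROX_COL, weight_column


@dataclass
class ExclusionAudit:
    """Counts of records dropped for inconsistent age reporting."""

    n_input: int
    n_excluded_inconsistent: int
    by_survey: pd.DataFrame = field(repr=False)  # survey_id, n_input, n_excluded

    def frame(self) -> pd.DataFrame:
        return self.by_survey


@dataclass
class RedistributionPlan:
    """Anchor distribution over ages 0..max_age for one survey's infancy answers."""

    survey_id: str
    weights: np.ndarray  # length max_age+1, sums to 1
    mode: str = "fractional"
    seed: int | None = None
    n_redistributed: int = 0
    pooled_fallback: bool = False

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float)
        if (self.weights < 0).any():
            raise ValueError("anchor weights must be non-negative")
        if abs(self.weights.sum() - 1.0) > 1e-12:
            raise ValueError("anchor weights must sum to 1")


def exclude_inconsistent(records: pd.DataFrame) -> tuple[pd.DataFrame, ExclusionAudit]:
    """Drop records whose numeric age at FGM exceeds their current age."""
    age = records["age_at_fgm"]
    bad = age.notna() & (age > records["current_age"])
    by_survey = (
        pd.DataFrame({"survey_id": records["survey_id"], "excluded": bad})
        .groupby("survey_id", sort=True)
        .agg(n_input=("excluded", "size"), n_excluded=("excluded", "sum"))
        .reset_index()
    )
    audit = ExclusionAudit(
        n_input=len(records),
        n_excluded_inconsistent=int(bad.sum()),
        by_survey=by_survey,
    )
    return records[~bad].reset_index(drop=True), audit


def build_anchor_distribution(
    records: pd.DataFrame,
    survey_id: str | None,
    max_age: int = 5,
    weighted: bool = True,
) -> RedistributionPlan | None:
    """Anchor distribution from precise women's-module answers at ages 0..max_age.

    ``survey_id=None`` pools every survey (the fallback used when one survey
    has no precise young-age answers at all).  Returns None when even the
    requested subset is empty.
    """
    sub = records[
        (records["module"] == "women")
        & (records["fgm_status"] == "yes")
        & records["age_at_fgm"].notna()
        & (records["age_at_fgm"] >= 0)
        & (records["age_at_fgm"] <= max_age)
    ]
    if survey_id is not None:
        sub = sub[sub["survey_id"] == survey_id]
    if len(sub) == 0:
        return None
    w = sub[weight_column(sub)].to_numpy() if weighted else np.ones(len(sub))
    counts = np.zeros(max_age + 1)
    np.add.at(counts, sub["age_at_fgm"].to_numpy().astype(int), w)
    return RedistributionPlan(
        survey_id=survey_id if survey_id is not None else "__pooled__",
        weights=counts / counts.sum(),
        pooled_fallback=survey_id is None,
    )


def redistribute_infancy(
    records: pd.DataFrame,
    plans: dict[str, RedistributionPlan],
    mode: str = "fractional",
    seed: int | None = None,
) -> pd.DataFrame:
    """Resolve every infancy sentinel using the per-survey plans.

    fractional
        Each sentinel record becomes one copy per anchor age with its
        weights multiplied by the anchor probability (zero-probability
        copies are dropped).
    stochastic
        Each sentinel record gets a single age drawn from the anchor
        distribution (reproducible under ``seed``).
    """
    if mode not in ("fractional", "stochastic"):
        raise ValueError(f"unknown mode {mode!r}")
    approx = records[APPROX_COL].astype(bool)
    if not approx.any():
        return records.reset_index(drop=True)
    missing_plan = set(records.loc[approx, "survey_id"]) - set(plans)
    if missing_plan:
        raise KeyError(f"no redistribution plan for survey {sorted(missing_plan)[0]!r}")

    base = records[~approx]
    todo = records[approx].copy()
    wcols = [c for c in ("weight_norm", "weight_denorm") if c in records.columns]

    if mode == "stochastic":
        rng = np.random.default_rng(seed)
        ages = np.empty(len(todo), dtype=float)
        pos = {s: np.flatnonzero(todo["survey_id"].to_numpy() == s) for s in sorted(plans)}
        for s in sorted(plans):
            idx = pos[s]
            if len(idx) == 0:
                continue
            plan = plans[s]
            ages[idx] = rng.choice(len(plan.weights), size=len(idx), p=plan.weights)
            plan.n_redistributed += len(idx)
            plan.mode, plan.seed = mode, seed
        todo["age_at_fgm"] = ages
        todo[APPROX_COL] = False
        out = pd.concat([base, todo], ignore_index=False).sort_index(kind="stable")
        return out.reset_index(drop=True)

    # fractional: expand each sentinel row across the anchor support
    parts = [base]
    for s in sorted(set(todo["survey_id"])):
        plan = plans[s]
        block = todo[todo["survey_id"] == s]
        k = len(plan.weights)
        rep = block.loc[block.index.repeat(k)].copy()
        rep["age_at_fgm"] = np.tile(np.arange(k, dtype=float), len(block))
        pw = np.tile(plan.weights, len(block))
        for c in wcols:
            rep[c] = rep[c].to_numpy() * pw
        rep = rep[pw > 0]
        rep[APPROX_COL] = False
        parts.append(rep)
        plan.n_redistributed += len(block)
        plan.mode = mode
    out = pd.concat(parts, ignore_index=False).sort_index(kind="stable")
    return out.reset_index(drop=True)


class InconsistentAgeFilter(BaseEstimator, TransformerMixin):
    """Transformer wrapper around :func:`exclude_inconsistent` (idempotent)."""

    def fit(self, X: pd.DataFrame, y=None):
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        out, self.audit_ = exclude_inconsistent(X)
        return out


class InfancyRedistributor(BaseEstimator, TransformerMixin):
    """Learn per-survey anchor distributions, then resolve infancy answers.

    Parameters
    ----------
    mode : {"fractional", "stochastic"}
        Fractional splitting is deterministic and is the default; stochastic
        assignment keeps one row per record for record-level uses.
    max_age : int
        Upper bound of the "infancy" age range (inclusive), default 5.
    random_state : int or None
        Seed for stochastic mode.
    weighted : bool
        Weight the anchor tallies by the analysis weight (default) or not.
    """

    def __init__(self, mode: str = "fractional", max_age: int = 5,
                 random_state: int | None = None, weighted: bool = True):
        self.mode = mode
        self.max_age = max_age
        self.random_state = random_state
        self.weighted = weighted

    def fit(self, X: pd.DataFrame, y=None):
        if self.max_age < 0:
            raise ValueError("max_age must be >= 0")
        plans: dict[str, RedistributionPlan] = {}
        pooled = None
        has_sentinel = set(X.loc[X[APPROX_COL].astype(bool), "survey_id"])
        for s in sorted(set(X["survey_id"])):
            plan = build_anchor_distribution(X, s, max_age=self.max_age, weighted=self.weighted)
            if plan is None:
                if s not in has_sentinel:
                    continue  # nothing to redistribute for this survey
                pooled = pooled or build_anchor_distribution(
                    X, None, max_age=self.max_age, weighted=self.weighted
                )
                if pooled is None:
                    continue  # no precise answers anywhere; transform will raise
                warnings.warn(
                    f"survey {s!r} has no precise ages 0..{self.max_age}; "
                    "using the pooled anchor distribution"
                )
                plan = RedistributionPlan(
                    survey_id=s, weights=pooled.weights.copy(), pooled_fallback=True
                )
            plans[s] = plan
        self.plans_ = plans
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        return redistribute_infancy(X, self.plans_, mode=self.mode, seed=self.random_state)
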