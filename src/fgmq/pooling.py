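"""Pooling surveys by denormalizing sample weights against population totals.

Each survey ships weights normalized to mean 1 within that survey, which
makes surveys of different sizes incommensurable.  Denormalization rescales
every survey's weights so they sum to the eligible population (women 15-49
plus girls 0-14) in the survey year:

    w_denorm_i = w_norm_i * T_s / sum_{j in s} w_norm_j

for record i of survey s with total T_s.  Relative weights within a survey
are untouched; across surveys each wave's influence becomes proportional to
the population it represents, which is the standard recipe for pooling
consecutive waves of the same survey program.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin


@dataclass
class PooledDataset:
    """Pooled records plus per-survey bookkeeping."""

    records: pd.DataFrame
    provenance: pd.DataFrame = field(repr=False)  # survey_id, n_records, weight_sum


class WeightDenormalizer(BaseEstimator, TransformerMixin):
    """Rescale normalized survey weights to population units.

    Parameters
    ----------
    totals : pandas.DataFrame
        Columns ``survey_id``, ``eligible_population`` and, when
        ``by_module=True``, ``module``.
    by_module : bool
        If True each survey module is rescaled against its own total;
        default rescales each survey as a whole against a combined total.
    """

    def __init__(self, totals: pd.DataFrame = None, by_module: bool = False):
        self.totals = totals
        self.by_module = by_module

    def _keys(self):
        return ["survey_id", "module"] if self.by_module else ["survey_id"]

    def fit(self, X: pd.DataFrame, y=None):
        if self.totals is None:
            raise ValueError("totals are required")
        totals = pd.DataFrame(self.totals)
        keys = self._keys()
        if self.by_module and "module" not in totals.columns:
            raise ValueError("by_module=True requires a module column in totals")
        totals = totals.drop_duplicates(keys)
        wsum = X.groupby(keys, sort=True)["weight_norm"].sum().reset_index(name="wsum")
        merged = wsum.merge(totals[keys + ["eligible_population"]], on=keys, how="left")
        if merged["eligible_population"].isna().any():
            miss = merged.loc[merged["eligible_population"].isna(), keys[0]].iloc[0]
            raise KeyError(f"no population total for survey {miss!r}")
        if (merged["wsum"] <= 0).any():
            raise ValueError("zero weight sum in a survey group")
        merged["scale_"] = merged["eligible_population"] / merged["wsum"]
        self.scale_ = merged[keys + ["scale_"]]
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        keys = self._keys()
        out = X.merge(self.scale_, on=keys, how="left")
        if out["scale_"].isna().any():
            miss = out.loc[out["scale_"].isna(), "survey_id"].iloc[0]
            raise KeyError(f"no population total for survey {miss!r}")
        out["weight_denorm"] = out["weight_norm"] * out["scale_"]
        out = out.drop(columns=["scale_"])
        out.index = X.index
        return out


def denormalize(records: pd.DataFrame, totals: pd.DataFrame, by_module: bool = False) -> PooledDataset:
    """One-shot pooling: denormalize weights and report per-survey sums."""
    pooled = WeightDenormalizer(totals=totals, by_module=by_module).fit_transform(records)
    provenance = (
        pooled.groupby("survey_id", sort=True)
        .agg(n_records=("survey_id", "size"), weight_sum=("weight_denorm", "sum"))
        .reset_index()
    )
    return PooledDataset(records=pooled, provenance=provenance)
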