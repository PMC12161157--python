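"""Exclusion of inconsistent records and infancy-age redistribution."""

import numpy as np
import pandas as pd
import pytest

from fgmq.preprocess import (
    InfancyRedistributor,
    RedistributionPlan,
    build_anchor_distribution,
    exclude_inconsistent,
    redistribute_infancy,
)
from fgmq.schema import APPROX_COL

from conftest import make_records


class TestExclusion:
    def test_age_after_current_age_is_excluded(self):
        records = make_records(
            [{"module": "daughters", "current_age": 4, "birth_cohort": "2010s",
              "age_at_fgm": 7.0}]
        )
        kept, audit = exclude_inconsistent(records)
        assert len(kept) == 0 and audit.n_excluded_inconsistent == 1

    def test_equality_is_retained(self):
        records = make_records([{"current_age": 30, "age_at_fgm": 30.0}])
        kept, audit = exclude_inconsistent(records)
        assert len(kept) == 1 and audit.n_excluded_inconsistent == 0

    def test_mixed_batch_matches_scan_oracle(self, rng):
        rows = []
        for i in range(10):
            cur = int(rng.integers(15, 50))
            age = float(rng.integers(0, 60))
            rows.append({"current_age": cur, "age_at_fgm": age,
                         "cluster_id": f"SV1-h0-c{i}"})
        # force exactly 3 violations
        rows[0].update(current_age=20, age_at_fgm=25.0)
        rows[1].update(current_age=20, age_at_fgm=21.0)
        rows[2].update(current_age=20, age_at_fgm=50.0)
        for r in rows[3:]:
            r["age_at_fgm"] = float(min(r["age_at_fgm"], r["current_age"]))
        records = make_records(rows)
        oracle = sum(r["age_at_fgm"] > r["current_age"] for r in rows)
        kept, audit = exclude_inconsistent(records)
        assert audit.n_excluded_inconsistent == oracle == 3
        assert len(kept) == 7
        assert audit.n_input == 10

    def test_idempotent(self):
        records = make_records(
            [{"current_age": 20, "age_at_fgm": 25.0}, {"cluster_id": "SV1-h0-c1"}]
        )
        once, _ = exclude_inconsistent(records)
        twice, audit = exclude_inconsistent(once)
        pd.testing.assert_frame_equal(once, twice)
        assert audit.n_excluded_inconsistent == 0


class TestAnchorDistribution:
    def test_counts_normalize(self):
        counts = (10, 20, 30, 20, 10, 10)
        rows = []
        i = 0
        for age, k in enumerate(counts):
            for _ in range(k):
                rows.append({"age_at_fgm": float(age), "cluster_id": f"SV1-h0-c{i}"})
                i += 1
        plan = build_anchor_distribution(make_records(rows), "SV1")
        assert np.allclose(plan.weights, np.array(counts) / 100)

    def test_degenerate_single_age(self):
        plan = build_anchor_distribution(
            make_records([{"age_at_fgm": 2.0}, {"age_at_fgm": 2.0}]), "SV1"
        )
        assert np.allclose(plan.weights, [0, 0, 1, 0, 0, 0])

    def test_weighted_tally_oracle(self):
        records = make_records([
            {"age_at_fgm": 0.0, "weight_norm": 1.0},
            {"age_at_fgm": 0.0, "weight_norm": 2.0, "cluster_id": "SV1-h0-c1"},
            {"age_at_fgm": 3.0, "weight_norm": 5.0, "cluster_id": "SV1-h0-c2"},
        ])
        records["weight_denorm"] = records["weight_norm"] * 10
        plan = build_anchor_distribution(records, "SV1")
        # hand summation on denormalized weights: (30, 0, 0, 50, 0, 0) / 80
        assert np.allclose(plan.weights, [30 / 80, 0, 0, 50 / 80, 0, 0])

    def test_only_precise_young_women_count(self):
        records = make_records([
            {"age_at_fgm": 2.0},
            {"age_at_fgm": 9.0, "cluster_id": "SV1-h0-c1"},       # outside 0..5
            {"age_at_fgm": np.nan, APPROX_COL: True, "cluster_id": "SV1-h0-c2"},
            {"module": "daughters", "current_age": 4, "birth_cohort": "2010s",
             "age_at_fgm": 1.0, "cluster_id": "SV1-h0-c3"},        # proxy module
        ])
        plan = build_anchor_distribution(records, "SV1")
        assert np.allclose(plan.weights, [0, 0, 1, 0, 0, 0])

    def test_empty_subset_returns_none(self):
        records = make_records([{"age_at_fgm": 9.0}])
        assert build_anchor_distribution(records, "SV1") is None


def _sentinel_rows(n, weight=1.0, survey="SV1"):
    return [
        {"survey_id": survey, "age_at_fgm": np.nan, APPROX_COL: True,
         "stratum_id": f"{survey}-h0", "cluster_id": f"{survey}-h0-c{i}",
         "weight_norm": weight}
        for i in range(n)
    ]


PLAN = (0.10, 0.20, 0.30, 0.20, 0.10, 0.10)


class TestRedistribution:
    def test_fractional_mass_is_linear_in_plan(self):
        records = make_records(_sentinel_rows(50))
        plans = {"SV1": RedistributionPlan("SV1", PLAN)}
        out = redistribute_infancy(records, plans, mode="fractional")
        mass = out.groupby(out["age_at_fgm"].astype(int))["weight_norm"].sum()
        assert np.allclose(mass.to_numpy(), [5, 10, 15, 10, 5, 5])
        assert not out[APPROX_COL].any()

    def test_fractional_drops_zero_weight_copies(self):
        records = make_records(_sentinel_rows(2))
        plans = {"SV1": RedistributionPlan("SV1", (0.5, 0.5, 0, 0, 0, 0))}
        out = redistribute_infancy(records, plans, mode="fractional")
        assert len(out) == 4 and (out["weight_norm"] > 0).all()

    def test_stochastic_deterministic_under_seed(self):
        records = make_records(_sentinel_rows(200))
        plans = {"SV1": RedistributionPlan("SV1", PLAN)}
        out1 = redistribute_infancy(records, plans, mode="stochastic", seed=7)
        out2 = redistribute_infancy(records, plans, mode="stochastic", seed=7)
        pd.testing.assert_frame_equal(out1, out2)

    def test_stochastic_share_matches_binomial_oracle(self):
        records = make_records(_sentinel_rows(10_000))
        plans = {"SV1": RedistributionPlan("SV1", (0.5, 0.5, 0, 0, 0, 0))}
        out = redistribute_infancy(records, plans, mode="stochastic", seed=11)
        share0 = (out["age_at_fgm"] == 0).mean()
        se = np.sqrt(0.25 / 10_000)
        assert abs(share0 - 0.5) <= 3 * se

    def test_weighted_mass_conserved_both_modes(self, rng):
        rows = _sentinel_rows(300)
        for i, r in enumerate(rows):
            r["weight_norm"] = float(rng.uniform(0.1, 5.0))
        rows += [{"cluster_id": "SV1-h9-c0", "stratum_id": "SV1-h9",
                  "age_at_fgm": 3.0, "weight_norm": 2.5}]
        records = make_records(rows)
        records["weight_denorm"] = records["weight_norm"] * 1234.5
        before = records.loc[records["fgm_status"] == "yes", "weight_denorm"].sum()
        plans = {"SV1": RedistributionPlan("SV1", PLAN)}
        for mode in ("fractional", "stochastic"):
            out = redistribute_infancy(records, plans, mode=mode, seed=5)
            after = out.loc[out["fgm_status"] == "yes", "weight_denorm"].sum()
            assert after == pytest.approx(before, rel=1e-9)
            assert not out[APPROX_COL].any()

    def test_missing_plan_is_hard_error(self):
        records = make_records(_sentinel_rows(1))
        with pytest.raises(KeyError, match="SV1"):
            redistribute_infancy(records, {}, mode="fractional")

    def test_transformer_falls_back_to_pooled_anchor(self):
        rows = _sentinel_rows(3, survey="SVA")
        rows += [{"survey_id": "SVB", "stratum_id": "SVB-h0",
                  "cluster_id": "SVB-h0-c0", "age_at_fgm": 1.0}]
        records = make_records(rows)
        red = InfancyRedistributor()
        with pytest.warns(UserWarning, match="pooled anchor"):
            red.fit(records)
        assert red.plans_["SVA"].pooled_fallback
        out = red.transform(records)
        assert (out.loc[out["survey_id"] == "SVA", "age_at_fgm"] == 1.0).all()

    def test_row_order_is_stable(self):
        rows = [{"age_at_fgm": 2.0}] + _sentinel_rows(1) + [
            {"age_at_fgm": 5.0, "cluster_id": "SV1-h0-c9"}
        ]
        records = make_records(rows)
        plans = {"SV1": RedistributionPlan("SV1", (1.0, 0, 0, 0, 0, 0))}
        out = redistribute_infancy(records, plans, mode="fractional")
        assert list(out["age_at_fgm"]) == [2.0, 0.0, 5.0]
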