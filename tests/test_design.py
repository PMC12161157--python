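"""Design matrix coding and the survey-weighted logistic estimator."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize
from scipy.special import expit

from fgmq.design import DesignLogit, build_design_matrix, completeness_model

from conftest import make_records


def _toy_2x2(a, b, c, d):
    """Exposure x (1/0) vs outcome y (1/0) with cell counts a,b,c,d."""
    rows = [(1, 1)] * a + [(1, 0)] * b + [(0, 1)] * c + [(0, 0)] * d
    df = pd.DataFrame(rows, columns=["x", "y"])
    X = pd.DataFrame({"(Intercept)": 1.0, "x": df["x"].astype(float)})
    return X, df["y"].to_numpy(dtype=float)


class TestDesignMatrix:
    def test_reference_cell_is_all_zero_dummies(self):
        records = make_records([{
            "survey_id": "SV2005", "module": "daughters", "current_age": 3,
            "birth_cohort": "2010s", "education": "none", "dob_complete": "imputed",
            "stratum_id": "SV2005-h0", "cluster_id": "SV2005-h0-c0",
        }])
        X, y, info = build_design_matrix(records)
        row = X.iloc[0]
        assert row["(Intercept)"] == 1.0 and row["age"] == 3.0
        assert all(row[c] == 0.0 for c in X.columns if c not in ("(Intercept)", "age"))

    def test_missing_education_dropped_and_counted(self):
        records = make_records([
            {"education": "missing"},
            {"education": "other", "cluster_id": "SV1-h0-c1"},
            {"education": "primary", "cluster_id": "SV1-h0-c2"},
        ])
        X, y, info = build_design_matrix(records)
        assert info["n_used"] == 1 and info["n_dropped"] == 2

    def test_six_record_batch_matches_manual_dummies(self):
        rows = [
            dict(survey_id="SVA", module="daughters", current_age=3,
                 birth_cohort="2010s", education="none", dob_complete="imputed"),
            dict(survey_id="SVA", module="women", current_age=20,
                 birth_cohort="1990s", education="primary", dob_complete="complete"),
            dict(survey_id="SVB", module="women", current_age=40,
                 birth_cohort="1970s", education="secondary", dob_complete="imputed",
                 age_at_fgm=np.nan),
            dict(survey_id="SVB", module="women", current_age=30,
                 birth_cohort="1980s", education="higher", dob_complete="complete"),
            dict(survey_id="SVA", module="daughters", current_age=7,
                 birth_cohort="2000s", education="none", dob_complete="complete"),
            dict(survey_id="SVB", module="daughters", current_age=12,
                 birth_cohort="2000s", education="primary", dob_complete="imputed"),
        ]
        for i, r in enumerate(rows):
            r["stratum_id"] = f"{r['survey_id']}-h0"
            r["cluster_id"] = f"{r['survey_id']}-h0-c{i}"
        X, y, info = build_design_matrix(make_records(rows))
        manual = pd.DataFrame({
            "(Intercept)": [1.0] * 6,
            "survey_id[SVB]": [0, 0, 1, 1, 0, 1],
            "module[women]": [0, 1, 1, 1, 0, 0],
            "age": [3.0, 20.0, 40.0, 30.0, 7.0, 12.0],
            "education[higher]": [0, 0, 0, 1, 0, 0],
            "education[primary]": [0, 1, 0, 0, 0, 1],
            "education[secondary]": [0, 0, 1, 0, 0, 0],
            "dob_complete[complete]": [0, 1, 0, 1, 1, 0],
        }, dtype=float, index=X.index)
        pd.testing.assert_frame_equal(X[manual.columns], manual)
        assert list(y) == [1, 1, 0, 1, 1, 1]  # record 3 has missing age

    def test_empty_level_dropped_with_warning(self):
        records = make_records([
            {"education": "none"},
            {"education": "none", "cluster_id": "SV1-h0-c1", "fgm_status": "no",
             "age_at_fgm": np.nan},
            {"education": "primary", "cluster_id": "SV1-h0-c2", "fgm_status": "no",
             "age_at_fgm": np.nan},
        ])
        # only FGM-positive rows enter; the primary level then has no rows left
        with pytest.warns(UserWarning, match="empty factor level"):
            X, y, info = build_design_matrix(records, terms=("education",))
        assert "education[primary]" not in X.columns
        assert info["n_used"] == 1


class TestDesignLogit:
    def test_balanced_2x2_gives_or_one(self):
        X, y = _toy_2x2(10, 10, 10, 10)
        m = DesignLogit().fit(X, y)
        assert np.exp(m.coef_[1]) == pytest.approx(1.0, abs=1e-8)

    def test_2x2_matches_cross_product_ratio(self):
        X, y = _toy_2x2(40, 10, 20, 30)
        m = DesignLogit().fit(X, y)
        assert np.exp(m.coef_[1]) == pytest.approx(6.0, rel=1e-6)

    def test_independent_psus_match_dense_sandwich_oracle(self, rng):
        n, p = 400, 3
        X = np.column_stack([np.ones(n), rng.normal(size=(n, p - 1))])
        y = (rng.random(n) < expit(X @ np.array([0.2, -0.7, 0.4]))).astype(float)
        w = rng.uniform(0.5, 2.0, n)
        m = DesignLogit().fit(X, y, sample_weight=w)

        def nll(b):
            eta = X @ b
            return -np.sum(w * (y * eta - np.log1p(np.exp(eta))))

        opt = minimize(nll, np.zeros(p), method="BFGS", options={"gtol": 1e-12})
        mu = expit(X @ opt.x)
        B = X.T @ (X * (w * mu * (1 - mu))[:, None])
        s = X * (w * (y - mu))[:, None]
        sc = s - s.mean(axis=0)
        cov = np.linalg.inv(B) @ ((n / (n - 1)) * sc.T @ sc) @ np.linalg.inv(B)
        assert np.allclose(m.coef_, opt.x, rtol=1e-6, atol=1e-8)
        assert np.allclose(m.bse_, np.sqrt(np.diag(cov)), rtol=1e-6)
        assert m.df_resid_ == n - 1

    def test_equal_weights_match_unweighted_mle(self, rng):
        statsmodels = pytest.importorskip("statsmodels.api")
        n = 500
        X = pd.DataFrame({"(Intercept)": 1.0, "x1": rng.normal(size=n),
                          "x2": rng.normal(size=n)})
        y = (rng.random(n) < expit(0.5 * X["x1"] - 0.3 * X["x2"])).astype(float)
        m = DesignLogit().fit(X, y)
        g = statsmodels.GLM(y, X, family=statsmodels.families.Binomial()).fit()
        assert np.allclose(m.coef_, g.params.to_numpy(), rtol=1e-6, atol=1e-8)

    def test_replicating_records_with_inverse_weights_changes_nothing(self, rng):
        n, k = 150, 3
        X = pd.DataFrame({"(Intercept)": 1.0, "x": rng.normal(size=n)})
        y = (rng.random(n) < expit(0.8 * X["x"])).astype(float)
        m1 = DesignLogit().fit(X, y)
        Xk = pd.concat([X] * k, ignore_index=True)
        yk = np.tile(y, k)
        m2 = DesignLogit().fit(Xk, yk, sample_weight=np.full(n * k, 1 / k))
        assert np.allclose(m1.coef_, m2.coef_, rtol=1e-8)

    def test_confidence_interval_brackets_or(self):
        X, y = _toy_2x2(40, 10, 20, 30)
        m = DesignLogit().fit(X, y)
        frame = m.summary_frame()
        row = frame[frame["term"] == "x"].iloc[0]
        assert row["ci_low"] < row["odds_ratio"] < row["ci_high"]
        assert row["odds_ratio"] == pytest.approx(np.exp(row["estimate"]))

    def test_stratified_design_reduces_df(self):
        # 4 strata x 2 PSUs of 5 records each
        rng = np.random.default_rng(5)
        n = 40
        strata = np.repeat(np.arange(4), 10)
        clusters = np.repeat(np.arange(8), 5)
        X = pd.DataFrame({"(Intercept)": 1.0, "x": rng.normal(size=n)})
        y = (rng.random(n) < 0.5).astype(float)
        m = DesignLogit().fit(X, y, strata=strata, clusters=clusters)
        assert m.df_resid_ == 8 - 4


def test_completeness_model_recovers_module_gap(rng):
    """Women's module built with worse completeness => OR < 1 vs daughters."""
    rows = []
    i = 0
    for module, n, p_missing in (("women", 400, 0.3), ("daughters", 400, 0.05)):
        miss = rng.random(n) < p_missing
        for j in range(n):
            rows.append({
                "module": module,
                "current_age": 30 if module == "women" else 5,
                "birth_cohort": "1980s" if module == "women" else "2010s",
                "age_at_fgm": np.nan if miss[j] else 2.0,
                "stratum_id": f"SV1-h{i % 4}",
                "cluster_id": f"SV1-h{i % 4}-c{i}",
            })
            i += 1
    model, table, info = completeness_model(
        make_records(rows), terms=("module",), weight="weight_norm"
    )
    row = table[table["term"] == "module[women]"].iloc[0]
    assert row["odds_ratio"] < 1.0 and row["ci_high"] < 1.0
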