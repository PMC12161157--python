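"""Design-based logistic regression for completeness of age reporting.

The outcome is defined on FGM-positive respondents only: 1 when the age at
FGM was reported (exactly or approximately), 0 when it is missing.  Point
estimates solve the survey-weighted logistic score equations by iteratively
reweighted least squares; the variance honors the stratified two-stage
cluster design by Taylor linearization: per-observation score contributions
s_i = w_i x_i (y_i - p_i) are summed to PSU totals, centered within their
stratum, and combined with the finite-sample stratum factor n_h/(n_h - 1):

    V = B^{-1} [ sum_h n_h/(n_h-1) sum_c (z_hc - zbar_h)(z_hc - zbar_h)' ] B^{-1}

with B = X'WX the weighted information at the solution.  Confidence
intervals use Student's t with design degrees of freedom
(#PSUs - #strata), the convention of standard complex-survey software.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import t as student_t
from sklearn.base import BaseEstimator

from .schema import age_reported


class ConvergenceError(RuntimeError):
    """IRLS failed to converge; carries the last iterate in ``last_coef``."""

    def __init__(self, msg, last_coef):
        super().__init__(msg)
        self.last_coef = last_coef


#: treatment-coding reference levels mirroring the published model
DEFAULT_REFERENCES = {"education": "none", "module": "daughters", "dob_complete": "imputed"}

_TERM_COLS = {
    "survey": "survey_id",
    "module": "module",
    "education": "education",
    "dob": "dob_complete",
    "age": "current_age",
}


def build_design_matrix(
    records: pd.DataFrame,
    terms=("survey", "module", "age", "education", "dob"),
    references: dict | None = None,
):
    """Outcome vector and treatment-coded design matrix for the completeness model.

    Restricts to FGM-positive records, applies listwise deletion of rows
    with unusable covariates (education ``missing``/``other``), and codes
    each categorical term against its reference level (education=none,
    module=daughters, dob=imputed, survey=first survey label).  Age enters
    as a single continuous term (current age in years).

    Returns
    -------
    X : pandas.DataFrame  (includes the "(Intercept)" column)
    y : numpy.ndarray     (1 = age reported, 0 = missing)
    info : dict           n_used, n_dropped, kept row index
    """
    refs = dict(DEFAULT_REFERENCES)
    refs.update(references or {})
    sub = records[records["fgm_status"] == "yes"]
    n0 = len(sub)
    if "education" in terms:
        sub = sub[~sub["education"].isin(["missing", "other"])]
    info = {"n_used": len(sub), "n_dropped": n0 - len(sub)}
    y = age_reported(sub).to_numpy().astype(float)

    X = pd.DataFrame(index=sub.index)
    X["(Intercept)"] = 1.0
    for term in terms:
        col = _TERM_COLS[term]
        if term == "age":
            X["age"] = sub[col].astype(float)
            continue
        all_levels = sorted(records[col].unique())
        levels = sorted(sub[col].unique())
        lost = [l for l in all_levels if l not in levels
                and not (col == "education" and l in ("missing", "other"))]
        if lost:
            warnings.warn(f"empty factor level(s) for {col} after subsetting: {lost}")
        ref = refs.get(col, levels[0] if levels else None)
        if ref not in levels:
            ref = levels[0]
        for lev in levels:
            if lev == ref:
                continue
            X[f"{col}[{lev}]"] = (sub[col] == lev).astype(float)
    info["index"] = sub.index
    return X, y, info


class DesignLogit(BaseEstimator):
    """Survey-weighted logistic regression with linearized design variance.

    Parameters
    ----------
    max_iter : int
        IRLS iteration cap.
    score_tol : float
        Convergence when the largest absolute score component falls below
        this, or when the relative deviance change falls below ``dev_tol``.
    alpha : float
        1 - confidence level for the reported intervals.

    Attributes (after ``fit``)
    --------------------------
    coef_ : array of log-odds estimates (order of the design columns)
    cov_ : linearized covariance matrix
    bse_ : design standard errors
    df_resid_ : design degrees of freedom (#PSUs - #strata)
    n_iter_, converged_, feature_names_in_
    """

    def __init__(self, max_iter: int = 50, score_tol: float = 1e-8,
                 dev_tol: float = 1e-10, alpha: float = 0.05):
        self.max_iter = max_iter
        self.score_tol = score_tol
        self.dev_tol = dev_tol
        self.alpha = alpha

    def fit(self, X, y, sample_weight=None, strata=None, clusters=None):
        X = pd.DataFrame(X)
        self.feature_names_in_ = np.asarray(X.columns, dtype=object)
        Xm = X.to_numpy(dtype=float)
        y = np.asarray(y, dtype=float)
        n, p = Xm.shape
        if sample_weight is None:
            sample_weight = np.ones(n)
        w = np.asarray(sample_weight, dtype=float)
        if (w <= 0).any():
            raise ValueError("weights must be positive")
        if clusters is None:
            clusters = np.arange(n)  # independent observations
        if strata is None:
            strata = np.zeros(n, dtype=int)
        strata = np.asarray(strata, dtype=object)
        clusters = np.asarray(clusters, dtype=object)

        beta = np.zeros(p)
        dev = np.inf
        converged = False
        for it in range(1, self.max_iter + 1):
            eta = Xm @ beta
            mu = expit(eta)
            score = Xm.T @ (w * (y - mu))
            wls = w * mu * (1 - mu)
            B = Xm.T @ (Xm * wls[:, None])
            try:
                step = np.linalg.solve(B, score)
            except np.linalg.LinAlgError as exc:
                raise ConvergenceError(f"singular information at iteration {it}", beta) from exc
            beta = beta + step
            eta = Xm @ beta
            mu = np.clip(expit(eta), 1e-12, 1 - 1e-12)
            new_dev = -2 * np.sum(w * (y * np.log(mu) + (1 - y) * np.log(1 - mu)))
            score = Xm.T @ (w * (y - mu))
            rel = abs(new_dev - dev) / (abs(new_dev) + 1e-300)
            if np.max(np.abs(score)) < self.score_tol or rel < self.dev_tol:
                converged = True
                dev = new_dev
                break
            dev = new_dev
        if not converged:
            raise ConvergenceError(f"IRLS did not converge in {self.max_iter} iterations", beta)
        if np.max(np.abs(beta)) > 15:
            warnings.warn("possible separation: |estimate| > 15 on the log-odds scale")

        # linearized variance: scores to PSU totals, centered within strata
        mu = expit(Xm @ beta)
        wls = w * mu * (1 - mu)
        B = Xm.T @ (Xm * wls[:, None])
        Binv = np.linalg.inv(B)
        s = Xm * (w * (y - mu))[:, None]

        psu_key = pd.MultiIndex.from_arrays([strata, clusters])
        psu_tot = pd.DataFrame(s, index=psu_key).groupby(level=[0, 1], sort=True).sum()
        M = np.zeros((p, p))
        n_psus = 0
        strata_labels = psu_tot.index.get_level_values(0).unique()
        for h in strata_labels:
            Z = psu_tot.xs(h, level=0).to_numpy()
            n_h = Z.shape[0]
            n_psus += n_h
            if n_h < 2:
                warnings.warn(
                    f"stratum {h!r} has a single PSU; it contributes no variance"
                )
                continue
            Zc = Z - Z.mean(axis=0)
            M += (n_h / (n_h - 1)) * (Zc.T @ Zc)
        self.cov_ = Binv @ M @ Binv
        self.coef_ = beta
        self.bse_ = np.sqrt(np.diag(self.cov_))
        self.df_resid_ = int(n_psus - len(strata_labels))
        self.n_strata_ = int(len(strata_labels))
        self.n_clusters_ = int(n_psus)
        self.n_iter_ = it
        self.converged_ = True
        self.deviance_ = float(dev)
        self.n_obs_ = int(n)
        return self

    def predict_proba(self, X):
        Xm = pd.DataFrame(X)[list(self.feature_names_in_)].to_numpy(dtype=float)
        p1 = expit(Xm @ self.coef_)
        return np.column_stack([1 - p1, p1])

    def conf_int(self):
        """Wald intervals on the log-odds scale with t(df_resid_) quantile."""
        if self.df_resid_ < 1:
            raise ValueError("design degrees of freedom < 1; no inference possible")
        tq = student_t.ppf(1 - self.alpha / 2, self.df_resid_)
        lo = self.coef_ - tq * self.bse_
        hi = self.coef_ + tq * self.bse_
        return np.column_stack([lo, hi])

    def summary_frame(self) -> pd.DataFrame:
        """Odds ratios with design-based confidence intervals, one row per term."""
        ci = self.conf_int()
        return pd.DataFrame(
            {
                "term": self.feature_names_in_,
                "estimate": self.coef_,
                "se": self.bse_,
                "odds_ratio": np.exp(self.coef_),
                "ci_low": np.exp(ci[:, 0]),
                "ci_high": np.exp(ci[:, 1]),
            }
        )


def completeness_model(
    records: pd.DataFrame,
    terms=("survey", "module", "age", "education", "dob"),
    references: dict | None = None,
    weight: str = "auto",
    **fit_params,
) -> tuple[DesignLogit, pd.DataFrame, dict]:
    """Fit the completeness-of-age-reporting model on FGM-positive records.

    ``weight`` selects ``weight_denorm`` (pooled person-units, default when
    present), ``weight_norm``, or ``none``.  Strata and PSUs are the survey's
    stratum and cluster labels, nested within survey.
    """
    X, y, info = build_design_matrix(records, terms=terms, references=references)
    sub = records.loc[info["index"]]
    if weight == "auto":
        weight = "weight_denorm" if "weight_denorm" in records.columns else "weight_norm"
    w = None if weight == "none" else sub[weight].to_numpy()
    strata = (sub["survey_id"] + "|" + sub["stratum_id"]).to_numpy()
    clusters = (sub["survey_id"] + "|" + sub["stratum_id"] + "|" + sub["cluster_id"]).to_numpy()
    model = DesignLogit(**fit_params).fit(X, y, sample_weight=w, strata=strata, clusters=clusters)
    table = model.summary_frame()
    info = dict(info, weight=weight, n_psus=model.n_clusters_, n_strata=model.n_strata_)
    info.pop("index")
    return model, table, info
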