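"""Small grouping-aware regression helpers shared across modules.

Group-level contracts in this package ask for random intercepts per group
(study or session). With more than one group this is a linear mixed model;
with a single group the random intercept is unidentified and the fit
degrades to ordinary least squares (or, for an intercept-only model, a
one-sample t-test).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats


def group_linear(endog, exog, groups, names=None) -> dict:
    """Linear fit of ``endog`` on ``exog`` with random intercepts per group.

    ``exog`` must not contain a constant column; one is added. Returns a
    dict with per-coefficient estimates, standard errors and Wald p-values
    (names: "intercept" plus ``names``).
    """
    endog = np.asarray(endog, dtype=float)
    exog = np.atleast_2d(np.asarray(exog, dtype=float))
    if exog.shape[0] != endog.size:
        exog = exog.T
    groups = np.asarray(groups)
    ok = np.isfinite(endog) & np.isfinite(exog).all(axis=1)
    endog, exog, groups = endog[ok], exog[ok], groups[ok]
    if names is None:
        names = [f"x{i}" for i in range(exog.shape[1])]
    X = sm.add_constant(exog, has_constant="add")
    n_groups = len(pd.unique(groups))
    if n_groups > 1:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                res = sm.MixedLM(endog, X, groups=groups).fit(reml=True, method="lbfgs")
                params, bse, pvalues = res.params[: X.shape[1]], res.bse[: X.shape[1]], res.pvalues[: X.shape[1]]
            except Exception:  # singular random-effects covariance etc.
                res = sm.OLS(endog, X).fit()
                params, bse, pvalues = res.params, res.bse, res.pvalues
    else:
        res = sm.OLS(endog, X).fit()
        params, bse, pvalues = res.params, res.bse, res.pvalues
    out = {"n": int(endog.size), "n_groups": n_groups}
    for i, nm in enumerate(["intercept"] + list(names)):
        out[nm] = float(np.asarray(params)[i])
        out[f"{nm}_se"] = float(np.asarray(bse)[i])
        out[f"{nm}_p"] = float(np.asarray(pvalues)[i])
    return out


def intercept_test(values, groups) -> tuple[float, float]:
    """Estimate and p-value for an intercept-only group model on ``values``.

    Multiple groups: random-intercept mixed model. Single group: one-sample
    t-test against zero.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    ok = np.isfinite(values)
    values, groups = values[ok], groups[ok]
    if len(pd.unique(groups)) > 1:
        res = group_linear(values, np.empty((values.size, 0)), groups, names=[])
        return res["intercept"], res["intercept_p"]
    t = stats.ttest_1samp(values, 0.0)
    return float(np.mean(values)), float(t.pvalue)


def _ridge_logit(y, X, alpha: float) -> np.ndarray:
    """L2-penalized logistic MLE via BFGS (robust under separation)."""
    from scipy.optimize import minimize as _minimize

    def nll(beta):
        z = X @ beta
        # log(1 + exp(-|z|)) + max(-z, 0) form keeps the loss finite
        return float(
            np.sum(np.logaddexp(0.0, -z) * y + np.logaddexp(0.0, z) * (1 - y))
            + 0.5 * alpha * beta @ beta
        )

    def grad(beta):
        p = 1.0 / (1.0 + np.exp(-(X @ beta)))
        return X.T @ (p - y) + alpha * beta

    res = _minimize(nll, np.zeros(X.shape[1]), jac=grad, method="BFGS",
                    options={"maxiter": 500})
    return res.x


def cluster_logit(endog, exog, groups, names=None, ridge_alpha: float = 1e-4) -> dict:
    """Pooled logistic regression with cluster-robust inference by group.

    Falls back to a ridge-penalized fit (strength ``ridge_alpha``) with a
    warning when the MLE does not exist (perfect separation) or fails to
    converge; penalized fits report estimates without p-values.
    """
    endog = np.asarray(endog, dtype=float)
    exog = np.atleast_2d(np.asarray(exog, dtype=float))
    if exog.shape[0] != endog.size:
        exog = exog.T
    groups = np.asarray(groups)
    ok = np.isfinite(endog) & np.isfinite(exog).all(axis=1)
    endog, exog, groups = endog[ok], exog[ok], groups[ok]
    if names is None:
        names = [f"x{i}" for i in range(exog.shape[1])]
    X = sm.add_constant(exog, has_constant="add")
    model = sm.Logit(endog, X)
    out = {"n": int(endog.size), "penalized": False}
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            if len(pd.unique(groups)) > 1:
                res = model.fit(disp=False, maxiter=200, cov_type="cluster",
                                cov_kwds={"groups": groups})
            else:
                res = model.fit(disp=False, maxiter=200)
        if not res.mle_retvals.get("converged", True) or not np.isfinite(res.bse).all():
            raise RuntimeError("logistic MLE did not converge")
        params, pvalues = res.params, res.pvalues
        out["llf"] = float(res.llf)
        out["aic"] = float(res.aic)
    except Exception:
        warnings.warn("logistic fit unstable (separation?); using ridge-penalized fallback")
        params = _ridge_logit(endog, X, ridge_alpha)
        pvalues = np.full(len(params), np.nan)
        llf = float(model.loglike(np.asarray(params)))
        out["llf"] = llf
        out["aic"] = float(2 * len(params) - 2 * llf)
        out["penalized"] = True
    for i, nm in enumerate(["intercept"] + list(names)):
        out[nm] = float(np.asarray(params)[i])
        out[f"{nm}_p"] = float(np.asarray(pvalues)[i])
    return out
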