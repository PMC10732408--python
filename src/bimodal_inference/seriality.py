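"""Serial dependence of congruence indicators against a permutation null.

The sample autocorrelation of a binary indicator (e.g. history-congruence)
is biased away from zero by any imbalance in the indicator itself — an
agent that simply prefers one response produces history-congruence above
50% and hence spurious positive autocorrelation at all lags. Comparing the
true coefficients with coefficients obtained after randomly permuting the
trial order removes exactly this imbalance-driven component, because
permutation preserves the marginal frequency while destroying all serial
structure. All group-level statistics therefore operate on the
permutation-corrected coefficients ``r_true - mean(r_perm)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.fft import next_fast_len, rfft, irfft

from ._stats import cluster_logit, group_linear, intercept_test

DEFAULT_N_PERM = 100


def autocorrelation(x: np.ndarray, max_lag: int) -> np.ndarray:
    """Biased sample autocorrelation at lags 0..max_lag.

    r_k = sum_{t=1}^{n-k} (x_t - xbar)(x_{t+k} - xbar) / sum_t (x_t - xbar)^2
    (1/n normalization, the conventional definition). The series must be
    complete (no missing entries). A zero-variance series returns all zeros
    with a warning.
    """
    x = np.asarray(x, dtype=float)
    if np.isnan(x).any():
        raise ValueError("autocorrelation requires a complete series; restrict to the defined sub-series")
    n = x.size
    if n <= max_lag:
        raise ValueError(f"series length {n} must exceed max_lag {max_lag}")
    xc = x - x.mean()
    denom = float(np.dot(xc, xc))
    if denom == 0.0:
        warnings.warn("zero-variance series: autocorrelation defined as 0")
        return np.zeros(max_lag + 1)
    nfft = next_fast_len(2 * n)
    f = rfft(xc, nfft)
    acov = irfft(f * np.conj(f), nfft)[: max_lag + 1]
    return acov / denom


def _batch_autocorrelation(rows: np.ndarray, max_lag: int) -> np.ndarray:
    """Autocorrelation of each row of a complete 2-D array, lags 0..max_lag."""
    rows = np.asarray(rows, dtype=float)
    n = rows.shape[1]
    xc = rows - rows.mean(axis=1, keepdims=True)
    denom = np.einsum("ij,ij->i", xc, xc)
    nfft = next_fast_len(2 * n)
    f = rfft(xc, nfft, axis=1)
    acov = irfft(f * np.conj(f), nfft, axis=1)[:, : max_lag + 1]
    out = np.zeros_like(acov)
    ok = denom > 0
    out[ok] = acov[ok] / denom[ok, None]
    return out


def permutation_null(
    x: np.ndarray,
    max_lag: int,
    n_perm: int = DEFAULT_N_PERM,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Autocorrelations (lags 0..max_lag) of ``n_perm`` random permutations of x."""
    x = np.asarray(x, dtype=float)
    if np.isnan(x).any():
        raise ValueError("permutation_null requires a complete series")
    rng = np.random.default_rng(rng)
    perms = np.empty((n_perm, x.size))
    for i in range(n_perm):
        perms[i] = x[rng.permutation(x.size)]
    return _batch_autocorrelation(perms, max_lag)


def history_indicator(choices: np.ndarray) -> np.ndarray:
    """Repeat indicator 1[c_t = c_{t-1}] on trials 2..n."""
    choices = np.asarray(choices)
    return (choices[1:] == choices[:-1]).astype(float)


def history_permutation_null(
    choices: np.ndarray,
    max_lag: int,
    n_perm: int = DEFAULT_N_PERM,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Permutation null for the autocorrelation of history-congruence.

    The trial order of the *choice sequence* is permuted and the repeat
    indicator recomputed before taking the autocorrelation. This matters:
    the repeat indicator of even an i.i.d. (possibly biased) choice
    sequence is itself serially dependent through overlapping trials, so
    permuting the indicator directly would understate the null and leave
    bias-induced autocorrelation in the corrected coefficients.
    """
    choices = np.asarray(choices, dtype=float)
    rng = np.random.default_rng(rng)
    perms = np.empty((n_perm, choices.size - 1))
    for i in range(n_perm):
        c = choices[rng.permutation(choices.size)]
        perms[i] = (c[1:] == c[:-1]).astype(float)
    return _batch_autocorrelation(perms, max_lag)


def individual_lag(r_true: np.ndarray, r_perm: np.ndarray) -> int:
    """Consecutive lags (from lag 1) at which the true coefficient beats the null.

    Counts lags, starting at lag 1, for which less than 50% of the permuted
    coefficients strictly exceed the true coefficient; stops at the first
    lag violating this. ``r_true`` has lags 0..K, ``r_perm`` is n_perm x (K+1).
    """
    r_true = np.asarray(r_true, dtype=float)
    r_perm = np.asarray(r_perm, dtype=float)
    count = 0
    for k in range(1, r_true.size):
        frac = float(np.mean(r_perm[:, k] > r_true[k]))
        if frac < 0.5:
            count += 1
        else:
            break
    return count


@dataclass
class AutocorrelationProfile:
    """True, permuted, and permutation-corrected autocorrelation of one series."""

    subject_id: str
    group_id: str
    lags: np.ndarray          # 1..K
    r_true: np.ndarray        # per lag 1..K
    r_perm: np.ndarray        # n_perm x K
    r_corrected: np.ndarray   # r_true - mean over permutations
    individual_lag: int

    @classmethod
    def from_series(
        cls,
        x: np.ndarray,
        max_lag: int,
        n_perm: int = DEFAULT_N_PERM,
        rng: np.random.Generator | int | None = None,
        subject_id: str = "",
        group_id: str = "",
    ) -> "AutocorrelationProfile":
        r = autocorrelation(x, max_lag)
        perm = permutation_null(x, max_lag, n_perm=n_perm, rng=rng)
        return cls(
            subject_id=subject_id,
            group_id=group_id,
            lags=np.arange(1, max_lag + 1),
            r_true=r[1:],
            r_perm=perm[:, 1:],
            r_corrected=r[1:] - perm[:, 1:].mean(axis=0),
            individual_lag=individual_lag(r, perm),
        )

    @classmethod
    def from_choice_history(
        cls,
        choices: np.ndarray,
        max_lag: int,
        n_perm: int = DEFAULT_N_PERM,
        rng: np.random.Generator | int | None = None,
        subject_id: str = "",
        group_id: str = "",
    ) -> "AutocorrelationProfile":
        """Profile of history-congruence with a choice-permutation null."""
        r = autocorrelation(history_indicator(choices), max_lag)
        perm = history_permutation_null(choices, max_lag, n_perm=n_perm, rng=rng)
        return cls(
            subject_id=subject_id,
            group_id=group_id,
            lags=np.arange(1, max_lag + 1),
            r_true=r[1:],
            r_perm=perm[:, 1:],
            r_corrected=r[1:] - perm[:, 1:].mean(axis=0),
            individual_lag=individual_lag(r, perm),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "subject_id": self.subject_id,
                "group_id": self.group_id,
                "lag": self.lags,
                "r_true": self.r_true,
                "r_perm_mean": self.r_perm.mean(axis=0),
                "r_corrected": self.r_corrected,
            }
        )


def group_autocorrelation_test(profiles: list[AutocorrelationProfile], alpha: float = 0.05) -> pd.DataFrame:
    """Per-lag test of whether the corrected autocorrelation exceeds zero.

    Intercept-only model on r_corrected with random intercepts per group
    (one-sample t-test when only one group is present). A lag is flagged
    significant when the intercept is positive with p < alpha.
    """
    if len(profiles) < 2:
        raise ValueError("need >= 2 subjects for the group test")
    lags = profiles[0].lags
    groups = np.array([p.group_id for p in profiles])
    rows = []
    for j, lag in enumerate(lags):
        vals = np.array([p.r_corrected[j] for p in profiles])
        est, p = intercept_test(vals, groups)
        rows.append({"lag": int(lag), "estimate": est, "pvalue": p,
                     "significant": bool(est > 0 and p < alpha)})
    return pd.DataFrame(rows)


def covariate_controlled_group_test(
    profiles: list[AutocorrelationProfile],
    covariate_profiles: dict[str, list[AutocorrelationProfile]],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Group test with covariate autocorrelation profiles as per-lag regressors.

    Each covariate (e.g. the corrected autocorrelation of task difficulty or
    of the stimulus sequence, computed by the same pipeline) enters the
    per-lag model as a fixed effect; collinear covariates are dropped with a
    warning.
    """
    lags = profiles[0].lags
    groups = np.array([p.group_id for p in profiles])
    names = list(covariate_profiles)
    rows = []
    for j, lag in enumerate(lags):
        vals = np.array([p.r_corrected[j] for p in profiles])
        cols, kept = [], []
        for nm in names:
            c = np.array([cp.r_corrected[j] for cp in covariate_profiles[nm]])
            if np.std(c) == 0 or any(np.allclose(c, prev) for prev in cols):
                warnings.warn(f"covariate {nm!r} collinear/degenerate at lag {lag}; dropped")
                continue
            cols.append(c)
            kept.append(nm)
        if cols:
            res = group_linear(vals, np.column_stack(cols), groups, names=kept)
            est, p = res["intercept"], res["intercept_p"]
        else:
            est, p = intercept_test(vals, groups)
        rows.append({"lag": int(lag), "estimate": est, "pvalue": p,
                     "significant": bool(est > 0 and p < alpha)})
    return pd.DataFrame(rows)


def lagged_logistic_regression(
    indicators: list[np.ndarray],
    max_lag: int,
    subject_ids: list | None = None,
) -> pd.DataFrame:
    """Pooled logistic regression of an indicator on its ``max_lag`` predecessors.

    Design rows need a complete lag history; earlier trials (and series
    shorter than ``max_lag + 1``) are dropped. Inference is cluster-robust
    by subject. Returns per-lag log-odds coefficients with p-values.
    """
    if subject_ids is None:
        subject_ids = list(range(len(indicators)))
    ys, Xs, gs = [], [], []
    for sid, ind in zip(subject_ids, indicators):
        ind = np.asarray(ind, dtype=float)
        ind = ind[np.isfinite(ind)]
        n = ind.size
        if n <= max_lag:
            continue
        y = ind[max_lag:]
        X = np.column_stack([ind[max_lag - k : n - k] for k in range(1, max_lag + 1)])
        ys.append(y)
        Xs.append(X)
        gs.append(np.repeat(sid, y.size))
    if not ys:
        raise ValueError("no series long enough for the requested lag depth")
    names = [f"lag{k}" for k in range(1, max_lag + 1)]
    res = cluster_logit(np.concatenate(ys), np.vstack(Xs), np.concatenate(gs), names=names)
    return pd.DataFrame(
        {
            "lag": np.arange(1, max_lag + 1),
            "coef": [res[nm] for nm in names],
            "pvalue": [res[f"{nm}_p"] for nm in names],
        }
    )


def choice_history_glm(cohort) -> dict:
    """Logistic regression of choice on stimulus, previous choice, and bias.

    The stimulus regressor is the centered category (binary dialect) or the
    signed contrast; the bias regressor is the subject's overall fraction of
    choice=1 (centered). Returns coefficients plus the AIC difference
    between the full model and the model without the history term
    (``delta_aic`` > 0 means history improves the fit).
    """
    ys, Xs, gs = [], [], []
    for s in cohort:
        if s.n_trials < 2:
            continue
        if s.dialect == "binary_category":
            stim = s.stimulus - 0.5
        else:
            stim = s.stimulus
        bias = s.choice.mean() - 0.5
        y = s.choice[1:].astype(float)
        X = np.column_stack(
            [stim[1:], s.choice[:-1] - 0.5, np.repeat(bias, s.n_trials - 1)]
        )
        ys.append(y)
        Xs.append(X)
        gs.append(np.repeat(f"{s.subject_id}/{s.group_id}", y.size))
    y = np.concatenate(ys)
    X = np.vstack(Xs)
    g = np.concatenate(gs)
    full = cluster_logit(y, X, g, names=["stimulus", "prev_choice", "bias"])
    reduced = cluster_logit(y, X[:, [0, 2]], g, names=["stimulus", "bias"])
    return {
        "stimulus": full["stimulus"],
        "stimulus_p": full["stimulus_p"],
        "prev_choice": full["prev_choice"],
        "prev_choice_p": full["prev_choice_p"],
        "bias": full["bias"],
        "bias_p": full["bias_p"],
        "aic_full": full["aic"],
        "aic_no_history": reduced["aic"],
        "delta_aic": reduced["aic"] - full["aic"],
    }
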