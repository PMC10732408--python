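"""The bimodal-inference observer model and its reduced controls.

The observer accumulates evidence about a binary hidden state across
trials. On trial t the noisy observation u of the stimulus yields a log
likelihood ratio LLR_t; the log prior ratio psi_t is carried over from the
previous posterior L_{t-1} through a hazard-rate transition (hazard H = the
assumed per-trial probability that the state switches, after Glaze-style
normative accumulation):

    psi_t = L_{t-1} + log((1-H)/H + exp(-L_{t-1})) - log((1-H)/H + exp(L_{t-1}))
    L_t   = LLR_t * omega_llr_t + psi_t * omega_psi_t

The two precision weights oscillate in antiphase around 1,

    omega_llr = a_llr * sin(f*t + p) + 1,   omega_psi = a_psi * sin(f*t + p + pi) + 1,

periodically tilting perception toward external evidence or internal
prediction. Choice probabilities follow a softmax on the posterior,
y_p = 1 / (1 + exp(-zeta * L)).

Model variants successively remove components: M2 drops the prior
oscillation (a_psi = 0), M3 the likelihood oscillation (a_llr = 0), M4 both
(pure normative accumulation), and M5 additionally the accumulation itself
(H = 0.5, flat prior), leaving 7/6/6/3/2 free parameters.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from numba import njit
from scipy.optimize import minimize
from scipy.stats import qmc

from ._stats import cluster_logit, group_linear
from .congruence import congruence_series
from .trialdata import BINARY_CATEGORY, TrialSeries

PARAM_NAMES = ("alpha", "hazard", "amp_llr", "amp_psi", "freq", "phase", "zeta")
PARAM_BOUNDS = {
    "alpha": (0.0, 5.0),
    "hazard": (0.0, 1.0),
    "amp_llr": (0.0, 10.0),
    "amp_psi": (0.0, 10.0),
    "freq": (1.0 / 40.0, 1.0 / 5.0),
    "phase": (0.0, 2.0 * math.pi),
    "zeta": (1.0, 10.0),
}

_HAZARD_EPS = 1e-6
_U_EPS = 1e-12
_YP_EPS = 1e-9
MIN_FIT_TRIALS = 50


@dataclass(frozen=True)
class ModelVariant:
    """A named constraint pattern over the seven observer parameters."""

    name: str
    free: tuple[str, ...]
    fixed: dict[str, float] = field(default_factory=dict)

    @property
    def k(self) -> int:
        return len(self.free)


VARIANTS: dict[str, ModelVariant] = {
    "M1": ModelVariant("M1", PARAM_NAMES),
    "M2": ModelVariant(
        "M2", ("alpha", "hazard", "amp_llr", "freq", "phase", "zeta"), {"amp_psi": 0.0}
    ),
    "M3": ModelVariant(
        "M3", ("alpha", "hazard", "amp_psi", "freq", "phase", "zeta"), {"amp_llr": 0.0}
    ),
    "M4": ModelVariant(
        "M4", ("alpha", "hazard", "zeta"),
        {"amp_llr": 0.0, "amp_psi": 0.0, "freq": 0.1, "phase": 0.0},
    ),
    "M5": ModelVariant(
        "M5", ("alpha", "zeta"),
        {"amp_llr": 0.0, "amp_psi": 0.0, "freq": 0.1, "phase": 0.0, "hazard": 0.5},
    ),
}


@dataclass
class ModelParams:
    """The seven observer parameters plus the stimulus dialect."""

    alpha: float
    hazard: float
    amp_llr: float
    amp_psi: float
    freq: float
    phase: float
    zeta: float
    dialect: str = BINARY_CATEGORY

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in PARAM_NAMES])

    def validate(self, variant: ModelVariant | None = None) -> None:
        for name in PARAM_NAMES:
            lo, hi = PARAM_BOUNDS[name]
            v = getattr(self, name)
            if not (lo - 1e-12 <= v <= hi + 1e-12):
                raise ValueError(f"{name}={v} outside [{lo}, {hi}]")
        if variant is not None:
            for name, v in variant.fixed.items():
                if name in ("freq", "phase") and self.amp_llr == 0 and self.amp_psi == 0:
                    continue  # irrelevant once both amplitudes vanish
                if not math.isclose(getattr(self, name), v, abs_tol=1e-12):
                    raise ValueError(
                        f"params violate {variant.name} constraint {name}={v}"
                    )


def stimulus_signal(series: TrialSeries) -> np.ndarray:
    """Centered stimulus signal entering the sensory sigmoid: s-0.5 or s."""
    if series.dialect == BINARY_CATEGORY:
        return series.stimulus - 0.5
    return series.stimulus.copy()


def sensory_observation(s, alpha: float, dialect: str = BINARY_CATEGORY) -> np.ndarray:
    """Noisy observation u in (0, 1) from the stimulus via the sensory sigmoid."""
    s = np.asarray(s, dtype=float)
    x = s - 0.5 if dialect == BINARY_CATEGORY else s
    return 1.0 / (1.0 + np.exp(-alpha * x))


def log_likelihood_ratio(u) -> np.ndarray:
    """LLR = log(u / (1-u)); u clipped away from {0, 1}."""
    u = np.clip(np.asarray(u, dtype=float), _U_EPS, 1.0 - _U_EPS)
    return np.log(u / (1.0 - u))


def prior_update(l_prev, hazard: float) -> np.ndarray:
    """Log prior ratio carried over from L_{t-1} through the hazard transition.

    Odd and increasing in L_{t-1} for H < 0.5, saturating at
    +/- log((1-H)/H); identically 0 at H = 0.5; the H -> 0 and H -> 1
    limits return L_{t-1} and -L_{t-1}.
    """
    l_prev = np.asarray(l_prev, dtype=float)
    if hazard <= _HAZARD_EPS:
        return l_prev + 0.0
    if hazard >= 1.0 - _HAZARD_EPS:
        return -l_prev
    lr = math.log((1.0 - hazard) / hazard)
    return l_prev + np.logaddexp(lr, -l_prev) - np.logaddexp(lr, l_prev)


def precision_weights(trial_index, amp_llr, amp_psi, freq, phase):
    """Antiphase sinusoidal weights (omega_llr, omega_psi) at 1-based trials."""
    t = np.asarray(trial_index, dtype=float)
    w_llr = amp_llr * np.sin(freq * t + phase) + 1.0
    w_psi = amp_psi * np.sin(freq * t + phase + math.pi) + 1.0
    return w_llr, w_psi


def posterior_step(llr, psi, omega_llr, omega_psi):
    """L = LLR * omega_llr + psi * omega_psi."""
    return np.asarray(llr) * omega_llr + np.asarray(psi) * omega_psi


def choice_probability(l_value, zeta: float) -> np.ndarray:
    """y_p = 1 / (1 + exp(-zeta * L)), clipped away from {0, 1} for the loss."""
    p = 1.0 / (1.0 + np.exp(-zeta * np.asarray(l_value, dtype=float)))
    return np.clip(p, _YP_EPS, 1.0 - _YP_EPS)


@njit(cache=True, inline="always")
def _logaddexp(a, b):
    m = a if a > b else b
    return m + math.log1p(math.exp(-abs(a - b)))


@njit(cache=True)
def _forward_jit(x, alpha, hazard, amp_llr, amp_psi, freq, phase, zeta):
    n = x.size
    u = np.empty(n)
    llr = np.empty(n)
    psi = np.empty(n)
    w_llr = np.empty(n)
    w_psi = np.empty(n)
    L = np.empty(n)
    yp = np.empty(n)
    low = hazard <= _HAZARD_EPS
    high = hazard >= 1.0 - _HAZARD_EPS
    lr = 0.0
    if not (low or high):
        lr = math.log((1.0 - hazard) / hazard)
    l_prev = 0.0
    for t in range(n):
        ut = 1.0 / (1.0 + math.exp(-alpha * x[t]))
        if ut < _U_EPS:
            ut = _U_EPS
        elif ut > 1.0 - _U_EPS:
            ut = 1.0 - _U_EPS
        u[t] = ut
        llr[t] = math.log(ut / (1.0 - ut))
        if t == 0:
            ps = 0.0
        elif low:
            ps = l_prev
        elif high:
            ps = -l_prev
        else:
            ps = l_prev + _logaddexp(lr, -l_prev) - _logaddexp(lr, l_prev)
        psi[t] = ps
        arg = freq * (t + 1.0) + phase
        wl = amp_llr * math.sin(arg) + 1.0
        wp = amp_psi * math.sin(arg + math.pi) + 1.0
        w_llr[t] = wl
        w_psi[t] = wp
        lt = llr[t] * wl + ps * wp
        L[t] = lt
        p = 1.0 / (1.0 + math.exp(-zeta * lt))
        if p < _YP_EPS:
            p = _YP_EPS
        elif p > 1.0 - _YP_EPS:
            p = 1.0 - _YP_EPS
        yp[t] = p
        l_prev = lt
    return u, llr, psi, w_llr, w_psi, L, yp


@njit(cache=True)
def _nll_jit(x, y, alpha, hazard, amp_llr, amp_psi, freq, phase, zeta):
    # same recursion as _forward_jit, written with the algebraic shortcuts
    # LLR = alpha*x and omega_psi = 1 - a_psi*sin(arg); no latents stored
    n = x.size
    low = hazard <= _HAZARD_EPS
    high = hazard >= 1.0 - _HAZARD_EPS
    lr = 0.0
    r = 1.0
    if not (low or high):
        r = (1.0 - hazard) / hazard
        lr = math.log(r)
    l_prev = 0.0
    nll = 0.0
    for t in range(n):
        llr = alpha * x[t]
        if t == 0:
            ps = 0.0
        elif low:
            ps = l_prev
        elif high:
            ps = -l_prev
        elif l_prev > 30.0 or l_prev < -30.0:
            ps = l_prev + _logaddexp(lr, -l_prev) - _logaddexp(lr, l_prev)
        else:
            el = math.exp(l_prev)
            ps = l_prev + math.log((r + 1.0 / el) / (r + el))
        s1 = math.sin(freq * (t + 1.0) + phase)
        lt = llr * (amp_llr * s1 + 1.0) + ps * (1.0 - amp_psi * s1)
        p = 1.0 / (1.0 + math.exp(-zeta * lt))
        if p < _YP_EPS:
            p = _YP_EPS
        elif p > 1.0 - _YP_EPS:
            p = 1.0 - _YP_EPS
        if y[t] > 0.5:
            nll -= math.log(p)
        else:
            nll -= math.log(1.0 - p)
        l_prev = lt
    return nll


@dataclass
class ModelFit:
    """Trialwise latents and loss of one observer on one series."""

    subject_id: str
    group_id: str
    variant: str
    params: ModelParams
    u: np.ndarray
    llr: np.ndarray
    psi: np.ndarray
    omega_llr: np.ndarray
    omega_psi: np.ndarray
    L: np.ndarray
    y_p: np.ndarray
    neg_log_loss: float
    aic: float = np.nan
    converged: bool = True
    n_starts: int = 0

    @property
    def certainty(self) -> np.ndarray:
        """Posterior decision certainty |L_t| (model surrogate for confidence)."""
        return np.abs(self.L)

    def latents_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "subject_id": self.subject_id,
                "trial_index": np.arange(1, self.L.size + 1),
                "u": self.u,
                "llr": self.llr,
                "psi": self.psi,
                "omega_llr": self.omega_llr,
                "omega_psi": self.omega_psi,
                "L": self.L,
                "y_p": self.y_p,
                "certainty": self.certainty,
            }
        )


def forward_pass(
    series: TrialSeries, params: ModelParams, variant: ModelVariant | str | None = None
) -> ModelFit:
    """Evaluate the observer on a series and score its choices by log loss."""
    if isinstance(variant, str):
        variant = VARIANTS[variant]
    if variant is not None:
        params.validate(variant)
    x = stimulus_signal(series)
    u, llr, psi, w_llr, w_psi, L, yp = _forward_jit(x, *params.as_array())
    if not np.isfinite(L).all():
        bad = int(np.flatnonzero(~np.isfinite(L))[0]) + 1
        raise FloatingPointError(f"non-finite posterior at trial {bad}")
    y = series.choice.astype(float)
    nll = -float(np.sum(y * np.log(yp) + (1.0 - y) * np.log(1.0 - yp)))
    return ModelFit(
        subject_id=series.subject_id,
        group_id=series.group_id,
        variant=variant.name if variant else "custom",
        params=params,
        u=u, llr=llr, psi=psi, omega_llr=w_llr, omega_psi=w_psi, L=L, y_p=yp,
        neg_log_loss=nll,
    )


def _expand(variant: ModelVariant, theta: np.ndarray) -> np.ndarray:
    full = np.empty(len(PARAM_NAMES))
    free_idx = {n: i for i, n in enumerate(variant.free)}
    for i, name in enumerate(PARAM_NAMES):
        full[i] = theta[free_idx[name]] if name in free_idx else variant.fixed[name]
    return full


def fit_subject(
    series: TrialSeries,
    variant: ModelVariant | str = "M1",
    n_starts: int = 10,
    seed: int | None = 0,
    min_trials: int = MIN_FIT_TRIALS,
) -> ModelFit:
    """Bounded maximum-likelihood fit of a variant to one subject's choices.

    Minimizes the Bernoulli log loss over the variant's free parameters
    within the parameter boxes using L-BFGS-B from ``n_starts``
    Latin-hypercube starts; the best incumbent is kept. AIC = 2k + 2 * loss.
    """
    if isinstance(variant, str):
        variant = VARIANTS[variant]
    if series.n_trials < min_trials:
        raise ValueError(f"need >= {min_trials} trials to fit (got {series.n_trials})")
    x = stimulus_signal(series)
    y = series.choice.astype(float)
    lo = np.array([PARAM_BOUNDS[n][0] for n in variant.free])
    hi = np.array([PARAM_BOUNDS[n][1] for n in variant.free])

    def objective(theta):
        return _nll_jit(x, y, *_expand(variant, theta))

    # Latin-hypercube starts; amplitude start values are drawn from [0, 2]
    # (full box kept for the optimizer) because starts with very large
    # amplitudes put most weights below zero and strand the local search
    start_hi = hi.copy()
    for j, name in enumerate(variant.free):
        if name in ("amp_llr", "amp_psi"):
            start_hi[j] = 2.0
    sampler = qmc.LatinHypercube(d=len(variant.free), seed=seed)
    starts = [lo + row * (start_hi - lo) for row in sampler.random(n_starts)]
    starts.append((lo + start_hi) / 2)
    # warm starts for oscillation variants: fit the nested no-oscillation
    # model, then seed the oscillation across a frequency x phase grid (the
    # likelihood is multimodal in f and p, and random starts alone often
    # miss the generating basin)
    has_osc = "amp_llr" in variant.free or "amp_psi" in variant.free
    if has_osc:
        nested = VARIANTS["M4"] if "hazard" in variant.free else VARIANTS["M5"]
        base = fit_subject(series, nested, n_starts=max(4, n_starts // 2),
                           seed=seed, min_trials=min_trials).params
        # frequency grid dense enough that a local search can slide into the
        # generating basin (basin width shrinks with series length)
        n_freq = int(np.clip(series.n_trials // 300, 6, 20))
        for fv in np.linspace(*PARAM_BOUNDS["freq"], n_freq):
            for pv in (0.0, np.pi / 2, np.pi, 3 * np.pi / 2):
                s0 = np.empty(len(variant.free))
                for j, name in enumerate(variant.free):
                    if name == "freq":
                        s0[j] = fv
                    elif name == "phase":
                        s0[j] = pv
                    elif name in ("amp_llr", "amp_psi"):
                        s0[j] = 0.7
                    else:
                        s0[j] = getattr(base, name)
                starts.append(s0)
    bounds = list(zip(lo, hi))
    # two-stage search: screen every start with a short run, then optimize
    # fully from the best few candidates
    screened = []
    n_ok = 0
    for theta0 in starts:
        try:
            res = minimize(objective, theta0, method="L-BFGS-B", bounds=bounds,
                           options={"maxiter": 30})
        except FloatingPointError:
            continue
        if np.isfinite(res.fun):
            n_ok += 1
            screened.append(res)
    if not screened:
        raise RuntimeError(f"all {len(starts)} starts failed for {variant.name} on {series.subject_id}")
    screened.sort(key=lambda r: r.fun)
    best, best_fun = screened[0], screened[0].fun
    for cand in screened[:5]:
        try:
            res = minimize(objective, cand.x, method="L-BFGS-B", bounds=bounds)
        except FloatingPointError:
            continue
        if np.isfinite(res.fun) and res.fun < best_fun:
            best, best_fun = res, res.fun
    # polish the incumbent at tight tolerance
    res = minimize(objective, best.x, method="L-BFGS-B", bounds=list(zip(lo, hi)),
                   options={"ftol": 1e-12, "gtol": 1e-9, "maxiter": 500})
    if np.isfinite(res.fun) and res.fun <= best_fun:
        best = res
    full = _expand(variant, best.x)
    params = ModelParams(*full, dialect=series.dialect)
    fit = forward_pass(series, params, variant)
    fit.aic = 2.0 * variant.k + 2.0 * fit.neg_log_loss
    fit.converged = bool(best.success)
    fit.n_starts = n_ok
    return fit


def compare_models(fits: dict[str, dict[str, ModelFit]]) -> pd.DataFrame:
    """AIC comparison table over subjects x variants.

    ``fits`` maps subject -> variant -> ModelFit (same data per subject).
    Subjects missing any variant are dropped from the group sums with a
    warning. Returns one row per variant with the group AIC sum, the
    difference to M1, and the number of subjects for which the variant is
    best.
    """
    variants = sorted({v for per in fits.values() for v in per})
    complete = {s: per for s, per in fits.items() if set(per) >= set(variants)}
    dropped = set(fits) - set(complete)
    if dropped:
        warnings.warn(f"subjects dropped from group AIC (missing fits): {sorted(dropped)}")
    rows = []
    best_counts = {v: 0 for v in variants}
    for per in complete.values():
        best = min(variants, key=lambda v: per[v].aic)
        best_counts[best] += 1
    ref = "M1" if "M1" in variants else variants[0]
    for v in variants:
        total = sum(per[v].aic for per in complete.values())
        ref_total = sum(per[ref].aic for per in complete.values())
        rows.append(
            {
                "variant": v,
                "k": VARIANTS[v].k if v in VARIANTS else np.nan,
                "group_aic": total,
                "delta_aic_vs_" + ref: total - ref_total,
                "n_best": best_counts[v],
                "n_subjects": len(complete),
            }
        )
    return pd.DataFrame(rows)


def certainty_diagnostics(fits, series_list, halfwidth: int = 5) -> dict:
    """Regress behavior on the model's posterior decision certainty |L|.

    Pools one or more fitted subjects: (i) RT on |L_t|, (ii) confidence on
    |L_t|, (iii) logistic regression of history-congruence at t on
    |L_{t-1}|. Summaries whose covariate is entirely missing are omitted.
    """
    if isinstance(fits, ModelFit):
        fits, series_list = [fits], [series_list]
    cert, rts, confs, groups = [], [], [], []
    hist_y, hist_x, hist_g = [], [], []
    for fit, series in zip(fits, series_list):
        c = fit.certainty
        cert.append(c)
        rts.append(series.response_time)
        confs.append(series.confidence)
        g = f"{series.subject_id}/{series.group_id}"
        groups.append(np.repeat(series.group_id, c.size))
        hc = congruence_series(series, halfwidth).hist_congruent
        ok = np.isfinite(hc[1:])
        hist_y.append(hc[1:][ok])
        hist_x.append(c[:-1][ok])
        hist_g.append(np.repeat(g, int(ok.sum())))
    cert = np.concatenate(cert)
    groups = np.concatenate(groups)
    out: dict[str, dict] = {}
    rt = np.concatenate(rts)
    if np.isfinite(rt).any():
        out["rt_on_certainty"] = group_linear(rt, cert, groups, names=["certainty"])
    conf = np.concatenate(confs)
    if np.isfinite(conf).any():
        out["confidence_on_certainty"] = group_linear(conf, cert, groups, names=["certainty"])
    out["history_on_prev_certainty"] = cluster_logit(
        np.concatenate(hist_y), np.concatenate(hist_x), np.concatenate(hist_g),
        names=["prev_certainty"],
    )
    return out
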