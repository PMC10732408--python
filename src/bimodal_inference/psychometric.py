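"""Lapse-rate psychometric function fitted by bounded maximum likelihood.

The probability of choosing option 1 given a weighted signal s_w is

    y_p = gamma + (1 - gamma - delta) * (erf((s_w + mu) / t) + 1) / 2

with lower/upper lapse rates gamma, delta in [0, 0.5], bias mu, and
threshold t (larger t = shallower curve = worse sensitivity). Parameter
boxes differ by dialect: human (binary-category) signals span roughly
+/- 3.5 signal units, mouse signed contrasts span +/- 1.

Signal weighting: in the binary-category dialect the category is centered
and scaled by a 7-level ordinal evidence strength derived from the trial's
difficulty (s_w = (s - 0.5) * D_b); in the signed-contrast dialect the
signed contrast is the signal itself.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import erf
from scipy.stats import qmc

from .congruence import DEFAULT_HALFWIDTH, congruence_series
from .trialdata import BINARY_CATEGORY, TrialSeries

#: (gamma, delta, mu, threshold) boxes per dialect
PARAM_BOUNDS = {
    "binary_category": ((0.0, 0.5), (0.0, 0.5), (-5.0, 5.0), (0.5, 25.0)),
    "signed_contrast": ((0.0, 0.5), (0.0, 0.5), (-0.5, 0.5), (0.01, 1.5)),
}

N_DIFFICULTY_LEVELS = 7
MIN_TRIALS = 20
_EPS = 1e-9


@dataclass
class PsychometricParams:
    gamma: float
    delta: float
    mu: float
    threshold: float
    loglik: float = np.nan
    n_trials: int = 0
    converged: bool = True

    def as_array(self) -> np.ndarray:
        return np.array([self.gamma, self.delta, self.mu, self.threshold])


def difficulty_levels(difficulty: np.ndarray, n_levels: int = N_DIFFICULTY_LEVELS) -> np.ndarray:
    """Map difficulty to ordinal evidence-strength levels 1..n_levels.

    Quantile binning; larger level = stronger evidence, so the hardest
    trials (largest difficulty values) get level 1. NaN difficulty stays NaN.
    """
    difficulty = np.asarray(difficulty, dtype=float)
    out = np.full(difficulty.shape, np.nan)
    ok = np.isfinite(difficulty)
    if not ok.any():
        return out
    ranks = pd.Series(difficulty[ok]).rank(method="average", pct=True).to_numpy()
    level = np.ceil(ranks * n_levels).clip(1, n_levels)
    out[ok] = n_levels + 1 - level  # invert: low difficulty -> high strength
    return out


def weighted_signal(series: TrialSeries) -> np.ndarray:
    """Per-trial weighted signal s_w; NaN where it cannot be formed.

    binary_category: s_w = (s - 0.5) * D_b with D_b the 7-level evidence
    strength from the trial's difficulty (trials with missing difficulty
    are dropped from psychometric fits). signed_contrast: s_w = stimulus.
    """
    if series.dialect == BINARY_CATEGORY:
        levels = difficulty_levels(series.difficulty)
        return (series.stimulus - 0.5) * levels
    return series.stimulus.copy()


def psychometric_prob(s_w, params: PsychometricParams | np.ndarray) -> np.ndarray:
    """Probability of choice = 1 under the lapse-rate erf model."""
    if isinstance(params, PsychometricParams):
        gamma, delta, mu, t = params.as_array()
    else:
        gamma, delta, mu, t = params
    if t <= 0:
        raise ValueError("threshold must be positive")
    s_w = np.asarray(s_w, dtype=float)
    return gamma + (1.0 - gamma - delta) * (erf((s_w + mu) / t) + 1.0) / 2.0


def _neg_loglik(theta, s_w, y):
    p = np.clip(psychometric_prob(s_w, theta), _EPS, 1.0 - _EPS)
    return -float(np.sum(y * np.log(p) + (1.0 - y) * np.log1p(-p)))


def fit_psychometric(
    series: TrialSeries,
    condition: str = "all",
    mode_subset: str = "all",
    halfwidth: int = DEFAULT_HALFWIDTH,
    n_starts: int = 8,
    seed: int | None = 0,
) -> PsychometricParams:
    """Bounded MLE of the psychometric function, optionally conditioned.

    ``condition``: "all", "prev0", or "prev1" (previous choice). ``mode_subset``:
    "all", "internal" (mode < 0), or "external" (mode > 0). The optimizer runs
    L-BFGS-B from ``n_starts`` Latin-hypercube starts plus the box center and
    keeps the best converged incumbent.
    """
    s_w = weighted_signal(series)
    y = series.choice.astype(float)
    keep = np.isfinite(s_w)
    if condition in ("prev0", "prev1"):
        prev = np.full(series.n_trials, np.nan)
        prev[1:] = series.choice[:-1]
        keep &= prev == (1.0 if condition == "prev1" else 0.0)
    elif condition != "all":
        raise ValueError(f"unknown condition {condition!r}")
    if mode_subset in ("internal", "external"):
        mode = congruence_series(series, halfwidth).mode
        keep &= np.isfinite(mode)
        keep &= (mode < 0) if mode_subset == "internal" else (mode > 0)
    elif mode_subset != "all":
        raise ValueError(f"unknown mode_subset {mode_subset!r}")
    s_w, y = s_w[keep], y[keep]
    if s_w.size < MIN_TRIALS:
        raise ValueError(f"only {s_w.size} trials after conditioning (need >= {MIN_TRIALS})")

    bounds = PARAM_BOUNDS[series.dialect]
    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])
    sampler = qmc.LatinHypercube(d=4, seed=seed)
    starts = lo + sampler.random(n_starts) * (hi - lo)
    starts = np.vstack([starts, (lo + hi) / 2])
    # keep the threshold start strictly inside the box
    starts[:, 3] = np.clip(starts[:, 3], lo[3] + 1e-6, hi[3])

    best = None
    for theta0 in starts:
        res = minimize(
            _neg_loglik, theta0, args=(s_w, y), method="L-BFGS-B",
            bounds=[(lo[0], hi[0]), (lo[1], hi[1]), (lo[2], hi[2]), (lo[3] + 1e-9, hi[3])],
        )
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun):
        raise RuntimeError("psychometric fit failed from all starts")
    g, d, mu, t = best.x
    return PsychometricParams(
        gamma=float(g), delta=float(d), mu=float(mu), threshold=float(t),
        loglik=-float(best.fun), n_trials=int(s_w.size), converged=bool(best.success),
    )
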