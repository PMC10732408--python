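"""Stimulus-/history-congruence, sliding probabilities, and the processing mode.

A choice is *stimulus-congruent* when it matches the presented stimulus
category and *history-congruent* when it repeats the previous choice.
Sliding-window probabilities of both indicators (windows of +/- ``halfwidth``
trials, complete windows only) define the *mode* of sensory processing:

    mode = p_stim - p_hist

Positive mode means externally oriented processing (perception tracks the
stimulus), negative mode internally oriented processing (perception tracks
its own history).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._stats import group_linear
from .trialdata import SIGNED_CONTRAST, TrialSeries

DEFAULT_HALFWIDTH = 5


def _sliding_probability(indicator: np.ndarray, halfwidth: int) -> np.ndarray:
    """Centered moving average over complete, fully defined windows.

    The window at trial t covers trials t-halfwidth..t+halfwidth; the value
    is missing unless all 2*halfwidth+1 trials exist and are non-missing, so
    every computed probability pools the same number of Bernoulli draws.
    """
    n = indicator.size
    width = 2 * halfwidth + 1
    out = np.full(n, np.nan)
    if n < width:
        warnings.warn("series shorter than the sliding window; all probabilities missing")
        return out
    valid = np.isfinite(indicator).astype(float)
    filled = np.where(np.isfinite(indicator), indicator, 0.0)
    kernel = np.ones(width)
    sums = np.convolve(filled, kernel, mode="valid")
    counts = np.convolve(valid, kernel, mode="valid")
    interior = np.where(counts == width, sums / width, np.nan)
    out[halfwidth : n - halfwidth] = interior
    return out


@dataclass
class CongruenceSeries:
    """Per-trial congruence indicators and their sliding probabilities."""

    subject_id: str
    group_id: str
    stim_congruent: np.ndarray  # 0/1, NaN where no correct answer is defined
    hist_congruent: np.ndarray  # 0/1, NaN at trial 1
    p_stim: np.ndarray
    p_hist: np.ndarray
    mode: np.ndarray
    halfwidth: int

    @property
    def n_trials(self) -> int:
        return int(self.stim_congruent.size)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "subject_id": self.subject_id,
                "group_id": self.group_id,
                "trial_index": np.arange(1, self.n_trials + 1),
                "stim_congruent": self.stim_congruent,
                "hist_congruent": self.hist_congruent,
                "p_stim": self.p_stim,
                "p_hist": self.p_hist,
                "mode": self.mode,
            }
        )


def stimulus_congruence(series: TrialSeries) -> np.ndarray:
    """1 where the choice matches the stimulus category, NaN where undefined."""
    cat = series.stimulus_category()
    out = (series.choice == cat).astype(float)
    out[np.isnan(cat)] = np.nan
    return out


def history_congruence(series: TrialSeries) -> np.ndarray:
    """1 where the choice repeats the previous choice; undefined at trial 1."""
    out = np.full(series.n_trials, np.nan)
    if series.n_trials >= 2:
        out[1:] = (series.choice[1:] == series.choice[:-1]).astype(float)
    return out


def processing_mode(p_stim: np.ndarray, p_hist: np.ndarray) -> np.ndarray:
    """Elementwise p_stim - p_hist; missing wherever either input is missing."""
    p_stim = np.asarray(p_stim, dtype=float)
    p_hist = np.asarray(p_hist, dtype=float)
    if p_stim.shape != p_hist.shape:
        raise ValueError("p_stim and p_hist must be aligned")
    return p_stim - p_hist


def congruence_series(series: TrialSeries, halfwidth: int = DEFAULT_HALFWIDTH) -> CongruenceSeries:
    """Compute congruence indicators, sliding probabilities, and mode."""
    stim = stimulus_congruence(series)
    hist = history_congruence(series)
    p_stim = _sliding_probability(stim, halfwidth)
    p_hist = _sliding_probability(hist, halfwidth)
    return CongruenceSeries(
        subject_id=series.subject_id,
        group_id=series.group_id,
        stim_congruent=stim,
        hist_congruent=hist,
        p_stim=p_stim,
        p_hist=p_hist,
        mode=processing_mode(p_stim, p_hist),
        halfwidth=halfwidth,
    )


def bin_mode(
    mode: np.ndarray,
    outcome: np.ndarray,
    bin_width: float = 0.1,
    min_bin_fraction: float = 0.005,
) -> pd.DataFrame:
    """Bin an outcome by mode in fixed left-closed intervals over [-1, 1].

    Bins holding fewer than ``min_bin_fraction`` of the non-missing trials
    are dropped. Returns columns ``bin_center, mean_outcome, n``.
    """
    mode = np.asarray(mode, dtype=float)
    outcome = np.asarray(outcome, dtype=float)
    ok = np.isfinite(mode) & np.isfinite(outcome)
    mode, outcome = mode[ok], outcome[ok]
    edges = np.round(np.arange(-1.0, 1.0 + bin_width / 2, bin_width), 10)
    idx = np.clip(np.digitize(mode, edges) - 1, 0, len(edges) - 2)
    rows = []
    min_n = min_bin_fraction * mode.size
    for b in range(len(edges) - 1):
        sel = idx == b
        n = int(sel.sum())
        if n == 0 or n < min_n:
            continue
        rows.append(
            {
                "bin_center": (edges[b] + edges[b + 1]) / 2,
                "mean_outcome": float(outcome[sel].mean()),
                "n": n,
            }
        )
    return pd.DataFrame(rows, columns=["bin_center", "mean_outcome", "n"])


def mode_outcome_regression(outcome, mode, groups) -> dict:
    """Fit outcome ~ b1*mode + b2*mode^2 with random intercepts per group.

    Returns coefficient estimates with Wald tests (keys ``mode``,
    ``mode_sq``, ``intercept`` and ``*_p``).
    """
    mode = np.asarray(mode, dtype=float)
    outcome = np.asarray(outcome, dtype=float)
    ok = np.isfinite(mode) & np.isfinite(outcome)
    if len(np.unique(mode[ok])) < 3:
        raise ValueError("need >= 3 distinct mode values for the quadratic fit")
    exog = np.column_stack([mode, mode**2])
    return group_linear(outcome, exog, np.asarray(groups), names=["mode", "mode_sq"])


def empirical_hazard(series: TrialSeries) -> float:
    """Fraction of consecutive trial pairs whose stimulus category switches.

    The stimulus is reduced to its binary category; trials without a defined
    category (zero contrast) are skipped, so switches are counted between
    consecutive *defined* categories.
    """
    cat = series.stimulus_category()
    cat = cat[~np.isnan(cat)]
    if cat.size < 2:
        raise ValueError("need >= 2 trials with a defined stimulus category")
    return float(np.mean(cat[1:] != cat[:-1]))


def error_conditioned_history(cs: CongruenceSeries) -> tuple[float, float]:
    """History-congruence on stimulus-incongruent vs stimulus-congruent trials.

    Returns ``(p_hist | stim-incongruent, p_hist | stim-congruent)`` over
    trials where both indicators are defined; an empty condition yields NaN
    with a warning.
    """
    ok = np.isfinite(cs.stim_congruent) & np.isfinite(cs.hist_congruent)
    stim = cs.stim_congruent[ok]
    hist = cs.hist_congruent[ok]
    out = []
    for value, label in ((0.0, "stimulus-incongruent"), (1.0, "stimulus-congruent")):
        sel = stim == value
        if not sel.any():
            warnings.warn(f"no {label} trials with defined history-congruence")
            out.append(np.nan)
        else:
            out.append(float(hist[sel].mean()))
    return out[0], out[1]


def sliding_response_bias(choice: np.ndarray, halfwidth: int = DEFAULT_HALFWIDTH) -> np.ndarray:
    """Sliding-window probability of choosing option 1 (general response bias)."""
    return _sliding_probability(np.asarray(choice, dtype=float), halfwidth)
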