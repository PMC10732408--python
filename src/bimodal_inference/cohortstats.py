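"""Cohort-level summary statistics of the full behavioral pipeline.

Bundles the congruence -> seriality -> spectral chain into the handful of
headline statistics reported for a cohort: pooled stimulus- and
history-congruence, error-conditioned history-congruence, mean individual
autocorrelation lags against the permutation null, pooled 1/f exponents of
the sliding congruence probabilities, and band-averaged cross-spectral
phase and squared coherence. Used by the analysis drivers and the
reproduction script.
"""

from __future__ import annotations

import numpy as np

from . import congruence as cg
from . import seriality as sr
from . import spectral as sp
from .trialdata import CohortDataset

DEFAULTS = dict(halfwidth=5, max_lag=100, n_perm=100, daniell_width=50, band_fmax=0.1)


def cohort_statistics(
    cohort: CohortDataset,
    seed: int = 0,
    halfwidth: int = 5,
    max_lag: int = 100,
    n_perm: int = 100,
    daniell_width: int = 50,
    band_fmax: float = 0.1,
) -> dict:
    """Headline pipeline statistics for one cohort.

    Percentages are returned on the 0-100 scale. ``seed`` drives the
    permutation nulls only.
    """
    cong = [cg.congruence_series(s, halfwidth) for s in cohort]

    stim = np.concatenate([c.stim_congruent for c in cong])
    hist = np.concatenate([c.hist_congruent for c in cong])

    err_diffs = []
    for c in cong:
        inc, con = cg.error_conditioned_history(c)
        if np.isfinite(inc) and np.isfinite(con):
            err_diffs.append(inc - con)

    root = np.random.SeedSequence(seed)
    lag_stim, lag_hist = [], []
    for s, c, ss in zip(cohort, cong, root.spawn(len(cong))):
        rng = np.random.default_rng(ss)
        x = c.stim_congruent[np.isfinite(c.stim_congruent)]
        if x.size > max_lag:
            lag_stim.append(
                sr.AutocorrelationProfile.from_series(x, max_lag, n_perm, rng).individual_lag
            )
        if s.n_trials - 1 > max_lag:
            lag_hist.append(
                sr.AutocorrelationProfile.from_choice_history(
                    s.choice, max_lag, n_perm, rng
                ).individual_lag
            )

    profiles = []
    for c in cong:
        ok = np.isfinite(c.p_stim) & np.isfinite(c.p_hist)
        if ok.sum() > daniell_width:
            profiles.append(
                sp.spectral_profile(c.p_stim, c.p_hist, daniell_width,
                                    subject_id=c.subject_id, group_id=c.group_id)
            )
    beta_stim = sp.powerlaw_exponent(profiles, band_fmax, which="stim")["beta"]
    beta_hist = sp.powerlaw_exponent(profiles, band_fmax, which="hist")["beta"]
    bands = [sp.band_summary(p, band_fmax) for p in profiles]
    phases = np.array([b[0] for b in bands])

    return {
        "n_agents": len(cohort),
        "stim_congruence_pct": 100 * float(np.nanmean(stim)),
        "hist_congruence_pct": 100 * float(np.nanmean(hist)),
        "error_history_excess_pct": 100 * float(np.mean(err_diffs)),
        "error_history_excess_sem_pct": 100 * float(
            np.std(err_diffs, ddof=1) / np.sqrt(len(err_diffs))
        ),
        "individual_lag_stim": float(np.mean(lag_stim)),
        "individual_lag_hist": float(np.mean(lag_hist)),
        "powerlaw_beta_stim": float(beta_stim),
        "powerlaw_beta_hist": float(beta_hist),
        "band_coherence_pct": 100 * float(np.mean([b[1] for b in bands])),
        "band_phases": phases,
    }


def phase_histogram_mode(phases: np.ndarray, n_bins: int = 10) -> float:
    """Center of the fullest bin of the phase histogram over [0, 2pi)."""
    hist, edges = np.histogram(phases, bins=n_bins, range=(0, 2 * np.pi))
    return float(edges[int(np.argmax(hist))] + np.pi / n_bins)
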