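"""Smoothed periodograms, 1/f exponents, and cross-spectral phase/coherence.

The sliding probabilities of stimulus- and history-congruence are treated
as discrete-time series in units of trials; frequencies are reported in
cycles per trial on the Fourier grid k/n for k = 1..floor(n/2). Raw
periodograms are mean-removed (no taper, no detrending) and smoothed with
a single modified Daniell kernel — a moving average with half-weight
endpoints — applied circularly over the full-circle periodogram, so
smoothing near the zero and Nyquist frequencies wraps through the
symmetric ordinates. Squared coherence between two series is only
meaningful after smoothing (the raw coherence of single periodograms is
identically 1); for independent series its expectation is approximately
the sum of squared kernel weights, i.e. ~1/width.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.fft import fft
from scipy.ndimage import convolve1d

from ._stats import group_linear

DEFAULT_DANIELL_WIDTH = 50
DEFAULT_BAND_FMAX = 0.1


def modified_daniell_kernel(width: int) -> np.ndarray:
    """Modified Daniell weights of span ``width`` (half-weight endpoints).

    A width of w gives a symmetric kernel over 2*(w//2)+1 ordinates whose
    weights sum to 1; interior weights are 1/(2m), endpoint weights 1/(4m)
    with m = w//2.
    """
    m = width // 2
    if m < 1:
        raise ValueError("daniell width must be >= 2")
    w = np.full(2 * m + 1, 1.0 / (2 * m))
    w[0] = w[-1] = 1.0 / (4 * m)
    return w


def _interpolate_zero_bin(pg: np.ndarray) -> np.ndarray:
    # the mean-removed ordinate at f=0 is identically 0; replace it by the
    # average of its two neighbors so circular smoothing near f=0 is not
    # dragged down by a structural zero
    pg = pg.copy()
    pg[0] = 0.5 * (pg[1] + pg[-1])
    return pg


def _full_periodogram(x: np.ndarray) -> np.ndarray:
    """Mean-removed periodogram at all n Fourier frequencies (two-sided)."""
    x = np.asarray(x, dtype=float)
    if np.isnan(x).any():
        raise ValueError("spectral analysis requires a complete series; trim missing edges")
    xc = x - x.mean()
    f = fft(xc)
    return _interpolate_zero_bin((f * np.conj(f)).real / x.size)


def _full_cross_periodogram(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("series must be aligned")
    if np.isnan(x).any() or np.isnan(y).any():
        raise ValueError("spectral analysis requires complete series")
    fx = fft(x - x.mean())
    fy = fft(y - y.mean())
    return _interpolate_zero_bin(fx * np.conj(fy) / x.size)


def _smooth_circular(values: np.ndarray, width: int) -> np.ndarray:
    kernel = modified_daniell_kernel(width)
    if np.iscomplexobj(values):
        return (
            convolve1d(values.real, kernel, mode="wrap")
            + 1j * convolve1d(values.imag, kernel, mode="wrap")
        )
    return convolve1d(values, kernel, mode="wrap")


def fourier_frequencies(n: int) -> np.ndarray:
    """One-sided Fourier grid k/n for k = 1..floor(n/2), in cycles per trial."""
    return np.arange(1, n // 2 + 1) / n


def smoothed_periodogram(x: np.ndarray, daniell_width: int = DEFAULT_DANIELL_WIDTH):
    """Daniell-smoothed periodogram on the one-sided frequency grid.

    Series shorter than the smoothing span get the unsmoothed periodogram
    with a warning.
    """
    x = np.asarray(x, dtype=float)
    pg = _full_periodogram(x)
    n = x.size
    if n <= daniell_width:
        warnings.warn("series shorter than the Daniell span; returning the raw periodogram")
        smoothed = pg
    else:
        smoothed = _smooth_circular(pg, daniell_width)
    return fourier_frequencies(n), smoothed[1 : n // 2 + 1]


def cross_spectrum(
    x: np.ndarray, y: np.ndarray, daniell_width: int = DEFAULT_DANIELL_WIDTH
):
    """Phase in [0, 2pi) and squared coherence of two aligned series.

    phase(f) = argument of the smoothed cross-spectrum;
    sq_coherence(f) = |smoothed cross|^2 / (smoothed auto_x * smoothed auto_y).
    Rejects spans < 2, for which coherence is identically 1.
    """
    if daniell_width < 2:
        raise ValueError("coherence requires smoothing (daniell_width >= 2)")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    sxx = _smooth_circular(_full_periodogram(x), daniell_width)
    syy = _smooth_circular(_full_periodogram(y), daniell_width)
    sxy = _smooth_circular(_full_cross_periodogram(x, y), daniell_width)
    sel = slice(1, n // 2 + 1)
    sxx, syy, sxy = sxx[sel], syy[sel], sxy[sel]
    phase = np.mod(np.angle(sxy), 2 * np.pi)
    with np.errstate(divide="ignore", invalid="ignore"):
        coh = np.abs(sxy) ** 2 / (sxx * syy)
    coh = np.clip(np.where(np.isfinite(coh), coh, 0.0), 0.0, 1.0)
    return fourier_frequencies(n), phase, coh


@dataclass
class SpectralProfile:
    """Per-subject spectral summary of the two congruence probability series."""

    subject_id: str
    group_id: str
    frequency: np.ndarray
    density_stim: np.ndarray
    density_hist: np.ndarray
    phase: np.ndarray
    sq_coherence: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "subject_id": self.subject_id,
                "group_id": self.group_id,
                "frequency": self.frequency,
                "density_stim": self.density_stim,
                "density_hist": self.density_hist,
                "phase": self.phase,
                "sq_coherence": self.sq_coherence,
            }
        )


def spectral_profile(
    p_stim: np.ndarray,
    p_hist: np.ndarray,
    daniell_width: int = DEFAULT_DANIELL_WIDTH,
    subject_id: str = "",
    group_id: str = "",
) -> SpectralProfile:
    """Spectral profile of a subject's sliding congruence probabilities.

    Both series are restricted to their shared defined (complete-window)
    interior before analysis.
    """
    p_stim = np.asarray(p_stim, dtype=float)
    p_hist = np.asarray(p_hist, dtype=float)
    ok = np.isfinite(p_stim) & np.isfinite(p_hist)
    idx = np.flatnonzero(ok)
    if idx.size == 0:
        raise ValueError("no trials where both probability series are defined")
    x = p_stim[idx[0] : idx[-1] + 1]
    y = p_hist[idx[0] : idx[-1] + 1]
    freq, dx = smoothed_periodogram(x, daniell_width)
    _, dy = smoothed_periodogram(y, daniell_width)
    _, phase, coh = cross_spectrum(x, y, daniell_width)
    return SpectralProfile(subject_id, group_id, freq, dx, dy, phase, coh)


def powerlaw_exponent(
    profiles: list[SpectralProfile],
    f_max: float = DEFAULT_BAND_FMAX,
    which: str = "stim",
) -> dict:
    """Pooled log-log slope of density vs frequency below ``f_max``.

    Fits log10(density) on log10(frequency) over all subjects' ordinates at
    frequencies < f_max, with random intercepts per group. Zero or negative
    densities are dropped with a warning. Returns the slope under key
    ``beta`` with standard error and p-value.
    """
    logf, logd, groups = [], [], []
    for p in profiles:
        d = p.density_stim if which == "stim" else p.density_hist
        band = p.frequency < f_max
        if band.sum() < 2:
            continue
        f, dd = p.frequency[band], d[band]
        ok = dd > 0
        if not ok.all():
            warnings.warn("nonpositive spectral density dropped from the power-law fit")
        logf.append(np.log10(f[ok]))
        logd.append(np.log10(dd[ok]))
        groups.append(np.repeat(p.group_id, ok.sum()))
    if not logf:
        raise ValueError("no subject has >= 2 frequencies below f_max")
    res = group_linear(
        np.concatenate(logd), np.concatenate(logf), np.concatenate(groups), names=["beta"]
    )
    return {"beta": res["beta"], "beta_se": res["beta_se"], "beta_p": res["beta_p"],
            "n": res["n"]}


def circular_mean(angles: np.ndarray) -> float:
    """Circular mean of angles, mapped to [0, 2pi)."""
    angles = np.asarray(angles, dtype=float)
    return float(np.mod(np.angle(np.mean(np.exp(1j * angles))), 2 * np.pi))


def band_summary(profile: SpectralProfile, f_max: float = DEFAULT_BAND_FMAX) -> tuple[float, float]:
    """(circular-mean phase, mean squared coherence) over frequencies < f_max."""
    band = profile.frequency < f_max
    if not band.any():
        warnings.warn("empty frequency band; summaries are missing")
        return np.nan, np.nan
    return circular_mean(profile.phase[band]), float(profile.sq_coherence[band].mean())
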