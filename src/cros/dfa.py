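"""Detrended fluctuation analysis and alpha-band amplitude envelopes.

DFA estimates a self-similarity exponent alpha from the scaling of the RMS
detrended fluctuation F(n) of the integrated (cumulatively summed,
mean-subtracted) series with window size n.  alpha ~ 0.5 indicates
uncorrelated fluctuations, 0.5 < alpha < 1 long-range temporal correlations,
and alpha = 1 corresponds to 1/f noise (for a spectrum S(f) ~ 1/f^v the
relation is v = 2*alpha - 1).  The exponent is fitted by least squares on
log10 F vs log10 n restricted to a fixed 4-14 s window range.

For the band-filtered variant the series is passed through a zero-phase
5th-order Butterworth band-pass (8-16 Hz by default) and the amplitude
envelope |hilbert(x)| is analyzed instead, with 1 s trimmed from each end
to suppress filter/Hilbert edge effects.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal, stats

FIT_RANGE_MS = (4000.0, 14000.0)
DEFAULT_BAND_HZ = (8.0, 16.0)
ENVELOPE_TRIM_MS = 1000


def default_window_sizes(min_ms: float = 100.0, max_ms: float = 20000.0,
                         per_decade: int = 20) -> np.ndarray:
    """Log-spaced window sizes (ms), ``per_decade`` points per decade."""
    n_dec = np.log10(max_ms / min_ms)
    n_pts = int(round(n_dec * per_decade)) + 1
    sizes = np.unique(np.round(np.logspace(
        np.log10(min_ms), np.log10(max_ms), n_pts)).astype(int))
    return sizes


@dataclass
class DFAResult:
    window_sizes: np.ndarray  # ms
    F: np.ndarray
    alpha: float
    intercept: float
    fit_range: tuple[float, float]
    variant: str = "raw"


def dfa(series, window_sizes=None, detrend_order: int = 1,
        fit_range: tuple[float, float] = FIT_RANGE_MS, dt_ms: float = 1.0,
        variant: str = "raw") -> DFAResult:
    """DFA of a uniformly sampled series (default DFA-1, 1 ms sampling).

    The profile is the cumulative sum of the mean-subtracted series; for each
    window size the profile is split into non-overlapping windows (trailing
    partial window discarded), a polynomial trend of ``detrend_order`` is
    removed per window, and F(n) is the RMS of the residuals pooled over
    windows.  alpha is the log-log slope inside ``fit_range``.
    """
    x = np.asarray(series, dtype=float)
    if window_sizes is None:
        window_sizes = default_window_sizes()
    window_sizes = np.asarray(window_sizes)
    ns = (window_sizes / dt_ms).astype(int)
    keep = (ns >= detrend_order + 2) & (ns <= x.size // 4)
    ns, window_sizes = ns[keep], window_sizes[keep]
    if ns.size < 2:
        raise ValueError("series too short for the requested window sizes")

    profile = np.cumsum(x - x.mean())
    F = np.empty(ns.size)
    for k, n in enumerate(ns):
        m = profile.size // n
        seg = profile[: m * n].reshape(m, n)
        t = np.arange(n, dtype=float)
        # least-squares polynomial detrend per window, vectorized over windows
        V = np.vander(t, detrend_order + 1)
        coef, *_ = np.linalg.lstsq(V, seg.T, rcond=None)
        resid = seg.T - V @ coef
        F[k] = np.sqrt(np.mean(resid ** 2))

    in_fit = (window_sizes >= fit_range[0]) & (window_sizes <= fit_range[1])
    if in_fit.sum() < 2:
        raise ValueError("fewer than 2 window sizes inside the fit range")
    res = stats.linregress(np.log10(window_sizes[in_fit]), np.log10(F[in_fit]))
    return DFAResult(window_sizes=window_sizes.astype(float), F=F,
                     alpha=float(res.slope), intercept=float(res.intercept),
                     fit_range=fit_range, variant=variant)


def band_envelope(series, band_hz: tuple[float, float] = DEFAULT_BAND_HZ,
                  filter_order: int = 5, fs: float = 1000.0) -> np.ndarray:
    """Amplitude envelope of the band-passed series (zero-phase Butterworth).

    The 5th-order design is applied forward-backward (sosfiltfilt) to avoid
    phase distortion, then the envelope is |analytic signal|.  Output length
    equals input length; callers analysing the envelope should trim the edges
    (see :func:`dfa_band_filtered`).
    """
    lo, hi = band_hz
    nyq = fs / 2.0
    if not (0.0 < lo < hi < nyq):
        raise ValueError(f"band {band_hz} outside (0, Nyquist={nyq}) Hz")
    x = np.asarray(series, dtype=float)
    sos = signal.butter(filter_order, [lo, hi], btype="bandpass", fs=fs,
                        output="sos")
    filtered = signal.sosfiltfilt(sos, x - x.mean())
    return np.abs(signal.hilbert(filtered))


def dfa_band_filtered(series, band_hz: tuple[float, float] = DEFAULT_BAND_HZ,
                      filter_order: int = 5, dt_ms: float = 1.0,
                      trim_ms: int = ENVELOPE_TRIM_MS, **dfa_kwargs) -> DFAResult:
    """DFA of the band-limited amplitude envelope (edges trimmed)."""
    fs = 1000.0 / dt_ms
    env = band_envelope(series, band_hz, filter_order, fs)
    k = int(trim_ms / dt_ms)
    res = dfa(env[k: len(env) - k] if k else env, dt_ms=dt_ms,
              variant="band_envelope", **dfa_kwargs)
    return res
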