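"""Power spectrum of the population activity and the oscillation order parameter.

The periodogram of A(t) is normalized by the network size (L^2) and the
total simulated time, then block-averaged over non-overlapping windows of
500 raw frequency bins (about 0.45 Hz per smoothed point for a 2^20-ms
trace at 1 kHz).

The order parameter phi quantifies how much spectral area is concentrated
in an oscillation peak.  Given the smoothed spectrum, the peak frequency
f_p is the band argmax; f_- is the nearest local minimum below it (searched
within 4-18 Hz); f_+ = f_p + (f_p - f_-) mirrors the interval.  A chord is
drawn from (f_-, S(f_-)) to (f_+, S(f_+)): phi_p is the area where the
spectrum exceeds the chord and phi_u the area under the chord, so
phi = phi_p / (phi_p + phi_u), and phi = 0 when no qualifying peak exists.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

SMOOTH_BLOCK = 500  # raw FFT bins per smoothed point
F_MIN_SEARCH = (4.0, 18.0)  # Hz band where the local minimum f_- is sought
PEAK_BAND = (4.0, 45.0)  # Hz band where the peak is sought (upper end a choice)
PEAK_SIGNIFICANCE = 2.0  # peak must exceed the chord by this many local SEs


@dataclass
class SpectrumAnalysis:
    freqs: np.ndarray   # Hz, smoothed grid
    power: np.ndarray   # normalized spectral density
    power_se: np.ndarray  # standard error of each block mean
    fs: float           # sampling rate, Hz
    f_minus: float = np.nan
    f_peak: float = np.nan
    f_plus: float = np.nan
    phi: float = 0.0
    phi_p: float = 0.0
    phi_u: float = 0.0

    def save_csv(self, path) -> None:
        np.savetxt(path, np.column_stack([self.freqs, self.power]),
                   delimiter=",", header="freq_hz,power", comments="")


def power_spectrum(A: np.ndarray, n_neurons: int, dt_ms: float = 1.0,
                   smooth_block: int = SMOOTH_BLOCK) -> SpectrumAnalysis:
    """Block-smoothed periodogram of the activity series.

    ``n_neurons`` is the network size L^2 used for normalization; the raw
    periodogram |FFT|^2 is divided by (n_neurons * total_time_s).
    """
    A = np.asarray(A, dtype=float)
    n = A.size
    if n < 2 * smooth_block:
        raise ValueError("trace shorter than one smoothing block")
    fs = 1000.0 / dt_ms
    spec = np.abs(np.fft.rfft(A - A.mean())) ** 2
    total_time_s = n / fs
    spec = spec / (n_neurons * total_time_s)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    # drop the DC bin, then block-average
    spec, freqs = spec[1:], freqs[1:]
    n_blocks = spec.size // smooth_block
    sb = spec[: n_blocks * smooth_block].reshape(n_blocks, smooth_block)
    fb = freqs[: n_blocks * smooth_block].reshape(n_blocks, smooth_block)
    power = sb.mean(axis=1)
    power_se = sb.std(axis=1) / np.sqrt(smooth_block)
    return SpectrumAnalysis(freqs=fb.mean(axis=1), power=power,
                            power_se=power_se, fs=fs)


def order_parameter(spec: SpectrumAnalysis,
                    peak_band: tuple[float, float] = PEAK_BAND,
                    fmin_band: tuple[float, float] = F_MIN_SEARCH,
                    significance: float = PEAK_SIGNIFICANCE) -> SpectrumAnalysis:
    """Detect the spectral peak and fill in (f_-, f_p, f_+) and phi.

    Mutates and returns ``spec``.  phi stays 0 when no peak qualifies:
    no local minimum below the argmax inside ``fmin_band``, or the peak does
    not exceed the chord by ``significance`` local standard errors.
    """
    f, S = spec.freqs, spec.power
    band = (f >= peak_band[0]) & (f <= peak_band[1])
    if not band.any():
        warnings.warn("smoothed spectrum does not cover the peak band",
                      RuntimeWarning, stacklevel=2)
        return spec
    i_peak = np.flatnonzero(band)[np.argmax(S[band])]
    f_peak = f[i_peak]

    # local minimum below the peak: first discrete-derivative sign change
    # walking down-frequency, restricted to the 4-18 Hz search band
    i_minus = -1
    for i in range(i_peak - 1, 0, -1):
        if f[i] < fmin_band[0]:
            break
        if f[i] <= fmin_band[1] and S[i - 1] >= S[i]:
            i_minus = i
            break
    if i_minus < 0:
        return spec  # no qualifying minimum -> phi = 0

    f_minus = f[i_minus]
    f_plus = f_peak + (f_peak - f_minus)
    nyq = spec.fs / 2.0
    if f_plus > f[-1]:
        warnings.warn("f_plus beyond the spectral range; clipping",
                      RuntimeWarning, stacklevel=2)
        f_plus = min(f_plus, f[-1], nyq)

    sel = (f >= f_minus) & (f <= f_plus)
    fi, Si = f[sel], S[sel]
    s_plus = float(np.interp(f_plus, f, S))
    if fi[-1] < f_plus:  # include the clipped right endpoint exactly
        fi = np.append(fi, f_plus)
        Si = np.append(Si, s_plus)
    chord = S[i_minus] + (fi - f_minus) * (s_plus - S[i_minus]) / (f_plus - f_minus)

    excess = Si - chord
    se_local = float(np.median(spec.power_se[sel])) if sel.any() else 0.0
    if excess.max() < significance * se_local:
        return spec  # peak not significant -> phi = 0

    phi_p = float(np.trapezoid(np.maximum(excess, 0.0), fi))
    phi_u = float(np.trapezoid(chord, fi))
    spec.f_minus, spec.f_peak, spec.f_plus = float(f_minus), float(f_peak), float(f_plus)
    spec.phi_p, spec.phi_u = phi_p, phi_u
    spec.phi = phi_p / (phi_p + phi_u) if (phi_p + phi_u) > 0 else 0.0
    return spec


def analyze_spectrum(A: np.ndarray, n_neurons: int, dt_ms: float = 1.0,
                     **kwargs) -> SpectrumAnalysis:
    """Spectrum + order parameter in one call."""
    return order_parameter(power_spectrum(A, n_neurons, dt_ms), **kwargs)
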