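"""Seeded generators with known ground truth for every analysis stage.

These fixtures make each analysis operation testable without running the
network simulator: bounded and exponentially truncated power-law samples
with known exponents, colored noise with spectrum S(f) ~ 1/f^v, oscillatory
signals with a known spectral peak, and families of avalanche temporal
profiles obeying s(t, T) = T^{gamma0 - 1} F(t/T) with F(u) = 4 u (1 - u).
Every generator takes an explicit seed; identical arguments reproduce the
output bit-exactly.
"""

from __future__ import annotations

import numpy as np

from .avalanches import AvalancheCatalog


def sample_bounded_powerlaw(mu: float, x_min: float, x_max: float, n: int,
                            seed: int) -> np.ndarray:
    """Inverse-CDF draws from ``x^{-mu}`` restricted to [x_min, x_max]."""
    _check_powerlaw_args(mu, x_min)
    if not x_max > x_min:
        raise ValueError("need x_max > x_min")
    rng = np.random.default_rng(seed)
    return bounded_powerlaw_ppf(rng.random(n), mu, x_min, x_max)


def bounded_powerlaw_ppf(q, mu: float, x_min: float, x_max: float) -> np.ndarray:
    """Quantile function of the bounded power law (vectorized)."""
    e = 1.0 - mu
    return (x_min ** e + np.asarray(q) * (x_max ** e - x_min ** e)) ** (1.0 / e)


def sample_truncated_powerlaw(mu: float, x0: float, x_min: float, n: int,
                              seed: int, max_batches: int = 10000
                              ) -> np.ndarray:
    """Rejection draws from ``x^{-mu} exp(-x/x0)`` on [x_min, inf).

    For mu > 1 the proposal is the pure power law (Pareto) with acceptance
    probability exp(-(x - x_min)/x0); for 0 < mu <= 1 the proposal is a
    shifted exponential of scale x0 with acceptance (x/x_min)^{-mu}.
    Aborts if the running acceptance rate falls below 1e-3.
    """
    _check_powerlaw_args(mu, x_min)
    if x0 <= 0:
        raise ValueError("x0 must be > 0")
    rng = np.random.default_rng(seed)
    out = np.empty(n)
    filled = 0
    proposed = accepted = 0
    batch = max(4 * n, 1000)
    for _ in range(max_batches):
        if mu > 1.0:
            x = x_min * (1.0 - rng.random(batch)) ** (-1.0 / (mu - 1.0))
            accept = rng.random(batch) < np.exp(-(x - x_min) / x0)
        else:
            x = x_min + rng.exponential(x0, size=batch)
            accept = rng.random(batch) < (x / x_min) ** (-mu)
        proposed += batch
        xs = x[accept]
        accepted += xs.size
        take = min(xs.size, n - filled)
        out[filled: filled + take] = xs[:take]
        filled += take
        if filled == n:
            return out
        if proposed >= 100 * batch and accepted / proposed < 1e-3:
            break
    raise RuntimeError(
        f"pathological acceptance rate {accepted / max(proposed, 1):.2e} "
        f"for mu={mu}, x0={x0}, x_min={x_min}")


def colored_noise(v: float, n: int, seed: int) -> np.ndarray:
    """Spectral synthesis of noise with power spectrum S(f) ~ 1/f^v.

    Gaussian spectral coefficients are shaped by f^{-v/2} with random phases
    and inverse-transformed; the output is standardized to zero mean and
    unit variance.
    """
    if not 0.0 <= v <= 2.0:
        raise ValueError("v must be in [0, 2]")
    rng = np.random.default_rng(seed)
    freqs = np.fft.rfftfreq(n, d=1.0)
    amp = np.zeros_like(freqs)
    amp[1:] = freqs[1:] ** (-v / 2.0)
    coef = amp * (rng.standard_normal(freqs.size)
                  + 1j * rng.standard_normal(freqs.size))
    coef[0] = 0.0
    if n % 2 == 0:
        coef[-1] = coef[-1].real
    x = np.fft.irfft(coef, n=n)
    return (x - x.mean()) / x.std()


def oscillatory_signal(f0: float, amp: float, noise_sd: float, n: int,
                       seed: int, fs: float = 1000.0) -> np.ndarray:
    """Sinusoid at f0 Hz plus white Gaussian noise, sampled at ``fs``."""
    rng = np.random.default_rng(seed)
    t = np.arange(n) / fs
    return amp * np.sin(2.0 * np.pi * f0 * t) + noise_sd * rng.standard_normal(n)


def profile_family(gamma0: float, durations, noise_sd: float,
                   samples_per_T: int, seed: int) -> AvalancheCatalog:
    """Avalanche-like catalog whose mean profiles obey the scaling form.

    Each event of duration T has profile
    ``s(t, T) = T^{gamma0 - 1} * 4 u (1 - u) * max(1 + noise, 0.05)`` with
    ``u = (t + 0.5)/T``, so the noiseless family collapses exactly at
    gamma = gamma0 and total sizes scale as ``s ~ T^{gamma0}``.
    """
    rng = np.random.default_rng(seed)
    profiles, T_list = [], []
    for T in durations:
        T = int(T)
        u = (np.arange(T) + 0.5) / T
        base = T ** (gamma0 - 1.0) * 4.0 * u * (1.0 - u)
        for _ in range(samples_per_T):
            noise = np.maximum(1.0 + noise_sd * rng.standard_normal(T), 0.05)
            profiles.append(base * noise)
            T_list.append(T)
    t_start = np.zeros(len(profiles), dtype=int)
    T_arr = np.asarray(T_list)
    s_g = np.array([p.sum() for p in profiles])
    return AvalancheCatalog(theta=0.0, gamma=np.nan, t_start=t_start,
                            t_end=T_arr, s_g=s_g, s_theta=s_g.copy(),
                            profiles=profiles)


def _check_powerlaw_args(mu: float, x_min: float) -> None:
    if mu <= 0:
        raise ValueError("mu must be > 0")
    if x_min <= 0:
        raise ValueError("x_min must be > 0")
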