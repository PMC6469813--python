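"""Avalanche size-duration scaling, shape collapse, and the crackling relation.

At a critical point the mean avalanche size scales with duration as
<s>(T) ~ T^{1/(sigma nu z)} and the mean temporal profiles obey
s(t, T) ~ T^{gamma - 1} F(t/T) with gamma = 1/(sigma nu z), so the profiles
of all durations collapse onto the single scaling function F.  Consistency
with the size/duration distribution exponents requires the crackling-noise
relation 1/(sigma nu z) = (tau_t - 1)/(tau - 1); testing whether the
independently measured left- and right-hand sides agree is a stringent
criticality check (they need not: the lattice model studied here fails it
throughout its transition region).

Only durations T > 10 ms with at least 10 events each enter these analyses.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .avalanches import AvalancheCatalog

MIN_DURATION_MS = 10.0   # strict: T > 10
MIN_SAMPLES_PER_T = 10
GAMMA_GRID = np.round(np.arange(1.0, 3.0 + 1e-9, 0.01), 2)
N_COLLAPSE_POINTS = 100  # interior t/T grid points


@dataclass
class MeanSizeFit:
    exponent: float      # 1/(sigma nu z) from the log-log regression
    stderr: float
    r_squared: float
    durations: np.ndarray
    mean_sizes: np.ndarray


@dataclass
class CollapseResult:
    gamma: float         # argmin of the collapse error over the gamma grid
    collapse_error: float
    gamma_grid: np.ndarray
    error_curve: np.ndarray
    durations: np.ndarray
    scaled_profiles: np.ndarray = field(repr=False)  # rows: durations, at gamma
    u_grid: np.ndarray = field(repr=False)

    def save_csv(self, path) -> None:
        pd.DataFrame({"gamma": self.gamma_grid,
                      "collapse_error": self.error_curve}).to_csv(path, index=False)


@dataclass
class CracklingCheck:
    lhs: float           # 1/(sigma nu z) measured from <s>(T) or collapse
    lhs_err: float
    rhs: float           # (tau_t - 1)/(tau - 1)
    rhs_err: float
    difference: float
    difference_err: float


def _qualifying_durations(T: np.ndarray, min_T: float = MIN_DURATION_MS,
                          min_count: int = MIN_SAMPLES_PER_T):
    vals, counts = np.unique(T, return_counts=True)
    keep = (vals > min_T) & (counts >= min_count)
    return vals[keep]


def mean_size_vs_duration(catalog: AvalancheCatalog, size: str = "s_theta",
                          min_T: float = MIN_DURATION_MS,
                          min_count: int = MIN_SAMPLES_PER_T) -> MeanSizeFit:
    """Least-squares slope of log<s> vs log T over qualifying durations."""
    T = catalog.T
    s = getattr(catalog, size)
    durs = _qualifying_durations(T, min_T, min_count)
    if durs.size < 5:
        raise ValueError(f"only {durs.size} qualifying durations (need >= 5)")
    means = np.array([s[T == d].mean() for d in durs])
    res = stats.linregress(np.log10(durs), np.log10(means))
    return MeanSizeFit(exponent=float(res.slope), stderr=float(res.stderr),
                       r_squared=float(res.rvalue ** 2),
                       durations=durs.astype(float), mean_sizes=means)


def _mean_profiles(catalog: AvalancheCatalog, durs: np.ndarray,
                   u: np.ndarray) -> np.ndarray:
    """Per-duration mean profiles interpolated onto the common t/T grid."""
    T = catalog.T
    out = np.empty((durs.size, u.size))
    for r, d in enumerate(durs):
        idx = np.flatnonzero(T == d)
        mean_prof = np.mean([catalog.profiles[i] for i in idx], axis=0)
        tt = (np.arange(int(d)) + 0.5) / d  # bin centres on (0, 1)
        out[r] = np.interp(u, tt, mean_prof)
    return out


def shape_collapse(catalog: AvalancheCatalog, gamma_grid=GAMMA_GRID,
                   n_points: int = N_COLLAPSE_POINTS,
                   min_T: float = MIN_DURATION_MS,
                   min_count: int = MIN_SAMPLES_PER_T) -> CollapseResult:
    """Estimate 1/(sigma nu z) by collapsing mean profiles onto one curve.

    Each qualifying duration's mean profile is interpolated onto a common
    t/T grid and divided by T^{gamma - 1}; the collapse error is the mean
    across-duration variance of the rescaled profiles, averaged over the
    grid and normalized by the squared span of their grand mean.  The
    reported gamma minimizes this error over the grid.
    """
    durs = _qualifying_durations(catalog.T, min_T, min_count)
    if durs.size < 3:
        raise ValueError(f"only {durs.size} qualifying durations (need >= 3)")
    u = (np.arange(n_points) + 0.5) / n_points
    profiles = _mean_profiles(catalog, durs, u)

    gamma_grid = np.asarray(gamma_grid, dtype=float)
    errs = np.empty(gamma_grid.size)
    logT = np.log(durs.astype(float))
    for k, g in enumerate(gamma_grid):
        scaled = profiles * np.exp(-(g - 1.0) * logT)[:, None]
        grand = scaled.mean(axis=0)
        span = float(grand.max() - grand.min())
        if span == 0.0:
            span = float(np.abs(grand).max()) or 1.0
        errs[k] = float(scaled.var(axis=0).mean()) / span ** 2
    best = int(np.argmin(errs))
    g = gamma_grid[best]
    scaled = profiles * np.exp(-(g - 1.0) * logT)[:, None]
    return CollapseResult(gamma=float(g), collapse_error=float(errs[best]),
                          gamma_grid=gamma_grid, error_curve=errs,
                          durations=durs.astype(float),
                          scaled_profiles=scaled, u_grid=u)


def crackling_check(tau: float, tau_t: float, one_over_snz: float,
                    tau_err: float = 0.0, tau_t_err: float = 0.0,
                    one_over_snz_err: float = 0.0) -> CracklingCheck:
    """Compare 1/(sigma nu z) with (tau_t - 1)/(tau - 1), with propagated spread.

    Returns the two sides and their difference; no verdict is attached (a
    model may measurably fail the relation).
    """
    if tau <= 1.0:
        raise ValueError("tau must be > 1 for the crackling relation")
    rhs = (tau_t - 1.0) / (tau - 1.0)
    rhs_err = float(np.hypot(tau_t_err / (tau - 1.0),
                             (tau_t - 1.0) * tau_err / (tau - 1.0) ** 2))
    diff = one_over_snz - rhs
    return CracklingCheck(lhs=one_over_snz, lhs_err=one_over_snz_err,
                          rhs=rhs, rhs_err=rhs_err, difference=diff,
                          difference_err=float(np.hypot(one_over_snz_err, rhs_err)))
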