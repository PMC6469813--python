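"""Sweep orchestration: simulate parameter grids and run the full analysis battery.

One sweep cell is a (r_E, r_I) point; five disorder realizations per cell by
default, each simulated for 2^20 1-ms steps.  Every row of a sweep table is
reproducible from its key (L, ell, r_E, r_I, Gamma, realization): disorder
and dynamics seeds are derived deterministically from the sweep's base seed.
"""

from __future__ import annotations

import logging
import time

import numpy as np
import pandas as pd
from scipy import stats

from . import avalanches as av
from .dfa import dfa as dfa_fn, dfa_band_filtered
from . import powerlaw_fit as plf
from . import scaling_laws as sl
from . import spectral
from . import topology as topo
from .dynamics import SimulationTrace, simulate

log = logging.getLogger("cros")

S_MIN = 10.0  # lower MLE bound for avalanche sizes
T_MIN = 4.0   # lower MLE bound for avalanche durations
DEFAULT_N_STEPS = 2 ** 20
DEFAULT_N_REALIZATIONS = 5


def derive_seed(base_seed: int, *key) -> int:
    """Deterministic 31-bit seed from a base seed and an integer key path."""
    ss = np.random.SeedSequence(entropy=int(base_seed), spawn_key=tuple(int(k) for k in key))
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2 ** 31))


def simulate_cell(L: int, ell: int, r_E: float, r_I: float,
                  disorder_seed: int, dynamics_seed: int,
                  n_steps: int = DEFAULT_N_STEPS) -> SimulationTrace:
    net = topo.build_network(L=L, ell=ell, r_E=r_E, r_I=r_I, seed=disorder_seed)
    return simulate(net, n_steps=n_steps, seed=dynamics_seed)


def _kappa_safe(sample, mu, x_min):
    sample = np.asarray(sample, dtype=float)
    if sample.size == 0:
        return np.nan
    x_max = float(np.quantile(sample, 0.99))
    if x_max <= x_min:
        return np.nan
    try:
        return av.kappa_index(sample, mu=mu, x_min=x_min, x_max=x_max)
    except ValueError:
        return np.nan


def analyze_trace(trace: SimulationTrace, n_neurons: int,
                  gammas=(0.5,), compute_band_dfa: bool = True) -> list[dict]:
    """Full analysis battery on one trace; one output row per Gamma.

    Spectrum, order parameter and DFA exponents are threshold-independent and
    shared across the Gamma rows; avalanche statistics (kappa variants, MLE
    exponents, LLR comparisons, scaling fits) are computed per threshold.
    """
    A = trace.A
    base = dict(trace.params)
    base["dyn_seed"] = trace.seed
    base["mean_A"] = float(A.mean())
    base["firing_rate"] = float(A.mean()) / n_neurons  # per neuron per step

    spec = spectral.analyze_spectrum(A, n_neurons, trace.dt)
    base["phi"] = spec.phi
    base["f_peak"] = spec.f_peak

    base["alpha_raw"] = dfa_fn(A, dt_ms=trace.dt).alpha
    if compute_band_dfa:
        base["alpha"] = dfa_band_filtered(A, dt_ms=trace.dt).alpha
    else:
        base["alpha"] = np.nan

    rows = []
    for g in gammas:
        row = dict(base)
        row["Gamma"] = g
        theta = av.compute_threshold(A, g)
        cat = av.extract_avalanches(A, theta, gamma=g)
        row["theta"] = theta
        row["n_events"] = len(cat)
        for name, s in (("g", cat.s_g), ("theta", cat.s_theta)):
            for cls, ex in av.DP_EXPONENTS.items():
                row[f"kappa_{name}_{cls}"] = _kappa_safe(s, ex["tau"], S_MIN)
        for cls, ex in av.DP_EXPONENTS.items():
            row[f"kappa_T_{cls}"] = _kappa_safe(cat.T, ex["tau_t"], T_MIN)

        for label, sample, x_min in (("tau", cat.s_theta, S_MIN),
                                     ("tau_t", cat.T, T_MIN)):
            try:
                fit = plf.fit_truncated_powerlaw(sample, x_min)
                row[label] = fit.mu
                row[f"{label}_x0"] = fit.x0
                for alt, (R, p) in fit.comparisons.items():
                    row[f"{label}_llr_{alt}"] = R
                    row[f"{label}_llr_{alt}_p"] = p
                if label == "tau":
                    row["truncated_wins"] = fit.favors_truncated()
            except ValueError:
                row[label] = np.nan
                row[f"{label}_x0"] = np.nan
                if label == "tau":
                    row["truncated_wins"] = False

        try:
            msf = sl.mean_size_vs_duration(cat)
            row["snz_fit"] = msf.exponent
            row["snz_fit_err"] = msf.stderr
            row["snz_fit_r2"] = msf.r_squared
        except ValueError:
            row["snz_fit"] = row["snz_fit_err"] = row["snz_fit_r2"] = np.nan
        try:
            col = sl.shape_collapse(cat)
            row["snz_collapse"] = col.gamma
            row["collapse_error"] = col.collapse_error
        except ValueError:
            row["snz_collapse"] = row["collapse_error"] = np.nan
        rows.append(row)
    return rows


def run_sweep(grid, L: int = 50, ell: int = 7, gamma_list=(0.5,),
              n_realizations: int = DEFAULT_N_REALIZATIONS,
              n_steps: int = DEFAULT_N_STEPS, base_seed: int = 0,
              compute_band_dfa: bool = True) -> pd.DataFrame:
    """Simulate + analyze every (r_E, r_I) cell of the grid.

    Individual cell failures are logged and skipped; the sweep continues.
    """
    rows = []
    for ci, (r_E, r_I) in enumerate(grid):
        for k in range(n_realizations):
            t0 = time.perf_counter()
            dis_seed = derive_seed(base_seed, ci, k, 0)
            dyn_seed = derive_seed(base_seed, ci, k, 1)
            try:
                trace = simulate_cell(L, ell, r_E, r_I, dis_seed, dyn_seed,
                                      n_steps)
                cell_rows = analyze_trace(trace, L * L, gamma_list,
                                          compute_band_dfa)
            except Exception:
                log.exception("cell (r_E=%s, r_I=%s, realization=%d) failed",
                              r_E, r_I, k)
                continue
            for row in cell_rows:
                row["realization"] = k
                rows.append(row)
            log.info("cell (r_E=%s, r_I=%s) realization %d done in %.1f s",
                     r_E, r_I, k, time.perf_counter() - t0)
    return pd.DataFrame(rows)


def transition_scan(sweep: pd.DataFrame) -> dict:
    """Exponent curves, (tau, tau_t) spread and the (alpha, tau) correlation.

    The transition region is the set of (r_E, Gamma) cells where the
    truncated power law wins all three LLR comparisons for a majority of
    realizations.  Returns per-Gamma mean/std curves, a linear fit of the
    per-run (tau, tau_t) scatter inside the region, and the per-run Pearson
    correlation between the band-filtered DFA exponent and tau.
    """
    if sweep.empty:
        return {"curves": pd.DataFrame(), "transition_cells": pd.DataFrame(),
                "tau_tau_t_fit": None, "alpha_tau_pearson": None}
    g = sweep.groupby(["Gamma", "r_E"])
    curves = g.agg(
        tau_mean=("tau", "mean"), tau_std=("tau", "std"),
        tau_t_mean=("tau_t", "mean"), tau_t_std=("tau_t", "std"),
        phi_mean=("phi", "mean"), phi_std=("phi", "std"),
        alpha_raw_mean=("alpha_raw", "mean"),
        alpha_mean=("alpha", "mean"),
        firing_rate_mean=("firing_rate", "mean"),
        win_frac=("truncated_wins", "mean"),
    ).reset_index()
    curves["in_transition"] = curves["win_frac"] > 0.5

    members = curves.loc[curves["in_transition"], ["Gamma", "r_E"]]
    in_region = sweep.merge(members, on=["Gamma", "r_E"])
    result = {"curves": curves, "transition_cells": members}

    ok = in_region.dropna(subset=["tau", "tau_t"])
    if len(ok) >= 3 and ok["tau"].nunique() > 1:
        fit = stats.linregress(ok["tau"], ok["tau_t"])
        result["tau_tau_t_fit"] = {"slope": float(fit.slope),
                                   "intercept": float(fit.intercept),
                                   "r": float(fit.rvalue), "n": len(ok)}
    else:
        result["tau_tau_t_fit"] = None

    ok2 = in_region.dropna(subset=["alpha", "tau"])
    if len(ok2) >= 3 and ok2["alpha"].nunique() > 1 and ok2["tau"].nunique() > 1:
        r, p = stats.pearsonr(ok2["alpha"], ok2["tau"])
        result["alpha_tau_pearson"] = {"r": float(r), "p": float(p), "n": len(ok2)}
    else:
        result["alpha_tau_pearson"] = None
    return result


def crackling_table(sweep: pd.DataFrame) -> pd.DataFrame:
    """Per (Gamma, r_E): LHS (snz fit) vs RHS ((tau_t-1)/(tau-1)) with spreads."""
    rows = []
    for (gamma, r_E), grp in sweep.groupby(["Gamma", "r_E"]):
        ok = grp.dropna(subset=["tau", "tau_t", "snz_fit"])
        if ok.empty:
            continue
        tau, tau_t = ok["tau"].mean(), ok["tau_t"].mean()
        if tau <= 1.0:
            continue
        chk = sl.crackling_check(
            tau, tau_t, ok["snz_fit"].mean(),
            tau_err=float(np.nan_to_num(ok["tau"].std())),
            tau_t_err=float(np.nan_to_num(ok["tau_t"].std())),
            one_over_snz_err=float(np.nan_to_num(ok["snz_fit"].std())),
        )
        rows.append({"Gamma": gamma, "r_E": r_E, "lhs": chk.lhs,
                     "lhs_err": chk.lhs_err, "rhs": chk.rhs,
                     "rhs_err": chk.rhs_err, "difference": chk.difference})
    return pd.DataFrame(rows)
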