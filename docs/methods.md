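# Methods

## The model

The network is an `L × L` square lattice of stochastic binary neurons with
open boundaries: 75% excitatory, 25% inhibitory, assigned by a seeded
permutation of the sites. Each neuron projects only inside the `ℓ × ℓ`
square centred on it (Chebyshev neighbourhood, self excluded; `ℓ = 7`, so an
interior neuron has 48 possible targets). Connection targets are drawn
favouring short Euclidean distance `r` with relative weight `e^(−r/a₀)`,
`a₀ = 1` lattice unit. The two control parameters are the connectivity
fractions `r_E` and `r_I`: the fraction of its in-range neighbourhood an
excitatory / inhibitory neuron connects to.

Per 1-ms step, with `S(t)` the previous step's binary spike vector and
`W` the signed weight matrix (`W_EE = 0.02`, `W_EI = 0.011`,
`W_IE = W_II = −2`):

    I(t+dt)   = (I(t) + Wᵀ S(t)) (1 − dt/τ_I),              τ_I = 9 ms
    R_S(t+dt) = (R_S(t) + I(t)) (1 − dt/τ_P) + P₀ dt/τ_P,   τ_P = 9 / 12 ms (E/I)
    P_spike   = clip(R_S(t+dt), 0, 1)

Spikes are drawn independently per neuron; a spiking neuron's `R_S` is reset
to −2 (excitatory) or −20 (inhibitory). `P₀ = 10⁻⁶` for excitatory neurons
only — a weak Poisson drive that removes the absorbing state. The population
activity `A(t) = Σᵢ Sᵢ(t)` is the series every analysis consumes. Runs are
2²⁰ steps (≈ 17.5 min of model time) from a zeroed initial state; no burn-in
is discarded by default (an option exists). The isolated-neuron fixed point
is `R_S* = P₀` exactly, and an input-free current decays by exactly 8/9 per
step — both are used as exact dynamical test anchors.

### Design choices in the model

* **Rate-update current.** The rate equation consumes the *previous* step's
  current `I(t)`, the simultaneous-update reading of the update rules
  (both right-hand sides at time `t`). `current_feed="post"` switches to the
  freshly decayed current; at L = 50 the difference in every statistic we
  track is within realization-to-realization spread.
* **Connectivity sampling.** Default `degree_model="fixed"`: each neuron
  connects to `k = frac × N_local` targets (stochastically rounded, so any
  real-valued fraction is resolved) drawn without replacement with weights
  `e^(−r)` (Gumbel top-k). The alternative `degree_model="bernoulli"`
  connects each in-range target independently with
  `p(r) = min(1, C e^(−r))`, `C` normalizing either the mean per-target
  probability to the fraction (`normalization="mean"`, one compensation pass
  redistributes probability mass lost to the `min(1, ·)` cap) or the summed
  probability (`normalization="sum"`; expected out-degree below one — the
  network never oscillates, kept only for comparison). The fixed-degree rule
  was adopted as default because, with all dynamical parameters as stated
  above, it places the oscillation onset at `r_E ≈ 0.12–0.14` for
  `r_I = 0.60`, `L = 50` — where the phenomenology of this model is known to
  sit — whereas per-edge Bernoulli sampling with cap compensation shifts the
  onset to `r_E ≈ 0.16–0.20`. The shift traces to the strongly capped
  inhibitory probabilities (at `r_I = 0.6` the uncapped `C e^(−r)` exceeds 1
  for all near neighbours): redistributing the capped mass raises realized
  inhibition by ≈ 20% relative to sampling rules that leave it where the cap
  put it.
* **Θ(0) = 0**: a neuron with `R_S = 0` never spikes; fixed for determinism.
* The simulation kernel flushes currents below 10⁻³⁰ to zero (they are
  dynamically irrelevant long before that, and denormal arithmetic is slow)
  and uses an inline xorshift128+ stream seeded via splitmix64, one uniform
  draw per neuron with spiking potential in fixed neuron order, making every
  trace bit-reproducible from `(disorder seed, dynamics seed)`.

## Avalanches and the κ index

The threshold is `θ = Γ × median(A)` over the full trace, zeros included,
per realization (`Γ = 0.5` by default). An avalanche is a maximal run of
steps with `A(t) > θ` (strict, so integer-valued thresholds resolve ties
deterministically); its duration `T` is the run length in ms, and its size is
either `s_g` (total spikes) or `s_θ = s_g − Tθ` (area above the threshold;
the more robust definition, used by default in scaling analyses). Events
touching either end of the trace are censored and counted. In a deeply
subcritical run the median is zero; `θ = 0` is returned with a warning and
events become runs of nonzero activity.

`κ` compares the empirical CDF of a sample restricted to `[x_min, x_max]`
with the bounded power-law CDF at `b = 10` log-spaced points:
`κ = 1 + mean(F_th − F_obs)`. κ ≃ 1 indicates scale invariance; short-scale
(subcritical) samples give κ < 1 and bump-dominated (supercritical) samples
κ > 1. The sign statement for subcritical samples presumes the sample's
scale is well inside the window; an exponential whose scale spans the window
can land slightly above 1. For the heat-map variants the window is
`x_min = 10` (sizes) / 4 (durations) and `x_max` = the 99th percentile of the
sample, both configurable; reference exponents are the directed-percolation
pairs (mean-field τ = 3/2, τ_t = 2; two-dimensional τ = 1.268, τ_t = 1.450).

## Truncated power-law MLE and model comparison

Sizes and durations are fitted with the continuous density
`p(x) ∝ x^(−μ) e^(−x/x₀)` on `x ≥ x_min`, normalized with the generalized
upper incomplete gamma function `Γ(1−μ, x_min/x₀)` (computed by upward
recurrence for non-positive arguments). `x_min` is fixed a priori — 10 for
sizes, 4 for durations — never scanned. Optimization is Nelder-Mead on
`(μ, log x₀)` from three starts, parameter tolerance 10⁻⁶; `μ` is
constrained to (1, 8] because the exponents of interest exceed 1 and an
unconstrained family nests the exponential (μ → 0), which would void the
likelihood-ratio comparison against it. A fit escaping to `x₀` far beyond
the sample maximum is reported as effectively a pure power law. Durations
are integers; the continuous likelihood is nonetheless the default for
comparability across size definitions (a discrete variant sums the
normalization over integer support behind a flag).

Model comparison uses the normalized (Vuong) loglikelihood-ratio statistic
against MLE-fitted pure power-law, lognormal (left-truncated) and
exponential alternatives: `R > 0` favours the truncated power law and the
two-sided p-value comes from `R / (σ √n)`. The *transition region* is
defined operationally as the set of parameter cells where the truncated
power law wins all three comparisons for a majority of disorder
realizations.

## Spectrum and order parameter

The periodogram of `A(t)` is normalized by `L²` and the total time, then
block-averaged over non-overlapping windows of 500 raw bins (≈ 0.45 Hz per
smoothed point at 2²⁰ ms). The oscillation order parameter φ is an area
ratio: `f_p` is the smoothed-spectrum argmax in a 4–45 Hz search band (the
upper bound is our choice; only the 4–18 Hz bound of the `f_−` search is
prescribed), `f_−` the nearest local minimum below it within 4–18 Hz
(first sign change of the discrete derivative walking down-frequency, ties
toward higher frequency), `f_+ = f_p + (f_p − f_−)` (clipped at the spectral
edge with a warning). A chord joins the spectrum at `f_−` and `f_+`;
`φ = φ_p/(φ_p + φ_u)` with `φ_p` the area where the spectrum exceeds the
chord and `φ_u` the area under the chord (trapezoidal quadrature). To make
"φ > 0 only when a peak is detectable" operational, the argmax must exceed
the chord by at least twice the local standard error of the block means,
else φ = 0. φ is scale-invariant by construction.

## DFA

DFA-1: the profile is the cumulative sum of the mean-subtracted series; for
each window size (20 log-spaced sizes per decade, 100 ms – 20 s,
non-overlapping windows, trailing partial window dropped) a linear trend is
removed per window and `F(n)` is the RMS of pooled residuals. The exponent α
is the least-squares slope of `log₁₀ F` vs `log₁₀ n` restricted to
4–14 s. Calibration against the spectral relation `v = 2α − 1` on
synthesized `1/f^v` noise of length 2¹⁸ recovers α = 0.5 / 1.0 / 1.5 for
v = 0 / 1 / 2 within ±0.05 (10-seed averages).

The band-filtered variant applies a 5th-order Butterworth band-pass
(8–16 Hz, zero-phase forward–backward application to keep the envelope
undistorted — the original filter direction is not documented, so the
phase-neutral choice was made), takes the amplitude envelope as the modulus
of the analytic signal, trims 1 s from each end, and runs the same DFA.

## Size-duration scaling and shape collapse

Only durations `T > 10` ms (strict) with ≥ 10 events each enter. The
`⟨s⟩(T)` exponent `1/(σνz)` is the least-squares slope of `log⟨s_θ⟩` vs
`log T` (≥ 5 qualifying durations). For shape collapse, per-duration mean
profiles are interpolated onto 100 interior `t/T` points and divided by
`T^(γ−1)`; the collapse error is the across-duration variance of the
rescaled profiles averaged over the grid and normalized by the squared span
of their grand mean, minimized over γ ∈ [1, 3] in steps of 0.01 (the
objective of the published collapse tooling is not documented; this
normalized-variance form recovers construction exponents of synthetic
families to grid resolution, which is how it is validated). The crackling
consistency check compares `1/(σνz)` with `(τ_t − 1)/(τ − 1)` and
propagates realization spreads; no verdict is attached — in this model the
left-hand side stays *below* the right-hand side across the transition
region, and the package reproduces that failure rather than fixing it.

## Synthetic data

The generators exist so every analysis stage is testable without the
simulator, and their ground truth defines the calibration suite: bounded
power laws by inverse-CDF sampling; exponentially truncated power laws by
rejection (Pareto proposal with acceptance `e^(−(x−x_min)/x₀)` for μ > 1,
shifted-exponential proposal for μ ≤ 1; aborts below 10⁻³ acceptance);
colored noise by spectral synthesis (Gaussian coefficients shaped by
`f^(−v/2)`, random phases, standardized output); sinusoid-plus-noise
signals; and avalanche-profile families `s(t,T) = T^(γ₀−1) · 4u(1−u)`,
`u = (t+0.5)/T`, with optional multiplicative noise floored at 0.05 to keep
profiles positive. All generators take explicit seeds; none touch global
random state. They emulate the *statistical* structures the analyses assume
— they have none of the temporal inhomogeneity, censoring or
median-threshold coupling of real simulation traces, so passing calibration
shows the estimators are unbiased on clean input, not that model output is
clean.

## Problem sizes and determinism

The desk profile is `L = 50`, 2²⁰ steps, five disorder realizations per
parameter cell — a single run takes tens of seconds in the compiled kernel
and the full three-regime DFA comparison about ten minutes on one core.
`L = 300` matches the large-lattice results (raw DFA exponent ≈ 1.16 at the
onset; the Γ = 0.85 exponent pair near mean-field directed percolation; the
per-run (α, τ) correlation r ≈ 0.9) but costs hours per run; the exact sweep
configurations are in `analysis/configs/`, marked cluster-scale. Every
table row records the seeds that produced it, and sweep seeds are derived
from a single base seed via `SeedSequence` spawn keys (kept below 2³¹).

## Known limitations

* At the onset point (`r_E = 0.12`, `L = 50`) the five-realization mean raw
  DFA exponent comes out ≈ 0.84 ± 0.07 — below the ≈ 1.09 reference value by
  more than the realization spread — and in the strongly oscillatory regime
  (`r_E = 0.24`) it lands at 0.48–0.53 across seed families, at the edge of
  the ≈ 0.60 reference. The subcritical value and the entire
  avalanche-scaling structure of the transition reproduce quantitatively.
  The critical point of a single disorder realization wanders by ~0.01–0.02
  in `r_E` (individual onset realizations reach α ≈ 0.93–1.05), so
  fixed-`r_E` averages near the onset mix sub- and supercritical
  realizations; exponents there are sensitive to connectivity-sampling
  details that the published description leaves open (see the connectivity
  paragraph above).
* Avalanche definitions via a global threshold on `A(t)` differ from the
  per-channel binarization + time-binning used on experimental recordings;
  no such variant is implemented.
* No long-range/small-world connections, synaptic delays, plasticity or
  refractory mechanisms; no multifractal or overlapping-window DFA.
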