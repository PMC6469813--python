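# Cluster-scale profile: the (alpha, tau) spread and correlation at L = 300.
# Single-run band-filtered DFA exponents vs avalanche size exponents inside
# the transition region, at Gamma = 0.85 (the threshold at which the exponent
# pair sits near the mean-field directed-percolation values and the per-run
# (alpha, tau) Pearson correlation reaches r ~ 0.9).
#
#   cros sweep --config analysis/configs/L300_alpha_tau_correlation.yaml -o sweep_corr.csv
#   cros scan sweep_corr.csv -o scan_corr      # summary JSON holds the Pearson r
lattice:
  L: 300
  ell: 7
dynamics:
  n_steps: 1048576
sweep:
  grid:
    - [0.105, 0.60]
    - [0.110, 0.60]
    - [0.115, 0.60]
    - [0.120, 0.60]
    - [0.125, 0.60]
    - [0.130, 0.60]
  gamma_list: [0.85]
  n_realizations: 5
seeds:
  base: 2
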