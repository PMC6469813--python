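# Cluster-scale profile: L = 300 transition scan (five realizations per cell).
# At this size a single 2^20-step run takes hours on one core; the sweep below
# reproduces the large-lattice results (alpha_raw ~ 1.16 at the onset point
# r_E = 0.12, r_I = 0.60, and the Gamma = 0.85 exponent pair near the
# mean-field directed-percolation values).
#
#   cros sweep --config analysis/configs/L300_transition.yaml -o sweep_L300.csv
#   cros scan sweep_L300.csv -o scan_L300
lattice:
  L: 300
  ell: 7
dynamics:
  n_steps: 1048576   # 2^20 steps of 1 ms
sweep:
  grid:
    - [0.04, 0.60]
    - [0.08, 0.60]
    - [0.10, 0.60]
    - [0.11, 0.60]
    - [0.12, 0.60]
    - [0.13, 0.60]
    - [0.14, 0.60]
    - [0.16, 0.60]
    - [0.24, 0.60]
  gamma_list: [0.5, 0.85]
  n_realizations: 5
seeds:
  base: 1
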