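{
  "comment": "Calibrated constants of the crossing-particle model for an N=100 bead semiflexible chain (lp = 5 sigma). Energies in kBT, lengths in sigma, forces in kBT/sigma, times in tau_LJ.",
  "knots": {
    "unknot": {"nk": 0, "l_k0": 0.0},
    "3_1": {"nk": 3, "l_k0": 13.7},
    "5_1": {"nk": 5, "l_k0": 20.8},
    "7_1": {"nk": 7, "l_k0": 29.12}
  },
  "eps_b0": 0.74,
  "l_tilde_over_l_k0": 1.85,
  "b": 0.6,
  "a_kT": 0.0,
  "delta": 0.65,
  "D0": 0.31,
  "zeta0": 0.0016,
  "tensions": [0.1, 0.17, 0.32, 0.56, 1.0, 1.7, 3.2, 5.6],
  "A_c": {
    "3_1": [0.02, 0.05, 0.10, 0.18, 0.20, 0.24, 0.32, 1.58],
    "5_1": [0.00, 0.02, 0.04, 0.09, 0.14, 0.11, 0.14, 1.2]
  }
}
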