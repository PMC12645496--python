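{
  "a1": 3.3498,
  "a2": 1.44,
  "d2": 0.2,
  "d3": 0.1732,
  "ktr": 8.4540,
  "kappa": 0.054,
  "delta": 2.48,
  "alpha": 1.12,
  "omega": 40.3,
  "kp": 9.23,
  "kQ": 0.064,
  "ks": 0.064,
  "psi_half": 0.00011,
  "kcp": 4.6754,
  "eta_half": 0.51,
  "C_half": 0.739,
  "gamma_P": 0.35,
  "Cprod_star": 3.9863e-4,
  "Cprod_max": 1.429,
  "k_elim": 0.16139,
  "j": 6,
  "tau": 0.7097,
  "T_star": 0.08090,
  "ka": 2.96,
  "V_PAC": 3390.45,
  "kep": 61.97,
  "k12P": 183.49,
  "k21P": 1.18,
  "alpha_T": 7.5837e-6,
  "kel": 45.0,
  "kon": 0.026,
  "R0": 457.49,
  "k12": 11.38,
  "k21": 0.0043,
  "V": 100.04,
  "kint": 22.15,
  "Emax_PAC": 0.8764,
  "Emax_TRAIL": 0.438,
  "gamma_PAC": 1.35,
  "gamma_TRAIL": 0.874,
  "Psi": 0.8,
  "EC50_PAC": 1176.7,
  "EC50_TRAIL": 5.0,
  "cells_per_unit": 1e10,
  "cells_per_cc": 1e9
}
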