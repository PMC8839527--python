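{
  "name": "southern-baltic-coastal",
  "description": "Per-band constants of the five-parameter remote-sensing reflectance model for southern-Baltic coastal waters. bbp: b_bp = C*SPM^B*exp(D*SPM_inorg/SPM); aph: a_ph = G*Chl^F*exp(H*SumC/Chl); ad: a_d = K*SPM^J*exp(L*SPM_inorg/SPM); acdom: a_CDOM = 10^(-M*u^2 + N*u - P), u = log10(a_CDOM(400)). a_w, b_bw: pure-seawater absorption/backscattering [1/m]; f_over_q [1/sr].",
  "bands": {
    "420": {
      "bbp": {"C": 0.009, "B": 0.911, "D": 0.337},
      "aph": {"G": 0.041, "F": 0.827, "H": 0.493},
      "ad": {"K": 0.057, "J": 0.807, "L": 0.750},
      "acdom": {"M": 0.077, "N": 1.006, "P": 0.132},
      "a_w": 0.0045,
      "b_bw": 0.0023,
      "f_over_q": 0.07
    },
    "488": {
      "bbp": {"C": 0.006, "B": 0.891, "D": 0.827},
      "aph": {"G": 0.022, "F": 0.820, "H": 0.824},
      "ad": {"K": 0.035, "J": 0.762, "L": 0.903},
      "acdom": {"M": 0.624, "N": 1.077, "P": 0.485},
      "a_w": 0.0147,
      "b_bw": 0.0012,
      "f_over_q": 0.10
    },
    "555": {
      "bbp": {"C": 0.005, "B": 0.935, "D": 0.977},
      "aph": {"G": 0.011, "F": 0.815, "H": 0.257},
      "ad": {"K": 0.022, "J": 0.646, "L": 1.157},
      "acdom": {"M": 1.037, "N": 1.072, "P": 0.689},
      "a_w": 0.0596,
      "b_bw": 0.0007,
      "f_over_q": 0.12
    },
    "620": {
      "bbp": {"C": 0.004, "B": 0.881, "D": 1.230},
      "aph": {"G": 0.007, "F": 0.926, "H": 0.261},
      "ad": {"K": 0.015, "J": 0.592, "L": 1.542},
      "acdom": {"M": 1.488, "N": 1.136, "P": 0.794},
      "a_w": 0.2755,
      "b_bw": 0.0004,
      "f_over_q": 0.13
    }
  }
}
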