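{
  "version": 1,
  "dynocc_single": {
    "psi1": 0.6,
    "phi": 0.7,
    "gamma": 0.15,
    "p_high": 0.73,
    "p_low": 0.27
  },
  "occ_multisp": {
    "mu_occ": [0.0, 0.5, -0.3, 0.2, 0.0],
    "sd_occ": [1.0, 0.5, 0.5, 0.5, 0.5],
    "mu_det": [0.0, 0.3, -0.2, 0.1, 0.0],
    "sd_det": [0.7, 0.3, 0.3, 0.3, 0.3]
  },
  "dynocc_multisp": {
    "psi1_coef": [-0.5, 0.4, -0.3, 0.2, 0.1, -0.1],
    "mu_phi": [0.8, 0.4, -0.3, 0.2],
    "sd_phi": [0.7, 0.3, 0.3, 0.3],
    "mu_gamma": [-1.5, 0.3, -0.2, 0.2],
    "sd_gamma": [0.7, 0.3, 0.3, 0.3],
    "mu_p": [0.0, 0.3, -0.2],
    "sd_p": [0.7, 0.3, 0.3],
    "phi_sh": [0.2, -0.2, 0.1],
    "gamma_sh": [0.2, -0.1, 0.1],
    "p_sh": [0.2, -0.2, 0.1, -0.1]
  },
  "nmix_zip": {
    "theta": 0.85,
    "lam_coef": [1.0, 0.6, -0.4, 0.3, -0.2, 0.2, -0.1, 0.1, 0.0, 0.0],
    "det_coef": [0.2, 0.3, -0.3, 0.2, -0.2, 0.1, -0.1, 0.1, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0],
    "sd_lam_site": 0.3,
    "sd_p_site": 0.3,
    "sd_p_survey": 0.2
  }
}
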