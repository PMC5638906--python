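{
  "_units": {
    "tau_E": "s", "tau_I": "s",
    "tau_rE": "s", "tau_rI": "s",
    "tau_fE": "s", "tau_fI": "s",
    "U_E": "dimensionless", "U_I": "dimensionless",
    "J_E": "dimensionless", "J_I": "dimensionless",
    "theta_E": "Hz", "theta_I": "Hz"
  },
  "_notes": "Mean parameter values of the developing E-I rate network at four postnatal days. tau_E/tau_I approximate the decay time constants of postsynaptic responses; tau_r*/tau_f* are the recovery (depression) and facilitation time constants of the presynaptic population's outgoing synapses; U_* is the release probability; J_* the absolute synaptic efficacy; theta_* the population activity threshold. The linear gain G above threshold is fixed at 1 for both populations.",
  "P3": {
    "tau_E": 0.045, "tau_I": 0.0225,
    "tau_rE": 5.5, "tau_rI": 5.0,
    "tau_fE": 0.8, "tau_fI": 0.8,
    "U_E": 0.9, "U_I": 0.9,
    "J_E": 3.7, "J_I": 0.1,
    "theta_E": 0.3, "theta_I": 0.3
  },
  "P10": {
    "tau_E": 0.03, "tau_I": 0.015,
    "tau_rE": 3.0, "tau_rI": 2.5,
    "tau_fE": 0.4, "tau_fI": 0.4,
    "U_E": 0.8, "U_I": 0.8,
    "J_E": 7.0, "J_I": 3.0,
    "theta_E": 0.47, "theta_I": 0.5
  },
  "P14": {
    "tau_E": 0.02, "tau_I": 0.01,
    "tau_rE": 0.7, "tau_rI": 0.4,
    "tau_fE": 0.1, "tau_fI": 0.1,
    "U_E": 0.65, "U_I": 0.55,
    "J_E": 6.3, "J_I": 4.0,
    "theta_E": 0.7, "theta_I": 1.7
  },
  "P20": {
    "tau_E": 0.01, "tau_I": 0.005,
    "tau_rE": 0.5, "tau_rI": 0.2,
    "tau_fE": 0.05, "tau_fI": 0.05,
    "U_E": 0.55, "U_I": 0.4,
    "J_E": 5.5, "J_I": 4.5,
    "theta_E": 1.0, "theta_I": 2.0
  }
}
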