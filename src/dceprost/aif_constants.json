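{
  "version": "1.0",
  "reference_dose_mmol_per_kg": 0.1,
  "parker": {
    "description": "Population-averaged high-temporal-resolution arterial input function; mixture of two Gaussians plus a sigmoid-modulated exponential washout. Whole-blood concentration domain. Time unit of the published constants: minutes.",
    "domain": "blood",
    "A1": {"value": 0.809, "units": "mmol.min"},
    "A2": {"value": 0.330, "units": "mmol.min"},
    "T1": {"value": 0.17046, "units": "min"},
    "T2": {"value": 0.365, "units": "min"},
    "sigma1": {"value": 0.0563, "units": "min"},
    "sigma2": {"value": 0.132, "units": "min"},
    "alpha": {"value": 1.050, "units": "mmol"},
    "beta": {"value": 0.1685, "units": "1/min"},
    "s": {"value": 38.078, "units": "1/min"},
    "tau": {"value": 0.483, "units": "min"}
  },
  "weinmann": {
    "description": "Low-temporal-resolution biexponential plasma clearance measured in healthy volunteers; Cp(t) = D*(a1*exp(-m1*t) + a2*exp(-m2*t)) with D in mmol per kg body weight. Plasma concentration domain. Time unit of the published constants: minutes.",
    "domain": "plasma",
    "a1": {"value": 3.99, "units": "kg/L"},
    "a2": {"value": 4.78, "units": "kg/L"},
    "m1": {"value": 0.144, "units": "1/min"},
    "m2": {"value": 0.0111, "units": "1/min"}
  }
}
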