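{
  "comment": "Physics constants for internal dosimetry in water. Photon mass attenuation and mass energy-absorption coefficients for liquid water from the NIST XCOM/X-ray attenuation tables (cm^2/g, log-log interpolated between grid points). Tc-99m emission data from standard decay-data compilations (ICRP 107 / MIRD): the 140.5 keV gamma, Tc K x-rays, and the mean conversion/Auger electron energy per decay aggregated into a single non-penetrating entry.",
  "water": {
    "density_g_per_ml": 1.0,
    "energy_keV":  [10.0, 15.0, 20.0, 30.0, 40.0, 50.0, 60.0, 80.0, 100.0, 150.0, 200.0, 300.0],
    "mu_over_rho": [5.329, 1.673, 0.8096, 0.3756, 0.2683, 0.2269, 0.2059, 0.1837, 0.1707, 0.1505, 0.1370, 0.1186],
    "mu_en_over_rho": [4.944, 1.374, 0.5503, 0.1557, 0.06947, 0.04223, 0.03190, 0.02597, 0.02546, 0.02764, 0.02967, 0.03192],
    "buildup_model": "energy-conserving-linear",
    "buildup_comment": "B(mu r) = 1 + a_E mu r with a_E = mu/mu_en(E) - 1 per photon line, so the infinite-medium energy integral of the point kernel equals the emitted photon energy (the standard dose-point-kernel normalization)."
  },
  "nuclides": {
    "Tc-99m": {
      "half_life_h": 6.0067,
      "emissions": [
        {"type": "photon", "energy_keV": 140.511, "yield": 0.885},
        {"type": "photon", "energy_keV": 18.367, "yield": 0.0407},
        {"type": "photon", "energy_keV": 18.251, "yield": 0.0215},
        {"type": "photon", "energy_keV": 20.62, "yield": 0.0142},
        {"type": "electron", "energy_keV": 16.8, "yield": 1.0,
         "comment": "mean conversion + Auger electron energy per decay, treated as locally absorbed"}
      ]
    }
  }
}
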