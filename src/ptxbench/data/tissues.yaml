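# Dielectric and density properties of the torso tissue classes at the two
# supported Larmor frequencies.  Values are representative of the published
# low-GHz tissue-property literature (4-Cole-Cole fits); sigma in S/m, eps_r
# dimensionless, rho in kg/m^3.  Label 0 is background air.
frequencies:
  297200000.0:
    skin:    {label: 1, sigma: 0.64,  eps_r: 49.9, rho: 1109.0}
    fat:     {label: 2, sigma: 0.077, eps_r: 5.6,  rho: 911.0}
    muscle:  {label: 3, sigma: 0.77,  eps_r: 58.2, rho: 1090.0}
    lung:    {label: 4, sigma: 0.48,  eps_r: 23.6, rho: 394.0}
    heart:   {label: 5, sigma: 0.95,  eps_r: 64.0, rho: 1081.0}
  600000000.0:
    skin:    {label: 1, sigma: 0.72,  eps_r: 44.5, rho: 1109.0}
    fat:     {label: 2, sigma: 0.087, eps_r: 5.45, rho: 911.0}
    muscle:  {label: 3, sigma: 0.86,  eps_r: 55.5, rho: 1090.0}
    lung:    {label: 4, sigma: 0.54,  eps_r: 22.5, rho: 394.0}
    heart:   {label: 5, sigma: 1.05,  eps_r: 60.8, rho: 1081.0}
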