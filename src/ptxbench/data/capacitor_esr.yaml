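# Equivalent series resistance (Ohm) of non-magnetic porcelain RF capacitors,
# tabulated by capacitance (pF) and frequency (MHz).  Representative of
# published case-A datasheet curves (ESR falls with capacitance and rises
# roughly with sqrt(frequency)); interpolated log-linearly in C, linearly in f.
capacitance_pf: [0.2, 0.5, 1.0, 2.0, 5.0, 10.0, 33.0, 100.0]
frequency_mhz: [300.0, 600.0]
esr_ohm:
  - [0.60, 0.90]
  - [0.38, 0.56]
  - [0.26, 0.39]
  - [0.18, 0.27]
  - [0.11, 0.17]
  - [0.08, 0.12]
  - [0.05, 0.08]
  - [0.03, 0.05]
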