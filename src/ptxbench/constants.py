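"""Physical constants and port reference conventions used throughout the package."""

import numpy as np

#: Proton gyromagnetic ratio, Hz/T.
GAMMA_HZ_PER_T = 42.577478518e6

#: Vacuum permeability, T*m/A.
MU0 = 4.0e-7 * np.pi

#: Speed of light in vacuum, m/s.
C0 = 299_792_458.0

#: Larmor frequencies of the two supported static field strengths, Hz.
F_7T_HZ = 297.2e6
F_14T_HZ = 600.0e6

#: Port reference impedance, Ohm.
R_REF_OHM = 50.0

#: Port reference voltage for 2 kW forward power into 50 Ohm (sqrt(2000*50)), V.
#: With this convention an excitation weight of unit amplitude corresponds to
#: 2 kW forward power at the port, so equal-amplitude drive of 64 channels
#: books exactly 128 kW of total forward power.
U_REF_V = float(np.sqrt(2000.0 * R_REF_OHM))
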