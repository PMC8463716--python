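"""Physical constants and study-wide defaults.

All public interfaces work in bench units — µT for flux density, mm for
length, mA for current — with SI used only inside field kernels.  Reports
switch to mT where the quantity is conventionally printed that way
(screen-extrapolated fields, gradients in mT/mm).
"""

import math

#: Vacuum magnetic permeability, T·m/A.
MU0 = 4.0e-7 * math.pi

#: Relative permeability of the idealized magnet core in the single-loop-of-
#: current (SLC) source model.  Enters the field only as a scalar prefactor
#: (and is therefore degenerate with the loop current; it is never fitted).
MU_R_DEFAULT = 5000.0

#: Sensor zeroing error bound, µT (uncertainty budget component 2).
U_ZERO_UT = 2.0

#: Fractional calibration error of the magnetometer (component 3).
U_CAL_FRACTION = 0.005

#: Uncertainty of the probe height above the screen, mm; midpoint of the
#: evaluated 1.5-1.7 mm range.  Multiplies the local dB/dz (component 4).
DELTA_Z_MM = 1.6

#: Field-gradient threshold (mT/mm) above which inhomogeneous static fields
#: blocked action-potential firing in cultured neurons (Cavopol et al.).
G_THRESHOLD_MT_PER_MM = 0.02

#: Companion minimum field intensity for the same neuronal effect, mT.
B_THRESHOLD_MT = 0.025

#: Skull thickness at the temporal lobe used for the inside-the-skull
#: exposure check, mm (reported average is 3-4 mm; the conservative end).
SKULL_DEPTH_MM = 4.0

#: ICNIRP general-public exposure limit for static magnetic fields, mT.
ICNIRP_PUBLIC_LIMIT_MT = 400.0

#: Geomagnetic field magnitude range, µT.
GMF_RANGE_UT = (25.0, 65.0)

#: A typical mid-latitude geomagnetic background vector, µT.
GMF_TYPICAL_UT = (20.0, 0.0, -45.0)

#: Mapping heights above the phone screen used throughout the study, mm.
Z_LEVELS_MM = (15.0, 20.0, 25.0, 30.0, 55.0)
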