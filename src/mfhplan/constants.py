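"""Physical constants used across the package (SI units)."""

import math

#: vacuum permeability (T·m/A)
MU0 = 4.0e-7 * math.pi

#: Boltzmann constant (J/K)
KB = 1.380649e-23
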