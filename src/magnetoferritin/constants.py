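"""Physical constants used throughout the package (CODATA, SI units).

Values are taken from :mod:`scipy.constants` so they track CODATA; the
module exposes them as plain floats because every computation in this
package is scalar SI arithmetic.
"""

from typing import Final

import scipy.constants as _sc

#: Bohr magneton, A·m²
BOHR_MAGNETON: Final[float] = _sc.physical_constants["Bohr magneton"][0]

#: Boltzmann constant, J/K
BOLTZMANN: Final[float] = _sc.k

#: Vacuum permeability, T·m/A
VACUUM_PERMEABILITY: Final[float] = _sc.mu_0

#: Spin gyromagnetic ratio used for iron, e/m_e, C/kg.
#: The electron g-factor correction (~0.1%) is deliberately omitted: the
#: moment-to-angular-momentum conversion here is the bare charge-to-mass
#: ratio convention.
GYROMAGNETIC_RATIO: Final[float] = _sc.e / _sc.m_e

#: Minimum force regarded as able to mechanically gate an ion channel, N.
#: Literature comparator, ~1 pN.
CHANNEL_GATING_FORCE: Final[float] = 1e-12

#: Typical maximum specific energy loss per AC cycle reported for magnetic
#: nanoparticle hyperthermia, J/kg. Literature comparator, never computed.
HYPERTHERMIA_LOSS_PER_CYCLE: Final[float] = 1.0
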