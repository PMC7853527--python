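"""Physical constants and unit-chain conversion factors.

The two headline factors (electrons-per-O2 rate conversion and the
electron-to-carbon conversion) are stored at the rounded precision at which
they are conventionally quoted, with re-derivation helpers that rebuild them
from first principles so tests can confirm the unit chains.
"""

from __future__ import annotations

AVOGADRO = 6.02214076e23  # mol^-1

#: (NP_O - R_d) in mg O2 m^-3 h^-1  ->  JV_O in umol e- m^-3 s^-1.
#: hours to seconds, mg O2 to umol O2, 4 mol e- per mol O2.
O2_TO_ELECTRON_FACTOR = 3.47e-2

#: J_f / PB_C ratio to mol e- mol C^-1: seconds to hours and umol C to mg C.
PHI_CONVERSION_FACTOR = 43.2

#: Unit bridge for sigma_PSII in the electron-transport product E x sigma' x qP.
#: sigma_PSII is carried in nm^2 and E in umol photons m^-2 s^-1:
#: 1e-6 x N_A (umol photons -> photons), 1e-18 (nm^2 -> m^2), and
#: 1e-3 (e- RCII^-1 s^-1 -> umol e- nmol RCII^-1 s^-1).
SIGMA_UNIT_SCALE = AVOGADRO * 1e-6 * 1e-18 * 1e-3  # = 6.02214076e-4

MOLAR_MASS_O2 = 32.0  # g mol^-1
MOLAR_MASS_C = 12.0  # g mol^-1
ELECTRONS_PER_O2 = 4.0
SECONDS_PER_HOUR = 3600.0


def derive_o2_to_electron_factor() -> float:
    """Rebuild the Eq-style O2-rate conversion from its unit chain.

    mg O2 m^-3 h^-1 -> umol e- m^-3 s^-1:
    (1/3600 h s^-1) x (1000/32 umol mg^-1) x 4 e- per O2.
    """
    return (1.0 / SECONDS_PER_HOUR) * (1000.0 / MOLAR_MASS_O2) * ELECTRONS_PER_O2


def derive_phi_conversion_factor() -> float:
    """Rebuild the electron-requirement conversion from its unit chain.

    umol e- s^-1 per (mg C h^-1): 3600 s h^-1 x 12 mg C mmol^-1 x 1e-3.
    """
    return SECONDS_PER_HOUR * MOLAR_MASS_C * 1e-3
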