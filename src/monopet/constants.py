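"""Physical constants and 511 keV material data.

All lengths are in mm, times in ns, energies in keV, activities in Bq.
Linear attenuation coefficients are single-energy values at the 511 keV
annihilation line, taken from the standard photon cross-section tables
(NIST XCOM mass attenuation coefficients times nominal densities).
``compton_fraction`` is the incoherent share of the total interaction
cross-section at 511 keV; coherent (Rayleigh) scattering is not modelled
and its small cross-section is folded into the transported total.
"""

from __future__ import annotations

from dataclasses import dataclass

#: Speed of light in mm/ns.
C_MM_PER_NS = 299.792458

#: Electron rest energy, keV.
ELECTRON_REST_KEV = 511.0

#: Conversion between Gaussian FWHM and standard deviation.
FWHM_TO_SIGMA = 1.0 / 2.3548200450309493

#: Photon energy below which transport terminates (keV).
ENERGY_CUTOFF_KEV = 50.0


@dataclass(frozen=True)
class Material:
    """Homogeneous material described by its 511 keV interaction data."""

    name: str
    density: float  # g/mL
    mu_511: float  # linear attenuation, 1/mm
    compton_fraction: float  # incoherent share of interactions at 511 keV

    def __post_init__(self) -> None:
        if self.mu_511 < 0:
            raise ValueError("mu_511 must be non-negative")
        if not 0.0 <= self.compton_fraction <= 1.0:
            raise ValueError("compton_fraction must lie in [0, 1]")


# One auditable table; every phantom primitive references these entries.
VACUUM = Material("vacuum", 0.0, 0.0, 0.0)
AIR = Material("air", 1.205e-3, 1.04e-5, 0.999)
WATER = Material("water", 1.0, 9.58e-3, 0.998)
POLYETHYLENE = Material("polyethylene", 0.96, 9.43e-3, 0.999)
GLASS = Material("glass", 2.5, 2.2e-2, 0.96)
LUNG = Material("lung", 0.3, 0.3 * WATER.mu_511, WATER.compton_fraction)
PVC = Material("pvc", 1.4, 1.33e-2, 0.97)

#: LYSO total linear attenuation at 511 keV (1/mm); 1/mu is the ~11.5 mm
#: attenuation length of the scintillator.
MU_LYSO = 0.087

MATERIALS = {
    m.name: m for m in (VACUUM, AIR, WATER, POLYETHYLENE, GLASS, LUNG, PVC)
}
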