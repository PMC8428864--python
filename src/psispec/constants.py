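"""Physical constants and unit conversions used throughout the package.

All distances are in Ångström, charges in units of the elementary charge e,
energies in wavenumbers (cm⁻¹) and dipole moments in e·Å internally, reported
in Debye.  These values are module-level constants and are never mutated.
"""

import math

#: Coulomb interaction prefactor e²/(4πε₀) expressed in cm⁻¹·Å.  Two unit
#: charges 1 Å apart interact with this energy in wavenumbers (vacuum).
COULOMB_CM1_ANGSTROM = 1.16140e5

#: Conversion from e·Å to Debye.
DEBYE_PER_E_ANGSTROM = 4.80320

#: Point-dipole prefactor for dipoles given in Debye and distances in Å:
#: V [cm⁻¹] = DIPOLE_COUPLING_CM1 · κ · μ₁μ₂ / R³.
DIPOLE_COUPLING_CM1 = COULOMB_CM1_ANGSTROM / DEBYE_PER_E_ANGSTROM**2

#: λ[nm] = WAVENUMBER_NM / E[cm⁻¹]  (and vice versa).
WAVENUMBER_NM = 1.0e7

#: For a Gaussian, σ = FWHM · FWHM_TO_SIGMA.
FWHM_TO_SIGMA = 1.0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))


def nm_to_wavenumber(nm):
    """Convert wavelength in nm to wavenumber in cm⁻¹ (elementwise)."""
    return WAVENUMBER_NM / nm


def wavenumber_to_nm(cm1):
    """Convert wavenumber in cm⁻¹ to wavelength in nm (elementwise)."""
    return WAVENUMBER_NM / cm1
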