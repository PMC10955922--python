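"""Line-shape functions for line-by-line absorption synthesis.

The pressure- and Doppler-broadened profile of a rovibrational transition at
~1 atm is modelled as a Voigt profile: the convolution of a Lorentzian
(collisional broadening, HWHM ``gamma``) with a Gaussian (thermal Doppler
broadening). The profile is area-normalised, so multiplying by a line
strength S (cm⁻¹ per molecule cm⁻²) and a molecular column yields absorbance.
"""

from __future__ import annotations

import numpy as np
from scipy import special

__all__ = ["voigt_profile", "doppler_hwhm", "SQRT_2LN2"]

SQRT_2LN2 = float(np.sqrt(2.0 * np.log(2.0)))

# speed of light (m/s), Boltzmann constant (J/K), Avogadro constant (1/mol)
_C_M_S = 2.99792458e8
_KB = 1.380649e-23
_NA = 6.02214076e23


def voigt_profile(
    offsets: np.ndarray, lorentz_hwhm: float, doppler_hwhm: float
) -> np.ndarray:
    """Area-normalised Voigt profile evaluated at ``offsets`` from line centre.

    Parameters
    ----------
    offsets : array-like
        Detuning from the line centre in cm⁻¹.
    lorentz_hwhm : float
        Lorentzian half width at half maximum (cm⁻¹), >= 0.
    doppler_hwhm : float
        Gaussian (Doppler) half width at half maximum (cm⁻¹), >= 0.

    Returns
    -------
    ndarray
        Profile values in 1/cm⁻¹; the integral over the real line is 1.

    Notes
    -----
    Degenerate limits reduce exactly to the pure Lorentzian
    (``doppler_hwhm == 0``) and pure Gaussian (``lorentz_hwhm == 0``).
    Both widths zero is rejected: a delta function has no finite samples.
    """
    if lorentz_hwhm < 0 or doppler_hwhm < 0:
        raise ValueError("line widths must be non-negative")
    if lorentz_hwhm == 0 and doppler_hwhm == 0:
        raise ValueError("at least one of the Voigt widths must be positive")
    x = np.asarray(offsets, dtype=float)
    sigma = doppler_hwhm / SQRT_2LN2  # Gaussian HWHM -> standard deviation
    return special.voigt_profile(x, sigma, lorentz_hwhm)


def doppler_hwhm(center: float, molar_mass_g: float, temperature_K: float) -> float:
    """Thermal Doppler HWHM (cm⁻¹) of a line at ``center`` cm⁻¹.

    ``alpha_D = (nu0 / c) * sqrt(2 ln 2 * k_B T / m)`` with m the molecular
    mass derived from the molar mass in g/mol.
    """
    if molar_mass_g <= 0:
        raise ValueError("molar mass must be positive")
    mass_kg = molar_mass_g * 1e-3 / _NA
    return center / _C_M_S * np.sqrt(2.0 * np.log(2.0) * _KB * temperature_K / mass_kg)
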