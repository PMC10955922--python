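"""Beer–Lambert forward model: per-gas unit absorbance and mixture blending.

The absorbance of a single transition is ``alpha(nu) = S(T) * phi(nu) * N_col``
where ``phi`` is the area-normalised Voigt profile and ``N_col`` the molecular
column (number density x mixing ratio x path length, molecules/cm²). Unit
absorbance is the spectrum at a 1 ppm mixing ratio; because absorbance is
linear in concentration, any mixture spectrum is a weighted sum of unit
spectra plus instrument noise:

    S_b(nu) = sum_i c_i * alpha_i(nu) / 1 ppm + N(nu)

Line-list gases (dense rovibrational absorbers such as CH4 and H2O) are
synthesised line by line; smooth broadband absorbers such as acetone come
from a measured composite cross-section table (absorbance per ppm·m).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .grid import EnvironmentConditions, SpectralGrid
from .lineshapes import doppler_hwhm, voigt_profile

__all__ = [
    "AbsorptionLine",
    "LineList",
    "CrossSectionTable",
    "UnitAbsorbance",
    "unit_absorbance_from_lines",
    "unit_absorbance_from_cross_section",
    "blend",
    "number_density_cm3",
    "SpectralRangeError",
    "T_REF",
]

logger = logging.getLogger(__name__)

T_REF = 296.0  # HITRAN reference temperature (K)

# Boltzmann constant in J/K and one atmosphere in Pa.
_KB = 1.380649e-23
_ATM_PA = 101325.0


class SpectralRangeError(ValueError):
    """A grid extends outside the span of tabulated data."""


@dataclass(frozen=True)
class AbsorptionLine:
    """One rovibrational transition (HITRAN-style parameters).

    center : line position, cm⁻¹ (vacuum).
    intensity : line strength S at 296 K, cm⁻¹/(molecule cm⁻²).
    air_hwhm / self_hwhm : pressure-broadening coefficients, cm⁻¹/atm.
    lower_state_energy : E'' in cm⁻¹ (kept for non-reference-temperature use).
    temp_exponent : exponent of the (296/T) width scaling.
    pressure_shift : air-induced line-centre shift, cm⁻¹/atm.
    """

    center: float
    intensity: float
    air_hwhm: float
    self_hwhm: float = 0.0
    lower_state_energy: float = 0.0
    temp_exponent: float = 0.5
    pressure_shift: float = 0.0

    def __post_init__(self) -> None:
        if self.intensity < 0:
            raise ValueError("line intensity must be >= 0")
        if self.air_hwhm < 0 or self.self_hwhm < 0:
            raise ValueError("broadening coefficients must be >= 0")


@dataclass
class LineList:
    """Ordered collection of lines for one gas.

    ``molar_mass_g`` (g/mol) sets the Doppler width; it is a property of the
    absorber, not of any individual line.
    """

    gas_id: str
    lines: list[AbsorptionLine] = field(default_factory=list)
    molar_mass_g: float = 18.0

    def __post_init__(self) -> None:
        self.lines = sorted(self.lines, key=lambda ln: ln.center)

    def __len__(self) -> int:
        return len(self.lines)


@dataclass
class CrossSectionTable:
    """Composite cross-section: absorbance per (ppm·m) on its own axis.

    Wavenumbers must be strictly ascending. Small negative values (baseline
    artifacts of measured composites) are tolerated here and clipped, with a
    log record, when projected onto a grid.
    """

    wavenumbers: np.ndarray
    values: np.ndarray
    gas_id: str = "xsec"

    def __post_init__(self) -> None:
        self.wavenumbers = np.asarray(self.wavenumbers, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.wavenumbers.ndim != 1 or self.wavenumbers.shape != self.values.shape:
            raise ValueError("wavenumbers and values must be 1-D and equal length")
        if self.wavenumbers.size < 2:
            raise ValueError("cross-section table needs at least two points")
        if not np.all(np.diff(self.wavenumbers) > 0):
            raise ValueError("cross-section wavenumbers must be strictly ascending")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("cross-section values must be finite")
        n_neg = int(np.sum(self.values < 0))
        if n_neg:
            logger.info(
                "cross-section %s: %d negative values (baseline artifacts); "
                "they will be clipped to 0 on grid projection",
                self.gas_id,
                n_neg,
            )


@dataclass
class UnitAbsorbance:
    """Absorbance per 1 ppm of one gas on a shared grid at fixed conditions."""

    gas_id: str
    grid: SpectralGrid
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.grid.n_points,):
            raise ValueError("unit absorbance length must match the grid")
        if np.any(self.values < 0):
            raise ValueError("unit absorbance must be non-negative")


def number_density_cm3(cond: EnvironmentConditions) -> float:
    """Ideal-gas total number density in molecules/cm³."""
    return cond.pressure_atm * _ATM_PA / (_KB * cond.temperature_K) * 1e-6


def unit_absorbance_from_lines(
    linelist: LineList,
    grid: SpectralGrid,
    cond: EnvironmentConditions,
    *,
    wing_cutoff: float = 25.0,
    partition_ratio=None,
) -> UnitAbsorbance:
    """Line-by-line unit absorbance (1 ppm) of a line-list gas.

    Each line is evaluated as a Voigt profile at its pressure-shifted centre
    with Lorentz HWHM ``gamma_air * P * (296/T)**n`` and a thermal Doppler
    HWHM, scaled by the line strength and the 1 ppm molecular column, and
    accumulated only within ``wing_cutoff`` cm⁻¹ of the centre (the usual
    line-by-line wing convention).

    ``partition_ratio`` is a hook ``f(T) -> S(T)/S(296 K)`` for operation away
    from the reference temperature; when ``None`` the reference-temperature
    strength is used unchanged (exact at T = 296 K, the condition this
    package targets).
    """
    nu = grid.wavenumbers
    alpha = np.zeros(grid.n_points)
    if len(linelist) == 0:
        warnings.warn(
            f"line list for {linelist.gas_id!r} is empty; unit absorbance is zero",
            stacklevel=2,
        )
        return UnitAbsorbance(linelist.gas_id, grid, alpha)

    # molecules/cm² per ppm of mixing ratio
    column = number_density_cm3(cond) * 1e-6 * cond.path_length_m * 100.0
    s_scale = 1.0 if partition_ratio is None else float(partition_ratio(cond.temperature_K))

    for line in linelist.lines:
        center = line.center + line.pressure_shift * cond.pressure_atm
        gamma_l = (
            line.air_hwhm
            * cond.pressure_atm
            * (T_REF / cond.temperature_K) ** line.temp_exponent
        )
        gamma_d = doppler_hwhm(center, linelist.molar_mass_g, cond.temperature_K)
        lo = np.searchsorted(nu, center - wing_cutoff, side="left")
        hi = np.searchsorted(nu, center + wing_cutoff, side="right")
        if lo >= hi:
            continue
        phi = voigt_profile(nu[lo:hi] - center, gamma_l, gamma_d)
        alpha[lo:hi] += line.intensity * s_scale * phi * column
    return UnitAbsorbance(linelist.gas_id, grid, alpha)


def unit_absorbance_from_cross_section(
    table: CrossSectionTable,
    grid: SpectralGrid,
    cond: EnvironmentConditions,
    *,
    xsec_log_base: float = 10.0,
) -> UnitAbsorbance:
    """Project a per-(ppm·m) cross-section table onto the grid at 1 ppm.

    The table is linearly interpolated onto the grid (extrapolation is an
    error), multiplied by the path length in metres, and converted from the
    table's logarithm base (composite libraries conventionally publish
    base-10 absorbance) to the natural-log absorbance used internally.
    Negative interpolated values are clipped to zero with a log record.
    """
    if grid.start < table.wavenumbers[0] or grid.end > table.wavenumbers[-1]:
        raise SpectralRangeError(
            f"grid [{grid.start}, {grid.end}] cm-1 exceeds the cross-section "
            f"span [{table.wavenumbers[0]}, {table.wavenumbers[-1]}] cm-1 of "
            f"{table.gas_id!r}; extrapolation is not allowed"
        )
    if xsec_log_base <= 0:
        raise ValueError("xsec_log_base must be positive")
    log_factor = 1.0 if xsec_log_base == np.e else float(np.log(xsec_log_base))
    vals = np.interp(grid.wavenumbers, table.wavenumbers, table.values)
    vals = vals * cond.path_length_m * log_factor
    n_neg = int(np.sum(vals < 0))
    if n_neg:
        logger.info(
            "clipped %d negative cross-section points of %s to zero",
            n_neg,
            table.gas_id,
        )
        vals = np.clip(vals, 0.0, None)
    return UnitAbsorbance(table.gas_id, grid, vals)


def blend(
    units: Sequence[UnitAbsorbance],
    concentrations: Sequence[float],
    noise: np.ndarray | None = None,
) -> np.ndarray:
    """Blend unit spectra into a mixture spectrum: ``sum_i c_i u_i + N``."""
    if len(units) != len(concentrations):
        raise ValueError("one concentration per unit spectrum is required")
    if not units:
        raise ValueError("at least one unit spectrum is required")
    g0 = units[0].grid
    for u in units[1:]:
        if u.grid != g0:
            raise ValueError(
                f"unit spectra must share one grid; {u.gas_id!r} differs"
            )
    conc = np.asarray(concentrations, dtype=float)
    if np.any(conc < 0):
        raise ValueError("concentrations must be non-negative")
    out = np.zeros(g0.n_points)
    for c, u in zip(conc, units):
        out += c * u.values
    if noise is not None:
        noise = np.asarray(noise, dtype=float)
        if noise.shape != out.shape:
            raise ValueError("noise vector must match the grid length")
        out = out + noise
    return out
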