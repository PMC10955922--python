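"""Synthetic line-list and cross-section fixtures.

These generators emulate the two archetypes of absorber found in the
2950–3150 cm⁻¹ window without requiring any database download:

* ``dense-narrow`` — many randomly placed Voigt lines, the character of the
  rovibrational manifolds of CH4 and H2O at 1 atm;
* ``broad-band`` — a smooth multi-hump cross-section, the character of the
  unresolved C-H stretch band of acetone.

``demo_gas_set`` builds the three-gas study fixture (methane-like,
acetone-like, water-like). Its per-ppm magnitudes are calibrated to the
detectability ordering of a 580 m multi-pass cell with a detector noise
floor of sigma = 0.01 absorbance: the methane-like gas is the most
detectable per ppm (peak ~0.15 absorbance/ppm, capped so a 50 ppm sample
stays within the measurable dynamic range of a real detector), the broad
acetone-like band is intermediate (~0.03/ppm, peak SNR ~120 near 44 ppm),
and the water-like background is weakest per ppm (~0.0025/ppm, peak SNR
~190 near 750 ppm) but present at 1000–2000 ppm.
"""

from __future__ import annotations

import numpy as np

from .forward import (
    AbsorptionLine,
    CrossSectionTable,
    LineList,
    UnitAbsorbance,
    unit_absorbance_from_cross_section,
    unit_absorbance_from_lines,
)
from .grid import EnvironmentConditions, SpectralGrid

__all__ = ["synth_linelist", "demo_gas_set", "GAS_NAMES"]

GAS_NAMES = ("methane_like", "acetone_like", "water_like")


def _dense_narrow(
    window: tuple[float, float],
    rng: np.random.Generator,
    *,
    n_lines_range: tuple[int, int],
    intensity_range: tuple[float, float],
    molar_mass_g: float,
    gas_id: str,
) -> LineList:
    lo, hi = window
    n = int(rng.integers(n_lines_range[0], n_lines_range[1] + 1))
    centers = rng.uniform(lo, hi, size=n)
    # log-uniform strengths: a few strong lines on a carpet of weak ones
    log_s = rng.uniform(np.log(intensity_range[0]), np.log(intensity_range[1]), size=n)
    lines = [
        AbsorptionLine(
            center=float(c),
            intensity=float(np.exp(ls)),
            air_hwhm=float(rng.uniform(0.03, 0.08)),
            self_hwhm=float(rng.uniform(0.05, 0.12)),
            lower_state_energy=float(rng.uniform(0.0, 1500.0)),
            temp_exponent=float(rng.uniform(0.4, 0.8)),
            pressure_shift=float(rng.uniform(-0.01, 0.01)),
        )
        for c, ls in zip(centers, log_s)
    ]
    return LineList(gas_id=gas_id, lines=lines, molar_mass_g=molar_mass_g)


def _broad_band(
    window: tuple[float, float],
    rng: np.random.Generator,
    *,
    n_humps_range: tuple[int, int],
    amplitude_range: tuple[float, float],
    width_range: tuple[float, float],
    gas_id: str,
) -> CrossSectionTable:
    # One dominant band plus weaker shoulders: the shape of an unresolved
    # C-H stretch composite, whose ~100 cm-1 FWHM main band is much broader
    # than any narrow interloper feature.
    lo, hi = window
    margin = 0.1 * (hi - lo)
    wn = np.linspace(lo - margin, hi + margin, 2048)
    main_c = rng.uniform(lo + 0.15 * (hi - lo), hi - 0.35 * (hi - lo))
    main_w = rng.uniform(0.6 * width_range[1], width_range[1])
    main_a = rng.uniform(0.6 * amplitude_range[1], amplitude_range[1])
    vals = main_a * np.exp(-0.5 * ((wn - main_c) / main_w) ** 2)
    n = int(rng.integers(n_humps_range[0], n_humps_range[1] + 1))
    for _ in range(n):
        c = rng.uniform(lo, hi)
        w = rng.uniform(*width_range)
        a = main_a * rng.uniform(0.15, 0.6)
        vals += a * np.exp(-0.5 * ((wn - c) / w) ** 2)
    return CrossSectionTable(wavenumbers=wn, values=vals, gas_id=gas_id)


def synth_linelist(
    archetype: str,
    window: tuple[float, float],
    rng: np.random.Generator,
    **kwargs,
) -> LineList | CrossSectionTable:
    """Draw a random absorber of the requested archetype inside ``window``.

    ``dense-narrow`` returns a :class:`LineList` (50–500 lines by default);
    ``broad-band`` returns a smooth :class:`CrossSectionTable`. Deterministic
    for a given generator state.
    """
    if window[1] <= window[0]:
        raise ValueError("window must be (low, high) with high > low")
    if archetype == "dense-narrow":
        opts = dict(
            n_lines_range=(50, 500),
            intensity_range=(1e-23, 1.5e-20),
            molar_mass_g=17.0,
            gas_id="dense-narrow",
        )
        opts.update(kwargs)
        return _dense_narrow(window, rng, **opts)
    if archetype == "broad-band":
        opts = dict(
            n_humps_range=(1, 3),
            amplitude_range=(8e-6, 2.5e-5),
            width_range=(25.0, 45.0),
            gas_id="broad-band",
        )
        opts.update(kwargs)
        return _broad_band(window, rng, **opts)
    raise ValueError(f"unknown archetype {archetype!r}")


def demo_gas_set(
    grid: SpectralGrid,
    cond: EnvironmentConditions,
    seed: int,
) -> list[UnitAbsorbance]:
    """The three-gas synthetic study fixture on ``grid``.

    Returns unit absorbance spectra in the canonical gas order
    (methane-like, acetone-like, water-like). Intensity ranges give
    per-ppm peak absorbances of roughly 0.7, 0.03 and 0.0025 at the
    default conditions — the SNR calibration described in the module
    docstring.
    """
    window = (grid.start, grid.end)
    rng = np.random.default_rng(seed)
    methane = synth_linelist(
        "dense-narrow",
        window,
        rng,
        n_lines_range=(80, 160),
        intensity_range=(1e-22, 1.5e-20),
        molar_mass_g=16.04,
        gas_id="methane_like",
    )
    acetone = synth_linelist(
        "broad-band",
        window,
        rng,
        gas_id="acetone_like",
    )
    water = synth_linelist(
        "dense-narrow",
        window,
        rng,
        n_lines_range=(150, 350),
        intensity_range=(5e-25, 3e-22),
        molar_mass_g=18.02,
        gas_id="water_like",
    )
    return [
        unit_absorbance_from_lines(methane, grid, cond),
        unit_absorbance_from_cross_section(acetone, grid, cond),
        unit_absorbance_from_lines(water, grid, cond),
    ]
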