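"""Shared spectral grid and thermodynamic conditions.

Every stage of the pipeline — forward simulation, dataset generation, the
neural model and the activation maps — operates on one uniform wavenumber
axis. The default axis spans 2950–3150 cm⁻¹ with 3321 points (spacing
200/3320 ≈ 0.0602 cm⁻¹), the window in which methane, acetone and water
vapour absorb with strong mutual overlap.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "SpectralGrid",
    "EnvironmentConditions",
    "build_grid",
    "DEFAULT_GRID",
    "DEFAULT_CONDITIONS",
]


@dataclass(frozen=True)
class SpectralGrid:
    """Uniform, strictly increasing wavenumber axis with inclusive endpoints.

    Parameters
    ----------
    start, end : float
        First and last wavenumber in cm⁻¹, ``end > start``.
    n_points : int
        Number of samples, at least 2. Spacing is ``(end - start) / (n_points - 1)``.
    """

    start: float
    end: float
    n_points: int

    def __post_init__(self) -> None:
        if not np.isfinite(self.start) or not np.isfinite(self.end):
            raise ValueError("grid endpoints must be finite")
        if self.end <= self.start:
            raise ValueError(
                f"grid end ({self.end}) must exceed start ({self.start})"
            )
        if int(self.n_points) != self.n_points or self.n_points < 2:
            raise ValueError("n_points must be an integer >= 2")
        object.__setattr__(self, "n_points", int(self.n_points))

    @property
    def spacing(self) -> float:
        return (self.end - self.start) / (self.n_points - 1)

    @property
    def wavenumbers(self) -> np.ndarray:
        """The axis as a float64 array (computed on demand)."""
        return np.linspace(self.start, self.end, self.n_points)

    def __len__(self) -> int:  # pragma: no cover - convenience
        return self.n_points


@dataclass(frozen=True)
class EnvironmentConditions:
    """Gas-cell conditions entering the Beer–Lambert forward model.

    pressure_atm : total pressure in atmospheres.
    temperature_K : gas temperature in kelvin.
    path_length_m : effective optical path in metres (580 m for the
        multi-pass cell emulated by the defaults).
    """

    pressure_atm: float = 1.0
    temperature_K: float = 296.0
    path_length_m: float = 580.0

    def __post_init__(self) -> None:
        for name in ("pressure_atm", "temperature_K", "path_length_m"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"{name} must be strictly positive, got {v!r}")


def build_grid(start: float, end: float, n_points: int) -> SpectralGrid:
    """Construct a :class:`SpectralGrid`; see the class for the contract."""
    return SpectralGrid(start=float(start), end=float(end), n_points=n_points)


DEFAULT_GRID = SpectralGrid(2950.0, 3150.0, 3321)
DEFAULT_CONDITIONS = EnvironmentConditions()
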