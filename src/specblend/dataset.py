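"""Labelled training-corpus generation.

Seven mixture classes over three gases (M = methane-like trace gas,
A = acetone-like broadband absorber, W = water-like humid background):
MAW, MA, MW, AW, M, A, W. Each sample carries a 6-digit label — three
binary component identifiers (CI) followed by three concentrations in ppm
(CR). Present trace gases draw uniformly from 0–50 ppm; the background gas
draws from 1000–2000 ppm; absent gases are exactly zero.

Four perturbation channels emulate instrument non-idealities and are
applied in a fixed order (the channels do not commute):

1. source power fluctuation — a slowly varying multiplicative gain in
   transmittance, i.e. a smooth additive term ``-ln g(nu)`` in absorbance;
2. unknown absorbers — a few additive Gaussian/Lorentzian bands of random
   position, width and depth (truncated to zero beyond 5 widths);
3. additive white Gaussian detector noise;
4. baseline miscalibration — a low-order polynomial offset in absorbance.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from typing import Sequence

import numpy as np

from .forward import UnitAbsorbance
from .grid import SpectralGrid

__all__ = [
    "MIXTURE_CLASSES",
    "CLASS_MASKS",
    "CONC_RANGES",
    "GroundTruthLabel",
    "PerturbationConfig",
    "SpectrumDataset",
    "DatasetSplit",
    "sample_concentrations",
    "apply_perturbations",
    "generate_dataset",
    "split_holdout",
    "kfold",
    "default_allocation",
]

MIXTURE_CLASSES = ("MAW", "MA", "MW", "AW", "M", "A", "W")

# presence of (methane, acetone, water) per class
CLASS_MASKS = {
    "MAW": (1, 1, 1),
    "MA": (1, 1, 0),
    "MW": (1, 0, 1),
    "AW": (0, 1, 1),
    "M": (1, 0, 0),
    "A": (0, 1, 0),
    "W": (0, 0, 1),
}

# per-gas concentration range (ppm) when the gas is present
CONC_RANGES = ((0.0, 50.0), (0.0, 50.0), (1000.0, 2000.0))


@dataclass(frozen=True)
class GroundTruthLabel:
    """Presence flags plus concentrations; ``ci[i] == 0`` implies ``cr[i] == 0``."""

    ci: tuple[int, int, int]
    cr: tuple[float, float, float]

    def __post_init__(self) -> None:
        for g, c in zip(self.ci, self.cr):
            if g == 0 and c != 0.0:
                raise ValueError("absent gas must have zero concentration")
            if c < 0:
                raise ValueError("concentrations must be non-negative")

    def as_row(self) -> np.ndarray:
        return np.array([*self.ci, *self.cr], dtype=float)


@dataclass
class PerturbationConfig:
    """Magnitudes of the four perturbation channels (all in absorbance
    units unless noted). Defaults bracket a well-behaved 580 m cell:
    noise sigma gives a peak SNR of ~150 for the humid background at
    mid-range concentration; the power gain wanders within +/-2% with at
    most 3 sine cycles across the window."""

    power_fluct_amplitude: float = 0.02  # relative gain excursion
    power_fluct_max_cycles: float = 3.0
    unknown_band_count_range: tuple[int, int] = (0, 3)
    unknown_band_width_range: tuple[float, float] = (1.0, 20.0)  # cm-1 (HWHM)
    unknown_band_depth_range: tuple[float, float] = (0.0, 0.1)
    noise_sigma: float = 0.01
    baseline_poly_order: int = 2
    baseline_amplitude: float = 0.05
    enable_power_fluct: bool = True
    enable_unknown_bands: bool = True
    enable_noise: bool = True
    enable_baseline: bool = True

    def __post_init__(self) -> None:
        if (
            self.power_fluct_amplitude < 0
            or self.noise_sigma < 0
            or self.baseline_amplitude < 0
            or self.unknown_band_depth_range[1] < 0
        ):
            raise ValueError("perturbation amplitudes must be >= 0")
        if self.baseline_poly_order < 0:
            raise ValueError("baseline polynomial order must be >= 0")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class SpectrumDataset:
    """In-memory corpus: spectra ``X`` (m x n), labels ``Y`` (m x 6,
    ordered CI1..CI3, CR1..CR3), class indices into ``MIXTURE_CLASSES``.

    ``X_clean`` optionally keeps the unperturbed blended spectra so a
    trainer can re-draw the stochastic perturbation channels on the fly.
    """

    X: np.ndarray
    Y: np.ndarray
    classes: np.ndarray
    grid: SpectralGrid
    meta: dict = field(default_factory=dict)
    X_clean: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.Y = np.asarray(self.Y, dtype=float)
        if self.X.ndim != 2 or self.X.shape[1] != self.grid.n_points:
            raise ValueError("X must be (m, grid.n_points)")
        if self.Y.shape != (self.X.shape[0], 6):
            raise ValueError("Y must be (m, 6)")
        if not np.all(np.isfinite(self.X)):
            raise ValueError("spectra must be finite")

    def __len__(self) -> int:
        return self.X.shape[0]


@dataclass(frozen=True)
class DatasetSplit:
    """Disjoint index sets covering a dataset."""

    train: np.ndarray
    test: np.ndarray
    validation: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))


def sample_concentrations(
    mixture_class: str,
    rng: np.random.Generator,
    conc_ranges: Sequence[tuple[float, float]] = CONC_RANGES,
) -> GroundTruthLabel:
    """Draw a label for one sample of ``mixture_class``.

    Present gases draw uniformly from their range; absent gases are exactly
    zero with CI = 0. Note the background-gas range applies only when that
    gas is present.
    """
    if mixture_class not in CLASS_MASKS:
        raise ValueError(f"unknown mixture class {mixture_class!r}")
    mask = CLASS_MASKS[mixture_class]
    cr = tuple(
        float(rng.uniform(lo, hi)) if g else 0.0
        for g, (lo, hi) in zip(mask, conc_ranges)
    )
    return GroundTruthLabel(ci=mask, cr=cr)


def _band_profile(offsets: np.ndarray, width: float, shape: str) -> np.ndarray:
    """Unit-peak band profile, truncated to zero beyond 5 widths."""
    if shape == "gaussian":
        prof = np.exp(-np.log(2.0) * (offsets / width) ** 2)
    else:  # lorentzian
        prof = width**2 / (offsets**2 + width**2)
    prof[np.abs(offsets) > 5.0 * width] = 0.0
    return prof


def apply_perturbations(
    spectrum: np.ndarray,
    cfg: PerturbationConfig,
    rng: np.random.Generator,
    wavenumbers: np.ndarray | None = None,
) -> np.ndarray:
    """Apply the four channels in their documented order.

    Disabled channels are exact identities. ``wavenumbers`` is needed only
    for the unknown-band channel (band widths are in cm⁻¹); a unit
    coordinate is substituted when omitted.
    """
    out = np.asarray(spectrum, dtype=float).copy()
    if not np.all(np.isfinite(out)):
        raise ValueError("input spectrum must be finite")
    n = out.size
    if wavenumbers is None:
        wavenumbers = np.linspace(0.0, n - 1.0, n)
    t = np.linspace(-1.0, 1.0, n)

    if cfg.enable_power_fluct and cfg.power_fluct_amplitude > 0:
        amp = rng.uniform(0.0, cfg.power_fluct_amplitude)
        cycles = rng.uniform(0.25, cfg.power_fluct_max_cycles)
        phase = rng.uniform(0.0, 2.0 * np.pi)
        gain = 1.0 + amp * np.sin(np.pi * cycles * (t + 1.0) + phase)
        out = out - np.log(gain)  # multiplicative on transmittance

    if cfg.enable_unknown_bands:
        lo_c, hi_c = cfg.unknown_band_count_range
        count = int(rng.integers(lo_c, hi_c + 1))
        for _ in range(count):
            center = rng.uniform(wavenumbers[0], wavenumbers[-1])
            width = rng.uniform(*cfg.unknown_band_width_range)
            depth = rng.uniform(*cfg.unknown_band_depth_range)
            shape = "gaussian" if rng.random() < 0.5 else "lorentzian"
            out = out + depth * _band_profile(wavenumbers - center, width, shape)

    if cfg.enable_noise and cfg.noise_sigma > 0:
        out = out + rng.normal(0.0, cfg.noise_sigma, size=n)

    if cfg.enable_baseline and cfg.baseline_amplitude > 0:
        # random polynomial in the normalised coordinate, bounded coefficients
        order = cfg.baseline_poly_order
        coeffs = rng.uniform(-1.0, 1.0, size=order + 1)
        coeffs *= cfg.baseline_amplitude / (order + 1)
        out = out + np.polynomial.polynomial.polyval(t, coeffs)

    return out


def default_allocation(m: int) -> dict[str, int]:
    """Split ``m`` as evenly as possible across the seven classes
    (2500 each at the full study size m = 17500)."""
    base = m // len(MIXTURE_CLASSES)
    rem = m - base * len(MIXTURE_CLASSES)
    return {
        cls: base + (1 if i < rem else 0) for i, cls in enumerate(MIXTURE_CLASSES)
    }


def generate_dataset(
    m: int,
    grid: SpectralGrid,
    unit_spectra: Sequence[UnitAbsorbance],
    class_allocation: dict[str, int] | None = None,
    cfg: PerturbationConfig | None = None,
    seed: int = 0,
    conc_ranges: Sequence[tuple[float, float]] = CONC_RANGES,
) -> SpectrumDataset:
    """Generate ``m`` perturbed blended samples with 6-digit labels.

    Deterministic for a given (configuration, seed). Class membership is
    shuffled so batches mix classes; the label matrix row order matches
    ``X``. Raises if the allocation does not sum to ``m`` or unit spectra
    are not on ``grid``.
    """
    if len(unit_spectra) != 3:
        raise ValueError("exactly three unit spectra (M, A, W order) required")
    for u in unit_spectra:
        if u.grid != grid:
            raise ValueError(f"unit spectrum {u.gas_id!r} is not on the target grid")
    if class_allocation is None:
        class_allocation = default_allocation(m)
    unknown = set(class_allocation) - set(MIXTURE_CLASSES)
    if unknown:
        raise ValueError(f"unknown classes in allocation: {sorted(unknown)}")
    total = sum(class_allocation.values())
    if total != m:
        raise ValueError(f"class allocation sums to {total}, expected m = {m}")
    if cfg is None:
        cfg = PerturbationConfig()

    rng = np.random.default_rng(seed)
    class_idx = np.concatenate(
        [
            np.full(class_allocation.get(cls, 0), i, dtype=np.uint8)
            for i, cls in enumerate(MIXTURE_CLASSES)
        ]
    )
    rng.shuffle(class_idx)

    units = np.stack([u.values for u in unit_spectra])  # (3, n)
    wn = grid.wavenumbers
    X = np.empty((m, grid.n_points))
    X_clean = np.empty((m, grid.n_points))
    Y = np.empty((m, 6))
    for j in range(m):
        cls = MIXTURE_CLASSES[class_idx[j]]
        label = sample_concentrations(cls, rng, conc_ranges)
        X_clean[j] = np.asarray(label.cr) @ units
        X[j] = apply_perturbations(X_clean[j], cfg, rng, wavenumbers=wn)
        Y[j] = label.as_row()

    meta = {
        "seed": int(seed),
        "m": int(m),
        "class_allocation": {k: int(v) for k, v in class_allocation.items()},
        "perturbations": cfg.to_dict(),
        "conc_ranges": [list(r) for r in conc_ranges],
        "gas_ids": [u.gas_id for u in unit_spectra],
    }
    return SpectrumDataset(
        X=X, Y=Y, classes=class_idx, grid=grid, meta=meta, X_clean=X_clean
    )


def split_holdout(m: int, ratio: float = 0.1, seed: int = 0) -> DatasetSplit:
    """Shuffled train/test holdout; ``ratio`` is the test fraction (9:1 at 0.1)."""
    if not 0.0 < ratio < 1.0:
        raise ValueError("holdout ratio must be in (0, 1)")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(m)
    n_test = int(round(m * ratio))
    return DatasetSplit(train=np.sort(perm[n_test:]), test=np.sort(perm[:n_test]))


def kfold(
    indices: np.ndarray, k: int, seed: int = 0
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Shuffled k folds over ``indices``: list of (train, validation) pairs.

    Folds are pairwise disjoint, cover ``indices``, and differ in size by
    at most one.
    """
    indices = np.asarray(indices)
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > indices.size:
        raise ValueError(f"k = {k} exceeds the number of items ({indices.size})")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(indices)
    folds = np.array_split(perm, k)
    out = []
    for i in range(k):
        val = np.sort(folds[i])
        train = np.sort(np.concatenate([folds[j] for j in range(k) if j != i]))
        out.append((train, val))
    return out
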