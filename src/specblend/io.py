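"""File formats: HITRAN ``.par`` line lists, cross-section tables,
two-column spectra, the HDF5 dataset container, and model checkpoints.

All containers embed a ``format_version``; readers reject unknown major
versions so stale artifacts fail loudly instead of silently misparsing.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np

from .forward import AbsorptionLine, CrossSectionTable, LineList
from .grid import SpectralGrid

__all__ = [
    "read_hitran_par",
    "read_cross_section",
    "write_cross_section",
    "read_spectrum_text",
    "write_spectrum_text",
    "save_dataset",
    "load_dataset",
    "save_checkpoint",
    "load_checkpoint",
    "FORMAT_VERSION",
    "HITRAN_MOLAR_MASS_G",
]

FORMAT_VERSION = "1.0"

# Molar masses (g/mol) of the HITRAN molecule ids this package cares about;
# used to set Doppler widths when reading .par files. 6 = CH4, 1 = H2O.
HITRAN_MOLAR_MASS_G = {1: 18.010565, 2: 43.989830, 5: 27.994915, 6: 16.031300}


def _check_version(found: str, where: str) -> None:
    major = str(found).split(".")[0]
    if major != FORMAT_VERSION.split(".")[0]:
        raise ValueError(
            f"{where}: unsupported format version {found!r} "
            f"(this reader understands {FORMAT_VERSION})"
        )


# ---------------------------------------------------------------------------
# HITRAN 160-character fixed-width records
# ---------------------------------------------------------------------------

def read_hitran_par(
    path: str | Path,
    *,
    molecule: int | None = None,
    isotopologue: int | None = None,
    gas_id: str | None = None,
    molar_mass_g: float | None = None,
) -> LineList:
    """Read a HITRAN 2004-format 160-character ``.par`` line list.

    Fixed-width fields used (1-based columns): molecule id (1-2),
    isotopologue (3), wavenumber (4-15), intensity (16-25), gamma_air
    (36-40), gamma_self (41-45), E'' (46-55), n_air (56-59),
    delta_air (60-67). ``molecule``/``isotopologue`` filter records; the
    molar mass defaults to a built-in table keyed by molecule id.
    """
    path = Path(path)
    lines: list[AbsorptionLine] = []
    mol_seen: set[int] = set()
    with path.open() as fh:
        for raw in fh:
            if len(raw.rstrip("\n")) < 67:
                continue  # ignore short/blank lines
            mol = int(raw[0:2])
            iso = int(raw[2:3], 36)  # HITRAN packs isotopologue 10 as '0'..'A'
            if molecule is not None and mol != molecule:
                continue
            if isotopologue is not None and iso != isotopologue:
                continue
            mol_seen.add(mol)
            lines.append(
                AbsorptionLine(
                    center=float(raw[3:15]),
                    intensity=float(raw[15:25]),
                    air_hwhm=float(raw[35:40]),
                    self_hwhm=float(raw[40:45]),
                    lower_state_energy=float(raw[45:55]),
                    temp_exponent=float(raw[55:59]),
                    pressure_shift=float(raw[59:67]),
                )
            )
    if molar_mass_g is None:
        key = molecule if molecule is not None else (next(iter(mol_seen)) if len(mol_seen) == 1 else None)
        molar_mass_g = HITRAN_MOLAR_MASS_G.get(key, 18.0)
    return LineList(
        gas_id=gas_id or (f"hitran-{molecule}" if molecule else path.stem),
        lines=lines,
        molar_mass_g=molar_mass_g,
    )


# ---------------------------------------------------------------------------
# Two-column text formats
# ---------------------------------------------------------------------------

def _read_two_column(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Whitespace- or comma-separated two-column text, optional header line."""
    rows: list[tuple[float, float]] = []
    with Path(path).open() as fh:
        for lineno, raw in enumerate(fh, 1):
            text = raw.strip()
            if not text or text.startswith("#"):
                continue
            parts = text.replace(",", " ").split()
            try:
                rows.append((float(parts[0]), float(parts[1])))
            except (ValueError, IndexError):
                if lineno == 1:
                    continue  # header line
                raise ValueError(f"{path}:{lineno}: cannot parse {text!r}")
    if len(rows) < 2:
        raise ValueError(f"{path}: fewer than two data rows")
    arr = np.asarray(rows, dtype=float)
    return arr[:, 0], arr[:, 1]


def read_cross_section(path: str | Path, gas_id: str = "xsec") -> CrossSectionTable:
    """Read a (wavenumber cm⁻¹, absorbance per ppm·m) table."""
    wn, vals = _read_two_column(path)
    order = np.argsort(wn)
    return CrossSectionTable(wavenumbers=wn[order], values=vals[order], gas_id=gas_id)


def write_cross_section(table: CrossSectionTable, path: str | Path) -> None:
    header = "wavenumber_cm-1,absorbance_per_ppm_m"
    np.savetxt(
        path,
        np.column_stack([table.wavenumbers, table.values]),
        delimiter=",",
        header=header,
        comments="",
    )


def read_spectrum_text(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Read a measured/exported spectrum as (wavenumbers, absorbance)."""
    wn, ab = _read_two_column(path)
    if not np.all(np.diff(wn) > 0):
        order = np.argsort(wn)
        wn, ab = wn[order], ab[order]
    return wn, ab


def write_spectrum_text(
    path: str | Path, wavenumbers: np.ndarray, values: np.ndarray
) -> None:
    np.savetxt(
        path,
        np.column_stack([wavenumbers, values]),
        delimiter="\t",
        header="wavenumber_cm-1\tabsorbance",
        comments="",
    )


def resample_to_grid(
    wavenumbers: np.ndarray, values: np.ndarray, grid: SpectralGrid
) -> np.ndarray:
    """Linearly resample a measured spectrum onto the model grid.

    The measurement must cover the grid; out-of-span input is an error
    (silent extrapolation would fabricate absorbance).
    """
    if grid.start < wavenumbers[0] or grid.end > wavenumbers[-1]:
        raise ValueError(
            f"spectrum spans [{wavenumbers[0]:.3f}, {wavenumbers[-1]:.3f}] cm-1 "
            f"but the model grid needs [{grid.start}, {grid.end}] cm-1"
        )
    return np.interp(grid.wavenumbers, wavenumbers, values)


# ---------------------------------------------------------------------------
# HDF5 dataset container
# ---------------------------------------------------------------------------

def save_dataset(path: str | Path, dataset) -> None:
    """Write a :class:`~specblend.dataset.SpectrumDataset` to HDF5.

    Layout: datasets ``X`` (float32, m x n_points), ``Y`` (float64, m x 6),
    ``class`` (uint8, m); attributes carry the grid, conditions, the
    perturbation/config JSON, the seed and the format version.
    """
    with h5py.File(path, "w") as h5:
        h5.create_dataset("X", data=np.asarray(dataset.X, dtype=np.float32))
        h5.create_dataset("Y", data=np.asarray(dataset.Y, dtype=np.float64))
        h5.create_dataset("class", data=np.asarray(dataset.classes, dtype=np.uint8))
        if dataset.X_clean is not None:
            h5.create_dataset(
                "X_clean", data=np.asarray(dataset.X_clean, dtype=np.float32)
            )
        h5.attrs["grid_start"] = dataset.grid.start
        h5.attrs["grid_end"] = dataset.grid.end
        h5.attrs["grid_n_points"] = dataset.grid.n_points
        h5.attrs["meta_json"] = json.dumps(dataset.meta, sort_keys=True)
        h5.attrs["format_version"] = FORMAT_VERSION


def load_dataset(path: str | Path):
    from .dataset import SpectrumDataset  # local import avoids a cycle

    with h5py.File(path, "r") as h5:
        _check_version(h5.attrs.get("format_version", "?"), str(path))
        grid = SpectralGrid(
            float(h5.attrs["grid_start"]),
            float(h5.attrs["grid_end"]),
            int(h5.attrs["grid_n_points"]),
        )
        return SpectrumDataset(
            X=h5["X"][...].astype(np.float64),
            Y=h5["Y"][...],
            classes=h5["class"][...],
            grid=grid,
            meta=json.loads(h5.attrs.get("meta_json", "{}")),
            X_clean=(
                h5["X_clean"][...].astype(np.float64) if "X_clean" in h5 else None
            ),
        )


# ---------------------------------------------------------------------------
# Model checkpoints
# ---------------------------------------------------------------------------

def write_training_log(history: list[dict], path: str | Path) -> None:
    """Per-epoch JSON-lines: epoch, total/identification/concentration loss,
    wall seconds."""
    with Path(path).open("w") as fh:
        for rec in history:
            fh.write(json.dumps(rec, sort_keys=True) + "\n")


def save_checkpoint(path: str | Path, model) -> None:
    """Persist a fitted :class:`~specblend.model.SpectralAnalysisModel`.

    Weights are stored losslessly (``.npz``); hyperparameters and fitted
    scalars travel as a JSON string so the round trip is bit-exact on
    weights and faithful on configuration.
    """
    from .model import SpectralAnalysisModel  # noqa: F401  (type anchor)

    arrays = {}
    for i, (w, b) in enumerate(zip(model.coefs_, model.intercepts_)):
        arrays[f"coef_{i}"] = w
        arrays[f"intercept_{i}"] = b
    meta = {
        "format_version": FORMAT_VERSION,
        "params": model.get_params(),
        "cr_scale": list(map(float, model.cr_scale_)),
        "n_features_in": int(model.n_features_in_),
        "history": model.history_,
        "grid": model.grid_attrs_ if hasattr(model, "grid_attrs_") else None,
    }
    arrays["meta_json"] = np.frombuffer(
        json.dumps(meta, sort_keys=True).encode(), dtype=np.uint8
    )
    with open(path, "wb") as fh:  # keep the exact path (no .npz auto-suffix)
        np.savez(fh, **arrays)


def load_checkpoint(path: str | Path):
    from .model import SpectralAnalysisModel

    with np.load(path, allow_pickle=False) as npz:
        meta = json.loads(bytes(npz["meta_json"].tobytes()).decode())
        _check_version(meta.get("format_version", "?"), str(path))
        model = SpectralAnalysisModel(**meta["params"])
        n_layers = sum(1 for k in npz.files if k.startswith("coef_"))
        model.coefs_ = [npz[f"coef_{i}"] for i in range(n_layers)]
        model.intercepts_ = [npz[f"intercept_{i}"] for i in range(n_layers)]
    model.cr_scale_ = np.asarray(meta["cr_scale"], dtype=float)
    model.n_features_in_ = meta["n_features_in"]
    model.history_ = meta["history"]
    if meta.get("grid") is not None:
        model.grid_attrs_ = meta["grid"]
    return model
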