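"""Gradient activation maps (GAM) for 1-D spectra.

Three ingredients explain which spectral regions drive a prediction:

* the activation map ``M`` over the last hidden layer — for the selected
  output neurons n, ``M_x = sum_n W[n, x] * a(L)_x``, the per-unit
  contribution of the last hidden activation to the output score;
* the guided backpropagation gradient ``g_b`` of the selected output
  scores with respect to the input spectrum, where at every ReLU both the
  inactive units and the negative upstream gradients are zeroed (fine
  spatial detail);
* their fusion ``g_a = g_b * M`` after ``M`` is linearly interpolated from
  hidden-unit index space onto the spectral grid (Grad-CAM-style
  upsampling; the hidden layer has no native wavenumber axis, so a uniform
  stretch is the interpretive choice, documented in the methods note).

Attribution targets are the output-layer pre-activation scores (the CI
logits and CR outputs), which are exactly linear in a(L).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .grid import SpectralGrid
from .model import SpectralAnalysisModel, _ACTIVATIONS

__all__ = [
    "GAMResult",
    "resolve_targets",
    "activation_map",
    "guided_backprop",
    "fuse",
    "compute_gam",
    "export_gam",
]

_TARGET_ALIASES = {
    "all": (0, 1, 2, 3, 4, 5),
    "ci": (0, 1, 2),
    "cr": (3, 4, 5),
}


@dataclass
class GAMResult:
    """Activation map, guided gradients and their fused map for one spectrum."""

    activation_map: np.ndarray  # over last-hidden units
    guided_gradients: np.ndarray  # over the input grid
    fused_map: np.ndarray  # over the input grid
    targets: tuple[int, ...]


def resolve_targets(
    targets: str | Iterable[int] | None, n_outputs: int = 6
) -> tuple[int, ...]:
    if targets is None:
        targets = "all"
    if isinstance(targets, str):
        try:
            return _TARGET_ALIASES[targets]
        except KeyError:
            raise ValueError(f"unknown target alias {targets!r}") from None
    out = tuple(int(t) for t in targets)
    if not out:
        raise ValueError("target set must not be empty")
    if any(t < 0 or t >= n_outputs for t in out):
        raise ValueError(f"targets must lie in [0, {n_outputs})")
    return out


def activation_map(
    model: SpectralAnalysisModel,
    spectrum: np.ndarray,
    targets: str | Iterable[int] | None = None,
) -> np.ndarray:
    """``M_x = sum_{n in targets} W_out[x, n] * a(L)_x`` for one spectrum.

    Linear both in the last-hidden activation and in the target set
    (``M_all = M_CI + M_CR``).
    """
    tsel = resolve_targets(targets)
    tr = model._forward_trace(np.atleast_2d(np.asarray(spectrum, dtype=float)))
    a_last = tr["a"][-1][0]
    w_out = model.coefs_[-1]  # (hidden, 6)
    return w_out[:, list(tsel)].sum(axis=1) * a_last


def guided_backprop(
    model: SpectralAnalysisModel,
    spectrum: np.ndarray,
    targets: str | Iterable[int] | None = None,
    mode: str = "guided",
) -> np.ndarray:
    """Gradient of the summed target output scores w.r.t. the input.

    ``mode="guided"`` applies the guided-ReLU rule (requires the ReLU
    hidden activation; other activations raise, with ``mode="plain"``
    offered as the exact-Jacobian fallback). The ReLU subgradient at 0 is
    taken as 0.
    """
    tsel = resolve_targets(targets)
    if mode not in ("guided", "plain"):
        raise ValueError("mode must be 'guided' or 'plain'")
    if mode == "guided" and model.hidden_activation != "relu":
        raise ValueError(
            "guided backpropagation is defined for ReLU activations only; "
            "use mode='plain' for the exact gradient"
        )
    x = np.atleast_2d(np.asarray(spectrum, dtype=float))
    tr = model._forward_trace(x)
    act_deriv = _ACTIVATIONS[model.hidden_activation][1]

    d_out = np.zeros((1, model.coefs_[-1].shape[1]))
    d_out[0, list(tsel)] = 1.0
    da = d_out @ model.coefs_[-1].T
    n_hidden = len(model.coefs_) - 1
    for i in range(n_hidden - 1, -1, -1):
        dz = da * act_deriv(tr["z"][i])
        if mode == "guided":
            dz = dz * (da > 0)
        da = dz @ model.coefs_[i].T
    return da[0]


def fuse(
    M: np.ndarray,
    g_b: np.ndarray,
    grid: SpectralGrid | None = None,
    rectify: bool = False,
) -> np.ndarray:
    """Fused map ``g_a = g_b * interp(M)`` on the input grid.

    ``M`` is stretched uniformly from hidden-unit index space onto the
    input length (endpoints map to endpoints). ``rectify`` keeps only the
    positive part — a rendering option, off by default.
    """
    M = np.asarray(M, dtype=float)
    g_b = np.asarray(g_b, dtype=float)
    n_out = g_b.size if grid is None else grid.n_points
    if g_b.size != n_out:
        raise ValueError("guided gradients must match the grid length")
    m_up = np.interp(
        np.linspace(0.0, 1.0, n_out), np.linspace(0.0, 1.0, M.size), M
    )
    g_a = g_b * m_up
    if rectify:
        g_a = np.clip(g_a, 0.0, None)
    return g_a


def compute_gam(
    model: SpectralAnalysisModel,
    spectrum: np.ndarray,
    targets: str | Iterable[int] | None = None,
    mode: str = "guided",
    rectify: bool = False,
) -> GAMResult:
    """End-to-end GAM for one spectrum: M, g_b and the fused g_a."""
    tsel = resolve_targets(targets)
    M = activation_map(model, spectrum, tsel)
    g_b = guided_backprop(model, spectrum, tsel, mode=mode)
    return GAMResult(
        activation_map=M,
        guided_gradients=g_b,
        fused_map=fuse(M, g_b, rectify=rectify),
        targets=tsel,
    )


def export_gam(
    result: GAMResult,
    grid: SpectralGrid,
    path: str | Path,
    metadata: dict | None = None,
) -> None:
    """Three-column text (wavenumber, fused map, interpolated activation
    map) plus a JSON metadata sidecar ``<path>.json``."""
    wn = grid.wavenumbers
    m_up = np.interp(
        np.linspace(0.0, 1.0, grid.n_points),
        np.linspace(0.0, 1.0, result.activation_map.size),
        result.activation_map,
    )
    np.savetxt(
        path,
        np.column_stack([wn, result.fused_map, m_up]),
        delimiter="\t",
        header="wavenumber_cm-1\tfused_gam\tactivation_map_interp",
        comments="",
    )
    meta = {"targets": list(result.targets)}
    if metadata:
        meta.update(metadata)
    Path(str(path) + ".json").write_text(json.dumps(meta, indent=2) + "\n")
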