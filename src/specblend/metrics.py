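"""Evaluation metrics for joint identification + retrieval.

Identification quality over the 3-flag multi-label predictions:

* EMR (exact match ratio) — fraction of samples whose full flag vector is
  exactly right;
* HA (Hamming accuracy) — fraction of individual flags that are right.
  HA >= EMR always, since an exact row match implies all its flags match.

Composition confusion is tabulated over the 7 mixture classes plus a
"none" bucket (a model may predict no gas at all, which the 7-class grid
cannot express). Concentration retrieval uses the coefficient of
determination R² = 1 - Σ(c - ĉ)² / Σ(c - c̄)², the mean absolute error in
ppm, and the mean relative error computed only over samples where the gas
is truly present (relative error is undefined at c = 0).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .dataset import CLASS_MASKS, MIXTURE_CLASSES

__all__ = [
    "emr",
    "ha",
    "composition_confusion",
    "regression_metrics",
    "CompositionConfusion",
    "MetricsReport",
    "evaluate",
]

_PATTERN_TO_CLASS = {mask: cls for cls, mask in CLASS_MASKS.items()}
CONFUSION_LABELS = (*MIXTURE_CLASSES, "none")


def _check_binary_pair(true_ci: np.ndarray, pred_ci: np.ndarray):
    t = np.asarray(true_ci)
    p = np.asarray(pred_ci)
    if t.shape != p.shape or t.ndim != 2:
        raise ValueError("true/pred flag matrices must be 2-D and equal shape")
    for arr in (t, p):
        if not np.isin(arr, (0, 1)).all():
            raise ValueError("flag matrices must be binary")
    return t.astype(int), p.astype(int)


def emr(true_ci: np.ndarray, pred_ci: np.ndarray) -> float:
    """Exact match ratio: fraction of rows predicted perfectly."""
    t, p = _check_binary_pair(true_ci, pred_ci)
    return float(np.mean(np.all(t == p, axis=1)))


def ha(true_ci: np.ndarray, pred_ci: np.ndarray) -> float:
    """Hamming accuracy: fraction of individual flags predicted correctly."""
    t, p = _check_binary_pair(true_ci, pred_ci)
    return float(np.mean(t == p))


@dataclass
class CompositionConfusion:
    """Row-stochastic confusion over the mixture classes (+ "none").

    ``counts[i, j]`` is the number of samples of true class i predicted as
    class j; ``normalized`` divides each row by its total (all-zero rows for
    unobserved classes stay zero).
    """

    labels: tuple[str, ...]
    counts: np.ndarray
    normalized: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        totals = self.counts.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            norm = np.where(totals > 0, self.counts / np.maximum(totals, 1), 0.0)
        self.normalized = norm

    def to_csv(self, path: str | Path) -> None:
        header = "true\\pred," + ",".join(self.labels)
        rows = [
            f"{lab}," + ",".join(f"{v:.6f}" for v in self.normalized[i])
            for i, lab in enumerate(self.labels)
        ]
        Path(path).write_text(header + "\n" + "\n".join(rows) + "\n")


def _pattern_index(row: np.ndarray) -> int:
    pattern = tuple(int(v) for v in row)
    if pattern == (0, 0, 0):
        return len(MIXTURE_CLASSES)  # "none"
    return MIXTURE_CLASSES.index(_PATTERN_TO_CLASS[pattern])


def composition_confusion(
    true_ci: np.ndarray, pred_ci: np.ndarray
) -> CompositionConfusion:
    t, p = _check_binary_pair(true_ci, pred_ci)
    k = len(CONFUSION_LABELS)
    counts = np.zeros((k, k), dtype=int)
    for tr, pr in zip(t, p):
        counts[_pattern_index(tr), _pattern_index(pr)] += 1
    return CompositionConfusion(labels=CONFUSION_LABELS, counts=counts)


def regression_metrics(
    true_c: np.ndarray,
    pred_c: np.ndarray,
    present_mask: np.ndarray | None = None,
    gas_names: tuple[str, ...] | None = None,
) -> dict:
    """Per-gas concentration metrics.

    R² and MAE are computed over all samples; the relative errors (RE, MRE)
    only over samples where the gas is truly present with c > 0.
    ``present_mask`` defaults to ``true_c > 0``. Zero variance in the true
    concentrations makes R² undefined: reported as NaN with a warning.
    """
    t = np.asarray(true_c, dtype=float)
    p = np.asarray(pred_c, dtype=float)
    if t.shape != p.shape or t.ndim != 2:
        raise ValueError("true/pred concentration matrices must match in shape")
    n_gas = t.shape[1]
    if present_mask is None:
        present_mask = t > 0
    if gas_names is None:
        gas_names = tuple(f"gas{i + 1}" for i in range(n_gas))

    out = {}
    for i in range(n_gas):
        ti, pi = t[:, i], p[:, i]
        ss_res = float(np.sum((ti - pi) ** 2))
        ss_tot = float(np.sum((ti - ti.mean()) ** 2))
        if ss_tot == 0.0:
            warnings.warn(
                f"R^2 undefined for {gas_names[i]}: zero variance in true values",
                stacklevel=2,
            )
            r2 = float("nan")
        else:
            r2 = 1.0 - ss_res / ss_tot
        ae = np.abs(ti - pi)
        mask = present_mask[:, i]
        with np.errstate(divide="ignore", invalid="ignore"):
            re = np.where(mask & (ti > 0), ae / np.where(ti > 0, ti, 1.0), np.nan)
        mre = float(np.nanmean(re)) if np.any(mask & (ti > 0)) else float("nan")
        out[gas_names[i]] = {
            "r2": r2,
            "mae": float(ae.mean()),
            "mre": mre,
            "ae": ae,
            "re": re,
        }
    return out


@dataclass
class MetricsReport:
    """Bundle of identification + retrieval metrics for one evaluation."""

    emr: float
    ha: float
    per_gas: dict
    confusion: CompositionConfusion
    n_samples: int

    def summary(self) -> dict:
        return {
            "n_samples": self.n_samples,
            "emr": self.emr,
            "ha": self.ha,
            "per_gas": {
                name: {k: v for k, v in d.items() if k in ("r2", "mae", "mre")}
                for name, d in self.per_gas.items()
            },
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.summary(), indent=2) + "\n")


def evaluate(
    true_Y: np.ndarray,
    pred_ci: np.ndarray,
    pred_c: np.ndarray,
    gas_names: tuple[str, ...] = ("methane", "acetone", "water"),
) -> MetricsReport:
    """Full report from 6-digit labels, predicted flags and gated ppm."""
    true_Y = np.asarray(true_Y, dtype=float)
    true_ci = true_Y[:, :3].astype(int)
    true_c = true_Y[:, 3:]
    return MetricsReport(
        emr=emr(true_ci, pred_ci),
        ha=ha(true_ci, pred_ci),
        per_gas=regression_metrics(true_c, pred_c, gas_names=gas_names),
        confusion=composition_confusion(true_ci, pred_ci),
        n_samples=true_Y.shape[0],
    )
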