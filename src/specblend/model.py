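"""The spectral analysis model (SAM): a multi-task MLP over absorbance spectra.

One fully connected network maps a blended absorbance spectrum to six
outputs: three component-identification (CI) logits, read through a
sigmoid as presence probabilities, and three concentration-regression (CR)
values. Both tasks are optimised jointly by minimising

    L_obj = L_iden + lambda * L_con

where ``L_iden`` is the mean binary cross-entropy over the m x n presence
flags and ``L_con`` the mean squared error over the m x n (scaled)
concentrations. The trade-off factor ``lambda = 100`` keeps the harder
regression task from being drowned out by the quickly converging
classification term. Optimisation uses Adam with beta1 = 0.5,
beta2 = 0.999.

At inference a concentration is reported only when its CI probability
exceeds 0.5; otherwise it is forced to zero (the gating rule), which
separates "gas absent" from "present at low concentration".

Implemented as a scikit-learn-style estimator so it composes with
sklearn model selection; the dense forward/backward passes are written in
NumPy, which also gives the interpretability module direct access to
pre-activations for guided backpropagation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_array, check_is_fitted

__all__ = [
    "SpectralAnalysisModel",
    "SAMConfig",
    "TrainConfig",
    "Prediction",
    "LossBreakdown",
    "TrainingDivergenceError",
    "loss_components",
    "gate",
    "train",
    "forward",
    "predict_gated",
    "DEFAULT_HIDDEN",
]

DEFAULT_HIDDEN = (196, 74, 211)

_ACTIVATIONS = {
    "relu": (lambda z: np.maximum(z, 0.0), lambda z: (z > 0).astype(float)),
    "tanh": (np.tanh, lambda z: 1.0 - np.tanh(z) ** 2),
    "identity": (lambda z: z, lambda z: np.ones_like(z)),
}


class TrainingDivergenceError(RuntimeError):
    """Raised when the training loss becomes non-finite."""

    def __init__(self, epoch: int):
        super().__init__(f"training loss became non-finite at epoch {epoch}")
        self.epoch = epoch


@dataclass(frozen=True)
class LossBreakdown:
    total: float
    identification: float
    concentration: float


@dataclass(frozen=True)
class Prediction:
    """CI probabilities, raw CR output (ppm) and the gated concentrations."""

    ci_prob: np.ndarray
    cr_raw: np.ndarray
    cr_gated: np.ndarray


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def loss_components(
    ci_prob: np.ndarray,
    cr_pred: np.ndarray,
    ci_true: np.ndarray,
    cr_true: np.ndarray,
    lambda_con: float = 100.0,
    eps: float = 1e-7,
) -> LossBreakdown:
    """Joint loss on a batch: mean BCE over flags + lambda * mean MSE.

    ``cr_pred``/``cr_true`` are expected on a common (possibly scaled)
    axis; the estimator trains on per-gas max-normalised targets.
    """
    ci_prob = np.asarray(ci_prob, dtype=float)
    cr_pred = np.asarray(cr_pred, dtype=float)
    ci_true = np.asarray(ci_true, dtype=float)
    cr_true = np.asarray(cr_true, dtype=float)
    if ci_prob.shape != ci_true.shape or cr_pred.shape != cr_true.shape:
        raise ValueError("prediction/label shapes must match")
    for arr in (ci_prob, cr_pred, ci_true, cr_true):
        if not np.all(np.isfinite(arr)):
            raise FloatingPointError("loss inputs must be finite")
    if lambda_con < 0:
        raise ValueError("lambda_con must be >= 0")
    p = np.clip(ci_prob, eps, 1.0 - eps)
    l_iden = float(-np.mean(ci_true * np.log(p) + (1.0 - ci_true) * np.log(1.0 - p)))
    l_con = float(np.mean((cr_true - cr_pred) ** 2))
    return LossBreakdown(l_iden + lambda_con * l_con, l_iden, l_con)


def gate(
    ci_prob: np.ndarray, cr: np.ndarray, threshold: float = 0.5
) -> np.ndarray:
    """Zero every concentration whose presence probability is <= threshold;
    clip the surviving values at zero. Idempotent."""
    ci_prob = np.asarray(ci_prob, dtype=float)
    cr = np.asarray(cr, dtype=float)
    return np.where(ci_prob > threshold, np.clip(cr, 0.0, None), 0.0)


class SpectralAnalysisModel(BaseEstimator):
    """Multi-task MLP for gas identification and concentration retrieval.

    Parameters
    ----------
    hidden_layer_sizes : tuple of int, default (196, 74, 211)
        Widths of the three hidden layers.
    dropout : float, default 0.2
        Dropout rate applied to the last hidden layer during training only.
    hidden_activation : {"relu", "tanh", "identity"}, default "relu"
    learning_rate, batch_size, epochs : Adam step size 0.01, minibatch 256,
        500 passes by default.
    lambda_con : float, default 100.0
        Weight of the concentration MSE term in the joint loss.
    beta1, beta2 : Adam moment decay constants (0.5, 0.999).
    lr_schedule : {"constant", "cosine"}, default "constant"
        "cosine" ramps the step size linearly over the first 5% of epochs
        then decays it to zero on a half-cosine — the small-step-budget
        schedule used by the desk-scale preset.
    cr_max : length-3 sequence or None
        Per-gas concentration scale used to normalise CR targets. ``None``
        uses the per-gas maximum of the training labels. Pass ``1`` values
        to train on raw ppm.
    ci_threshold : float, default 0.5
        Gating threshold on the CI probability (strict ``>``).
    bce_epsilon : float, default 1e-7
        Probability clamp inside the cross-entropy.
    random_state : int or None
        Seeds weight initialisation, shuffling and dropout.

    Attributes
    ----------
    coefs_, intercepts_ : per-layer weights (fan-in x fan-out) and biases.
    cr_scale_ : the per-gas normalisation actually used.
    history_ : per-epoch dicts with keys epoch, loss, l_iden, l_con.
    n_features_in_ : input spectrum length.
    """

    N_GASES = 3

    def __init__(
        self,
        hidden_layer_sizes: tuple[int, ...] = DEFAULT_HIDDEN,
        dropout: float = 0.2,
        hidden_activation: str = "relu",
        learning_rate: float = 0.01,
        batch_size: int = 256,
        epochs: int = 500,
        lambda_con: float = 100.0,
        beta1: float = 0.5,
        beta2: float = 0.999,
        lr_schedule: str = "constant",
        cr_max=None,
        ci_threshold: float = 0.5,
        bce_epsilon: float = 1e-7,
        random_state: int | None = None,
    ):
        self.hidden_layer_sizes = hidden_layer_sizes
        self.dropout = dropout
        self.hidden_activation = hidden_activation
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.epochs = epochs
        self.lambda_con = lambda_con
        self.beta1 = beta1
        self.beta2 = beta2
        self.lr_schedule = lr_schedule
        self.cr_max = cr_max
        self.ci_threshold = ci_threshold
        self.bce_epsilon = bce_epsilon
        self.random_state = random_state

    # ------------------------------------------------------------------
    # construction helpers
    # ------------------------------------------------------------------

    def _validate_params_(self) -> None:
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")
        if self.hidden_activation not in _ACTIVATIONS:
            raise ValueError(f"unknown activation {self.hidden_activation!r}")
        if self.epochs < 0 or self.batch_size < 1:
            raise ValueError("epochs must be >= 0 and batch_size >= 1")
        if self.learning_rate <= 0 or self.lambda_con < 0:
            raise ValueError("learning_rate must be > 0 and lambda_con >= 0")
        if self.lr_schedule not in ("constant", "cosine"):
            raise ValueError("lr_schedule must be 'constant' or 'cosine'")

    def _init_weights(self, n_features: int, rng: np.random.Generator) -> None:
        sizes = [n_features, *self.hidden_layer_sizes, 2 * self.N_GASES]
        self.coefs_, self.intercepts_ = [], []
        for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
            bound = 1.0 / np.sqrt(fan_in)  # uniform fan-in scaling
            self.coefs_.append(rng.uniform(-bound, bound, size=(fan_in, fan_out)))
            self.intercepts_.append(np.zeros(fan_out))

    # ------------------------------------------------------------------
    # forward passes
    # ------------------------------------------------------------------

    def _forward_trace(self, X: np.ndarray) -> dict:
        """Evaluation-mode forward pass keeping all pre-activations.

        Returns ``{"z": [...], "a": [...], "ci_prob", "cr_scaled"}`` where
        ``a[-1]`` is the last hidden activation a(L) and ``z[-1]`` the
        six output scores.
        """
        act, _ = _ACTIVATIONS[self.hidden_activation]
        zs, activations = [], []
        a = X
        n_hidden = len(self.coefs_) - 1
        for i in range(n_hidden):
            z = a @ self.coefs_[i] + self.intercepts_[i]
            a = act(z)
            zs.append(z)
            activations.append(a)
        z_out = a @ self.coefs_[-1] + self.intercepts_[-1]
        zs.append(z_out)
        return {
            "z": zs,
            "a": activations,
            "ci_prob": _sigmoid(z_out[..., : self.N_GASES]),
            "cr_scaled": z_out[..., self.N_GASES :],
        }

    def _forward_train(self, X: np.ndarray, rng: np.random.Generator) -> dict:
        act, _ = _ACTIVATIONS[self.hidden_activation]
        zs, activations = [], []
        a = X
        n_hidden = len(self.coefs_) - 1
        for i in range(n_hidden):
            z = a @ self.coefs_[i] + self.intercepts_[i]
            a = act(z)
            zs.append(z)
            activations.append(a)
        # inverted dropout on the last hidden layer only
        if self.dropout > 0:
            keep = 1.0 - self.dropout
            mask = (rng.random(a.shape) < keep) / keep
        else:
            mask = np.ones_like(a)
        a_drop = a * mask
        z_out = a_drop @ self.coefs_[-1] + self.intercepts_[-1]
        zs.append(z_out)
        return {"z": zs, "a": activations, "a_drop": a_drop, "mask": mask}

    # ------------------------------------------------------------------
    # training
    # ------------------------------------------------------------------

    def fit(self, X: np.ndarray, Y: np.ndarray, augment_fn=None):
        """Train on spectra ``X`` (m x n) and 6-digit labels ``Y`` (m x 6,
        CI flags then CR concentrations in ppm).

        ``augment_fn(X, rng) -> X'`` is an optional per-epoch resampling
        hook: when the perturbation channels are stochastic instrument
        effects, re-drawing them every epoch exposes the model to fresh
        noise realisations of the same m physical samples instead of one
        frozen draw. ``X`` is then conventionally the clean blended
        spectra and ``augment_fn`` applies the perturbations.
        """
        self._validate_params_()
        X = check_array(X, dtype=np.float64)
        Y = check_array(Y, dtype=np.float64)
        if Y.shape != (X.shape[0], 2 * self.N_GASES):
            raise ValueError(f"Y must be (m, {2 * self.N_GASES})")
        if X.shape[0] == 0:
            raise ValueError("training set is empty")
        rng = np.random.default_rng(self.random_state)
        self.n_features_in_ = X.shape[1]
        self._init_weights(self.n_features_in_, rng)

        g_true = Y[:, : self.N_GASES]
        if self.cr_max is not None:
            self.cr_scale_ = np.asarray(self.cr_max, dtype=float)
        else:
            self.cr_scale_ = np.maximum(Y[:, self.N_GASES :].max(axis=0), 1.0)
        c_true = Y[:, self.N_GASES :] / self.cr_scale_

        self.history_ = []
        if self.epochs == 0:
            return self

        act_deriv = _ACTIVATIONS[self.hidden_activation][1]
        # Adam state
        m_w = [np.zeros_like(w) for w in self.coefs_]
        v_w = [np.zeros_like(w) for w in self.coefs_]
        m_b = [np.zeros_like(b) for b in self.intercepts_]
        v_b = [np.zeros_like(b) for b in self.intercepts_]
        t = 0
        eps_adam = 1e-8
        m_samples = X.shape[0]
        n_hidden = len(self.coefs_) - 1

        import time as _time

        warmup = max(1, round(0.05 * self.epochs))
        for epoch in range(self.epochs):
            t_epoch = _time.perf_counter()
            if self.lr_schedule == "cosine":
                if epoch < warmup:
                    lr_now = self.learning_rate * (epoch + 1) / warmup
                else:
                    frac = (epoch - warmup) / max(1, self.epochs - warmup)
                    lr_now = self.learning_rate * 0.5 * (1.0 + np.cos(np.pi * frac))
            else:
                lr_now = self.learning_rate
            X_ep = X if augment_fn is None else augment_fn(X, rng)
            perm = rng.permutation(m_samples)
            ep_tot = ep_iden = ep_con = 0.0
            n_batches = 0
            for start in range(0, m_samples, self.batch_size):
                idx = perm[start : start + self.batch_size]
                xb, gb, cb = X_ep[idx], g_true[idx], c_true[idx]
                B = xb.shape[0]

                tr = self._forward_train(xb, rng)
                z_out = tr["z"][-1]
                p = _sigmoid(z_out[:, : self.N_GASES])
                chat = z_out[:, self.N_GASES :]
                lb = loss_components(
                    p, chat, gb, cb, self.lambda_con, self.bce_epsilon
                )
                if not np.isfinite(lb.total):
                    raise TrainingDivergenceError(epoch)
                ep_tot += lb.total
                ep_iden += lb.identification
                ep_con += lb.concentration
                n_batches += 1

                # backprop
                denom = B * self.N_GASES
                dz_out = np.empty_like(z_out)
                dz_out[:, : self.N_GASES] = (p - gb) / denom
                dz_out[:, self.N_GASES :] = (
                    2.0 * self.lambda_con * (chat - cb) / denom
                )
                grads_w = [None] * len(self.coefs_)
                grads_b = [None] * len(self.coefs_)
                grads_w[-1] = tr["a_drop"].T @ dz_out
                grads_b[-1] = dz_out.sum(axis=0)
                da = (dz_out @ self.coefs_[-1].T) * tr["mask"]
                for i in range(n_hidden - 1, -1, -1):
                    dz = da * act_deriv(tr["z"][i])
                    a_prev = xb if i == 0 else tr["a"][i - 1]
                    grads_w[i] = a_prev.T @ dz
                    grads_b[i] = dz.sum(axis=0)
                    if i > 0:
                        da = dz @ self.coefs_[i].T

                # Adam update
                t += 1
                bc1 = 1.0 - self.beta1**t
                bc2 = 1.0 - self.beta2**t
                for i in range(len(self.coefs_)):
                    m_w[i] = self.beta1 * m_w[i] + (1 - self.beta1) * grads_w[i]
                    v_w[i] = self.beta2 * v_w[i] + (1 - self.beta2) * grads_w[i] ** 2
                    self.coefs_[i] -= (
                        lr_now * (m_w[i] / bc1) / (np.sqrt(v_w[i] / bc2) + eps_adam)
                    )
                    m_b[i] = self.beta1 * m_b[i] + (1 - self.beta1) * grads_b[i]
                    v_b[i] = self.beta2 * v_b[i] + (1 - self.beta2) * grads_b[i] ** 2
                    self.intercepts_[i] -= (
                        lr_now * (m_b[i] / bc1) / (np.sqrt(v_b[i] / bc2) + eps_adam)
                    )

            self.history_.append(
                {
                    "epoch": epoch,
                    "loss": ep_tot / n_batches,
                    "l_iden": ep_iden / n_batches,
                    "l_con": ep_con / n_batches,
                    "seconds": _time.perf_counter() - t_epoch,
                }
            )
        return self

    # ------------------------------------------------------------------
    # inference
    # ------------------------------------------------------------------

    def _check_input(self, X: np.ndarray) -> np.ndarray:
        check_is_fitted(self, "coefs_")
        X = check_array(np.atleast_2d(X), dtype=np.float64)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"spectrum length {X.shape[1]} does not match the model input "
                f"width {self.n_features_in_}"
            )
        return X

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """CI presence probabilities, shape (m, 3)."""
        X = self._check_input(X)
        return self._forward_trace(X)["ci_prob"]

    def predict_components(self, X: np.ndarray) -> np.ndarray:
        """Binary presence flags under the gating threshold (strict >)."""
        return (self.predict_proba(X) > self.ci_threshold).astype(int)

    def predict_concentrations(self, X: np.ndarray) -> np.ndarray:
        """Gated concentrations in ppm, shape (m, 3)."""
        X = self._check_input(X)
        tr = self._forward_trace(X)
        cr_raw = tr["cr_scaled"] * self.cr_scale_
        return gate(tr["ci_prob"], cr_raw, self.ci_threshold)

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Full 6-digit prediction (m, 6): binary CI flags then gated CR ppm."""
        X = self._check_input(X)
        tr = self._forward_trace(X)
        ci = (tr["ci_prob"] > self.ci_threshold).astype(float)
        cr = gate(tr["ci_prob"], tr["cr_scaled"] * self.cr_scale_, self.ci_threshold)
        return np.hstack([ci, cr])

    def forward(self, spectrum: np.ndarray) -> Prediction:
        """Single-spectrum forward pass returning the full prediction."""
        X = self._check_input(spectrum)
        if X.shape[0] != 1:
            raise ValueError("forward() takes a single spectrum")
        tr = self._forward_trace(X)
        ci = tr["ci_prob"][0]
        cr_raw = (tr["cr_scaled"] * self.cr_scale_)[0]
        return Prediction(
            ci_prob=ci, cr_raw=cr_raw, cr_gated=gate(ci, cr_raw, self.ci_threshold)
        )

    def score(self, X: np.ndarray, Y: np.ndarray) -> float:
        """Exact-match ratio of the identification half (sklearn scorer hook)."""
        from .metrics import emr

        pred = self.predict_components(X)
        return emr(np.asarray(Y)[:, : self.N_GASES].astype(int), pred)


# ---------------------------------------------------------------------------
# Thin functional wrappers mirroring the pipeline vocabulary
# ---------------------------------------------------------------------------


@dataclass
class SAMConfig:
    """Architecture block: widths, dropout, activations."""

    hidden_layer_sizes: tuple[int, ...] = DEFAULT_HIDDEN
    dropout: float = 0.2
    hidden_activation: str = "relu"
    cr_max: tuple[float, float, float] | None = None
    ci_threshold: float = 0.5


@dataclass
class TrainConfig:
    """Optimisation block: the study defaults are batch 256 / 500 epochs /
    learning rate 0.01 / Adam(0.5, 0.999) / lambda = 100."""

    batch_size: int = 256
    epochs: int = 500
    learning_rate: float = 0.01
    beta1: float = 0.5
    beta2: float = 0.999
    lambda_con: float = 100.0
    seed: int = 0


def train(
    X: np.ndarray,
    Y: np.ndarray,
    sam_cfg: SAMConfig | None = None,
    train_cfg: TrainConfig | None = None,
) -> SpectralAnalysisModel:
    sam_cfg = sam_cfg or SAMConfig()
    train_cfg = train_cfg or TrainConfig()
    model = SpectralAnalysisModel(
        hidden_layer_sizes=tuple(sam_cfg.hidden_layer_sizes),
        dropout=sam_cfg.dropout,
        hidden_activation=sam_cfg.hidden_activation,
        cr_max=sam_cfg.cr_max,
        ci_threshold=sam_cfg.ci_threshold,
        learning_rate=train_cfg.learning_rate,
        batch_size=train_cfg.batch_size,
        epochs=train_cfg.epochs,
        lambda_con=train_cfg.lambda_con,
        beta1=train_cfg.beta1,
        beta2=train_cfg.beta2,
        random_state=train_cfg.seed,
    )
    return model.fit(X, Y)


def forward(model: SpectralAnalysisModel, spectrum: np.ndarray) -> Prediction:
    return model.forward(spectrum)


def predict_gated(model: SpectralAnalysisModel, spectrum: np.ndarray) -> Prediction:
    """Forward pass with the gating rule applied (alias of ``forward``;
    the returned ``cr_gated`` field is the gated output)."""
    return model.forward(spectrum)
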