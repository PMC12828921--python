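"""The multi-task network: shared trunk, classification and regression heads.

A fully connected trunk (default input -> 109 -> 35; batch normalisation,
ReLU, dropout 0.20) feeds two heads: eight sigmoid outputs selecting
muscle-procedure labels, and eight linear outputs for recession/resection
doses (clipped to 0-10 mm at inference).  Weights are Xavier-uniform
initialised; training uses Adam with weight decay, global gradient-norm
clipping and early stopping on validation loss.  Forward, backward and the
optimiser are implemented directly in numpy — the network is small (a few
thousand parameters) and trains on a CPU in seconds.

The regression head operates internally on a standardised dose scale whose
location/scale are fitted on the training targets; predictions are mapped
back to mm before clipping.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field

import numpy as np


@dataclass
class ModelConfig:
    """Architecture and optimisation hyper-parameters."""

    input_width: int = 10
    trunk_widths: tuple[int, ...] = (109, 35)
    dropout: float = 0.20
    learning_rate: float = 2.95e-3
    weight_decay: float = 1e-4
    batch_size: int = 64
    clip_norm: float = 1.0
    patience: int = 20
    max_epochs: int = 500
    # reduce-on-plateau: after early stopping fires, restore the best
    # parameters, multiply the learning rate by lr_decay_factor and continue
    # for up to lr_restarts further rounds (0 = plain early stopping)
    lr_restarts: int = 2
    lr_decay_factor: float = 0.2
    n_init: int = 2  # independent initialisations; best kept by validation loss
    seed: int = 0
    n_outputs: int = 8
    loss_lambda: float = 10.0  # task-mixing coefficient (regression term)
    mask_regression: bool = True  # train dose head on operated slots only

    def validate(self) -> None:
        if self.input_width < 1 or any(w < 1 for w in self.trunk_widths):
            raise ValueError("layer widths must be >= 1")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError(f"dropout must be in [0, 1), got {self.dropout}")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.patience < 1:
            raise ValueError("patience must be >= 1")
        if self.loss_lambda <= 0:
            raise ValueError("loss_lambda must be > 0")


@dataclass
class LossWeights:
    """Per-label positive-class weights and the task-mixing coefficient."""

    pos_weights: np.ndarray
    lam: float = 1.0

    @classmethod
    def from_labels(cls, Y: np.ndarray, lam: float = 1.0, cap: float = 20.0) -> "LossWeights":
        """Class-balanced weights (n - n_j) / n_j from training label counts,
        capped so that very rare labels do not dominate the loss."""
        Y = np.asarray(Y)
        n = Y.shape[0]
        n_pos = Y.sum(axis=0)
        with np.errstate(divide="ignore"):
            w = np.where(n_pos > 0, (n - n_pos) / np.maximum(n_pos, 1), cap)
        return cls(pos_weights=np.clip(w, 1e-6, cap), lam=lam)


def xavier_uniform(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    bound = math.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-bound, bound, size=(fan_in, fan_out))


def init_model(config: ModelConfig) -> dict[str, np.ndarray]:
    """Xavier-uniform weights, zero biases, unit batch-norm scale.

    Deterministic per ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    params: dict[str, np.ndarray] = {}
    widths = [config.input_width, *config.trunk_widths]
    for i in range(len(widths) - 1):
        params[f"W{i}"] = xavier_uniform(rng, widths[i], widths[i + 1])
        params[f"b{i}"] = np.zeros(widths[i + 1])
        params[f"gamma{i}"] = np.ones(widths[i + 1])
        params[f"beta{i}"] = np.zeros(widths[i + 1])
    h = widths[-1]
    params["Wc"] = xavier_uniform(rng, h, config.n_outputs)
    params["bc"] = np.zeros(config.n_outputs)
    # regression head: shared base column + per-slot deltas (hierarchical
    # shrinkage — weight decay pulls slot-specific behaviour toward the
    # shared dose predictor, so rare labels borrow strength)
    params["Wr0"] = xavier_uniform(rng, h, 1)
    params["br0"] = np.zeros(1)
    params["Wr"] = np.zeros((h, config.n_outputs))
    params["br"] = np.zeros(config.n_outputs)
    return params


def count_params(params: dict[str, np.ndarray]) -> int:
    return int(sum(v.size for v in params.values()))


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _softplus(z: np.ndarray) -> np.ndarray:
    return np.maximum(z, 0.0) + np.log1p(np.exp(-np.abs(z)))


def multitask_loss(
    probs: np.ndarray,
    doses: np.ndarray,
    labels: np.ndarray,
    true_doses: np.ndarray,
    weights: LossWeights,
    eps: float = 1e-7,
    dose_mask: np.ndarray | None = None,
) -> float:
    """Weighted binary cross-entropy + lambda * MSE, averaged over all slots.

    The classification term weights the positive class of label j by
    ``weights.pos_weights[j]``; probabilities are clamped to
    ``(eps, 1 - eps)``.  The dose term runs over all 8 outputs with target
    0 mm for unoperated muscles unless ``dose_mask`` restricts it.
    """
    probs = np.asarray(probs, dtype=float)
    doses = np.asarray(doses, dtype=float)
    labels = np.asarray(labels, dtype=float)
    true_doses = np.asarray(true_doses, dtype=float)
    if not (np.isfinite(probs).all() and np.isfinite(doses).all()):
        raise FloatingPointError("non-finite prediction passed to multitask_loss")
    p = np.clip(probs, eps, 1.0 - eps)
    w = weights.pos_weights
    bce = -(w * labels * np.log(p) + (1.0 - labels) * np.log(1.0 - p))
    cls_term = float(bce.mean())
    if dose_mask is None:
        reg_term = float(((doses - true_doses) ** 2).mean())
    else:
        m = np.asarray(dose_mask, dtype=float)
        denom = max(m.sum(), 1.0)
        reg_term = float((m * (doses - true_doses) ** 2).sum() / denom)
    return cls_term + weights.lam * reg_term


def clip_gradients(grads: dict[str, np.ndarray], clip_norm: float) -> float:
    """Scale gradients in place so their global L2 norm is <= clip_norm.

    Returns the pre-clipping norm.
    """
    total = math.sqrt(sum(float((g ** 2).sum()) for g in grads.values()))
    if total > clip_norm and total > 0:
        scale = clip_norm / total
        for g in grads.values():
            g *= scale
    return total


class EarlyStopper:
    """Patience-based early stopping bookkeeping on a validation loss."""

    def __init__(self, patience: int):
        self.patience = patience
        self.best = math.inf
        self.best_epoch = 0
        self.bad_epochs = 0

    def update(self, epoch: int, loss: float) -> bool:
        """Record this epoch's validation loss; return True to stop."""
        if loss < self.best:
            self.best = loss
            self.best_epoch = epoch
            self.bad_epochs = 0
            return False
        self.bad_epochs += 1
        return self.bad_epochs >= self.patience


class TrainingDiverged(RuntimeError):
    pass


class MultiTaskNet:
    """Shared-trunk multi-task network with manual numpy backprop."""

    BN_MOMENTUM = 0.1
    BN_EPS = 1e-5

    def __init__(self, config: ModelConfig):
        config.validate()
        self.config = config
        self.params = init_model(config)
        self.n_trunk = len(config.trunk_widths)
        # batch-norm running statistics (inference mode)
        self.running_mean = [np.zeros(w) for w in config.trunk_widths]
        self.running_var = [np.ones(w) for w in config.trunk_widths]
        # dose target scale (identity until train() fits it)
        self.dose_loc = np.zeros(config.n_outputs)
        self.dose_scale = np.ones(config.n_outputs)
        self._adam_m = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._adam_v = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._adam_t = 0

    # ------------------------------------------------------------------ #
    @property
    def n_params(self) -> int:
        return count_params(self.params)

    def _forward(self, X: np.ndarray, training: bool, rng: np.random.Generator | None):
        """Trunk + heads; returns (logits, reg_std, cache)."""
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.config.input_width:
            raise ValueError(
                f"feature width {X.shape[-1] if X.ndim == 2 else X.shape} does "
                f"not match input_width {self.config.input_width}"
            )
        cache = {"X": X, "layers": []}
        h = X
        for i in range(self.n_trunk):
            z = h @ self.params[f"W{i}"] + self.params[f"b{i}"]
            if training:
                mu = z.mean(axis=0)
                var = z.var(axis=0)
                self.running_mean[i] = (
                    (1 - self.BN_MOMENTUM) * self.running_mean[i] + self.BN_MOMENTUM * mu
                )
                self.running_var[i] = (
                    (1 - self.BN_MOMENTUM) * self.running_var[i] + self.BN_MOMENTUM * var
                )
            else:
                mu = self.running_mean[i]
                var = self.running_var[i]
            inv_std = 1.0 / np.sqrt(var + self.BN_EPS)
            zhat = (z - mu) * inv_std
            a_pre = self.params[f"gamma{i}"] * zhat + self.params[f"beta{i}"]
            relu_mask = a_pre > 0
            a = a_pre * relu_mask
            if training and self.config.dropout > 0:
                if rng is None:
                    rng = np.random.default_rng(self.config.seed)
                keep = 1.0 - self.config.dropout
                drop_mask = (rng.random(a.shape) < keep) / keep
                a = a * drop_mask
            else:
                drop_mask = None
            cache["layers"].append(
                {
                    "h_in": h,
                    "zhat": zhat,
                    "inv_std": inv_std,
                    "relu_mask": relu_mask,
                    "drop_mask": drop_mask,
                    "batch": training,
                }
            )
            h = a
        logits = h @ self.params["Wc"] + self.params["bc"]
        reg = (
            h @ (self.params["Wr0"] + self.params["Wr"])
            + self.params["br0"]
            + self.params["br"]
        )
        cache["h_last"] = h
        return logits, reg, cache

    def forward(
        self, X: np.ndarray, training: bool = False, rng: np.random.Generator | None = None
    ) -> tuple[np.ndarray, np.ndarray]:
        """Probabilities in [0,1] and doses in mm clipped to [0, 10].

        Dropout and batch-statistics normalisation are active only when
        ``training`` is set; inference is deterministic.
        """
        logits, reg, _ = self._forward(X, training, rng)
        probs = _sigmoid(logits)
        doses = np.clip(reg * self.dose_scale + self.dose_loc, 0.0, 10.0)
        return probs, doses

    def predict_logits(self, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Raw classification logits and doses in mm (eval mode)."""
        logits, reg, _ = self._forward(X, training=False, rng=None)
        doses = np.clip(reg * self.dose_scale + self.dose_loc, 0.0, 10.0)
        return logits, doses

    # ------------------------------------------------------------------ #
    def _loss_and_grads(
        self,
        X: np.ndarray,
        Y: np.ndarray,
        D_std: np.ndarray,
        weights: LossWeights,
        rng: np.random.Generator,
        dose_mask: np.ndarray | None,
        training: bool = True,
    ):
        logits, reg, cache = self._forward(X, training, rng)
        n, k = logits.shape
        w = weights.pos_weights
        s = _sigmoid(logits)
        # weighted BCE with logits, mean over n*k slots
        bce = w * Y * _softplus(-logits) + (1.0 - Y) * _softplus(logits)
        cls_loss = float(bce.mean())
        if dose_mask is None:
            resid = reg - D_std
            reg_loss = float((resid ** 2).mean())
            d_reg = 2.0 * weights.lam * resid / (n * k)
        else:
            m = dose_mask.astype(float)
            denom = max(float(m.sum()), 1.0)
            resid = (reg - D_std) * m
            reg_loss = float((resid ** 2).sum() / denom)
            d_reg = 2.0 * weights.lam * resid / denom
        loss = cls_loss + weights.lam * reg_loss
        if not math.isfinite(loss):
            raise TrainingDiverged(f"loss became non-finite ({loss})")

        d_logits = (-w * Y * (1.0 - s) + (1.0 - Y) * s) / (n * k)

        grads = {k_: np.zeros_like(v) for k_, v in self.params.items()}
        h = cache["h_last"]
        grads["Wc"] = h.T @ d_logits
        grads["bc"] = d_logits.sum(axis=0)
        dW_eff = h.T @ d_reg
        grads["Wr"] = dW_eff
        grads["Wr0"] = dW_eff.sum(axis=1, keepdims=True)
        grads["br"] = d_reg.sum(axis=0)
        grads["br0"] = np.array([d_reg.sum()])
        W_eff = self.params["Wr0"] + self.params["Wr"]
        dh = d_logits @ self.params["Wc"].T + d_reg @ W_eff.T

        for i in range(self.n_trunk - 1, -1, -1):
            layer = cache["layers"][i]
            if layer["drop_mask"] is not None:
                dh = dh * layer["drop_mask"]
            dh = dh * layer["relu_mask"]
            zhat = layer["zhat"]
            grads[f"gamma{i}"] = (dh * zhat).sum(axis=0)
            grads[f"beta{i}"] = dh.sum(axis=0)
            dzhat = dh * self.params[f"gamma{i}"]
            if layer["batch"]:
                m_rows = dh.shape[0]
                dz = (
                    layer["inv_std"]
                    / m_rows
                    * (
                        m_rows * dzhat
                        - dzhat.sum(axis=0)
                        - zhat * (dzhat * zhat).sum(axis=0)
                    )
                )
            else:
                dz = dzhat * layer["inv_std"]
            grads[f"W{i}"] = layer["h_in"].T @ dz
            grads[f"b{i}"] = dz.sum(axis=0)
            dh = dz @ self.params[f"W{i}"].T
        return loss, grads

    def _adam_step(self, grads: dict[str, np.ndarray], lr: float | None = None):
        cfg = self.config
        lr = cfg.learning_rate if lr is None else lr
        self._adam_t += 1
        t = self._adam_t
        b1, b2, eps = 0.9, 0.999, 1e-8
        for key, p in self.params.items():
            g = grads[key]
            if cfg.weight_decay > 0 and key.startswith(("W",)):
                g = g + cfg.weight_decay * p
            m = self._adam_m[key] = b1 * self._adam_m[key] + (1 - b1) * g
            v = self._adam_v[key] = b2 * self._adam_v[key] + (1 - b2) * g * g
            mhat = m / (1 - b1 ** t)
            vhat = v / (1 - b2 ** t)
            p -= lr * mhat / (np.sqrt(vhat) + eps)

    def evaluate_loss(
        self, X: np.ndarray, Y: np.ndarray, D_mm: np.ndarray, weights: LossWeights
    ) -> float:
        """Validation loss in eval mode on the standardised dose scale."""
        D_std = (D_mm - self.dose_loc) / self.dose_scale
        mask = Y.astype(bool) if self.config.mask_regression else None
        logits, reg, _ = self._forward(X, training=False, rng=None)
        probs = _sigmoid(logits)
        return multitask_loss(
            probs, reg, Y, D_std, weights, dose_mask=mask
        )

    def train(
        self,
        X_train: np.ndarray,
        Y_train: np.ndarray,
        D_train: np.ndarray,
        X_val: np.ndarray,
        Y_val: np.ndarray,
        D_val: np.ndarray,
        weights: LossWeights | None = None,
    ) -> dict:
        """Adam training with gradient clipping and early stopping.

        Returns a log dict with per-epoch train/validation losses, the best
        epoch, and the stopping epoch; the network is left holding the
        parameters of the best validation epoch.
        """
        cfg = self.config
        if len(X_train) == 0 or len(X_val) == 0:
            raise ValueError("train and validation sets must be non-empty")
        rng = np.random.default_rng(cfg.seed)
        weights = weights or LossWeights.from_labels(Y_train, lam=cfg.loss_lambda)
        weights = LossWeights(pos_weights=weights.pos_weights, lam=cfg.loss_lambda)

        # dose target scale: operated doses when masking (the head models
        # "dose given operated"), otherwise all slots including zeros
        if cfg.mask_regression and Y_train.any():
            ref = D_train[Y_train.astype(bool)]
        else:
            ref = D_train
        self.dose_loc = np.full(cfg.n_outputs, float(ref.mean()))
        scale = float(ref.std())
        self.dose_scale = np.full(cfg.n_outputs, scale if scale > 0 else 1.0)
        D_tr_std = (D_train - self.dose_loc) / self.dose_scale

        log = {"train_loss": [], "val_loss": [], "grad_norms": [], "lr_stages": []}
        best_state = None
        best_loss = math.inf
        best_epoch = 0
        n = len(X_train)
        epoch = 0
        lr = cfg.learning_rate
        for stage in range(cfg.lr_restarts + 1):
            stopper = EarlyStopper(cfg.patience)
            stopper.best = best_loss
            log["lr_stages"].append(lr)
            stage_stopped = False
            while epoch < cfg.max_epochs:
                epoch += 1
                order = rng.permutation(n)
                epoch_loss = 0.0
                n_batches = 0
                for start in range(0, n, cfg.batch_size):
                    idx = order[start : start + cfg.batch_size]
                    if len(idx) < 2:
                        continue  # batch-norm needs at least two rows
                    mask = (
                        Y_train[idx].astype(bool) if cfg.mask_regression else None
                    )
                    loss, grads = self._loss_and_grads(
                        X_train[idx], Y_train[idx], D_tr_std[idx], weights, rng, mask
                    )
                    norm = clip_gradients(grads, cfg.clip_norm)
                    self._adam_step(grads, lr)
                    epoch_loss += loss
                    n_batches += 1
                    log["grad_norms"].append(norm)
                log["train_loss"].append(epoch_loss / max(n_batches, 1))
                val_loss = self.evaluate_loss(X_val, Y_val, D_val, weights)
                log["val_loss"].append(val_loss)
                improved = val_loss < best_loss
                stop = stopper.update(epoch, val_loss)
                if improved:
                    best_loss = val_loss
                    best_epoch = epoch
                    best_state = (
                        copy.deepcopy(self.params),
                        copy.deepcopy(self.running_mean),
                        copy.deepcopy(self.running_var),
                    )
                if stop:
                    stage_stopped = True
                    break
            # restore the best checkpoint before decaying the learning rate
            if best_state is not None:
                self.params = copy.deepcopy(best_state[0])
                self.running_mean = copy.deepcopy(best_state[1])
                self.running_var = copy.deepcopy(best_state[2])
            if not stage_stopped:
                break  # max_epochs exhausted
            lr *= cfg.lr_decay_factor
        if best_state is not None:
            self.params, self.running_mean, self.running_var = best_state
        log["best_epoch"] = best_epoch
        log["stopped_epoch"] = epoch
        log["best_val_loss"] = best_loss
        log["weights"] = weights
        return log
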