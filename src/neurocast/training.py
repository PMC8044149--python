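"""Scheduled-sampling BPTT training of the graph seq2seq forecaster.

Training minimizes the mean absolute error of the decoder outputs with
Adam on shuffled mini-batches. Early in training the decoder mostly sees
ground-truth previous frames (teacher forcing); the probability of that
decays with the global iteration count along an inverse sigmoid, so the
model is gradually weaned onto its own predictions (scheduled sampling).
The learning rate anneals by a fixed factor at preset epochs or when the
validation error plateaus, and the best-validation weights are restored
before every decay and at the end.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import autodiff as ad
from .model import Seq2SeqModel
from .preprocess import WindowedDataset

__all__ = ["TrainConfig", "TrainHistory", "scheduled_sampling_prob", "mae",
           "train", "finetune", "evaluate_horizons", "Adam"]


@dataclass
class TrainConfig:
    """Hyperparameters of the training loop.

    Defaults follow the reference full-scale setup: 70 epochs, batches of
    32, Adam starting at 0.1 decayed by 0.1 at epochs 20/40/60 or on a
    10-epoch validation plateau, and sampling-decay constant tau = 5000.
    ``finetune_lr`` (0.001) is the lowered rate used when continuing from
    pretrained weights.
    """

    epochs: int = 70
    batch_size: int = 32
    lr_init: float = 0.1
    lr_decay: float = 0.1
    decay_epochs: tuple[int, ...] = (20, 40, 60)
    plateau_patience: int = 10
    tau: float = 5000.0
    finetune_lr: float = 0.001
    grad_clip: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs < 0 or self.batch_size <= 0 or self.lr_init <= 0:
            raise ValueError("epochs, batch_size, lr_init must be positive")
        if self.tau <= 0:
            raise ValueError("tau must be positive")
        if list(self.decay_epochs) != sorted(self.decay_epochs):
            raise ValueError("decay_epochs must be sorted")


@dataclass
class TrainHistory:
    """Per-epoch trace of a training run."""

    train_mae: list[float] = field(default_factory=list)
    val_mae: list[float] = field(default_factory=list)
    lr: list[float] = field(default_factory=list)
    sampling_prob: list[float] = field(default_factory=list)
    best_epoch: int = -1
    tag: str = "train"

    @property
    def best_val_mae(self) -> float:
        return min(self.val_mae) if self.val_mae else float("nan")


def scheduled_sampling_prob(iteration: int, tau: float) -> float:
    """Teacher-forcing probability ``tau / (tau + exp(i / tau))``.

    Inverse-sigmoid decay: ~1 for small iteration counts, 0.5 exactly at
    ``i = tau * ln(tau)``, and -> 0 as training proceeds.
    """
    if tau <= 0:
        raise ValueError("tau must be positive")
    if iteration < 0:
        raise ValueError("iteration must be >= 0")
    # guard the exponent so extreme iteration counts underflow to 0 cleanly
    z = iteration / tau
    if z > 700:
        return 0.0
    return tau / (tau + np.exp(z))


def mae(truth: np.ndarray, pred: np.ndarray) -> float:
    """Mean absolute error over all timepoints, nodes and samples."""
    truth = np.asarray(truth, dtype=float)
    pred = np.asarray(pred, dtype=float)
    if truth.shape != pred.shape:
        raise ValueError(f"shape mismatch {truth.shape} vs {pred.shape}")
    return float(np.mean(np.abs(truth - pred)))


class Adam:
    """Adam optimizer over the model's named parameter dict."""

    def __init__(self, params: dict[str, ad.Var], lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = {k: np.zeros_like(v.value) for k, v in params.items()}
        self.v = {k: np.zeros_like(v.value) for k, v in params.items()}
        self.t = 0

    def step(self, grad_clip: float | None = None) -> None:
        grads = {k: p.grad for k, p in self.params.items() if p.grad is not None}
        if grad_clip is not None and grads:
            total = np.sqrt(sum(float(np.sum(g * g)) for g in grads.values()))
            if total > grad_clip:
                scale = grad_clip / total
                grads = {k: g * scale for k, g in grads.items()}
        self.t += 1
        for k, g in grads.items():
            self.m[k] = self.beta1 * self.m[k] + (1 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1 - self.beta2) * g * g
            mhat = self.m[k] / (1 - self.beta1 ** self.t)
            vhat = self.v[k] / (1 - self.beta2 ** self.t)
            self.params[k].value = (
                self.params[k].value - self.lr * mhat / (np.sqrt(vhat) + self.eps)
            )

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.grad = None


def _stack(ds: WindowedDataset, idx: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    x = np.stack([ds.inputs[i] for i in idx])
    y = np.stack([ds.targets[i] for i in idx])
    return x, y


def _validation_mae(model: Seq2SeqModel, ds: WindowedDataset,
                    batch_size: int = 256) -> float:
    """Free-running MAE over a partition (decoder feeds back its output)."""
    errs, weights = [], []
    for start in range(0, len(ds), batch_size):
        idx = np.arange(start, min(start + batch_size, len(ds)))
        x, y = _stack(ds, idx)
        pred = model.forecast(x, ds.t_f)
        errs.append(mae(y, pred))
        weights.append(idx.size)
    return float(np.average(errs, weights=weights))


def train(model: Seq2SeqModel, data: WindowedDataset, cfg: TrainConfig,
          log=None) -> tuple[Seq2SeqModel, TrainHistory]:
    """Scheduled-sampling Adam training; returns the best-validation weights.

    Mini-batches are drawn in a fresh random order each epoch. One global
    iteration counter ``i`` advances per mini-batch and sets the
    teacher-forcing probability; the Bernoulli draw is made per decoder
    time-step per batch. The learning rate is multiplied by ``lr_decay``
    at each epoch in ``decay_epochs`` and whenever the validation MAE has
    not improved for ``plateau_patience`` epochs, restoring the
    best-validation weights before each decay.
    """
    train_ds = data.partition("train")
    val_ds = data.partition("val")
    if len(train_ds) == 0 or len(val_ds) == 0:
        raise ValueError("train and validation partitions must be non-empty")

    rng = np.random.default_rng(cfg.seed)
    history = TrainHistory()
    optimizer = Adam(model.parameters(), cfg.lr_init)
    best_weights = model.get_weights()
    best_val = np.inf
    lr = cfg.lr_init
    iteration = 0
    stale = 0

    for epoch in range(cfg.epochs):
        if epoch in cfg.decay_epochs:
            model.set_weights(best_weights)
            lr *= cfg.lr_decay
        optimizer.lr = lr

        order = rng.permutation(len(train_ds))
        epoch_losses = []
        eps_epoch = scheduled_sampling_prob(iteration, cfg.tau)
        for start in range(0, len(order), cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            x, y = _stack(train_ds, idx)
            eps = scheduled_sampling_prob(iteration, cfg.tau)
            use_teacher = (rng.random(data.t_f) < eps).tolist()
            optimizer.zero_grad()
            states = model.encode(x)
            outputs = model.decode(states, data.t_f, teacher=y,
                                   use_teacher=use_teacher)
            pred = ad.concat(outputs, axis=-1)
            loss = ad.mean_abs_error(pred, y)
            if not np.isfinite(loss.value):
                raise FloatingPointError(
                    f"training diverged at epoch {epoch}, iteration "
                    f"{iteration}: loss={loss.value}"
                )
            ad.backward(loss)
            optimizer.step(grad_clip=cfg.grad_clip)
            epoch_losses.append(float(loss.value))
            iteration += 1

        val = _validation_mae(model, val_ds)
        history.train_mae.append(float(np.mean(epoch_losses)))
        history.val_mae.append(val)
        history.lr.append(lr)
        history.sampling_prob.append(eps_epoch)
        if log is not None:
            log(f"epoch={epoch} lr={lr:g} eps={eps_epoch:.4f} "
                f"train_mae={history.train_mae[-1]:.5f} val_mae={val:.5f}")

        if val < best_val:
            best_val = val
            best_weights = model.get_weights()
            history.best_epoch = epoch
            stale = 0
        else:
            stale += 1
            if stale > cfg.plateau_patience:
                model.set_weights(best_weights)
                lr *= cfg.lr_decay
                stale = 0

    model.set_weights(best_weights)
    return model, history


def finetune(pretrained: Seq2SeqModel, data: WindowedDataset,
             cfg: TrainConfig, log=None) -> tuple[Seq2SeqModel, TrainHistory]:
    """Continue training pretrained weights at the lowered fine-tune rate."""
    cfg = replace(cfg, lr_init=cfg.finetune_lr)
    model, history = train(pretrained, data, cfg, log=log)
    history.tag = "finetune"
    return model, history


def evaluate_horizons(model: Seq2SeqModel, test: WindowedDataset,
                      batch_size: int = 256) -> tuple[np.ndarray, float]:
    """Free-running test MAE at each forecast step 1..T_f, plus the mean.

    The per-horizon value averages |error| over samples and nodes at that
    step only; the overall value is the mean across horizons.
    """
    if len(test) == 0:
        raise ValueError("test partition is empty")
    sums = np.zeros(test.t_f)
    count = 0
    for start in range(0, len(test), batch_size):
        idx = np.arange(start, min(start + batch_size, len(test)))
        x, y = _stack(test, idx)
        pred = model.forecast(x, test.t_f)
        sums += np.abs(y - pred).mean(axis=1).sum(axis=0)
        count += idx.size
    per_horizon = sums / count
    return per_horizon, float(per_horizon.mean())
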