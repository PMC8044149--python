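"""Linear vector-autoregressive baseline (the Granger-causality workhorse).

A VAR(P) models each region's next value as a linear function of the last
``P`` values of *all* regions::

    x(t) = b + A_1 x(t-1) + ... + A_P x(t-P) + u(t)

Two fitting routes are provided: a closed-form least-squares fit on the
raw session time courses (pooling the lagged design across sessions), and
a stochastic-gradient fit that minimizes the iterated multi-step forecast
MAE on the same windowed samples the recurrent model trains on, so both
model families are optimized for the same objective. Multi-step forecasts
feed each one-step prediction back as input. An augmented Dickey-Fuller
unit-root check is reported per region (the model is still fit when some
rows fail it, mirroring common practice).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from statsmodels.tsa.stattools import adfuller

from . import autodiff as ad
from .preprocess import GraphSignalSequence, WindowedDataset

__all__ = ["VARModel", "var_fit_ols", "var_fit_sgd", "var_forecast",
           "adf_gate", "adf_report", "var_evaluate_horizons"]


@dataclass
class VARModel:
    """Coefficients of a fitted VAR(P): lag matrices ``A_1..A_P`` and intercept."""

    lag_order: int
    coeffs: np.ndarray  # (P, N, N)
    intercept: np.ndarray  # (N,)

    def __post_init__(self) -> None:
        c = np.asarray(self.coeffs, dtype=float)
        b = np.asarray(self.intercept, dtype=float)
        if self.lag_order < 1:
            raise ValueError("lag order must be >= 1")
        if c.shape != (self.lag_order, b.size, b.size):
            raise ValueError(f"coeffs shape {c.shape} inconsistent with "
                             f"P={self.lag_order}, N={b.size}")
        if not (np.all(np.isfinite(c)) and np.all(np.isfinite(b))):
            raise ValueError("model parameters must be finite")
        self.coeffs = c
        self.intercept = b

    @property
    def n_regions(self) -> int:
        return self.intercept.size


def _lagged_design(x: np.ndarray, p: int) -> tuple[np.ndarray, np.ndarray]:
    """Build (rows = usable timepoints) design [1, x(t-1).. x(t-p)] and targets."""
    n, t = x.shape
    rows = t - p
    design = np.empty((rows, 1 + n * p))
    design[:, 0] = 1.0
    for lag in range(1, p + 1):
        design[:, 1 + (lag - 1) * n:1 + lag * n] = x[:, p - lag:t - lag].T
    targets = x[:, p:].T
    return design, targets


def var_fit_ols(
    x: GraphSignalSequence | list[GraphSignalSequence], p: int
) -> VARModel:
    """Closed-form least-squares fit of a VAR(P).

    Accepts one session or a list of sessions; lagged designs never cross
    session boundaries. Raises if the stacked design is rank-deficient.
    """
    sessions = x if isinstance(x, list) else [x]
    n = sessions[0].n_regions
    designs, targets = [], []
    for s in sessions:
        if s.n_regions != n:
            raise ValueError("sessions disagree on region count")
        if s.n_timepoints <= n * p + 1:
            raise ValueError(
                f"T={s.n_timepoints} too short to identify VAR({p}) with N={n}"
            )
        d, y = _lagged_design(s.data, p)
        designs.append(d)
        targets.append(y)
    design = np.vstack(designs)
    target = np.vstack(targets)
    beta, _, rank, _ = np.linalg.lstsq(design, target, rcond=None)
    if rank < design.shape[1]:
        raise np.linalg.LinAlgError(
            f"singular lagged design (rank {rank} < {design.shape[1]})"
        )
    intercept = beta[0]
    coeffs = np.stack([beta[1 + k * n:1 + (k + 1) * n].T for k in range(p)])
    return VARModel(lag_order=p, coeffs=coeffs, intercept=intercept)


def var_forecast(m: VARModel, history: np.ndarray, t_f: int) -> np.ndarray:
    """Iterated multi-step forecast; each step feeds back its own output.

    ``history`` is ``(N, >= P)``; returns ``(N, t_f)``.
    """
    history = np.asarray(history, dtype=float)
    if history.shape[1] < m.lag_order:
        raise ValueError(
            f"history has {history.shape[1]} frames, need >= {m.lag_order}"
        )
    buf = list(history[:, -m.lag_order:].T)  # most recent last
    out = np.empty((m.n_regions, t_f))
    for t in range(t_f):
        nxt = m.intercept.copy()
        for lag in range(1, m.lag_order + 1):
            nxt += m.coeffs[lag - 1] @ buf[-lag]
        out[:, t] = nxt
        buf.append(nxt)
        buf.pop(0)
    return out


def var_fit_sgd(
    data: WindowedDataset,
    p: int,
    lr: float = 0.005,
    epochs: int = 100,
    decay_epochs: tuple[int, ...] = (70, 90),
    lr_decay: float = 0.1,
    batch_size: int = 1,
    seed: int = 0,
    partition: str | None = "train",
) -> VARModel:
    """Gradient fit minimizing the iterated T_f-step forecast MAE.

    Trains on the same windowed samples as the recurrent model, with
    stochastic gradient descent (default batch of 1), annealing the
    learning rate by ``lr_decay`` at ``decay_epochs``. Coefficients start
    at zero. Window inputs must span at least ``p`` frames.
    """
    ds = (data.partition(partition)
          if partition and data.split_index is not None else data)
    if len(ds) == 0:
        raise ValueError("no samples to fit on")
    if ds.t_p < p:
        raise ValueError(f"window length {ds.t_p} shorter than lag order {p}")
    n = ds.inputs[0].shape[0]
    lag_mats = [ad.Var(np.zeros((n, n)), requires_grad=True) for _ in range(p)]
    intercept = ad.Var(np.zeros((n, 1)), requires_grad=True)
    params = lag_mats + [intercept]
    rng = np.random.default_rng(seed)

    for epoch in range(epochs):
        if epoch in decay_epochs:
            lr *= lr_decay
        order = rng.permutation(len(ds))
        for start in range(0, len(order), batch_size):
            idx = order[start:start + batch_size]
            x = np.stack([ds.inputs[i] for i in idx])   # (B, N, t_p)
            y = np.stack([ds.targets[i] for i in idx])  # (B, N, t_f)
            buf = [ad.const(x[:, :, -lag][:, :, None])
                   for lag in range(p, 0, -1)]  # oldest first, each (B, N, 1)
            preds = []
            for _ in range(ds.t_f):
                step = ad.const(np.zeros((idx.size, n, 1))) + intercept
                for lag in range(1, p + 1):
                    step = step + ad.left_matmul(lag_mats[lag - 1], buf[-lag])
                preds.append(step)
                buf.append(step)
                buf.pop(0)
            pred = ad.concat(preds, axis=-1)
            loss = ad.mean_abs_error(pred, y)
            if not np.isfinite(loss.value):
                raise FloatingPointError("VAR SGD fit diverged")
            for var in params:
                var.grad = None
            ad.backward(loss)
            for var in params:
                if var.grad is not None:
                    var.value = var.value - lr * var.grad
    return VARModel(lag_order=p,
                    coeffs=np.stack([a.value.copy() for a in lag_mats]),
                    intercept=intercept.value[:, 0].copy())


def adf_gate(row: np.ndarray, alpha: float = 0.01) -> str:
    """Augmented Dickey-Fuller stationarity verdict for one time course.

    Returns ``"stationary"`` when the unit-root null is rejected at
    ``alpha``; lag order is chosen automatically by AIC.
    """
    row = np.asarray(row, dtype=float)
    if row.size < 20:
        raise ValueError("ADF gate needs at least 20 timepoints")
    if np.ptp(row) == 0:
        raise ValueError("constant series has no unit-root test")
    _, pvalue, *_ = adfuller(row, autolag="AIC")
    return "stationary" if pvalue < alpha else "nonstationary"


def adf_report(x: GraphSignalSequence, alpha: float = 0.01) -> dict:
    """Per-region ADF verdicts plus the fraction of nonstationary rows."""
    verdicts = [adf_gate(row, alpha) for row in x.data]
    frac = verdicts.count("nonstationary") / len(verdicts)
    return {"verdicts": verdicts, "fraction_nonstationary": frac}


def var_evaluate_horizons(
    m: VARModel, test: WindowedDataset
) -> tuple[np.ndarray, float]:
    """Per-horizon free-running MAE of the VAR on windowed test samples."""
    if len(test) == 0:
        raise ValueError("test partition is empty")
    sums = np.zeros(test.t_f)
    for x, y in zip(test.inputs, test.targets):
        pred = var_forecast(m, x, test.t_f)
        sums += np.abs(y - pred).mean(axis=0)
    per_horizon = sums / len(test)
    return per_horizon, float(per_horizon.mean())
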