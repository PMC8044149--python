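"""Session preprocessing: bandpass, global signal regression, scaling, windowing.

Turns a raw regional activity matrix ``X`` (N regions x T timepoints, one
row per parcel-averaged BOLD time course) into model-ready windowed samples.
The default pipeline order is bandpass -> global signal regression ->
per-session scaling, after which overlapping input/target window pairs are
cut and split 80/10/10 in temporal order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

__all__ = [
    "GraphSignalSequence",
    "WindowedDataset",
    "Scaler",
    "bandpass_filter",
    "global_signal_regression",
    "scale_session",
    "windowize",
    "split_samples",
    "preprocess_session",
]


@dataclass
class GraphSignalSequence:
    """An ``(N, T)`` regional activity matrix with its sampling interval.

    Rows are regions (graph nodes), columns are timepoints; ``tr_seconds``
    is the repetition time of the acquisition (0.72 s for the reference
    dataset this pipeline emulates).
    """

    data: np.ndarray
    tr_seconds: float
    node_labels: list[str] | None = None

    def __post_init__(self) -> None:
        x = np.asarray(self.data, dtype=float)
        if x.ndim != 2:
            raise ValueError(f"data must be 2-D (N, T), got shape {x.shape}")
        if x.shape[1] < 2:
            raise ValueError("need at least 2 timepoints")
        if not np.all(np.isfinite(x)):
            raise ValueError("data contains NaN or Inf")
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")
        if self.node_labels is not None and len(self.node_labels) != x.shape[0]:
            raise ValueError("node_labels length does not match row count")
        self.data = x

    @property
    def n_regions(self) -> int:
        return self.data.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[1]


@dataclass
class Scaler:
    """Invertible session scaling parameters (min-max or z-score)."""

    mode: str
    offset: float  # value mapped to 0
    scale: float   # divisor

    def transform(self, x: np.ndarray) -> np.ndarray:
        return (x - self.offset) / self.scale

    def inverse(self, y: np.ndarray) -> np.ndarray:
        return y * self.scale + self.offset

    @property
    def data_mean(self) -> float:
        """The raw-data mean expressed in scaled units.

        0 for z-scoring by construction; for min-max scaling the session
        mean lands strictly inside (0, 1).
        """
        return (self._raw_mean - self.offset) / self.scale

    _raw_mean: float = 0.0


@dataclass
class WindowedDataset:
    """Overlapping (input, target) window pairs with an 80/10/10 split.

    From a session of ``T`` timepoints, windows of ``t_p`` past frames and
    ``t_f`` future frames give ``T - t_p - t_f + 1`` consecutive samples;
    ``split_index[i]`` is 0/1/2 for train/val/test, assigned in temporal
    order per session.
    """

    inputs: list[np.ndarray]
    targets: list[np.ndarray]
    t_p: int
    t_f: int
    session_id: np.ndarray = field(default=None)  # type: ignore[assignment]
    split_index: np.ndarray | None = None

    def __post_init__(self) -> None:
        if len(self.inputs) != len(self.targets):
            raise ValueError("inputs and targets differ in length")
        if self.session_id is None:
            self.session_id = np.zeros(len(self.inputs), dtype=int)

    def __len__(self) -> int:
        return len(self.inputs)

    def partition(self, which: str) -> "WindowedDataset":
        """Return the train/val/test subset (split must have been assigned)."""
        codes = {"train": 0, "val": 1, "test": 2}
        if self.split_index is None:
            raise ValueError("dataset has no split; call split_samples first")
        keep = np.flatnonzero(self.split_index == codes[which])
        return WindowedDataset(
            inputs=[self.inputs[i] for i in keep],
            targets=[self.targets[i] for i in keep],
            t_p=self.t_p,
            t_f=self.t_f,
            session_id=self.session_id[keep],
            split_index=self.split_index[keep],
        )


def bandpass_filter(
    x: GraphSignalSequence, low_hz: float, high_hz: float, order: int = 5
) -> GraphSignalSequence:
    """Zero-phase Butterworth bandpass applied identically to every region.

    Forward-backward (``sosfiltfilt``) application preserves signal shape
    (no phase shift); DC is out of band, so each output row is ~zero-mean.
    The default band for the data this emulates is 0.04-0.07 Hz.
    """
    nyquist = 0.5 / x.tr_seconds
    if not 0 < low_hz < high_hz < nyquist:
        raise ValueError(
            f"band ({low_hz}, {high_hz}) Hz must satisfy "
            f"0 < low < high < Nyquist ({nyquist:.4f} Hz)"
        )
    sos = sps.butter(order, [low_hz, high_hz], btype="bandpass",
                     fs=1.0 / x.tr_seconds, output="sos")
    filtered = sps.sosfiltfilt(sos, x.data, axis=1)
    return GraphSignalSequence(filtered, x.tr_seconds, x.node_labels)


def global_signal_regression(x: GraphSignalSequence) -> GraphSignalSequence:
    """Regress the across-region mean time course out of every region.

    Each row is replaced by its residual from an ordinary least-squares fit
    on the global signal plus intercept, leaving every residual orthogonal
    to the global time course. Removes global modulations (e.g. residual
    motion or respiration effects) so that local interactions dominate.
    """
    if x.n_regions < 2:
        raise ValueError("global signal regression needs at least 2 regions")
    g = x.data.mean(axis=0)
    if np.ptp(g) == 0:
        raise ValueError("global signal is constant; design is degenerate")
    design = np.column_stack([np.ones_like(g), g])          # (T, 2)
    beta, *_ = np.linalg.lstsq(design, x.data.T, rcond=None)
    residual = x.data - (design @ beta).T
    return GraphSignalSequence(residual, x.tr_seconds, x.node_labels)


def scale_session(
    x: GraphSignalSequence, mode: str = "minmax01"
) -> tuple[GraphSignalSequence, Scaler]:
    """Scale a whole session and keep the parameters for inversion.

    ``minmax01`` maps the session-wide minimum to 0 and maximum to 1 (the
    scaling used for model training); ``zscore`` maps to zero mean and unit
    variance (the scaling used for reporting errors in population units).
    """
    data = x.data
    if np.ptp(data) == 0:
        raise ValueError("cannot scale a constant session")
    if mode == "minmax01":
        scaler = Scaler(mode=mode, offset=float(data.min()),
                        scale=float(data.max() - data.min()))
    elif mode == "zscore":
        scaler = Scaler(mode=mode, offset=float(data.mean()),
                        scale=float(data.std()))
    else:
        raise ValueError(f"unknown scaling mode {mode!r}")
    scaler._raw_mean = float(data.mean())
    return (
        GraphSignalSequence(scaler.transform(data), x.tr_seconds, x.node_labels),
        scaler,
    )


def windowize(x: GraphSignalSequence, t_p: int, t_f: int,
              session_id: int = 0) -> WindowedDataset:
    """Cut all ``T - t_p - t_f + 1`` consecutive input/target window pairs.

    Sample ``i`` has input ``X[:, i:i+t_p]`` and target
    ``X[:, i+t_p:i+t_p+t_f]`` — the target starts at the timepoint
    immediately following the input.
    """
    t = x.n_timepoints
    if t < t_p + t_f:
        raise ValueError(
            f"session of T={t} too short for t_p={t_p}, t_f={t_f}"
        )
    n = t - t_p - t_f + 1
    inputs = [x.data[:, i:i + t_p] for i in range(n)]
    targets = [x.data[:, i + t_p:i + t_p + t_f] for i in range(n)]
    return WindowedDataset(inputs=inputs, targets=targets, t_p=t_p, t_f=t_f,
                           session_id=np.full(n, session_id, dtype=int))


def concat_windowed(parts: list[WindowedDataset]) -> WindowedDataset:
    """Concatenate per-session windowed datasets (window sizes must match)."""
    if not parts:
        raise ValueError("no datasets to concatenate")
    t_p, t_f = parts[0].t_p, parts[0].t_f
    if any(p.t_p != t_p or p.t_f != t_f for p in parts):
        raise ValueError("window sizes differ across sessions")
    split = None
    if all(p.split_index is not None for p in parts):
        split = np.concatenate([p.split_index for p in parts])
    return WindowedDataset(
        inputs=[w for p in parts for w in p.inputs],
        targets=[w for p in parts for w in p.targets],
        t_p=t_p,
        t_f=t_f,
        session_id=np.concatenate([p.session_id for p in parts]),
        split_index=split,
    )


def split_samples(
    ds: WindowedDataset,
    fractions: tuple[float, float, float] = (0.8, 0.1, 0.1),
    gap: int = 0,
) -> WindowedDataset:
    """Assign train/val/test labels per session, in temporal order.

    Flooring rule, applied per session with ``S`` samples: the *last*
    ``floor(f_test * S)`` samples are test, the ``floor(f_val * S)``
    before them validation, and everything earlier training — so with the
    reference session length (S=1141 at T=1200, t_p=t_f=30) the test set
    has exactly 114 samples. Every sample receives a label.

    ``gap > 0`` additionally discards ``gap`` samples before the val and
    test blocks (labels set to -1), removing the timepoint overlap that
    consecutive windows otherwise leak across split boundaries.
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    split = np.zeros(len(ds), dtype=int)
    for sid in np.unique(ds.session_id):
        idx = np.flatnonzero(ds.session_id == sid)
        s = idx.size
        n_test = int(np.floor(fractions[2] * s))
        n_val = int(np.floor(fractions[1] * s))
        n_train = s - n_val - n_test
        if min(n_train, n_val, n_test) <= 0:
            raise ValueError(
                f"session {sid} with {s} samples yields an empty partition"
            )
        split[idx[:n_train]] = 0
        split[idx[n_train:n_train + n_val]] = 1
        split[idx[n_train + n_val:]] = 2
        if gap > 0:
            split[idx[max(0, n_train - gap):n_train]] = -1
            split[idx[max(0, n_train + n_val - gap):n_train + n_val]] = -1
    return WindowedDataset(inputs=ds.inputs, targets=ds.targets, t_p=ds.t_p,
                           t_f=ds.t_f, session_id=ds.session_id,
                           split_index=split)


def preprocess_session(
    x: GraphSignalSequence,
    band: tuple[float, float] = (0.04, 0.07),
    gsr: bool = True,
    scale_mode: str = "minmax01",
) -> tuple[GraphSignalSequence, Scaler]:
    """Full per-session pipeline: bandpass -> GSR -> scale."""
    y = bandpass_filter(x, *band)
    if gsr:
        y = global_signal_regression(y)
    return scale_session(y, mode=scale_mode)
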