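"""Diffusion-convolutional GRU encoder-decoder for graph signal forecasting.

The recurrent cell is a gated recurrent unit whose dense matrix products
are replaced by diffusion convolutions over the structural graph::

    r(t) = sigmoid(Theta_r *G [x(t), H(t-1)] + b_r)
    u(t) = sigmoid(Theta_u *G [x(t), H(t-1)] + b_u)
    c(t) = tanh(Theta_c *G [x(t), r(t) . H(t-1)] + b_c)
    H(t) = u(t) . H(t-1) + (1 - u(t)) . c(t)

where ``*G`` is the truncated diffusion filter of :mod:`neurocast.graph`
applied to the node-wise feature concatenation, and ``.`` is elementwise.
A stack of such cells forms the encoder; a mirrored stack plus a per-node
linear readout forms the decoder, which starts from a zero "go" frame and
feeds back its own predictions (or, during scheduled-sampling training,
the ground truth). Filter parameters are shared across nodes, so the
parameter count is independent of the graph size.
"""

from __future__ import annotations

import json

import numpy as np

from . import autodiff as ad
from .graph import TransitionOperator

__all__ = ["DCGRUCell", "Seq2SeqModel", "dcgru_step",
           "save_checkpoint", "load_checkpoint"]


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


class DCGRUCell:
    """One diffusion-convolutional GRU layer.

    Parameters
    ----------
    input_size
        Feature count F of the per-node input.
    hidden_size
        Feature count Q of the hidden state.
    operator
        Transition operator of the structural graph.
    order
        Maximum diffusion walk order K (K=0 disables cross-node mixing).
    """

    def __init__(self, input_size: int, hidden_size: int,
                 operator: TransitionOperator, order: int,
                 rng: np.random.Generator, dtype=np.float32):
        if order < 0:
            raise ValueError("diffusion order K must be >= 0")
        self.input_size = input_size
        self.hidden_size = hidden_size
        self.operator = operator
        self.order = order
        self.dtype = np.dtype(dtype)
        self.n_matrices = 1 + order * operator.n_directions
        self._supports = [s.astype(self.dtype) for s in operator.supports()]
        fan_in = self.n_matrices * (input_size + hidden_size)
        q = hidden_size

        def p(a):
            return ad.Var(np.asarray(a, dtype=self.dtype), requires_grad=True)

        self.params = {
            "w_r": p(_glorot(rng, fan_in, q)),
            "w_u": p(_glorot(rng, fan_in, q)),
            "w_c": p(_glorot(rng, fan_in, q)),
            "b_r": p(np.zeros(q)),
            # positive update-gate bias starts the cell near "carry memory"
            "b_u": p(np.ones(q)),
            "b_c": p(np.zeros(q)),
        }

    def _diffused_features(self, xh: ad.Var) -> ad.Var:
        """Concatenate [xh, T xh, ..., T^K xh, T' xh, ...] along features."""
        terms = [xh]
        for support in self._supports:
            acc = xh
            for _ in range(self.order):
                acc = ad.apply_operator(support, acc)
                terms.append(acc)
        return ad.concat(terms, axis=-1) if len(terms) > 1 else xh

    def step(self, x: ad.Var, h: ad.Var) -> ad.Var:
        """Advance the hidden state by one frame; shapes ``(..., N, F/Q)``."""
        p = self.params
        xh = ad.concat([x, h], axis=-1)
        feats = self._diffused_features(xh)
        r = ad.sigmoid(ad.matmul(feats, p["w_r"]) + p["b_r"])
        u = ad.sigmoid(ad.matmul(feats, p["w_u"]) + p["b_u"])
        gated = ad.concat([x, r * h], axis=-1)
        c = ad.tanh(ad.matmul(self._diffused_features(gated), p["w_c"])
                    + p["b_c"])
        one = ad.const(self.dtype.type(1.0))
        return u * h + (one - u) * c


def dcgru_step(x_t: np.ndarray, h_prev: np.ndarray, cell: DCGRUCell) -> np.ndarray:
    """Numpy-facing single cell update (no gradient tape kept)."""
    out = cell.step(ad.const(x_t), ad.const(h_prev))
    if not np.all(np.isfinite(out.value)):
        raise FloatingPointError("non-finite activations in DCGRU step")
    return out.value


class Seq2SeqModel:
    """Stacked DCGRU encoder-decoder with a shared per-node linear readout.

    ``n_layers`` cells encode the input window into hidden states that seed
    an equally deep decoder. The decoder's first input is a zero frame; at
    each subsequent step it consumes either its previous prediction
    (validation/testing, and free-running training steps) or the previous
    ground-truth frame (teacher forcing).
    """

    def __init__(self, operator: TransitionOperator, hidden_size: int = 64,
                 order: int = 1, n_layers: int = 2, input_size: int = 1,
                 seed: int = 0, dtype=np.float32):
        rng = np.random.default_rng(seed)
        self.operator = operator
        self.hidden_size = hidden_size
        self.order = order
        self.n_layers = n_layers
        self.input_size = input_size
        self.dtype = np.dtype(dtype)
        self.encoder_cells = [
            DCGRUCell(input_size if i == 0 else hidden_size, hidden_size,
                      operator, order, rng, dtype=dtype)
            for i in range(n_layers)
        ]
        self.decoder_cells = [
            DCGRUCell(input_size if i == 0 else hidden_size, hidden_size,
                      operator, order, rng, dtype=dtype)
            for i in range(n_layers)
        ]
        self.w_out = ad.Var(_glorot(rng, hidden_size, input_size).astype(self.dtype),
                            requires_grad=True)
        self.b_out = ad.Var(np.zeros(input_size, dtype=self.dtype),
                            requires_grad=True)

    # ---- parameter bookkeeping -------------------------------------------
    def parameters(self) -> dict[str, ad.Var]:
        out: dict[str, ad.Var] = {}
        for tag, cells in (("enc", self.encoder_cells),
                           ("dec", self.decoder_cells)):
            for i, cell in enumerate(cells):
                for name, var in cell.params.items():
                    out[f"{tag}{i}.{name}"] = var
        out["w_out"] = self.w_out
        out["b_out"] = self.b_out
        return out

    def n_parameters(self) -> int:
        return sum(v.value.size for v in self.parameters().values())

    def get_weights(self) -> dict[str, np.ndarray]:
        return {k: v.value.copy() for k, v in self.parameters().items()}

    def set_weights(self, weights: dict[str, np.ndarray]) -> None:
        params = self.parameters()
        if set(weights) != set(params):
            raise ValueError("weight names do not match model architecture")
        for k, v in params.items():
            if v.value.shape != weights[k].shape:
                raise ValueError(f"shape mismatch for {k}")
            v.value = weights[k].astype(v.value.dtype)

    # ---- forward passes ---------------------------------------------------
    def _as_frames(self, inputs: np.ndarray) -> list[ad.Var]:
        """Split an (N, T) or (B, N, T) array into per-step (B, N, F) Vars."""
        x = np.asarray(inputs, dtype=self.dtype)
        if x.ndim == 2:
            x = x[None]
        return [ad.const(x[..., t:t + 1]) for t in range(x.shape[-1])]

    def encode(self, inputs: np.ndarray) -> list[ad.Var]:
        """Consume the input window; return final hidden state per layer."""
        frames = self._as_frames(inputs)
        batch, n = frames[0].value.shape[0], frames[0].value.shape[1]
        states = [ad.const(np.zeros((batch, n, self.hidden_size),
                                    dtype=self.dtype))
                  for _ in range(self.n_layers)]
        for frame in frames:
            layer_in = frame
            for i, cell in enumerate(self.encoder_cells):
                states[i] = cell.step(layer_in, states[i])
                layer_in = states[i]
        return states

    def decode(self, init: list[ad.Var], t_f: int,
               teacher: np.ndarray | None = None,
               use_teacher: list[bool] | None = None) -> list[ad.Var]:
        """Roll the decoder ``t_f`` steps; returns per-step (B, N, F) outputs.

        ``use_teacher[t]`` selects the ground-truth frame ``teacher[..., t]``
        as the input of step ``t + 1`` (scheduled sampling); free-running
        everywhere it is False or absent.
        """
        if t_f < 0:
            raise ValueError("t_f must be >= 0")
        if use_teacher is not None and teacher is None and any(use_teacher):
            raise ValueError("use_teacher set but no teacher sequence given")
        states = list(init)
        batch, n = init[0].value.shape[0], init[0].value.shape[1]
        go = ad.const(np.zeros((batch, n, self.input_size), dtype=self.dtype))
        teacher_frames = (self._as_frames(teacher)
                          if teacher is not None else None)
        outputs: list[ad.Var] = []
        layer_input = go
        for t in range(t_f):
            for i, cell in enumerate(self.decoder_cells):
                states[i] = cell.step(layer_input, states[i])
                layer_input = states[i]
            pred = ad.matmul(states[-1], self.w_out) + self.b_out
            outputs.append(pred)
            if t + 1 < t_f:
                if (use_teacher is not None and use_teacher[t]
                        and teacher_frames is not None):
                    layer_input = teacher_frames[t]
                else:
                    layer_input = pred
        return outputs

    def forecast(self, inputs: np.ndarray, t_f: int) -> np.ndarray:
        """Deterministic free-running prediction of the next ``t_f`` frames.

        Accepts ``(N, T_p)`` or ``(B, N, T_p)``; returns the matching
        ``(N, t_f)`` or ``(B, N, t_f)`` array.
        """
        x = np.asarray(inputs, dtype=self.dtype)
        single = x.ndim == 2
        outputs = self.decode(self.encode(x), t_f)
        pred = np.concatenate([o.value for o in outputs], axis=-1)
        return pred[0] if single else pred


# ---- checkpointing --------------------------------------------------------

CHECKPOINT_VERSION = 1


def save_checkpoint(model: Seq2SeqModel, path: str) -> None:
    """Write all parameter arrays plus an architecture manifest (.npz)."""
    manifest = {
        "version": CHECKPOINT_VERSION,
        "hidden_size": model.hidden_size,
        "order": model.order,
        "n_layers": model.n_layers,
        "input_size": model.input_size,
        "include_reverse": model.operator.include_reverse,
        "normalization": model.operator.normalization,
        "n_independent": True,  # filter weights shared across nodes
    }
    arrays = {k.replace(".", "__"): v for k, v in model.get_weights().items()}
    np.savez(path, __manifest__=json.dumps(manifest), **arrays)


def load_checkpoint(path: str, operator: TransitionOperator) -> Seq2SeqModel:
    """Rebuild a model on ``operator`` from a checkpoint archive.

    Because parameters are node-independent, the graph supplied here may
    have a different node count than the one the model was trained on, but
    the walk-direction configuration must match.
    """
    with np.load(path, allow_pickle=False) as archive:
        manifest = json.loads(str(archive["__manifest__"]))
        if manifest["version"] != CHECKPOINT_VERSION:
            raise ValueError(f"unsupported checkpoint version {manifest['version']}")
        if manifest["include_reverse"] != operator.include_reverse:
            raise ValueError("checkpoint walk directions do not match operator")
        weights = {k.replace("__", "."): archive[k] for k in archive.files
                   if k != "__manifest__"}
    model = Seq2SeqModel(operator, hidden_size=manifest["hidden_size"],
                         order=manifest["order"],
                         n_layers=manifest["n_layers"],
                         input_size=manifest["input_size"])
    model.set_weights(weights)
    return model
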