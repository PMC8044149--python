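"""Perturbation-based causal connectivity from a trained forecaster.

Following the Granger principle — a cause's past improves prediction of
its effect — the influence of a source region on every other region is
measured by silencing the source in the model input (replacing its time
course by the data-distribution mean) and quantifying how much each
region's forecast changes::

    I_n(sources) = mean_s mean_t | xhat_n(t) - xhat'_n(t) |

averaged over ``S`` evaluation samples and the ``T_f`` forecast steps,
where ``xhat`` and ``xhat'`` are the clean and perturbed forecasts. A
nonzero ``I_n`` means the source's past carried information the model
used to predict region ``n`` — a directed, multi-modal analogue of
Granger-causal connectivity constrained by the structural graph.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import Seq2SeqModel

__all__ = ["InfluenceMap", "perturb_inputs", "influence_map",
           "normalize_influence", "influence_matrix"]


@dataclass
class InfluenceMap:
    """Per-target influence of a (possibly joint) set of source regions."""

    sources: tuple[int, ...]
    influence: np.ndarray  # (N,), nonnegative
    n_samples: int
    normalized: np.ndarray | None = None
    node_labels: list[str] | None = None

    def __post_init__(self) -> None:
        inf = np.asarray(self.influence, dtype=float)
        if np.any(inf < 0) or not np.all(np.isfinite(inf)):
            raise ValueError("influence must be finite and nonnegative")
        self.influence = inf
        self.sources = tuple(int(s) for s in self.sources)


def perturb_inputs(sample: np.ndarray, sources,
                   fill_value: float = 0.0) -> np.ndarray:
    """Replace the source rows of an input window by the distribution mean.

    After z-scoring the data mean is 0, the default fill; for min-max
    scaled data pass the stored session mean instead. One or more sources
    may be silenced jointly (e.g. a functional area spanning two parcels).
    Non-source rows are returned bit-identical.
    """
    sources = np.atleast_1d(np.asarray(sources, dtype=int))
    if sources.size == 0:
        raise ValueError("source set must not be empty")
    sample = np.asarray(sample, dtype=float)
    if np.any(sources < 0) or np.any(sources >= sample.shape[0]):
        raise IndexError(f"source indices {sources.tolist()} out of range")
    out = sample.copy()
    out[sources, :] = fill_value
    return out


def influence_map(model: Seq2SeqModel, samples: list[np.ndarray],
                  sources, t_f: int, fill_value: float = 0.0,
                  node_labels: list[str] | None = None,
                  batch_size: int = 256) -> InfluenceMap:
    """Average forecast change per region when the sources are silenced."""
    if len(samples) == 0:
        raise ValueError("need at least one evaluation sample")
    sources = tuple(np.atleast_1d(np.asarray(sources, dtype=int)).tolist())
    n = samples[0].shape[0]
    total = np.zeros(n)
    for start in range(0, len(samples), batch_size):
        chunk = samples[start:start + batch_size]
        clean = np.stack(chunk)
        perturbed = np.stack([perturb_inputs(s, sources, fill_value)
                              for s in chunk])
        pred = model.forecast(clean, t_f)
        pred_p = model.forecast(perturbed, t_f)
        if not (np.all(np.isfinite(pred)) and np.all(np.isfinite(pred_p))):
            raise FloatingPointError("model produced non-finite forecasts")
        total += np.abs(pred - pred_p).mean(axis=2).sum(axis=0)
    return InfluenceMap(sources=sources, influence=total / len(samples),
                        n_samples=len(samples), node_labels=node_labels)


def normalize_influence(m: InfluenceMap,
                        exclude_sources: bool = True) -> InfluenceMap:
    """Affine rescale of the influence vector to the 0-100 range.

    By default the source self-entries are excluded from the scale (and
    clipped to 100), since self-influence conflates self-prediction with
    causal effect and would otherwise dominate the map.
    """
    values = m.influence
    mask = np.ones(values.size, dtype=bool)
    if exclude_sources:
        mask[list(m.sources)] = False
    ref = values[mask]
    lo, hi = ref.min(), ref.max()
    if hi == lo:
        raise ValueError("influence vector is constant; nothing to normalize")
    normalized = np.clip((values - lo) / (hi - lo) * 100.0, 0.0, 100.0)
    return InfluenceMap(sources=m.sources, influence=m.influence,
                        n_samples=m.n_samples, normalized=normalized,
                        node_labels=m.node_labels)


def influence_matrix(model: Seq2SeqModel, samples: list[np.ndarray],
                     t_f: int, fill_value: float = 0.0) -> np.ndarray:
    """All-pairs influence: entry ``(target, source)`` is I_target(source).

    Silences each region in turn; the diagonal holds self-influence and is
    typically excluded from downstream edge ranking.
    """
    n = samples[0].shape[0]
    out = np.empty((n, n))
    for src in range(n):
        out[:, src] = influence_map(model, samples, [src], t_f,
                                    fill_value=fill_value).influence
    return out
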