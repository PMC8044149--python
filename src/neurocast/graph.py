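"""Graph operators for diffusion convolution on a structural connectome.

A brain network is modelled as an undirected weighted graph whose nodes are
parcellated regions and whose edge weights are anatomical connection
strengths (e.g. normalized streamline counts from diffusion tractography).
Activity propagating on this substrate is treated as a random walk: the
row-normalized transition matrix ``T = D^-1 A_w`` gives the probability of
diffusing from one region to a structurally connected neighbour, and a
*diffusion convolution* is a learned polynomial in ``T`` (and, optionally,
``T^T`` for the reverse walk) truncated at walk order ``K``::

    y = sum_{k=0..K} theta_k T^k x

Filters of this form are localized (order ``K`` reaches only ``K``-hop
neighbourhoods) and their parameter count is independent of the number of
nodes, which is what makes them practical for whole-brain graphs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "Graph",
    "TransitionOperator",
    "FilterCoefficients",
    "build_transition_matrix",
    "random_walk_laplacian",
    "diffusion_convolve",
    "spectral_convolve_oracle",
    "stationary_distribution",
]


@dataclass
class Graph:
    """An undirected weighted graph over ``n_nodes`` brain regions.

    Parameters
    ----------
    adjacency
        Symmetric nonnegative ``(N, N)`` weight matrix. Streamline counts,
        or any nonnegative connection strength.
    node_labels
        Optional region identifiers, one per row of ``adjacency``.
    """

    adjacency: np.ndarray
    node_labels: list[str] | None = None

    def __post_init__(self) -> None:
        a = np.asarray(self.adjacency, dtype=float)
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ValueError(f"adjacency must be square, got shape {a.shape}")
        if not np.all(np.isfinite(a)):
            raise ValueError("adjacency contains NaN or Inf")
        if np.any(a < 0):
            raise ValueError("adjacency entries must be nonnegative")
        if not np.allclose(a, a.T, atol=1e-8):
            raise ValueError("adjacency must be symmetric (undirected graph)")
        degree = a.sum(axis=1)
        isolated = np.flatnonzero(degree == 0)
        if isolated.size:
            names = (
                [self.node_labels[i] for i in isolated]
                if self.node_labels
                else isolated.tolist()
            )
            raise ValueError(f"graph has isolated node(s): {names}")
        if self.node_labels is not None and len(self.node_labels) != a.shape[0]:
            raise ValueError("node_labels length does not match adjacency size")
        self.adjacency = a

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]


@dataclass
class TransitionOperator:
    """Random-walk transition matrix ``T = D^-1 A_w`` of a graph.

    ``matrix`` is row-stochastic; ``degree`` holds the diagonal of ``D``.
    When ``include_reverse`` is set, filters built on this operator also use
    the transposed (reverse-walk) direction.
    """

    matrix: np.ndarray
    degree: np.ndarray
    include_reverse: bool = True
    normalization: str = "random_walk"

    def __post_init__(self) -> None:
        t = np.asarray(self.matrix, dtype=float)
        if self.normalization == "random_walk":
            if np.any(t < -1e-12) or np.any(t > 1 + 1e-12):
                raise ValueError("transition entries must lie in [0, 1]")
            rows = t.sum(axis=1)
            if not np.allclose(rows, 1.0, atol=1e-10):
                raise ValueError("transition matrix rows must sum to 1")
        elif self.normalization == "symmetric":
            if not np.allclose(t, t.T, atol=1e-10):
                raise ValueError("symmetric normalization requires T == T^T")
        else:
            raise ValueError(f"unknown normalization {self.normalization!r}")
        self.matrix = t

    @property
    def n_nodes(self) -> int:
        return self.matrix.shape[0]

    def supports(self) -> list[np.ndarray]:
        """Walk directions used by filters: forward, plus reverse if enabled.

        A symmetric operator equals its own transpose, so it contributes a
        single direction regardless of ``include_reverse``.
        """
        if self.include_reverse and self.normalization == "random_walk":
            return [self.matrix, self.matrix.T]
        return [self.matrix]

    @property
    def n_directions(self) -> int:
        return len(self.supports())


@dataclass
class FilterCoefficients:
    """Coefficients of a truncated diffusion-polynomial filter.

    ``theta`` is either a 1-D array of scalar per-order coefficients
    (pure polynomial, features preserved) with length ``n_matrices(order,
    n_directions)``, or a 3-D array ``(n_matrices, f_in, f_out)`` mixing
    input features into output features. The order-0 (identity) term
    appears once; orders 1..K appear once per walk direction.
    """

    order: int
    theta: np.ndarray
    n_directions: int = 1

    def __post_init__(self) -> None:
        if self.order < 0:
            raise ValueError("filter order K must be >= 0")
        if self.n_directions not in (1, 2):
            raise ValueError("n_directions must be 1 or 2")
        th = np.asarray(self.theta, dtype=float)
        if not np.all(np.isfinite(th)):
            raise ValueError("filter coefficients must be finite")
        if th.ndim not in (1, 3):
            raise ValueError("theta must be 1-D (scalar) or 3-D (feature-mixing)")
        if th.shape[0] != self.n_matrices:
            raise ValueError(
                f"theta has {th.shape[0]} leading entries, expected "
                f"{self.n_matrices} for K={self.order}, "
                f"{self.n_directions} direction(s)"
            )
        self.theta = th

    @property
    def n_matrices(self) -> int:
        """Number of polynomial terms: one identity plus K per direction."""
        return 1 + self.order * self.n_directions


def build_transition_matrix(
    graph: Graph,
    include_reverse: bool = True,
    normalization: str = "random_walk",
) -> TransitionOperator:
    """Normalize the adjacency into a diffusion operator.

    ``random_walk`` (default) gives the row-stochastic ``T = D^-1 A_w``;
    ``symmetric`` gives ``D^-1/2 A_w D^-1/2``, which is similar to ``T``
    (same eigenvalues) but admits a real orthonormal eigenbasis.
    """
    degree = graph.adjacency.sum(axis=1)
    zero = np.flatnonzero(degree == 0)
    if zero.size:  # unreachable through Graph, but guards raw construction
        raise ValueError(f"zero-degree node(s): {zero.tolist()}")
    if normalization == "random_walk":
        matrix = graph.adjacency / degree[:, None]
    elif normalization == "symmetric":
        inv_sqrt = 1.0 / np.sqrt(degree)
        matrix = graph.adjacency * np.outer(inv_sqrt, inv_sqrt)
    else:
        raise ValueError(f"unknown normalization {normalization!r}")
    return TransitionOperator(matrix=matrix, degree=degree,
                              include_reverse=include_reverse,
                              normalization=normalization)


def random_walk_laplacian(t: TransitionOperator) -> np.ndarray:
    """Random-walk normalized Laplacian ``L_rw = I - T``; rows sum to 0."""
    return np.eye(t.n_nodes) - t.matrix


def _walk_terms(x: np.ndarray, t: TransitionOperator, order: int):
    """Yield T^k x for k=0..K per direction via iterated mat-vec.

    Never materializes T^k. Order-0 term is yielded once.
    """
    yield x
    for support in t.supports():
        acc = x
        for _ in range(order):
            acc = support @ acc
            yield acc


def diffusion_convolve(
    x: np.ndarray, t: TransitionOperator, f: FilterCoefficients
) -> np.ndarray:
    """Apply the truncated diffusion filter ``sum_k theta_k T^k x``.

    ``x`` may be an ``(N,)`` vector or an ``(N, F)`` feature matrix. With
    3-D coefficients the result has ``f_out`` feature columns; with 1-D
    (scalar) coefficients the feature shape of ``x`` is preserved.
    """
    x = np.asarray(x, dtype=float)
    if x.shape[0] != t.n_nodes:
        raise ValueError(
            f"signal has {x.shape[0]} nodes, operator has {t.n_nodes}"
        )
    if f.n_directions != t.n_directions:
        raise ValueError(
            "filter direction count does not match operator include_reverse"
        )
    if f.theta.ndim == 1:
        out = np.zeros_like(x)
        for coef, term in zip(f.theta, _walk_terms(x, t, f.order)):
            out = out + coef * term
        return out
    # feature-mixing: (N, f_in) -> (N, f_out)
    if x.ndim != 2 or x.shape[1] != f.theta.shape[1]:
        raise ValueError(
            f"signal feature dim {x.shape} incompatible with theta "
            f"{f.theta.shape}"
        )
    out = np.zeros((x.shape[0], f.theta.shape[2]))
    for w, term in zip(f.theta, _walk_terms(x, t, f.order)):
        out = out + term @ w
    return out


def spectral_convolve_oracle(
    x: np.ndarray, graph: Graph, f: FilterCoefficients
) -> np.ndarray:
    """Reference graph convolution via the graph Fourier basis (test oracle).

    Filters the signal in the spectral domain of the *symmetrically*
    normalized operator ``S = D^-1/2 A_w D^-1/2``: ``y = U diag(sum_k
    theta_k lambda^k) U^T x``. ``S`` is similar to the row-normalized
    transition matrix, shares its eigenvalues, and (being symmetric) admits
    a real orthonormal eigen-decomposition, which ``T`` itself does not for
    non-regular degree. Supports scalar (1-D) single-direction filters only;
    intended as an independent cross-check of :func:`diffusion_convolve`.
    """
    if f.theta.ndim != 1 or f.n_directions != 1:
        raise ValueError("spectral oracle supports scalar one-direction filters")
    d = graph.adjacency.sum(axis=1)
    s = graph.adjacency / np.sqrt(np.outer(d, d))
    lam, u = np.linalg.eigh(s)
    if not np.all(np.isfinite(lam)):
        raise np.linalg.LinAlgError("eigen-decomposition did not converge")
    gain = np.zeros_like(lam)
    for k in range(f.order + 1):
        gain += f.theta[k] * lam**k
    return u @ (gain[:, None] * (u.T @ np.asarray(x, dtype=float)[:, None]))[:, 0]


def stationary_distribution(
    t: TransitionOperator, alpha: float, k_max: int
) -> np.ndarray:
    """Truncated restart-walk proximity matrix ``sum_k alpha (1-alpha)^k T^k``.

    Row ``i`` approximates the long-run visiting profile of a random walk
    restarting at node ``i`` with probability ``alpha``; a diagnostic for
    interpreting how far diffusion filters can reach. Row sums equal the
    geometric partial sum ``1 - (1-alpha)^(k_max+1)``.
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must lie in [0, 1]")
    if k_max < 0:
        raise ValueError("k_max must be >= 0")
    p = np.zeros_like(t.matrix)
    power = np.eye(t.n_nodes)
    for k in range(k_max + 1):
        p += alpha * (1 - alpha) ** k * power
        if k < k_max:
            power = power @ t.matrix
    return p
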