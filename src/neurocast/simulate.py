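"""Synthetic graph-coupled signal generator with known directed couplings.

Emulates the statistical shape of parcel-averaged resting-state BOLD on a
structural connectome: an undirected weighted random graph, a directed
coupling matrix supported on its edges, and temporally smooth band-limited
node signals in which structurally connected regions carry lagged
information about each other. The latent dynamics are a noisy lagged tanh
map::

    x(t) = tanh(a x(t-1) + s C x(t-lag)) + noise

where the innovations ``noise`` are themselves band-limited (band-passed
white noise), so the recursion operates on narrowband signals and its
saturation appears *inside* the band as amplitude compression — a
nonlinearity a linear autoregression cannot represent. (Driving the
recursion with broadband noise and band-passing the output instead would
strip the tanh distortion together with the out-of-band noise, leaving an
effectively linear observable.) A mild, wider cleanup filter removes the
residual harmonic distortion far outside the band, and a small broadband
observation-noise floor is added last. Every planted directed edge is
known exactly — the ground truth that the influence measure and
edge-recovery benchmarks are scored against.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, field
from pathlib import Path

import networkx as nx
import numpy as np

from .graph import Graph
from .preprocess import GraphSignalSequence

__all__ = ["SimulationConfig", "GroundTruth", "simulate_graph",
           "simulate_signals", "simulate_dataset", "export_fixture",
           "load_fixture"]


@dataclass
class SimulationConfig:
    """Generator settings; defaults are the desk-scale benchmark conditions.

    ``coupling_strength`` scales the directed cross-node term, with each
    undirected edge carrying each direction independently with probability
    ``coupling_prob``; ``self_coupling`` is the lag-1 self-memory ``a``.
    ``noise_sd`` is the standard deviation of the band-limited driving
    innovations in pre-saturation units — 2.0 drives the tanh well into
    its compressive range. ``obs_noise_sd`` is the broadband measurement
    noise added after generation. ``tr_seconds`` and ``band`` match the
    fMRI acquisition this emulates (TR 0.72 s, 0.04-0.07 Hz).
    """

    n_nodes: int = 10
    graph_density: float = 0.3
    coupling_strength: float = 1.2
    coupling_lag: int = 2
    coupling_prob: float = 0.5
    self_coupling: float = 0.8
    noise_sd: float = 2.0
    obs_noise_sd: float = 0.02
    n_timepoints: int = 500
    tr_seconds: float = 0.72
    band: tuple[float, float] = (0.04, 0.07)
    n_sessions: int = 3
    seed: int = 0
    burn_in: int = 200

    def __post_init__(self) -> None:
        if not 0 < self.graph_density <= 1:
            raise ValueError("graph_density must lie in (0, 1]")
        if self.coupling_lag < 1:
            raise ValueError("coupling_lag must be >= 1")
        for name in ("n_nodes", "n_timepoints", "n_sessions", "tr_seconds"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.noise_sd < 0 or self.coupling_strength < 0:
            raise ValueError("noise_sd and coupling_strength must be >= 0")


@dataclass
class GroundTruth:
    """What the generator planted: the graph weights and directed couplings.

    ``coupling[i, j]`` is the strength of the directed edge j -> i; its
    support is a subset of the undirected adjacency support.
    """

    adjacency: np.ndarray
    coupling: np.ndarray
    session_seeds: list[int] = field(default_factory=list)

    def directed_edges(self) -> list[tuple[int, int]]:
        """Planted (source, target) pairs."""
        targets, sources = np.nonzero(self.coupling)
        return list(zip(sources.tolist(), targets.tolist()))


def simulate_graph(cfg: SimulationConfig,
                   max_retries: int = 100) -> tuple[Graph, GroundTruth]:
    """Draw a connected weighted random graph and plant directed couplings."""
    rng = np.random.default_rng(cfg.seed)
    for _ in range(max_retries):
        g = nx.gnp_random_graph(cfg.n_nodes, cfg.graph_density,
                                seed=int(rng.integers(2**31)))
        if nx.is_connected(g) and g.number_of_edges() > 0:
            break
    else:
        raise RuntimeError(
            f"no connected graph in {max_retries} draws at density "
            f"{cfg.graph_density}; increase density"
        )
    adj = np.zeros((cfg.n_nodes, cfg.n_nodes))
    for i, j in g.edges:
        w = rng.uniform(0.5, 1.5)
        adj[i, j] = adj[j, i] = w
    coupling = np.zeros_like(adj)
    for i, j in g.edges:
        if rng.random() < cfg.coupling_prob:
            coupling[j, i] = 1.0  # i -> j
        if rng.random() < cfg.coupling_prob:
            coupling[i, j] = 1.0  # j -> i
    if not coupling.any():  # guarantee at least one planted direction
        i, j = next(iter(g.edges))
        coupling[j, i] = 1.0
    # total incoming strength is fixed per node: keeps every node's
    # saturation depth comparable regardless of its planted in-degree
    indegree = np.maximum(coupling.sum(axis=1), 1.0)
    coupling = cfg.coupling_strength * coupling / indegree[:, None]
    session_seeds = [int(s) for s in
                     rng.integers(2**31, size=cfg.n_sessions)]
    graph = Graph(adjacency=adj,
                  node_labels=[f"R{i:03d}" for i in range(cfg.n_nodes)])
    return graph, GroundTruth(adjacency=adj, coupling=coupling,
                              session_seeds=session_seeds)


def _run_dynamics(truth: GroundTruth, cfg: SimulationConfig,
                  rng: np.random.Generator) -> np.ndarray:
    from scipy import signal as sps

    n = truth.adjacency.shape[0]
    steps = cfg.n_timepoints + cfg.burn_in
    fs = 1.0 / cfg.tr_seconds
    # band-limited innovations: the drive already lives in the analysis band
    sos = sps.butter(5, list(cfg.band), btype="bandpass", fs=fs, output="sos")
    drive = sps.sosfiltfilt(sos, rng.normal(size=(n, steps)), axis=1)
    drive *= cfg.noise_sd / max(drive.std(), 1e-12)
    x = np.zeros((n, steps))
    for t in range(cfg.coupling_lag, steps):
        pre = (cfg.self_coupling * x[:, t - 1]
               + truth.coupling @ x[:, t - cfg.coupling_lag]
               + drive[:, t])
        x[:, t] = np.tanh(pre)
        if not np.all(np.isfinite(x[:, t])):
            raise FloatingPointError("simulated dynamics diverged")
    # mild wide cleanup: removes harmonic distortion far outside the band
    # while keeping the in-band amplitude compression intact
    sos2 = sps.butter(3, [0.75 * cfg.band[0], 1.4 * cfg.band[1]],
                      btype="bandpass", fs=fs, output="sos")
    return sps.sosfiltfilt(sos2, x, axis=1)[:, cfg.burn_in:]


def simulate_signals(truth: GroundTruth,
                     cfg: SimulationConfig) -> list[GraphSignalSequence]:
    """Generate all sessions of band-limited coupled node signals.

    A small broadband observation-noise floor (``obs_noise_sd``) is added
    last, mimicking measurement noise that survives analog filtering.
    """
    sessions = []
    for seed in truth.session_seeds:
        rng = np.random.default_rng(seed)
        raw = _run_dynamics(truth, cfg, rng)
        noisy = raw + rng.normal(0, cfg.obs_noise_sd, size=raw.shape)
        sessions.append(GraphSignalSequence(noisy, cfg.tr_seconds))
    return sessions


def simulate_dataset(
    cfg: SimulationConfig,
) -> tuple[Graph, GroundTruth, list[GraphSignalSequence]]:
    """Graph, ground truth and sessions in one call."""
    graph, truth = simulate_graph(cfg)
    return graph, truth, simulate_signals(truth, cfg)


def export_fixture(cfg: SimulationConfig, out_dir: str | Path) -> dict:
    """Write a complete fixture (time series, adjacency, couplings, manifest).

    Everything is delimited text plus a JSON manifest recording the exact
    configuration, so the fixture regenerates bit-identically from the
    manifest alone. Returns the manifest dict.
    """
    from .io import write_adjacency, write_timeseries  # local: avoid cycle

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    graph, truth, sessions = simulate_dataset(cfg)
    write_adjacency(out / "adjacency.csv", graph)
    np.savetxt(out / "coupling.csv", truth.coupling, delimiter=",")
    for i, sess in enumerate(sessions):
        write_timeseries(out / f"session_{i:02d}.csv",
                         GraphSignalSequence(sess.data, sess.tr_seconds,
                                             graph.node_labels))
    manifest = {"config": asdict(cfg), "n_sessions": len(sessions),
                "session_files": [f"session_{i:02d}.csv"
                                  for i in range(len(sessions))]}
    manifest["config"]["band"] = list(cfg.band)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def load_fixture(
    fixture_dir: str | Path,
) -> tuple[Graph, GroundTruth, list[GraphSignalSequence]]:
    """Regenerate a fixture's ground truth and load its exported sessions."""
    from .io import read_adjacency, read_timeseries

    d = Path(fixture_dir)
    manifest = json.loads((d / "manifest.json").read_text())
    raw = dict(manifest["config"])
    raw["band"] = tuple(raw["band"])
    cfg = SimulationConfig(**raw)
    graph = read_adjacency(d / "adjacency.csv")
    _, truth = simulate_graph(cfg)
    sessions = [read_timeseries(d / f, tr_seconds=cfg.tr_seconds)
                for f in manifest["session_files"]]
    return graph, truth, sessions
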