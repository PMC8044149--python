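"""Delimited-text readers/writers and run configuration.

Time series are N x T matrices (rows = regions) with an optional label
header; adjacencies are N x N matrices with an optional label sidecar.
All writes go through a temp-file + rename so partially written outputs
never appear under the final name.
"""

from __future__ import annotations

import json
import os
import tempfile
from pathlib import Path

import numpy as np
import yaml

from .graph import Graph
from .preprocess import GraphSignalSequence

__all__ = ["read_timeseries", "write_timeseries", "read_adjacency",
           "write_adjacency", "atomic_write_text", "load_config",
           "write_manifest"]


def atomic_write_text(path: str | Path, text: str) -> None:
    """Write text via a temp file in the same directory, then rename."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.")
    try:
        with os.fdopen(fd, "w") as handle:
            handle.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def _parse_matrix(path: Path) -> tuple[np.ndarray, list[str] | None]:
    text = path.read_text().strip()
    if not text:
        raise ValueError(f"{path}: empty file")
    lines = [ln for ln in text.splitlines() if ln.strip()]

    def split(line: str) -> list[str]:
        return line.replace(",", " ").split()

    labels = None
    first = split(lines[0])
    try:
        [float(c) for c in first]
    except ValueError:
        labels = first
        lines = lines[1:]
        if not lines:
            raise ValueError(f"{path}: header but no data rows")
    rows = []
    width = None
    for r, line in enumerate(lines):
        cells = split(line)
        if width is None:
            width = len(cells)
        elif len(cells) != width:
            raise ValueError(
                f"{path}: ragged row {r} ({len(cells)} cells, expected {width})"
            )
        row = []
        for c, cell in enumerate(cells):
            try:
                val = float(cell)
            except ValueError:
                raise ValueError(
                    f"{path}: non-numeric cell at row {r}, column {c}: {cell!r}"
                ) from None
            if not np.isfinite(val):
                raise ValueError(
                    f"{path}: non-finite value at row {r}, column {c}"
                )
            row.append(val)
        rows.append(row)
    return np.asarray(rows, dtype=float), labels


def read_timeseries(path: str | Path, tr_seconds: float = 0.72
                    ) -> GraphSignalSequence:
    """Read an N x T delimited matrix; a leading label row names the regions.

    The optional header lists the N region names in row order (one name
    per data row that follows).
    """
    data, labels = _parse_matrix(Path(path))
    return GraphSignalSequence(data, tr_seconds=tr_seconds, node_labels=labels)


def write_timeseries(path: str | Path, x: GraphSignalSequence) -> None:
    lines = []
    if x.node_labels:
        lines.append(",".join(x.node_labels))
    lines += [",".join(f"{v:.12g}" for v in row) for row in x.data]
    atomic_write_text(path, "\n".join(lines) + "\n")


def read_adjacency(path: str | Path, labels_path: str | Path | None = None,
                   symmetry_tol: float = 1e-8) -> Graph:
    """Read an N x N weight matrix; symmetrized when within tolerance."""
    data, labels = _parse_matrix(Path(path))
    if data.shape[0] != data.shape[1]:
        raise ValueError(f"{path}: adjacency must be square, got {data.shape}")
    if not np.allclose(data, data.T, atol=symmetry_tol):
        raise ValueError(f"{path}: adjacency asymmetric beyond {symmetry_tol}")
    data = 0.5 * (data + data.T)
    if labels_path is not None:
        labels = Path(labels_path).read_text().split()
    return Graph(adjacency=data, node_labels=labels)


def write_adjacency(path: str | Path, graph: Graph) -> None:
    lines = [",".join(f"{v:.12g}" for v in row) for row in graph.adjacency]
    atomic_write_text(path, "\n".join(lines) + "\n")
    if graph.node_labels:
        atomic_write_text(Path(path).with_suffix(".labels.txt"),
                          "\n".join(graph.node_labels) + "\n")


_KNOWN_KEYS = {
    "timeseries", "adjacency", "checkpoint", "out_dir", "tr", "band",
    "gsr", "scale_mode", "t_p", "t_f", "hidden_size", "order", "layers",
    "include_reverse", "train", "seed", "simulation",
}


def load_config(path: str | Path) -> dict:
    """Load a YAML run configuration, rejecting unknown top-level keys."""
    cfg = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a mapping")
    unknown = set(cfg) - _KNOWN_KEYS
    if unknown:
        raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
    return cfg


def write_manifest(path: str | Path, payload: dict) -> None:
    """Record the exact configuration and seed that produced an output."""
    import neurocast

    payload = dict(payload)
    payload.setdefault("neurocast_version", neurocast.__version__)
    payload.setdefault("numpy_version", np.__version__)
    atomic_write_text(path, json.dumps(payload, indent=2, sort_keys=True) + "\n")
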