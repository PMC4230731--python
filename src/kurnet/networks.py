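"""Network specifications and file I/O.

Adjacency orientation, fixed package-wide: ``adjacency[i, j]`` is the weight
of the directed connection through which node *j*'s mean field drives node
*i* (row = receiver).  Edge-list files use (source, target, weight) columns,
so an edge-list row ``(j, i, w)`` becomes ``adjacency[i, j] = w``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["ModularNetworkSpec", "load_network", "save_network", "validate_adjacency"]


class InvalidSpecError(ValueError):
    """Raised when a network specification violates its invariants."""


def validate_adjacency(adjacency: np.ndarray) -> np.ndarray:
    """Validate and return a directed weighted adjacency matrix.

    Requires a square matrix with finite, non-negative entries and a zero
    diagonal (no self-coupling at the node level; within-node coupling is
    carried by the intrinsic couplings instead).
    """
    a = np.asarray(adjacency, dtype=float)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise InvalidSpecError(f"adjacency must be square, got shape {a.shape}")
    if not np.all(np.isfinite(a)):
        raise InvalidSpecError("adjacency contains non-finite entries")
    if np.any(a < 0):
        raise InvalidSpecError("adjacency entries must be non-negative")
    if np.any(np.diag(a) != 0):
        raise InvalidSpecError("adjacency diagonal must be zero")
    return a


@dataclass
class ModularNetworkSpec:
    """A two-scale Kuramoto network.

    Parameters
    ----------
    adjacency : (n, n) array
        Directed weights; ``adjacency[i, j]`` lets node j drive node i.
    intrinsic_couplings : (n,) array
        Within-node all-to-all coupling K_i >= 0 for each node.
    global_coupling : float
        Global scale kappa >= 0 applied to every inter-node connection.
    freq_mean : float
        Mean of the natural-frequency distribution (default 0, i.e. the
        co-rotating frame).
    freq_sd : float
        Standard deviation of the natural frequencies (default 1; this sets
        the time unit of the model).
    oscillators_per_node : int
        Number N of phase oscillators forming each node.
    """

    adjacency: np.ndarray
    intrinsic_couplings: np.ndarray
    global_coupling: float = 0.0
    freq_mean: float = 0.0
    freq_sd: float = 1.0
    oscillators_per_node: int = 1000
    labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.adjacency = validate_adjacency(self.adjacency)
        k = np.asarray(self.intrinsic_couplings, dtype=float)
        if k.ndim == 0:
            k = np.full(self.n_nodes, float(k))
        if k.shape != (self.n_nodes,):
            raise InvalidSpecError(
                f"intrinsic_couplings shape {k.shape} != ({self.n_nodes},)"
            )
        if not np.all(np.isfinite(k)) or np.any(k < 0):
            raise InvalidSpecError("intrinsic couplings must be finite and >= 0")
        self.intrinsic_couplings = k
        if not np.isfinite(self.global_coupling) or self.global_coupling < 0:
            raise InvalidSpecError("global_coupling must be finite and >= 0")
        if not np.isfinite(self.freq_mean):
            raise InvalidSpecError("freq_mean must be finite")
        if not np.isfinite(self.freq_sd) or self.freq_sd <= 0:
            raise InvalidSpecError("freq_sd must be positive")
        if int(self.oscillators_per_node) < 1:
            raise InvalidSpecError("oscillators_per_node must be a positive integer")
        self.oscillators_per_node = int(self.oscillators_per_node)
        if not self.labels:
            self.labels = [str(i) for i in range(self.n_nodes)]
        if len(self.labels) != self.n_nodes:
            raise InvalidSpecError("labels length must equal n_nodes")

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]


def _read_adjacency_csv(path: Path) -> tuple[np.ndarray, list[str]]:
    df = pd.read_csv(path, index_col=0)
    if df.shape[0] == df.shape[1]:
        # square matrix with header row = node labels
        return df.to_numpy(dtype=float), [str(c) for c in df.columns]
    raise InvalidSpecError(f"{path}: adjacency CSV must be square")


def _read_edge_list(path: Path) -> tuple[np.ndarray, list[str]]:
    df = pd.read_csv(path)
    if df.shape[1] != 3:
        raise InvalidSpecError(f"{path}: edge list must have 3 columns")
    src, tgt, w = (df.iloc[:, k] for k in range(3))
    labels = sorted(set(map(str, src)) | set(map(str, tgt)))
    idx = {lab: i for i, lab in enumerate(labels)}
    a = np.zeros((len(labels), len(labels)))
    for s, t, ww in zip(src, tgt, w):
        a[idx[str(t)], idx[str(s)]] = float(ww)  # row = receiver
    return a, labels


def load_network(path: str | Path, params_path: str | Path | None = None) -> ModularNetworkSpec:
    """Load a network from a CSV adjacency matrix or a 3-column edge list.

    A square CSV (header row + index column of node labels) is read as a
    receiver-by-sender adjacency matrix; any other CSV is read as a
    (source, target, weight) edge list.  An optional JSON sidecar supplies
    ``K`` (scalar or per-node list), ``kappa``, ``Omega``, ``freq_sd`` and
    ``N``.
    """
    path = Path(path)
    try:
        a, labels = _read_adjacency_csv(path)
    except (InvalidSpecError, ValueError):
        a, labels = _read_edge_list(path)
    params: dict = {}
    if params_path is not None:
        params = json.loads(Path(params_path).read_text())
    k = params.get("K", 0.0)
    return ModularNetworkSpec(
        adjacency=a,
        intrinsic_couplings=np.broadcast_to(np.asarray(k, float), (a.shape[0],)).copy(),
        global_coupling=float(params.get("kappa", 0.0)),
        freq_mean=float(params.get("Omega", 0.0)),
        freq_sd=float(params.get("freq_sd", 1.0)),
        oscillators_per_node=int(params.get("N", 1000)),
        labels=labels,
    )


def save_network(spec: ModularNetworkSpec, path: str | Path,
                 params_path: str | Path | None = None) -> None:
    """Write the adjacency as a labelled square CSV plus optional JSON params."""
    path = Path(path)
    df = pd.DataFrame(spec.adjacency, index=spec.labels, columns=spec.labels)
    df.to_csv(path)
    if params_path is not None:
        Path(params_path).write_text(json.dumps({
            "K": spec.intrinsic_couplings.tolist(),
            "kappa": spec.global_coupling,
            "Omega": spec.freq_mean,
            "freq_sd": spec.freq_sd,
            "N": spec.oscillators_per_node,
        }, indent=2))
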