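"""Onset of network-driven synchrony: linearization and critical coupling.

Linearizing the mean-field self-consistency r = H(K r + kappa A r) around
the incoherent state r = 0 (using H'(0) = 1/K_c) gives

    D r = kappa A r,     D = diag(K_c - K_i),

valid when every node is individually sub-critical (K_i < K_c, so D is
invertible).  Non-trivial solutions appear where det(D - kappa A) = 0, or
equivalently at eigenvalues of M = D^{-1} A: each real positive eigenvalue
lambda admits synchrony at kappa = 1/lambda, so the critical global
coupling is the inverse of the largest real eigenvalue,

    kappa_c = 1 / lambda_max(D^{-1} A).

Since M is entrywise non-negative, its spectral radius is itself attained
by a real non-negative eigenvalue (Perron–Frobenius), which serves as an
internal cross-check.  If no positive real eigenvalue exists — in
particular for any DAG, whose adjacency is nilpotent in a topological
ordering — kappa_c is infinite and only node-driven synchrony (a
self-synchronized node driving its downstream hierarchy) can occur.

Closed forms for small motifs:

* two nodes with weights a12, a21:
  kappa_c = sqrt((K_c - K_1)(K_c - K_2) / (a12 * a21)); with equal K and
  unit weights this reduces to kappa_c = K_c - K.  Uni-directional coupling
  makes the expression undefined: network-driven synchrony is impossible.
* an n-cycle with edge weights a_e:
  kappa_c = (prod_i (K_c - K_i) / prod_e a_e)^(1/n); equal K and unit
  weights again give K_c - K, and removing any edge sends kappa_c to
  infinity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from kurnet.networks import validate_adjacency

__all__ = [
    "CriticalCouplingResult", "linearization_matrix", "kappa_c_eigen",
    "kappa_c_determinant", "classify_scenario", "motif_kappa_c",
    "NodeAboveCriticalError",
]

#: relative imaginary-part tolerance for calling an eigenvalue real
IM_TOL = 1e-9


class NodeAboveCriticalError(ValueError):
    """Some K_i >= K_c: the network-driven linearization does not apply.

    A node that synchronizes on its own makes D singular (or negative);
    analyze such systems with the node-driven scan instead.
    """


@dataclass
class CriticalCouplingResult:
    kappa_c: float                    # positive real, or np.inf
    lambda_max: float                 # largest admissible eigenvalue (0 if none)
    spectrum: np.ndarray              # full eigenvalue list of D^{-1} A
    scenario: str                     # "network_driven" or "node_driven_only"
    scc_nodes: list[set] = field(default_factory=list)  # SCCs containing a cycle


def _check_subcritical(K: np.ndarray, K_c: float) -> None:
    if np.any(K >= K_c):
        bad = np.nonzero(K >= K_c)[0].tolist()
        raise NodeAboveCriticalError(
            f"nodes {bad} have K_i >= K_c = {K_c:g}; network-driven linearization "
            "requires all nodes sub-critical — use the node-driven scan instead")


def linearization_matrix(adjacency, K, K_c: float) -> np.ndarray:
    """The matrix M = D^{-1} A whose largest real eigenvalue is 1/kappa_c."""
    a = validate_adjacency(adjacency)
    K = np.broadcast_to(np.asarray(K, float), (a.shape[0],))
    _check_subcritical(K, K_c)
    return a / (K_c - K)[:, None]


def _admissible_eigenvalues(spectrum: np.ndarray) -> np.ndarray:
    scale = np.maximum(1.0, np.abs(spectrum))
    real = spectrum[np.abs(spectrum.imag) <= IM_TOL * scale].real
    return real[real > IM_TOL]


def kappa_c_eigen(adjacency, K, K_c: float) -> CriticalCouplingResult:
    """Critical global coupling via the eigenvalue condition kappa_c = 1/lambda_max.

    An empty admissible set (no real positive eigenvalue) is a valid
    outcome: kappa_c = +inf and the scenario is node-driven only.
    """
    m = linearization_matrix(adjacency, K, K_c)
    spectrum = np.linalg.eigvals(m)
    admissible = _admissible_eigenvalues(spectrum)
    scenario_label, sccs = classify_scenario(adjacency)
    if admissible.size == 0:
        return CriticalCouplingResult(kappa_c=np.inf, lambda_max=0.0,
                                      spectrum=spectrum,
                                      scenario="node_driven_only",
                                      scc_nodes=sccs)
    lam = float(np.max(admissible))
    # Perron–Frobenius: for the non-negative matrix M the spectral radius is
    # attained by a real non-negative eigenvalue, so lambda_max must equal it.
    rho = float(np.max(np.abs(spectrum)))
    if not np.isclose(lam, rho, rtol=1e-8, atol=1e-12):
        raise RuntimeError(
            f"largest real eigenvalue {lam:g} != spectral radius {rho:g}; "
            "eigen-solver inconsistency")
    return CriticalCouplingResult(kappa_c=1.0 / lam, lambda_max=lam,
                                  spectrum=spectrum, scenario="network_driven",
                                  scc_nodes=sccs)


def kappa_c_determinant(adjacency, K, K_c: float, n_grid: int = 400,
                        rel_tol: float = 1e-10) -> float:
    """Critical coupling from the determinant condition det(D - kappa A) = 0.

    Scans a log-spaced kappa grid over [1e-3, 1e3] * (K_c - max K_i) for the
    first sign change of the determinant and bisects it down to ``rel_tol``
    relative width.  Returns +inf when no sign change occurs on the scanned
    range (no admissible onset).  Cross-validates :func:`kappa_c_eigen`.
    """
    a = validate_adjacency(adjacency)
    K = np.broadcast_to(np.asarray(K, float), (a.shape[0],))
    _check_subcritical(K, K_c)
    d = np.diag(K_c - K)

    def det(kappa: float) -> float:
        return float(np.linalg.det(d - kappa * a))

    scale = float(K_c - np.max(K))
    grid = np.concatenate(([0.0], np.logspace(-3, 3, n_grid) * scale))
    vals = np.array([det(k) for k in grid])
    sign_change = np.nonzero(np.sign(vals[:-1]) * np.sign(vals[1:]) < 0)[0]
    if sign_change.size == 0:
        return np.inf
    lo, hi = grid[sign_change[0]], grid[sign_change[0] + 1]
    flo = det(lo)
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        fm = det(mid)
        if fm == 0.0:
            return mid
        if np.sign(fm) == np.sign(flo):
            lo, flo = mid, fm
        else:
            hi = mid
        if hi - lo <= rel_tol * hi:
            break
    return 0.5 * (lo + hi)


def classify_scenario(adjacency) -> tuple[str, list[set]]:
    """Classify the network by its strongly connected components.

    Network-driven synchrony requires at least one cycle of positive-weight
    edges, i.e. a strongly connected component of size >= 2 (self-loops are
    excluded by the zero-diagonal invariant).  Returns the label
    ("network_driven_possible" or "node_driven_only") and the list of SCC
    node sets that contain a cycle.
    """
    a = validate_adjacency(adjacency)
    # adjacency[i, j] is the edge j -> i; build the digraph in source->target form
    g = nx.from_numpy_array(a.T, create_using=nx.DiGraph)
    sccs = [set(c) for c in nx.strongly_connected_components(g) if len(c) >= 2]
    label = "network_driven_possible" if sccs else "node_driven_only"
    return label, sccs


def motif_kappa_c(motif_name: str, params: dict) -> float:
    """Closed-form kappa_c for the analytically solved motifs.

    Motifs: ``two_node_general`` (params K1, K2, a12, a21, K_c),
    ``two_node_symmetric`` (K, K_c; unit weights) and ``cycle_n``
    (K: scalar or per-node vector, weights: optional per-edge vector, K_c).
    A uni-directional two-node request (a zero weight) returns +inf:
    network-driven synchrony is impossible without a cycle.
    """
    K_c = float(params["K_c"])
    if motif_name == "two_node_symmetric":
        K = float(params["K"])
        _check_subcritical(np.array([K, K]), K_c)
        return K_c - K
    if motif_name == "two_node_general":
        K1, K2 = float(params["K1"]), float(params["K2"])
        _check_subcritical(np.array([K1, K2]), K_c)
        a12, a21 = float(params["a12"]), float(params["a21"])
        if a12 <= 0 or a21 <= 0:
            return np.inf
        return float(np.sqrt((K_c - K1) * (K_c - K2) / (a12 * a21)))
    if motif_name == "cycle_n":
        n = int(params["n"])
        K = np.broadcast_to(np.asarray(params["K"], float), (n,))
        _check_subcritical(K, K_c)
        weights = np.broadcast_to(
            np.asarray(params.get("weights", 1.0), float), (n,))
        if np.any(weights <= 0):
            return np.inf
        # geometric-mean form keeps the n-th root stable for large n
        log_val = (np.sum(np.log(K_c - K)) - np.sum(np.log(weights))) / n
        return float(np.exp(log_val))
    raise ValueError(f"unknown motif {motif_name!r}")
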