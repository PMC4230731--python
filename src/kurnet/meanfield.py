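"""Thermodynamic-limit mean field of the modular Kuramoto network.

In the limit of infinitely many oscillators per node, the order parameter of
node i obeys the self-consistency relation

    r_i = H(X_i),    X_i = K_i r_i + kappa * sum_j A[i, j] r_j,

where X_i is the total locking field felt by the node's oscillators (its
magnitude sets the locking window: oscillators with |omega| <= X_i
phase-lock) and H is the locked-population response of the frequency
density g:

    H(x) = integral over |omega| <= x of g(omega) sqrt(1 - (omega/x)^2)
         = x * int_{-pi/2}^{pi/2} g(x sin phi) cos^2(phi) dphi.

For the standard normal density the integral has the classical Bessel form

    H(x) = sqrt(pi/8) * x * e^{-x^2/4} * [I_0(x^2/4) + I_1(x^2/4)],

and the onset of synchrony of an isolated node is at K_c = 2 / (pi g(0))
= sqrt(8/pi) ~= 1.59577.  Both evaluations are implemented and must agree;
the zero vector is always a fixed point, and the locked branch (when it
exists) is found by damped fixed-point iteration from r = 1.

Only symmetric unimodal densities with mean 0 are admitted: the argument
that all node mean fields align in phase beyond onset (which reduces the
global order parameter to the arithmetic mean of the node r_i) relies on
that symmetry.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import integrate, special

from kurnet.networks import validate_adjacency

__all__ = [
    "NormalDensity", "UniformDensity", "MeanFieldProblem", "MeanFieldSolution",
    "effective_drive", "self_consistency_map", "solve",
    "single_node_critical_coupling", "global_order_parameter",
    "ConvergenceError", "NoOnsetError",
]


class ConvergenceError(RuntimeError):
    """Fixed-point iteration failed to converge; carries the residual history."""

    def __init__(self, message: str, residual_history: list[float]):
        super().__init__(message)
        self.residual_history = residual_history


class NoOnsetError(ValueError):
    """The frequency density has no mass at zero, so no finite onset exists."""


class NormalDensity:
    """Zero-mean normal frequency density with standard deviation ``sd``."""

    symmetric_unimodal = True

    def __init__(self, sd: float = 1.0):
        if sd <= 0:
            raise ValueError("sd must be positive")
        self.sd = float(sd)

    def pdf(self, omega):
        s = self.sd
        return np.exp(-0.5 * (np.asarray(omega) / s) ** 2) / (s * np.sqrt(2 * np.pi))

    def __repr__(self):
        return f"NormalDensity(sd={self.sd})"


class UniformDensity:
    """Zero-mean uniform density on [-sd*sqrt(3), sd*sqrt(3)] (unit-variance default)."""

    symmetric_unimodal = True

    def __init__(self, sd: float = 1.0):
        if sd <= 0:
            raise ValueError("sd must be positive")
        self.sd = float(sd)
        self.half_width = float(sd) * np.sqrt(3.0)

    def pdf(self, omega):
        w = np.asarray(omega, float)
        return np.where(np.abs(w) <= self.half_width, 1.0 / (2 * self.half_width), 0.0)

    def __repr__(self):
        return f"UniformDensity(sd={self.sd})"


def _check_density(density) -> None:
    if not getattr(density, "symmetric_unimodal", False):
        raise ValueError(
            "frequency density must declare symmetric_unimodal=True; asymmetric "
            "densities break the in-phase alignment the mean field assumes")


def locked_response_bessel(x, sd: float = 1.0):
    """Bessel-form H(x) for the normal density with standard deviation sd.

    Uses exponentially scaled Bessel functions so large arguments do not
    overflow; H(x) -> 1 as x -> infinity (full locking).
    """
    x = np.asarray(x, dtype=float) / sd
    u = 0.25 * x * x
    return np.sqrt(np.pi / 8.0) * x * (special.ive(0, u) + special.ive(1, u))


def locked_response_quad(x: float, density, epsabs: float = 1e-10,
                         epsrel: float = 1e-12) -> float:
    """H(x) by adaptive quadrature over the finite locking window of any density."""
    _check_density(density)
    x = float(x)
    if x < 0:
        raise ValueError("locking field must be non-negative")
    if x == 0.0:
        return 0.0
    val, _ = integrate.quad(
        lambda phi: density.pdf(x * np.sin(phi)) * np.cos(phi) ** 2,
        -np.pi / 2, np.pi / 2, epsabs=epsabs, epsrel=epsrel, limit=200)
    return x * val


def _locked_response(x: np.ndarray, density, method: str = "auto") -> np.ndarray:
    x = np.atleast_1d(np.asarray(x, float))
    if method == "auto":
        method = "bessel" if isinstance(density, NormalDensity) else "quadrature"
    if method == "bessel":
        if not isinstance(density, NormalDensity):
            raise ValueError("Bessel form is only valid for the normal density")
        return locked_response_bessel(x, sd=density.sd)
    if method == "quadrature":
        return np.array([locked_response_quad(xi, density) for xi in x])
    raise ValueError(f"unknown method {method!r}")


@dataclass
class MeanFieldProblem:
    """Self-consistency problem for the node order parameters.

    ``adjacency[i, j]`` is the weight with which node j's mean field drives
    node i; ``intrinsic_couplings`` are the within-node K_i; the frequency
    density must be symmetric unimodal with mean 0 (default standard
    normal, sd 1).
    """

    adjacency: np.ndarray
    intrinsic_couplings: np.ndarray
    global_coupling: float = 0.0
    freq_density: object = field(default_factory=NormalDensity)

    def __post_init__(self):
        self.adjacency = validate_adjacency(self.adjacency)
        k = np.broadcast_to(np.asarray(self.intrinsic_couplings, float),
                            (self.adjacency.shape[0],)).copy()
        if np.any(k < 0) or not np.all(np.isfinite(k)):
            raise ValueError("intrinsic couplings must be finite and >= 0")
        self.intrinsic_couplings = k
        if self.global_coupling < 0:
            raise ValueError("global_coupling must be >= 0")
        _check_density(self.freq_density)

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]


@dataclass
class MeanFieldSolution:
    node_r: np.ndarray          # headline branch (locked when it exists, else zero)
    residuals: np.ndarray       # |r - map(r)| per node on the headline branch
    converged: bool
    branch: str                 # "zero" or "locked"


def _validate_node_r(problem: MeanFieldProblem, node_r) -> np.ndarray:
    r = np.asarray(node_r, dtype=float)
    if r.shape != (problem.n_nodes,):
        raise ValueError(f"node_r shape {r.shape} != ({problem.n_nodes},)")
    if np.any(r < 0) or np.any(r > 1):
        raise ValueError("node_r entries must lie in [0, 1]")
    return r


def effective_drive(problem: MeanFieldProblem, node_r) -> np.ndarray:
    """Total locking field per node: K_i r_i + kappa * (A r)_i."""
    r = _validate_node_r(problem, node_r)
    return problem.intrinsic_couplings * r + problem.global_coupling * (
        problem.adjacency @ r)


def self_consistency_map(problem: MeanFieldProblem, node_r,
                         method: str = "auto") -> np.ndarray:
    """One application of the mean-field map: r -> H(K r + kappa A r).

    ``method`` selects the H evaluation: "bessel" (normal density only),
    "quadrature" (any symmetric unimodal density) or "auto".
    """
    x = effective_drive(problem, node_r)
    return _locked_response(x, problem.freq_density, method=method)


def solve(problem: MeanFieldProblem, damping: float = 0.5, tol: float = 1e-10,
          max_iter: int = 10_000, method: str = "auto",
          raise_on_fail: bool = True) -> MeanFieldSolution:
    """Damped fixed-point solution of the self-consistency system.

    Starts from the upper seed r = 1 (the map is monotone and bounded by 1,
    so the iterates decrease onto the largest fixed point); returns the
    locked branch when one exists, otherwise the zero branch.  Deterministic.
    """
    r = np.ones(problem.n_nodes)
    history: list[float] = []
    converged = False
    for _ in range(max_iter):
        r_new = np.clip(self_consistency_map(problem, r, method=method), 0.0, 1.0)
        step = float(np.max(np.abs(r_new - r)))
        history.append(step)
        r = (1.0 - damping) * r + damping * r_new
        if step <= tol:
            converged = True
            break
    if not converged and raise_on_fail:
        raise ConvergenceError(
            f"fixed-point iteration did not reach tol={tol} in {max_iter} "
            f"iterations (last step {history[-1]:.3e})", history)
    residuals = np.abs(r - self_consistency_map(problem, r, method=method))
    # collapse a numerically-vanishing branch onto the exact zero fixed point
    if np.max(r) < 1e-6:
        return MeanFieldSolution(node_r=np.zeros(problem.n_nodes),
                                 residuals=np.zeros(problem.n_nodes),
                                 converged=converged, branch="zero")
    return MeanFieldSolution(node_r=r, residuals=residuals,
                             converged=converged, branch="locked")


def single_node_critical_coupling(freq_density=None, method: str = "slope") -> float:
    """Critical intrinsic coupling K_c of an isolated node.

    method="slope" uses the linearized onset condition K_c * H'(0) = 1 with
    H'(0) = pi g(0) / 2, i.e. the classical K_c = 2 / (pi g(0)).
    method="bisection" instead bisects K on the existence of a positive root
    of the nonlinear scalar self-consistency r = H(K r) evaluated by
    quadrature, an independent check of the closed form.  For the standard
    normal density both give sqrt(8/pi) ~= 1.59577.
    """
    density = freq_density if freq_density is not None else NormalDensity()
    _check_density(density)
    g0 = float(density.pdf(0.0))
    if g0 <= 0:
        raise NoOnsetError("frequency density has zero mass at omega = 0; "
                           "no finite onset exists")
    if method == "slope":
        return 2.0 / (np.pi * g0)
    if method == "bisection":
        r_grid = np.logspace(-5, 0, 25)

        def has_locked_root(K: float) -> bool:
            # a positive fixed point exists iff H(K r) > r somewhere
            return any(locked_response_quad(K * r, density, epsabs=0.0,
                                            epsrel=1e-13) > r for r in r_grid)

        lo, hi = 1e-3, 1.0
        while not has_locked_root(hi):
            hi *= 2.0
            if hi > 1e6:
                raise NoOnsetError("no onset found below K = 1e6")
        for _ in range(200):
            mid = 0.5 * (lo + hi)
            if has_locked_root(mid):
                hi = mid
            else:
                lo = mid
            if hi - lo <= 1e-10 * hi:
                break
        return 0.5 * (lo + hi)
    raise ValueError(f"unknown method {method!r}")


def global_order_parameter(solution: MeanFieldSolution, adjacency=None) -> float:
    """Analytic global order parameter beyond onset: the mean of the node r_i.

    With non-negative weights and a symmetric frequency density, all node
    mean fields align in phase beyond onset, so the modulus of the grand
    mean reduces to the arithmetic mean of the per-node moduli.  Below onset
    the convention R = mean(node_r) = 0 applies.
    """
    if not solution.converged:
        raise ValueError("solution did not converge; refusing to summarize it")
    return float(np.mean(solution.node_r))
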