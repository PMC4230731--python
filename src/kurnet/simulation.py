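"""Direct numerical simulation of the modular Kuramoto network.

Each node i hosts N phase oscillators with all-to-all sine coupling of
strength K_i/N; nodes interact through the directed adjacency A scaled by
the global coupling kappa.  The inter-node term uses the driving node's mean
field: an oscillator of node i feels kappa * A[i, j] * r_j * sin(psi_j -
theta), which is the form the thermodynamic-limit reduction assumes and
equals the microscopic per-oscillator double sum divided by N in the large-N
limit.  Writing z_i = r_i e^{i psi_i} for the node-i mean field, the phase
velocity of oscillator k of node i is

    dtheta_ik/dt = omega_ik + Im[(K_i z_i + kappa (A z)_i) e^{-i theta_ik}].

Integration is fixed-step RK4 (non-stiff dynamics, exactly reproducible).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from kurnet.networks import ModularNetworkSpec, InvalidSpecError

__all__ = [
    "PhaseTrajectory", "OrderParameterTrace", "draw_natural_frequencies",
    "simulate", "order_parameters", "node_signal", "mean_order_parameter",
]

TWO_PI = 2.0 * np.pi


class NumericalFailureError(RuntimeError):
    """Raised when the integrator produces non-finite phases."""


@dataclass
class PhaseTrajectory:
    """Oscillator phases over time for every (node, oscillator) pair."""

    times: np.ndarray                 # (n_times,)
    phases: np.ndarray                # (n_times, n_nodes, N), wrapped to [0, 2pi)
    natural_frequencies: np.ndarray   # (n_nodes, N)
    seed: int


@dataclass
class OrderParameterTrace:
    """Per-node and global Kuramoto order parameters over time."""

    times: np.ndarray    # (n_times,)
    node_r: np.ndarray   # (n_times, n_nodes) in [0, 1]
    node_psi: np.ndarray # (n_times, n_nodes) in [0, 2pi)
    global_R: np.ndarray # (n_times,) in [0, 1]


def draw_natural_frequencies(spec: ModularNetworkSpec, seed: int) -> np.ndarray:
    """Draw i.i.d. normal natural frequencies, identically distributed per node.

    Returns a (n_nodes, N) array with mean ``spec.freq_mean`` and standard
    deviation ``spec.freq_sd``; reproducible given the seed.
    """
    if spec.oscillators_per_node < 1:
        raise InvalidSpecError("oscillators_per_node must be positive")
    rng = np.random.default_rng(seed)
    return rng.normal(spec.freq_mean, spec.freq_sd,
                      size=(spec.n_nodes, spec.oscillators_per_node))


def _phase_velocity(theta: np.ndarray, omega: np.ndarray, K: np.ndarray,
                    kappa: float, A: np.ndarray) -> np.ndarray:
    # Im(drive_i e^{-i theta}) = Im(drive_i) cos(theta) - Re(drive_i) sin(theta)
    s, c = np.sin(theta), np.cos(theta)
    z = c.mean(axis=1) + 1j * s.mean(axis=1)     # node mean fields r_i e^{i psi_i}
    drive = K * z + kappa * (A @ z)              # complex per-node drive
    return omega + drive.imag[:, None] * c - drive.real[:, None] * s


def _rk4_step(theta, dt, omega, K, kappa, A):
    k1 = _phase_velocity(theta, omega, K, kappa, A)
    k2 = _phase_velocity(theta + 0.5 * dt * k1, omega, K, kappa, A)
    k3 = _phase_velocity(theta + 0.5 * dt * k2, omega, K, kappa, A)
    k4 = _phase_velocity(theta + dt * k3, omega, K, kappa, A)
    return theta + (dt / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)


def _initial_state(spec, seed, initial_phases, frequencies):
    n, N = spec.n_nodes, spec.oscillators_per_node
    ss = np.random.SeedSequence(seed)
    s_freq, s_phase = ss.spawn(2)
    if frequencies is None:
        frequencies = np.random.default_rng(s_freq).normal(
            spec.freq_mean, spec.freq_sd, size=(n, N))
    frequencies = np.asarray(frequencies, float)
    if frequencies.shape != (n, N):
        raise InvalidSpecError(f"frequencies shape {frequencies.shape} != {(n, N)}")
    if initial_phases is None:
        initial_phases = np.random.default_rng(s_phase).uniform(0, TWO_PI, size=(n, N))
    theta = np.mod(np.asarray(initial_phases, float), TWO_PI)
    if theta.shape != (n, N):
        raise InvalidSpecError(f"initial_phases shape {theta.shape} != {(n, N)}")
    return theta, frequencies


def simulate(spec: ModularNetworkSpec, duration: float, dt: float = 0.01,
             seed: int = 0, store_every: int = 1,
             initial_phases: np.ndarray | None = None,
             frequencies: np.ndarray | None = None) -> PhaseTrajectory:
    """Integrate the modular Kuramoto network with fixed-step RK4.

    Parameters
    ----------
    duration, dt : float
        Total integration time and step, in units where freq_sd = 1.
    seed : int
        Seeds both the natural frequencies and the uniform initial phases
        (either can be overridden explicitly).
    store_every : int
        Keep every k-th step (plus the initial state); thins the stored
        trajectory for long runs without changing the integration.

    Returns the wrapped phases at every stored step.  Raises
    ``NumericalFailureError`` (naming the step) if the state leaves the
    finite range.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if duration < dt:
        raise ValueError("duration must be at least dt")
    if store_every < 1:
        raise ValueError("store_every must be >= 1")
    theta, omega = _initial_state(spec, seed, initial_phases, frequencies)
    K = spec.intrinsic_couplings
    A, kappa = spec.adjacency, spec.global_coupling
    n_steps = int(round(duration / dt))
    times = [0.0]
    stored = [theta.copy()]
    for step in range(1, n_steps + 1):
        theta = _rk4_step(theta, dt, omega, K, kappa, A)
        if step % store_every == 0 or step == n_steps:
            if not np.all(np.isfinite(theta)):
                raise NumericalFailureError(
                    f"non-finite phases at integration step {step} (t={step * dt:g})")
            theta = np.mod(theta, TWO_PI)
            times.append(step * dt)
            stored.append(theta.copy())
    return PhaseTrajectory(times=np.asarray(times), phases=np.asarray(stored),
                           natural_frequencies=omega, seed=seed)


def order_parameters(traj: PhaseTrajectory) -> OrderParameterTrace:
    """Empirical order parameters: per-node r_i e^{i psi_i} and global R.

    r_i e^{i psi_i} is the mean over the node's oscillators of e^{i theta};
    R is the modulus of the grand mean over all n*N oscillators.
    """
    if traj.phases.size == 0:
        raise ValueError("empty trajectory")
    z = np.exp(1j * traj.phases)            # (time, node, N)
    node_z = z.mean(axis=2)
    global_z = z.mean(axis=(1, 2))
    return OrderParameterTrace(
        times=traj.times,
        node_r=np.abs(node_z),
        node_psi=np.mod(np.angle(node_z), TWO_PI),
        global_R=np.abs(global_z),
    )


def node_signal(traj: PhaseTrajectory, node: int) -> np.ndarray:
    """EEG-like observable of one node: sum over its oscillators of sin(theta).

    For a phase-locked node this is approximately N * r * sin(psi(t)), a
    large-amplitude sinusoid; for an incoherent node it is a low-amplitude
    irregular signal with standard deviation about sqrt(N/2).
    """
    n = traj.phases.shape[1]
    if not -n <= node < n:
        raise IndexError(f"node index {node} out of range for {n} nodes")
    return np.sin(traj.phases[:, node, :]).sum(axis=1)


def mean_order_parameter(spec: ModularNetworkSpec, duration: float = 200.0,
                         dt: float = 0.01, seed: int = 0,
                         transient_fraction: float = 0.5,
                         initial_phases: np.ndarray | None = None,
                         frequencies: np.ndarray | None = None
                         ) -> tuple[np.ndarray, float]:
    """Long-time mean per-node r and global R without storing the trajectory.

    Integrates like :func:`simulate` but accumulates running means of the
    order parameters over the retained part of the run (the first
    ``transient_fraction`` of the run is discarded), keeping memory flat for
    large N.  Returns ``(mean_node_r, mean_global_R)``.
    """
    if dt <= 0 or duration < dt:
        raise ValueError("need dt > 0 and duration >= dt")
    theta, omega = _initial_state(spec, seed, initial_phases, frequencies)
    K = spec.intrinsic_couplings
    A, kappa = spec.adjacency, spec.global_coupling
    n_steps = int(round(duration / dt))
    skip = int(np.floor(transient_fraction * n_steps))
    acc_r = np.zeros(spec.n_nodes)
    acc_R = 0.0
    count = 0
    for step in range(1, n_steps + 1):
        theta = _rk4_step(theta, dt, omega, K, kappa, A)
        if step > skip:
            z = np.exp(1j * theta)
            acc_r += np.abs(z.mean(axis=1))
            acc_R += np.abs(z.mean())
            count += 1
        if step % 1000 == 0 and not np.all(np.isfinite(theta)):
            raise NumericalFailureError(f"non-finite phases at step {step}")
        theta = np.mod(theta, TWO_PI)
    return acc_r / count, acc_R / count
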