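"""Synthetic inputs: motif networks, lag-coupled recordings, cohorts.

The clinical EEG that motivates the study design (19-channel 10–20 montage,
20-second artefact-free resting segments, two cohorts of a few dozen
subjects) is emulated here with known ground truth:

* named motif networks for the analytic machinery (two-node,
  n-cycles, the three seven-node variants illustrating how one edge creates
  or destroys a strongly connected component, random DAGs/SCCs);
* a linear lagged-coupling process for the inference pipeline — each
  channel is 1/f-like band-limited noise plus delayed, gain-weighted copies
  of its parent channels, so the true directed, lagged dependency structure
  is known exactly (the inference method is correlation-based and
  resting-state EEG is predominantly linear, so a linear test bed is the
  appropriate calibration target; the Kuramoto generator below exercises
  the nonlinear path qualitatively);
* two-group network ensembles in which the case generator plants extra
  reciprocal edges, creating strongly connected components with a
  controlled probability and hence stochastically lower critical coupling.

All generators are pure functions of (parameters, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from kurnet.inference import (MONTAGE_10_20, ChannelRecording,
                              DirectedFunctionalNetwork)
from kurnet.networks import ModularNetworkSpec
from kurnet.simulation import node_signal, simulate

__all__ = [
    "SyntheticGroundTruth", "make_motif", "gen_lagged_recording",
    "gen_kuramoto_recording", "gen_cohort",
]

MOTIF_NAMES = ("two_node_uni", "two_node_bi", "cycle_n", "seven_node_a", "seven_node_b",
               "seven_node_c", "dag_random", "scc_random")


@dataclass
class SyntheticGroundTruth:
    """Known directed lagged dependency structure of a generated recording.

    ``true_adjacency[i, j]`` is the gain with which channel j drives
    channel i (row = receiver); ``true_lags`` holds the corresponding
    positive delays in samples (zero where there is no edge).
    """

    true_adjacency: np.ndarray
    true_lags: np.ndarray
    generator_params: dict = field(default_factory=dict)


def _edges_to_adjacency(n: int, edges: list[tuple[int, int]],
                        weight: float = 1.0) -> np.ndarray:
    """Build a receiver-oriented adjacency from 1-indexed (source, target) pairs."""
    a = np.zeros((n, n))
    for s, t in edges:
        a[t - 1, s - 1] = weight
    return a


# Seven-node illustration, reconstructed from its description: variant A has
# the cycle {2,3,5} plus downstream nodes 6,7 (nodes 1 and 4 receive nothing
# from the cycle and stay incoherent); variant B removes the 5->2 edge,
# breaking the cycle (a pure hierarchy); variant C reverses the 1->2 edge,
# creating the 4-node strongly connected component {1,2,3,5} that reaches
# every node, so the whole network can synchronize.
_SEVEN_NODE_A = [(1, 2), (2, 3), (1, 3), (3, 5), (5, 2), (5, 6), (6, 7), (1, 4)]
_SEVEN_NODE_B = [e for e in _SEVEN_NODE_A if e != (5, 2)]
_SEVEN_NODE_C = [(2, 1) if e == (1, 2) else e for e in _SEVEN_NODE_A]


def make_motif(name: str, params: dict | None = None) -> ModularNetworkSpec:
    """Named fixture networks.

    ``cycle_n`` needs params["n"]; ``dag_random`` / ``scc_random`` take
    n (default 8), edge probability p (default 0.3) and seed.  Common
    params: K (intrinsic couplings, default 0.8), kappa, N.
    """
    params = dict(params or {})
    K = params.pop("K", 0.8)
    kappa = params.pop("kappa", 0.0)
    N = params.pop("N", 1000)

    if name == "two_node_uni":
        a = np.array([[0.0, 0.0], [1.0, 0.0]])   # node 1 drives node 2
    elif name == "two_node_bi":
        a = np.array([[0.0, 1.0], [1.0, 0.0]])
    elif name == "cycle_n":
        n = int(params["n"])
        w = np.broadcast_to(np.asarray(params.get("weights", 1.0), float), (n,))
        a = np.zeros((n, n))
        for i in range(n):   # edge i -> i+1 (mod n) with weight w[i]
            a[(i + 1) % n, i] = w[i]
    elif name == "seven_node_a":
        a = _edges_to_adjacency(7, _SEVEN_NODE_A)
    elif name == "seven_node_b":
        a = _edges_to_adjacency(7, _SEVEN_NODE_B)
    elif name == "seven_node_c":
        a = _edges_to_adjacency(7, _SEVEN_NODE_C)
    elif name in ("dag_random", "scc_random"):
        n = int(params.get("n", 8))
        p = float(params.get("p", 0.3))
        rng = np.random.default_rng(params.get("seed", 0))
        a = np.zeros((n, n))
        order = rng.permutation(n)
        for i in range(n):
            for j in range(i + 1, n):
                if rng.random() < p:
                    a[order[j], order[i]] = rng.uniform(0.2, 1.0)
        if name == "scc_random":
            # close the topological order into a ring so one SCC spans all nodes
            for i in range(n):
                a[order[(i + 1) % n], order[i]] = max(
                    a[order[(i + 1) % n], order[i]], rng.uniform(0.2, 1.0))
    else:
        raise ValueError(f"unknown motif {name!r}; choose from {MOTIF_NAMES}")
    return ModularNetworkSpec(adjacency=a, intrinsic_couplings=K,
                              global_coupling=kappa, oscillators_per_node=N)


# ---------------------------------------------------------------------------
# recordings

def _ar1_band_noise(n_channels: int, n_samples: int, fs: float,
                    rng: np.random.Generator, coef: float = 0.95,
                    lo: float = 1.0, hi: float = 70.0) -> np.ndarray:
    """1/f-like innovations: AR(1) driven by white noise, band-passed lo–hi Hz."""
    pad = 200
    e = rng.standard_normal((n_channels, n_samples + pad))
    x = sps.lfilter([1.0], [1.0, -coef], e, axis=1)[:, pad:]
    hi = min(hi, 0.45 * fs)
    sos = sps.butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")
    x = sps.sosfiltfilt(sos, x, axis=1)
    return x / x.std(axis=1, keepdims=True)


def make_lagged_truth(n_channels: int = 19, n_edges: int = 10,
                      fs: float = 256.0, duration: float = 20.0,
                      gain: float = 0.7, noise_sd: float = 0.3,
                      lag_range_ms: tuple[float, float] = (15.0, 120.0),
                      seed: int = 0) -> SyntheticGroundTruth:
    """Draw a random ground-truth structure with planted lagged dependencies.

    The planted edges form disjoint directed chains (every node has
    in-degree and out-degree at most one, no cycles): along a random
    ordering of the channels, ``n_edges`` consecutive-pair positions are
    selected.  Chains make the recovery problem honest but well-posed —
    indirect ancestor correlations exist (and must be pruned), while no
    two channels share a hidden common driver, a confound the pairwise
    method cannot reject.  Each edge gets a positive lag drawn inside
    ``lag_range_ms`` and the common coupling gain.
    """
    if n_edges > n_channels - 1:
        raise ValueError("chain construction needs n_edges <= n_channels - 1")
    rng = np.random.default_rng(seed)
    adj = np.zeros((n_channels, n_channels))
    lags = np.zeros((n_channels, n_channels), dtype=int)
    lo = max(1, int(round(lag_range_ms[0] / 1000 * fs)))
    hi = max(lo + 1, int(round(lag_range_ms[1] / 1000 * fs)))
    perm = rng.permutation(n_channels)
    positions = rng.choice(n_channels - 1, size=n_edges, replace=False)
    for k in positions:
        s, t = int(perm[k]), int(perm[k + 1])
        adj[t, s] = gain
        lags[t, s] = int(rng.integers(lo, hi))
    return SyntheticGroundTruth(
        true_adjacency=adj, true_lags=lags,
        generator_params={"fs": fs, "duration": duration, "gain": gain,
                          "noise_sd": noise_sd, "seed": seed})


def gen_lagged_recording(truth: SyntheticGroundTruth, seed: int = 0
                         ) -> ChannelRecording:
    """Linear lagged-coupling process realizing a ground-truth structure.

    channel_i[t] = innovation_i[t] + sum_j gain[i, j] * channel_j[t - lag[i, j]]
    + white measurement noise.  Innovations are AR(1)-filtered band-limited
    noise (non-trivial autocorrelation for the surrogate test to control
    for).  Channels carry the 10–20 montage labels when there are 19.
    """
    p = truth.generator_params
    fs = float(p.get("fs", 256.0))
    duration = float(p.get("duration", 20.0))
    noise_sd = float(p.get("noise_sd", 0.3))
    adj = np.asarray(truth.true_adjacency, float)
    lags = np.asarray(truth.true_lags, int)
    if np.any((lags > 0) != (adj != 0)):
        raise ValueError("lags must be positive exactly where adjacency is non-zero")
    rho = np.max(np.abs(np.linalg.eigvals(adj)))
    if rho >= 1:
        raise ValueError(f"unstable generator: spectral radius {rho:.3f} >= 1")
    nch = adj.shape[0]
    n = int(round(fs * duration))
    rng = np.random.default_rng(seed)
    innov = _ar1_band_noise(nch, n, fs, rng)
    x = np.zeros((nch, n))
    edge_list = [(i, j) for i, j in zip(*np.nonzero(adj))]
    for t in range(n):
        x[:, t] = innov[:, t]
        for i, j in edge_list:
            d = lags[i, j]
            if t >= d:
                x[i, t] += adj[i, j] * x[j, t - d]
    x += noise_sd * rng.standard_normal((nch, n))
    labels = (MONTAGE_10_20 if nch == len(MONTAGE_10_20)
              else [f"ch{c:02d}" for c in range(nch)])
    return ChannelRecording(labels=labels, fs=fs, data=x)


def gen_kuramoto_recording(spec: ModularNetworkSpec, fs: float = 256.0,
                           duration: float = 20.0, seed: int = 0,
                           model_time: float | None = None,
                           dt: float = 0.01) -> ChannelRecording:
    """EEG-like recording from a simulated modular Kuramoto network.

    Simulates ``model_time`` model time units (default: enough for
    ``duration * fs`` samples at the integrator step) and emits each node's
    summed-sine signal, linearly resampled onto the requested sampling
    grid.  The nonlinear test bed for the inference pipeline.
    """
    n_samples = int(round(fs * duration))
    if model_time is None:
        model_time = max(n_samples * dt, 2 * dt)
    traj = simulate(spec, duration=model_time, dt=dt, seed=seed)
    sig = np.stack([node_signal(traj, i) for i in range(spec.n_nodes)])
    t_out = np.linspace(0.0, traj.times[-1], n_samples)
    data = np.stack([np.interp(t_out, traj.times, s) for s in sig])
    labels = (MONTAGE_10_20 if spec.n_nodes == len(MONTAGE_10_20)
              else [f"node{c}" for c in range(spec.n_nodes)])
    return ChannelRecording(labels=labels, fs=fs, data=data)


# ---------------------------------------------------------------------------
# cohorts

def _random_subject_network(n_nodes: int, p_edge: float, p_recip: float,
                            rng: np.random.Generator,
                            labels: list[str]) -> DirectedFunctionalNetwork:
    """Sparse DAG-dominant digraph; reciprocal partners close cycles.

    Edges run forward along a random topological order with probability
    ``p_edge``; each forward edge gains, with probability ``p_recip``, a
    reciprocal partner, closing a 2-cycle.  More reciprocal pairs mean
    stronger strongly connected components and a lower critical coupling.
    The one-direction-per-pair invariant of inferred networks is relaxed
    here: these are generator-side effective networks, not pipeline output.
    """
    order = rng.permutation(n_nodes)
    w = np.zeros((n_nodes, n_nodes))
    for i in range(n_nodes):
        for j in range(i + 1, n_nodes):
            if rng.random() < p_edge:
                s, t = order[i], order[j]
                w[t, s] = rng.uniform(0.3, 1.0)
                if rng.random() < p_recip:
                    w[s, t] = rng.uniform(0.3, 1.0)
    return DirectedFunctionalNetwork(weights=w, labels=labels,
                                     band="synthetic",
                                     provenance={"generator": "gen_cohort"},
                                     enforce_antisymmetry=False)


def gen_cohort(n_cases: int, n_controls: int, effect: float,
               base_params: dict | None = None, seed: int = 0,
               bands: tuple[str, ...] = ("theta", "low_alpha")
               ) -> tuple[list[DirectedFunctionalNetwork],
                          list[DirectedFunctionalNetwork], dict]:
    """Two-group ensemble of subject networks with a controlled kappa_c shift.

    Controls are sparse DAG-dominant digraphs whose forward edges are
    reciprocated with a small base probability; cases use the identical
    generator with the reciprocation probability raised in proportion to
    ``effect`` in [0, 1], planting more strongly connected components and
    hence stochastically lower critical couplings.  effect = 0 makes the
    groups exchangeable.

    One independent network is drawn per subject and per entry of
    ``bands`` (default: the theta and low-alpha bands, the two bands the
    study design treats as carriers of the effect), so the downstream
    group comparison corrects over that family of hypotheses.  Returns
    (cases, controls, truth record); the returned lists are flat, with
    each network labelled by its band and subject in its provenance.
    """
    if n_cases < 2 or n_controls < 2:
        raise ValueError("need at least 2 subjects per group")
    if not 0.0 <= effect <= 1.0:
        raise ValueError("effect must lie in [0, 1]")
    p = dict(base_params or {})
    n_nodes = int(p.get("n_nodes", 19))
    p_edge = float(p.get("p_edge", 0.15))
    p_recip_base = float(p.get("p_recip_base", 0.05))
    p_recip_case = p_recip_base + effect * float(p.get("recip_gain", 0.45))
    labels = (MONTAGE_10_20 if n_nodes == len(MONTAGE_10_20)
              else [f"node{c}" for c in range(n_nodes)])
    band_jitter = float(p.get("band_jitter", 0.1))
    rng = np.random.default_rng(seed)
    controls, cases = [], []
    for group, out, n_subj, p_recip in (("control", controls, n_controls,
                                         p_recip_base),
                                        ("case", cases, n_cases,
                                         p_recip_case)):
        for i in range(n_subj):
            # one topology per subject; per-band networks share it with
            # band-specific multiplicative weight noise, emulating the
            # strong within-subject dependence of real band networks
            base = _random_subject_network(n_nodes, p_edge, p_recip, rng,
                                           labels)
            for band in bands:
                w = base.weights * rng.uniform(1 - band_jitter,
                                               1 + band_jitter,
                                               size=base.weights.shape)
                net = DirectedFunctionalNetwork(
                    weights=w, labels=labels, band=band,
                    provenance={"generator": "gen_cohort",
                                "subject": f"{group}{i:03d}", "group": group},
                    enforce_antisymmetry=False)
                out.append(net)
    truth = {"effect": effect, "p_edge": p_edge,
             "p_recip_control": p_recip_base, "p_recip_case": p_recip_case,
             "n_nodes": n_nodes, "bands": list(bands), "seed": seed}
    return cases, controls, truth
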