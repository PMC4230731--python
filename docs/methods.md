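# Methods

## Model

Each node i of a directed weighted network hosts N phase oscillators with
all-to-all sine coupling of strength K_i/N; nodes interact through the
adjacency A (orientation: `A[i, j]` lets node j drive node i) scaled by a
global coupling κ.  The inter-node term acts through the driving node's
mean field, κ A_ij r_j sin(ψ_j − θ): this is the form the
thermodynamic-limit reduction assumes, and it equals the microscopic
per-oscillator double sum divided by N in the large-N limit.  Natural
frequencies are i.i.d. draws from a symmetric unimodal density with mean Ω
and sd 1 (the sd fixes the model's time unit; Ω defaults to 0, the
co-rotating frame, which leaves every order parameter unchanged).

### Simulation

Fixed-step RK4 with default dt = 0.01 time units.  The dynamics are
non-stiff (phase velocities are O(K + κ‖A‖)), so a fixed step keeps runs
exactly reproducible; halving dt changes long-time mean order parameters
by less than their Monte-Carlo error (tested).  Phases are wrapped to
[0, 2π) at stored steps; initial phases are i.i.d. uniform from the seed.
Reported r values are time averages over the second half of a run (the
first half is discarded as transient).  Default problem sizes: N = 10³
oscillators per node in tests, N = 5·10³–10⁴ where a run serves as the
oracle for the mean field.  The summed-sine node signal Σ_k sin θ_ik is
the EEG-like observable: ≈ N·r·sin ψ(t) when locked (a large sinusoid at
the mean frequency), sd ≈ √(N/2) when incoherent.

### Mean field

In the limit N → ∞ the locked population of node i contributes

    r_i = H(X_i),   X_i = K_i r_i + κ (A r)_i,

where X_i is the total locking field (oscillators with |ω| ≤ X_i lock)
and H(x) = x ∫ g(x sin φ) cos²φ dφ over φ ∈ (−π/2, π/2).  For normal g the
integral reduces to the Bessel form √(π/8)·x·e^{−x²/4}[I₀ + I₁](x²/4),
evaluated with exponentially scaled Bessel functions (`scipy.special.ive`)
so large drives cannot overflow; for any admissible density the same
quantity is computed by adaptive quadrature, and the two routes agree to
10⁻⁸ across the drive range (tested).  Only symmetric unimodal zero-mean
densities are admitted: the reduction of the global order parameter R to
the arithmetic mean of the node r_i relies on all node mean fields
aligning in phase beyond onset, which that symmetry (plus non-negative
weights) guarantees.  Below onset R = mean(node_r) = 0 by convention.

The system is solved by damped fixed-point iteration (damping 0.5,
tolerance 10⁻¹⁰ on the sup-norm step, max 10⁴ iterations) from the upper
seed r = 1: the map is monotone and bounded by 1, so the iterates descend
onto the largest fixed point — the locked branch when it exists, the zero
branch otherwise.  A converged vector with max r < 10⁻⁶ is collapsed onto
the exact zero branch.  Near-critical couplings (within ~10⁻³ of onset)
converge slowly and may exhaust the iteration budget; callers that sweep κ
should treat a non-converged solve as diagnostic, not as data.

The isolated-node critical coupling is computed two independent ways:
K_c = 2/(π g(0)) from the linearized slope condition K·H′(0) = 1, and by
bisection on the existence of a positive root of r = H(K r) with H
evaluated by quadrature.  Both give √(8/π) ≈ 1.59577 for the standard
normal density to 10⁻⁸.

### Critical coupling of a network

Linearizing r = H(K r + κ A r) around r = 0 with H′(0) = 1/K_c gives
D r = κ A r, D = diag(K_c − K_i), valid when every node is sub-critical
(otherwise the package directs the caller to the node-driven scan).  The
critical global coupling is κ_c = 1/λ_max(D⁻¹A) over real positive
eigenvalues; since D⁻¹A is entrywise non-negative its spectral radius is
attained by a real non-negative eigenvalue (Perron–Frobenius), which the
implementation asserts as an internal cross-check.  Numerically real
eigenvalues are admitted at |Im λ| ≤ 10⁻⁹·max(1, |λ|), because the matrix
is non-symmetric and rounding scatters tiny imaginary parts.  An
independent determinant route scans det(D − κA) on 400 log-spaced κ values
over [10⁻³, 10³]·(K_c − max K_i) and bisects the first sign change to
10⁻¹⁰ relative; the two methods agree to better than 10⁻⁶ on random
strongly connected digraphs (tested).  No sign change means κ_c = +∞ —
a valid result (hierarchical flow), not an error.

Motif closed forms: two nodes with weights a₁₂, a₂₁ give
κ_c = √((K_c−K₁)(K_c−K₂)/(a₁₂a₂₁)); an n-cycle gives
(Π(K_c−K_i)/Π a_e)^{1/n}, evaluated in log space for numerical stability
at large n.  Both reduce to K_c − K for unit weights and equal couplings.

### The seven-node illustration

The packaged seven-node fixtures are *reconstructed* from their prose
description (the original edge list is not fully printed): variant A has
edges 1→2, 2→3, 1→3, 3→5, 5→2, 5→6, 6→7, 1→4, containing the cycle
{2,3,5} with downstream nodes 6, 7 while nodes 1 and 4 receive nothing
from the cycle; variant B removes 5→2 (a pure hierarchy, κ_c = ∞);
variant C reverses 1→2, creating the strongly connected component
{1,2,3,5} that reaches every node, so the whole network synchronizes
beyond a finite κ_c.  All three behaviours are verified analytically and,
for variant A, microscopically.

## Functional network inference

The pipeline is built for 19-channel 10–20-montage scalp recordings of
about 20 s at 256 Hz, but accepts any ≥2-channel recording.

* **Preprocessing** — zero-phase (forward–backward) 4th-order Butterworth
  band-pass 1–70 Hz, band-stop 48–52 Hz, per-channel demeaning.
  Zero-phase filtering matters: filter delay would bias every lag
  estimate downstream.
* **Bands** — delta 1–3, theta 3–6, low-alpha 6–9, high-alpha 9–12,
  beta 12–25, gamma 25–70 Hz.  The theta and low-alpha edges are the
  physiologically pinned ones; the rest follow the same
  maximally-independent subdivision of the clinical bands and are fully
  config-overridable.
* **Lagged cross-correlation** — for each pair, the Pearson correlation
  of the overlapping windows at every lag τ ∈ [−max_lag, max_lag]
  (default max_lag = 200 ms of samples, the physiological conduction-delay
  range), computed via FFT cross-products plus prefix-sum window moments
  so every lag's value is exactly normalized to [−1, 1].  The pair
  statistic is the maximum absolute value; ties break toward the smallest
  |lag|, then the negative lag, making output deterministic.  Positive
  best lag means the first channel leads and takes the source role.
* **IAAFT surrogates** — iterative amplitude-adjusted Fourier transform,
  default 100 iterations, ending on the amplitude step so the surrogate's
  value multiset equals the original's exactly while the power spectrum
  is matched to <1% relative L2 error on AR(1)-like signals (tested).
  Surrogates preserve each channel's autocorrelation but destroy genuine
  cross-correlation, giving a per-pair null for the max-lagged-correlation
  statistic.
* **Significance** — rank test: a pair survives iff
  (1 + #{null ≥ observed})/(n_surrogates + 1) ≤ α.  Defaults: 199
  surrogates, α = 0.005, i.e. the observed value must exceed every
  surrogate.  The choice is driven by the package's own recovery bar:
  with 171 channel pairs, a per-pair level of 0.05 admits ~8 false pairs
  in expectation, overwhelming ~10 genuine edges; at 0.005 the expected
  false count is 0.8.  Both the level and the count are configuration.
* **Directionalization** — each surviving pair becomes one directed edge,
  source = leading channel; pairs with best lag exactly 0 are discarded
  as putative volume conduction, which also guarantees at most one
  direction per pair.
* **Pruning** — an edge is removed when a stronger 2-edge path (first
  pass, on the directionalized weights) or 3-edge path (second pass, on
  the first pass's survivors) connects the same nodes.  Path strength is
  the bottleneck (minimum edge weight) by default — the weakest-link
  reading, which is scale-free — with the edge-weight product available
  as config.  Pruning never adds edges and is idempotent.

## Cohort analysis

Per subject and band, two model-based measures: (1) κ_c of the subject's
inferred network with all K_i fixed at K_c/2 (sub-critical; any common
sub-critical value only rescales the measure), and (2) the node-driven
scan — each node in turn gets K_s = 2·K_c while the others stay at K_c/2,
the nonlinear mean field is solved at a scan coupling κ = K_c/2, and
R = mean(node_r) records how strongly that node drives the network.
Groups are compared with the two-sided Wilcoxon rank-sum test (exact
enumeration for pooled n ≤ 12 without ties, tie-corrected
continuity-corrected normal approximation otherwise; +∞ values rank at
the extreme), Bonferroni-corrected over the family actually tested (bands
for κ_c; the 19 electrodes for the node-driven family).  Measures
significant after correction get an ROC sweep over all thresholds
("score ≤ threshold ⇒ positive" for κ_c, flipped for R), trapezoidal AUC,
and PPV/FDR/sensitivity/specificity at the point closest to perfect
classification (0, 1).

## Synthetic data: what it emulates and what it does not

The clinical recordings behind the study design are not publicly
deposited, so every input is generated with known ground truth.

* **Lagged recordings** (primary inference test bed): each channel is
  AR(1)-filtered (coefficient 0.95) band-limited 1–70 Hz noise — a 1/f-like
  background whose autocorrelation forces the surrogate test to do real
  work — plus gain-weighted (0.7), delayed (15–120 ms) copies of its
  parent channels and white measurement noise (sd 0.3).  Planted edges
  form disjoint directed chains (in/out-degree ≤ 1): chains make indirect
  ancestor correlations that the pruning stage must remove, while
  avoiding hidden common drivers, whose induced sibling correlation no
  pairwise method can reject even in principle.  A correlation-based
  pipeline is matched to this linear generator by design; the Kuramoto
  recording generator provides the nonlinear path (background-to-seizure
  amplitude transitions) for qualitative checks.  The generator does not
  model volume-conduction mixing or electrode physics beyond additive
  white noise, so passing recovery tests demonstrate correctness of the
  pipeline, not robustness to mixing artifacts in real scalp data.
* **Cohorts**: per subject, a sparse random digraph — edges run forward
  along a random node order with probability 0.15, weights U(0.3, 1) —
  whose forward edges gain a reciprocal partner with probability 0.05
  (controls) rising to 0.50 at effect = 1 (cases).  Reciprocal pairs
  close cycles, raising the spectral radius and stochastically lowering
  κ_c for cases; effect = 0 makes the groups exchangeable.  Each subject
  contributes one network per band (theta, low-alpha) sharing the
  subject's topology with ±10% band-specific weight noise, emulating the
  strong within-subject dependence of real band networks; that dependence
  is what makes the Bonferroni correction conservative rather than exact,
  as in the real study design.  At the study's sample sizes (35 vs 40)
  the designed effect yields near-certain detection with ROC PPV ≈ 0.9.

## Empirical onset detection

Where a simulated synchronization onset is compared against the analytic
κ_c (the two-node motif at N = 5000), the detector is: take the κ = 0
baseline run, form the time series of per-node-averaged r(t) over the
retained half, and set the threshold at its mean plus three temporal
standard deviations; the empirical onset is the smallest κ in the sweep
whose time-averaged r exceeds that threshold.  The sweep grid
(0.55, 0.75, 0.95, 1.1, 1.25, 1.4)·κ_c is coarse below onset, where
finite-size critical precursors grow smoothly and would otherwise trip
any fixed threshold well below κ_c — with this design the detector lands
within one grid step of the true onset.  Beyond onset the analytic r(κ)
and the simulated time-average agree within 0.05 pointwise.

## Known limitations

* The mean-field machinery assumes non-negative weights and symmetric
  unimodal frequency densities; inhibitory (negative) connections and
  bimodal densities are out of scope.
* No time-delayed coupling, no noise term in the phase equation, no
  amplitude dynamics.
* The locked branch is reported on existence; its stability beyond onset
  is not analyzed, and partially locked drifting-cluster corrections are
  ignored.
* Near-critical mean-field solves converge slowly (critical slowing of
  the fixed-point map); sweeps should avoid κ within ~10⁻³·κ_c of onset
  or raise the iteration budget.
* The surrogate test controls autocorrelation-induced false positives
  per pair; it does not correct for the multiplicity of pairs beyond the
  per-pair level, and it cannot reject correlations induced by hidden
  common sources.
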