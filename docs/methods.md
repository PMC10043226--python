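# Methods

## Model

Each node is a six-dimensional Epileptor: the five canonical state
variables plus the auxiliary filter state g. The convolution
g(t) = ∫ e^(−γ(t−τ)) x₁(τ) dτ is realized exactly as the linear ODE
ġ = x₁ − γg with g(0) = 0, which costs O(1) per step instead of O(t)
quadrature; the equivalence is oracle-tested against trapezoid quadrature
of the integral (agreement is O(dt²), the quadrature's own order).

Three conventions in this model family circulate with both signs or both
arguments; all are configurable, with the following defaults:

- **SLE observable**: x₁ + x₂ (the alternative −x₁ + x₂ is available as
  `convention="inverted"`).
- **f₂ branch condition**: tested on x₁ (switchable to x₂).
- **Memory-filter input**: x₁ feeds g (switchable to x₂), consistent with
  the single-oscillator definition of g.

### Coupling sign

Nodes couple through the permittivity variable:
ż ᵢ includes −Σⱼ Sᵢⱼ (x₁,ⱼ − x₁,ᵢ). With this (default, `"spread"`) sign a
seizing neighbour (x₁ high) drives a healthy node's z *down*, toward the
saddle-node seizure-onset bifurcation — the mechanism of delayed
recruitment, and the standard convention of the permittivity-coupling
literature. The transposed sign (`"printed"`, subtracting
Σⱼ Sᵢⱼ (x₁,ᵢ − x₁,ⱼ)) acts suppressively: it pushes a healthy node's z up
and away from onset when neighbours seize, cannot produce recruitment, and
under strong focal coupling is numerically unstable. Since seizure onset
occurs when z *falls* through the saddle-node bifurcation (and offset when
it rises through the homoclinic one), only the spread sign is consistent
with network seizure propagation; it is therefore the default, with the
suppressive variant retained as a configuration switch.

## Numerics

- Classic fixed-step RK4, default dt = 0.05 model time units — small
  enough to resolve the fast discharges (fourth-order convergence is
  verified by step-halving, error ratio ≈ 16). The coupling vector is
  recomputed at every RK4 substage.
- Default run length 6 τ₀ (≈ 17 000 time units, 5–9 seizure cycles), with
  the first τ₀ discarded as an initial-condition transient.
  Functional-connectivity runs use 4 τ₀ (transient τ₀ discarded, ≈ 3 full
  cycles analysed), trading run length for replicate breadth.
- Initial condition (x₁, y₁, z, x₂, y₂, g) = (−1.6, −10, 3, −0.6, 0, 0)
  (on the interictal branch) plus per-node uniform jitter of ±0.05 under a
  stated seed to break symmetry in networks.
- Overflow guard: integration aborts with a diagnostic naming the first
  bad step when any component leaves ±10⁶.
- Optional noise is additive Gaussian on x₂ only, applied
  Euler–Maruyama-style (√dt increments) after each RK4 drift step; all
  headline experiments run with noise off. Note that below seizure onset
  the x₂ subsystem does not feed back into (x₁, y₁, z), so this noise
  cannot itself trigger onsets — it is a waveform perturbation, not an
  escape mechanism.
- Determinism: every stage is bit-reproducible from (config, seed).
  Synchrony invariance (identical nodes, identical initial conditions →
  identical trajectories) is exact because each difference-coupling addend
  is exactly zero. Permutation equivariance is exact for networks of up to
  three nodes (coupling sums then have at most two nonzero addends, and
  floating-point addition is commutative); for larger networks relabeling
  reorders the coupling summation and equivariance holds only to rounding,
  which is why the exactness test runs at n = 3.

## Synthetic study inputs

- **Base network**: fully connected; nodes on a ring indexed 0..n−1,
  weight = 1/ring-distance. The underlying distance rule is pluggable —
  any notion of inter-node path length works; the ring is the simplest
  consistent choice.
- **Focal subnetwork**: Watts–Strogatz ring (mean degree k, rewiring p,
  with p = 0 the regular and p = 1 the random case) or a scale-free graph
  parameterized directly by its power-law exponent γ_sf: degrees sampled
  from P(k) ∝ k^−γ (minimum 1), realized via the configuration model
  collapsed to a simple graph, extra components reconnected into the giant
  one. Focal edges are written into the base matrix at
  K × max(base weight), K = 10 by default, so every focal–focal edge
  strictly dominates every other weight while the network stays fully
  connected ("prominent" embedding, replacement rather than addition).
- **Excitability**: focal x₀ ~ N(μ, σ²) truncated above the threshold by
  rejection sampling (σ = 0 degenerates to exactly μ); non-focal nodes
  share x₀ = −2.2 — below threshold yet recruitable. μ defaults to −1.6,
  well inside the seizing regime. Neither value is forced by theory; they
  are the conventional operating points for this model family. The global
  coupling scale defaults to 1.
- All generators are seeded and deterministic; experiment drivers expand
  one root seed counter-style (`derive_seed`) so growing the replicate
  count never reshuffles earlier replicates.

What the generator does *not* emulate: empirical connectome topology or
tract weights, conduction delays, directed or signed coupling,
physiological noise. Passing tests therefore demonstrate the mechanisms
(recruitment via permittivity coupling, excitability-controlled rhythm,
heterogeneity-driven desynchronization) on idealized networks, not
quantitative agreement with recorded EEG or imaging data.

## Seizure analytics

Events are detected on x₁ with hysteresis: onset at an upward crossing of
−0.5, offset after a dwell of min_ictal/5 time units below −1.0, events
shorter than min_ictal = 50 discarded. These levels sit in the wide gap
between the model's ictal x₁ (≈ −0.5 … +1.2, never reaching −1 during a
discharge) and its interictal branch (≈ −1.9 … −0.9), so detection is
insensitive to the fast ictal ripple.

The **seizure period** is the mean onset-to-onset interval with each
node's first onset discarded as transient, pooled *over the whole
network*. The system-wide pooling matters: at low focal proportion the
focal cluster exhibits extra re-entrant onsets (echo events between
collective cycles, driven by the delayed seizures of the larger healthy
population pulling focal z back down), which are not part of the
network-wide rhythm; healthy nodes lock cleanly to the collective cycle.
Measured system-wide, the period falls with the focal excitability level
μ and with the focal proportion and is insensitive (< 10 % here) to the
excitability spread σ.

**Recruitment** is the fraction of non-focal nodes with at least one
event; **onset delay** is a non-focal node's first onset minus the
earliest focal first onset.

## Functional connectivity

Functional networks keep the top fraction (default 27.5 %) of pairwise
Pearson correlations, ranked by signed value (large correlations in this
model are positive co-oscillation; absolute ranking is available), with
ties at the cut broken by node index for determinism and the edge count
fixed at round(fraction · n(n−1)/2), rounding half up.

The heterogeneity experiment correlates the **permittivity variable z**,
each node's slow functional-activity signal. The raw electrographic
observable is a poor correlation substrate here: the permittivity coupling
locks the slow on/off cycle across nodes but not the phases of the fast
ictal spikes, so raw-SLE correlations saturate near 0.5 even for a
perfectly homogeneous focal cluster (and smoothed-SLE envelopes over
100–400 time-unit windows behave no better); correlations of z express
exactly the co-seizing structure the functional network is meant to
capture. With homogeneous focal excitability (σ = 0) the focal cluster's z
traces are near-identical, the cluster survives proportional thresholding
as a clique, and its normalized average degree sits at
(n_focal − 1)/(n − 1) ≈ the lesion proportion; growing σ desynchronizes
the cluster and prunes those edges. The raw-SLE observable remains
selectable (`signal="sle"`).

The replicate design is paired: within a replicate, the network seed, the
initial-condition jitter, and the underlying standard-normal deviations of
the x₀ draws are shared across σ cells (x₀ = μ + σ·ε with common ε), so
each replicate follows one network through increasing heterogeneity and
σ-comparisons are common-random-number paired. Monotonicity of the
degree–σ curve is accordingly judged on the paired per-replicate
differences (a consecutive uptick is accepted only if within one standard
error of the paired difference), since a strict inequality between noisy
replicate means is brittle on the small-world plateaus.

## Study sizes used by the default configurations

Scaled to run comfortably on one CPU: recruitment on 20 nodes,
period sweeps on 30 nodes (3 replicates), heterogeneity–degree on 40
nodes × 10 paired replicates per (family, σ) cell, with the 100-node
study scale behind `--full`. The threshold scan integrates 6 τ₀ per
bisection probe at dt = 0.05.

## Known limitations

- The coupling matrix is synthetic (ring-distance weights), not an
  empirical connectome; conclusions are about mechanism, not anatomy.
- Event detection assumes the Epileptor's waveform geometry; the default
  hysteresis levels are not meaningful for other models or for recorded
  EEG.
- The scale-free generator enforces connectedness by rewiring stranded
  components, which slightly perturbs the realized degree sequence at
  small n_focal.
- Permutation equivariance beyond n = 3 and cross-platform bit
  reproducibility are limited by floating-point summation order.
- With noise enabled the integrator is a first-order (Euler–Maruyama)
  splitting around the RK4 drift, adequate for the qualitative
  perturbation role noise plays here, not for SDE-convergence studies.
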