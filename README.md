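# epileptornet

Seizure generation and propagation on focal epileptic whole-brain networks
of coupled slow–fast **Epileptor** oscillators.

The package is aimed at computational neuroscientists studying how the
*distribution* of cortical excitability — its level, its spatial extent, and
its heterogeneity — shapes network-scale seizure dynamics: who gets
recruited, how often the network seizes, and what the resulting functional
connectivity looks like.

## The model

Each network node is an Epileptor, a five-variable phenomenological neural
mass model. A fast subsystem (x₁, y₁) produces ictal discharges, a slower
subsystem (x₂, y₂) produces spike–wave activity, and a very slow
*permittivity* variable z (standing for extracellular ion/metabolic
processes) carries the system around a hysteresis loop between interictal
and ictal branches:

```
ẋ₁ = y₁ − f₁(x₁, x₂, z) − z + I₁
ẏ₁ = 1 − 5x₁² − y₁
ż  = (1/τ₀) [ 4(x₁ − x₀) − z − Σⱼ Sᵢⱼ (x₁,ⱼ − x₁,ᵢ) ]
ẋ₂ = −y₂ + x₂ − x₂³ + I₂ + 0.002 g − 0.3 (z − 3.5)
ẏ₂ = (1/τ₂) [ −y₂ + f₂(x₁, x₂) ]
ġ  = x₁ − γ g
```

with I₁ = 3.1, I₂ = 0.45, τ₀ = 2857, τ₂ = 10, γ = 0.01. The
excitability parameter x₀ controls the regime of a node: above a critical
value **x₀ ≈ −2.05** a node seizes autonomously; below it the node rests
but can be *recruited* through the difference coupling in ż, which pulls a
healthy node's permittivity toward the seizure-onset bifurcation whenever
its neighbours seize.

The study networks are fully connected graphs (edge weight = inverse ring
distance between node indices) in which a subset of *focal* (lesion) nodes
receives suprathreshold excitability x₀,ᵢ ~ N(μ, σ²) truncated above the
threshold, and prominently strengthened mutual connections wired as a
regular ring, a Watts–Strogatz small world, a random graph, or a
scale-free graph.

## Worked example

Locate the epileptogenicity threshold of an isolated oscillator, then run
the recruitment experiment on a 20-node network (4 focal nodes at μ = −1.6,
healthy nodes at x₀ = −2.2):

```bash
$ epileptornet threshold-scan
...
--- bracket_trace ---
 iteration        lo        hi
         6 -2.064062 -2.050000
         7 -2.064062 -2.057031
$ epileptornet recruitment --seed 2
--- summary ---
   condition  replicate  recruitment_fraction  median_delay
  full_focal          0                1.0000         231.5
full_nofocal          0                0.0000           NaN
sparse_focal          0                0.8125         232.0
sparse_focal          1                0.6250         290.0
...
```

The threshold scan brackets the critical excitability at −2.06 (the
interval `[lo, hi]` after the final bisection step). The recruitment table
shows the three study conditions: with full connectivity every healthy node
is recruited (fraction 1.0) with a median onset delay of ~230 time units
behind the first focal seizure; with no focal nodes nothing seizes; with
sparse random coupling (density 0.1) recruitment is partial.

The same drivers are available as library functions
(`epileptornet.experiments.run_recruitment` etc.); the other two verbs are
`period-sweep` (seizure period vs. excitability level μ, focal proportion,
and heterogeneity σ) and `heterogeneity-degree` (normalized average degree
of the focal cluster in the top-27.5 % Pearson-correlation functional
network vs. σ, per focal topology family; `--full` switches from the
40-node CI scale to the 100-node study scale).

## Layout

- `epileptornet.dynamics` — single oscillator: model terms, RK4
  integration, regime classification, threshold bisection
- `epileptornet.synthetic` — base networks, focal topologies,
  truncated-normal excitability profiles
- `epileptornet.simulate` — coupled whole-network simulation
- `epileptornet.events` — seizure event detection, periods, onset delays,
  recruitment, synchrony
- `epileptornet.funcnet` — correlation matrices, proportional
  thresholding, degree statistics
- `epileptornet.experiments` / `epileptornet.cli` — config-driven
  experiment drivers
- `epileptornet.io` — delimited-text / NPZ export with YAML provenance
  sidecars

See `docs/methods.md` for modelling assumptions, parameter choices, and
known limitations.
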