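"""Coupled whole-network simulation.

All oscillators interact through the slow permittivity variable z: node i's
ż receives the difference coupling sum_j S_ij (x1,j - x1,i), so a seizing
neighbour (high x1) pulls a healthy node's z downward toward the seizure
onset bifurcation — the mechanism behind delayed recruitment.  The sign
convention is configurable; ``"spread"`` (the default, standard in the
permittivity-coupling literature and required for recruitment) subtracts
sum_j S_ij (x1,j - x1,i) inside ż, while ``"printed"`` subtracts the
transposed difference sum_j S_ij (x1,i - x1,j), which acts suppressively.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dynamics import (
    DEFAULT_DT,
    DEFAULT_INIT,
    ModelParams,
    Trajectory,
    _run_kernel,
)
from .errors import ParameterError
from .synthetic import ConnectivityMatrix, ExcitabilityProfile

__all__ = ["NetworkRunConfig", "coupling_term", "simulate_network"]


@dataclass(frozen=True)
class NetworkRunConfig:
    """Run-level knobs for a network simulation.

    ``record_every`` subsamples the stored trajectory (output spacing is
    dt * record_every).  ``jitter`` is the half-width of the uniform
    perturbation added to every component of every node's initial state to
    break symmetry; ``noise_sigma`` scales additive Gaussian noise applied
    to x2 after each RK4 step (Euler-Maruyama), 0 meaning fully
    deterministic.  ``coupling`` selects the z-coupling sign convention and
    ``g_input``/``f2_branch`` the fast-variable conventions of the memory
    filter and the f2 branch condition.
    """

    duration: float
    dt: float = DEFAULT_DT
    seed: int = 0
    noise_sigma: float = 0.0
    jitter: float = 0.05
    record_every: int = 20
    coupling: str = "spread"
    g_input: str = "x1"
    f2_branch: str = "x1"

    def __post_init__(self) -> None:
        if self.duration < 10 * self.dt:
            raise ParameterError("duration must be at least 10 steps")
        if self.dt <= 0 or self.record_every < 1:
            raise ParameterError("dt must be positive and record_every >= 1")
        if self.noise_sigma < 0 or self.jitter < 0:
            raise ParameterError("noise_sigma and jitter must be nonnegative")
        if self.coupling not in ("spread", "printed"):
            raise ParameterError("coupling must be 'spread' or 'printed'")


def coupling_term(x1_all: np.ndarray, weights, i: int) -> float:
    """Difference coupling sum_j S_ij (x1_i - x1_j) for node i.

    ``weights`` may be a ConnectivityMatrix (its scaled weights are used)
    or a plain array.  Algebraically equal to
    (row-sum of S at i) * x1_i - (S @ x1)_i.
    """
    w = weights.scaled_weights() if isinstance(weights, ConnectivityMatrix) else np.asarray(weights, dtype=float)
    x1 = np.asarray(x1_all, dtype=float)
    if not 0 <= i < x1.size:
        raise ParameterError("node index out of range")
    return float(np.dot(w[i], x1[i] - x1))


def default_initial_states(
    n: int, jitter: float, rng: np.random.Generator
) -> np.ndarray:
    """Per-node initial conditions: the interictal-branch default plus
    uniform jitter of +/- ``jitter`` on every component."""
    y0 = np.tile(np.asarray(DEFAULT_INIT, dtype=float), (n, 1))
    if jitter > 0:
        y0 += rng.uniform(-jitter, jitter, size=(n, 6))
    return y0


def simulate_network(
    weights: ConnectivityMatrix,
    profile: ExcitabilityProfile,
    params: ModelParams | None = None,
    cfg: NetworkRunConfig | None = None,
    init: np.ndarray | None = None,
) -> Trajectory:
    """Integrate the coupled network with fixed-step RK4.

    The coupling vector is recomputed at every RK4 substage.  With
    ``noise_sigma`` = 0 the run is bit-reproducible from
    (weights, profile, params, cfg); with noise on, additive Gaussian
    increments sqrt(dt) * noise_sigma * xi are applied to x2 after each
    drift step, drawn reproducibly from ``cfg.seed``.  ``init`` overrides
    the jittered default initial states (shape (n, 6)).
    """
    params = params or ModelParams()
    if cfg is None:
        cfg = NetworkRunConfig(duration=6.0 * params.tau0)
    n = weights.n
    if profile.n != n:
        raise ParameterError(
            f"profile has {profile.n} nodes but the network has {n}")
    rng = np.random.default_rng(cfg.seed)
    if init is None:
        y0 = default_initial_states(n, cfg.jitter, rng)
    else:
        y0 = np.asarray(init, dtype=float)
        if y0.shape != (n, 6):
            raise ParameterError(f"init must have shape ({n}, 6)")
    n_steps = int(round(cfg.duration / cfg.dt))
    if cfg.noise_sigma > 0:
        noise = (np.sqrt(cfg.dt) * cfg.noise_sigma
                 * rng.standard_normal((n_steps, n)))
    else:
        noise = np.empty((0, 0))
    S = weights.scaled_weights()
    times, out = _run_kernel(
        y0, S, bool(np.any(S)), profile.x0_values, params,
        cfg.dt, n_steps, cfg.record_every, noise,
        g_input=cfg.g_input, f2_branch=cfg.f2_branch,
        coupling_sign=1.0 if cfg.coupling == "spread" else -1.0,
    )
    return Trajectory(times=times, states=out, dt=cfg.dt * cfg.record_every)
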