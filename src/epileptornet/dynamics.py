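"""The single Epileptor oscillator: model definition, integration, and the
epileptogenicity threshold.

The Epileptor is a five-variable phenomenological neural mass model of
seizure-like events.  A fast subsystem (x1, y1) generates the rapid ictal
discharges, a slower subsystem (x2, y2) produces spike-wave activity, and
the very slow permittivity variable z — standing in for extracellular
processes such as ion concentrations and metabolism — drives the system
around a hysteresis loop between the interictal and ictal branches.
Seizures start when z falls through a saddle-node-on-invariant-circle
bifurcation of the fast subsystem and stop when it rises through a
homoclinic one.

The excitability parameter x0 positions the z-nullcline: above a critical
value (about -2.05 for the default constants) the oscillator cycles
autonomously between ictal and interictal phases; below it the system rests
at a stable fixed point.

The slow memory term g is the exponentially weighted history of the fast
variable, realized here as the state of the equivalent linear low-pass
filter dg/dt = x_in - gamma * g with g(0) = 0, which is exactly the
convolution integral with kernel exp(-gamma * (t - tau)).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from . import _kernel
from .errors import (
    BracketError,
    DomainError,
    InsufficientDataError,
    IntegrationBlowupError,
    ParameterError,
)

__all__ = [
    "ModelParams",
    "EpileptorState",
    "Trajectory",
    "DEFAULT_INIT",
    "DEFAULT_DT",
    "OVERFLOW_GUARD",
    "f1",
    "f2",
    "derivatives",
    "integrate",
    "sle_signal",
    "classify_regime",
    "find_threshold",
]

#: default integration step (model time units); resolves the fast discharges
DEFAULT_DT = 0.05

#: default initial condition (x1, y1, z, x2, y2, g): on the interictal branch
DEFAULT_INIT = (-1.6, -10.0, 3.0, -0.6, 0.0, 0.0)

#: integration aborts when any state component leaves [-guard, guard]
OVERFLOW_GUARD = 1e6

GInput = Literal["x1", "x2"]
F2Branch = Literal["x1", "x2"]
SleConvention = Literal["sum", "inverted"]


@dataclass(frozen=True)
class ModelParams:
    """Epileptor model constants.

    Defaults are the standard values for this model family: I1 = 3.1 and
    I2 = 0.45 are the external currents of the fast and slower subsystems,
    tau0 = 2857 sets the permittivity timescale (and hence the seizure
    cycle length), tau2 = 10 the spike-wave subsystem timescale, and
    gamma_filter = 0.01 the decay rate of the memory kernel g.
    ``x_threshold`` is the critical epileptogenicity separating the
    quiescent from the autonomously seizing regime.
    """

    I1: float = 3.1
    I2: float = 0.45
    tau0: float = 2857.0
    tau2: float = 10.0
    gamma_filter: float = 0.01
    x_threshold: float = -2.05

    def __post_init__(self) -> None:
        if not (self.tau0 > 0 and self.tau2 > 0 and self.gamma_filter > 0):
            raise ParameterError("tau0, tau2 and gamma_filter must be positive")


@dataclass(frozen=True)
class EpileptorState:
    """Per-node state vector (x1, y1, z, x2, y2) plus the filter state g."""

    x1: float
    y1: float
    z: float
    x2: float
    y2: float
    g: float = 0.0

    def as_array(self) -> np.ndarray:
        arr = np.array([self.x1, self.y1, self.z, self.x2, self.y2, self.g],
                       dtype=float)
        if not np.all(np.isfinite(arr)):
            raise DomainError("state components must be finite")
        return arr

    @classmethod
    def from_array(cls, arr) -> "EpileptorState":
        a = np.asarray(arr, dtype=float).reshape(6)
        return cls(*a.tolist())


@dataclass(frozen=True)
class Trajectory:
    """A uniformly sampled path of one oscillator or of a whole network.

    ``states`` has shape (T, 6) for a single node or (T, n, 6) for a
    network; the last axis is ordered (x1, y1, z, x2, y2, g).  ``dt`` is
    the spacing of the *recorded* samples, which may be a multiple of the
    integration step.
    """

    times: np.ndarray
    states: np.ndarray
    dt: float

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        states = np.asarray(self.states, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "states", states)
        if times.ndim != 1 or times.size < 2:
            raise ParameterError("a trajectory needs at least 2 samples")
        if times[0] < 0:
            raise ParameterError("times must start at a nonnegative instant")
        spacing = np.diff(times)
        if not np.allclose(spacing, self.dt, rtol=1e-9, atol=1e-9):
            raise ParameterError("trajectory samples must be uniformly spaced")
        if states.shape[0] != times.size or states.shape[-1] != 6:
            raise ParameterError("states must be (T, 6) or (T, n, 6)")

    @property
    def n_nodes(self) -> int:
        return 1 if self.states.ndim == 2 else self.states.shape[1]

    def var(self, name: str) -> np.ndarray:
        """Return one state variable, shape (T,) or (T, n)."""
        idx = _kernel.STATE_VARS.index(name)
        return self.states[..., idx]

    @property
    def x1(self) -> np.ndarray:
        return self.var("x1")


def _check_finite(*vals: float) -> None:
    for v in vals:
        if not math.isfinite(v):
            raise DomainError("non-finite input")


def f1(x1: float, x2: float, z: float) -> float:
    """Cubic/paraboloid branch function of the fast subsystem.

    Returns x1^3 - 3 x1^2 for x1 < 0 and (x2 - 0.6 (z - 4)^2) x1 otherwise.
    """
    _check_finite(x1, x2, z)
    if x1 < 0.0:
        return x1 ** 3 - 3.0 * x1 ** 2
    return (x2 - 0.6 * (z - 4.0) ** 2) * x1


def f2(x1: float, x2: float, branch: F2Branch = "x1") -> float:
    """Rectified drive of the spike-wave subsystem: 0 below the branch
    point, 6 (x2 + 0.25) above.

    The branch condition tests x1 by default; ``branch="x2"`` switches the
    test to x2 (both conventions circulate in the model literature).
    """
    _check_finite(x1, x2)
    bvar = x1 if branch == "x1" else x2
    if bvar < -0.25:
        return 0.0
    return 6.0 * (x2 + 0.25)


def derivatives(
    state: EpileptorState,
    params: ModelParams,
    x0: float,
    coupling: float = 0.0,
    *,
    g_input: GInput = "x1",
    f2_branch: F2Branch = "x1",
    coupling_convention: str = "spread",
) -> np.ndarray:
    """Right-hand side of the six-dimensional Epileptor ODE for one node.

    ``coupling`` is the precomputed permittivity coupling sum
    sum_j S_ij (x1_i - x1_j) (zero for an isolated node).  Under the
    default ``"spread"`` convention it is added inside the z equation
    (equivalently, sum_j S_ij (x1_j - x1_i) is subtracted), so seizing
    neighbours pull z toward onset; ``"printed"`` subtracts it instead (see
    :mod:`epileptornet.simulate`).  ``g_input`` selects which fast variable
    feeds the memory filter g.
    """
    s = state.as_array()
    _check_finite(x0, coupling)
    if coupling_convention not in ("spread", "printed"):
        raise ParameterError("coupling_convention must be 'spread' or 'printed'")
    sign = 1.0 if coupling_convention == "spread" else -1.0
    x1v, y1v, zv, x2v, y2v, gv = s
    dx1 = y1v - f1(x1v, x2v, zv) - zv + params.I1
    dy1 = 1.0 - 5.0 * x1v ** 2 - y1v
    dz = (4.0 * (x1v - x0) - zv + sign * coupling) / params.tau0
    dx2 = (-y2v + x2v - x2v ** 3 + params.I2 + 0.002 * gv
           - 0.3 * (zv - 3.5))
    dy2 = (-y2v + f2(x1v, x2v, branch=f2_branch)) / params.tau2
    dg = (x1v if g_input == "x1" else x2v) - params.gamma_filter * gv
    return np.array([dx1, dy1, dz, dx2, dy2, dg])


def _run_kernel(
    y0: np.ndarray,
    S: np.ndarray,
    has_coupling: bool,
    x0_vec: np.ndarray,
    params: ModelParams,
    dt: float,
    n_steps: int,
    record_every: int,
    noise: np.ndarray,
    *,
    g_input: GInput = "x1",
    f2_branch: F2Branch = "x1",
    coupling_sign: float = 1.0,
    guard: float = OVERFLOW_GUARD,
) -> tuple[np.ndarray, np.ndarray]:
    """Shared wrapper around the compiled RK4 loop; raises on blowup."""
    out, n_rec, bad_step = _kernel._rk4_run(
        np.ascontiguousarray(y0, dtype=float),
        np.ascontiguousarray(S, dtype=float),
        has_coupling,
        np.ascontiguousarray(x0_vec, dtype=float),
        params.I1, params.I2, params.tau0, params.tau2, params.gamma_filter,
        g_input == "x2", f2_branch == "x2", coupling_sign,
        float(dt), int(n_steps), int(record_every),
        noise, float(guard),
    )
    if bad_step:
        raise IntegrationBlowupError(bad_step, bad_step * dt, guard)
    times = dt * record_every * np.arange(n_rec)
    return times, out[:n_rec]


def integrate(
    params: ModelParams,
    x0: float,
    init: EpileptorState | None = None,
    duration: float = None,
    dt: float = DEFAULT_DT,
    record_every: int = 1,
    *,
    g_input: GInput = "x1",
    f2_branch: F2Branch = "x1",
) -> Trajectory:
    """Integrate the isolated oscillator with classic fixed-step RK4.

    Deterministic: identical inputs give bit-identical trajectories.
    ``duration`` defaults to 6 * tau0, long enough for several seizure
    cycles.  ``record_every`` subsamples the stored path (the integration
    step itself is always ``dt``).
    """
    if duration is None:
        duration = 6.0 * params.tau0
    if dt <= 0:
        raise ParameterError("dt must be positive")
    if duration < dt:
        raise ParameterError("duration must be at least one step")
    if record_every < 1:
        raise ParameterError("record_every must be >= 1")
    if init is None:
        init = EpileptorState(*DEFAULT_INIT)
    _check_finite(x0)
    y0 = init.as_array()[None, :]
    n_steps = int(round(duration / dt))
    times, out = _run_kernel(
        y0, np.zeros((1, 1)), False, np.array([float(x0)]), params,
        dt, n_steps, record_every, np.empty((0, 0)),
        g_input=g_input, f2_branch=f2_branch,
    )
    return Trajectory(times=times, states=out[:, 0, :], dt=dt * record_every)


def sle_signal(traj: Trajectory, convention: SleConvention = "sum") -> np.ndarray:
    """Electrographic seizure-like-event observable.

    ``"sum"`` returns x1 + x2; ``"inverted"`` returns -x1 + x2, the
    convention of the original model literature.  Shape (T,) or (T, n).
    """
    if convention == "sum":
        return traj.var("x1") + traj.var("x2")
    if convention == "inverted":
        return -traj.var("x1") + traj.var("x2")
    raise ParameterError(f"unknown SLE convention {convention!r}")


def classify_regime(
    traj: Trajectory,
    transient_fraction: float = 1.0 / 6.0,
    amp_tol: float = 1.0,
    min_samples: int = 10,
) -> str:
    """Classify a single-node trajectory as ``"oscillatory"`` or
    ``"quiescent"``.

    Oscillatory means the post-transient peak-to-peak range of x1 exceeds
    ``amp_tol`` (default 1.0; the ictal/interictal x1 excursion is of order
    2, so this cleanly separates limit cycling from fixed-point ringing).
    The trajectory should span several potential seizure cycles, i.e. a few
    multiples of tau0.
    """
    if not 0.0 <= transient_fraction < 1.0:
        raise ParameterError("transient_fraction must be in [0, 1)")
    x1 = traj.x1
    if x1.ndim != 1:
        raise ParameterError("classify_regime expects a single-node trajectory")
    start = int(len(x1) * transient_fraction)
    tail = x1[start:]
    if tail.size < min_samples:
        raise InsufficientDataError(
            f"only {tail.size} post-transient samples (< {min_samples})")
    return "oscillatory" if float(tail.max() - tail.min()) > amp_tol else "quiescent"


def find_threshold(
    params: ModelParams,
    lo: float = -2.5,
    hi: float = -1.6,
    tol: float = 0.01,
    *,
    dt: float = DEFAULT_DT,
    duration: float | None = None,
    record_every: int = 10,
    amp_tol: float = 1.0,
    trace: list | None = None,
) -> float:
    """Locate the epileptogenicity threshold by bisection on x0.

    ``lo`` must classify quiescent and ``hi`` oscillatory; the bracket is
    narrowed until its width is at most ``tol`` and the midpoint of the
    final bracket is returned.  Each probe integrates for ``duration``
    (default 6 * tau0) and classifies the post-transient x1 amplitude,
    discarding the first sixth of the run as transient.  Pass ``trace`` to
    collect (lo, hi) after each step.
    """
    if tol <= 0:
        raise ParameterError("tol must be positive")
    if not lo < hi:
        raise ParameterError("need lo < hi")

    def probe(x0: float) -> str:
        traj = integrate(params, x0, duration=duration, dt=dt,
                         record_every=record_every)
        return classify_regime(traj, amp_tol=amp_tol)

    if probe(lo) != "quiescent":
        raise BracketError(f"lo = {lo} is not quiescent")
    if probe(hi) != "oscillatory":
        raise BracketError(f"hi = {hi} is not oscillatory")
    if trace is not None:
        trace.append((lo, hi))
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if probe(mid) == "oscillatory":
            hi = mid
        else:
            lo = mid
        if trace is not None:
            trace.append((lo, hi))
    return 0.5 * (lo + hi)
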