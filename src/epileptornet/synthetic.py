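"""Synthetic study inputs: weighted base networks, focal subnetwork
topologies, and truncated-normal excitability profiles.

The study networks are fully connected graphs whose edge weights decay with
the ring distance between node indices, with a small set of *focal* (lesion)
nodes whose mutual connections are made prominently strong and wired in a
chosen topology family (regular ring / Watts-Strogatz small-world / fully
rewired random / scale-free).  Focal nodes receive suprathreshold
excitability values drawn from a normal distribution truncated above the
epileptogenicity threshold; all other nodes share one healthy subthreshold
value.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import networkx as nx
import numpy as np

from .dynamics import ModelParams
from .errors import GenerationError, ParameterError, SamplingError

__all__ = [
    "ConnectivityMatrix",
    "FocalTopologySpec",
    "ExcitabilityProfile",
    "build_base_network",
    "build_sparse_random_network",
    "build_focal_adjacency",
    "embed_focal",
    "sample_x0",
    "build_study_network",
    "DEFAULT_X0_NONFOCAL",
    "DEFAULT_MU",
    "DEFAULT_STRENGTH_FACTOR",
]

#: healthy (non-focal) excitability: below threshold yet recruitable
DEFAULT_X0_NONFOCAL = -2.2

#: default mean excitability of focal nodes (well inside the seizing regime)
DEFAULT_MU = -1.6

#: focal-edge prominence multiplier relative to the strongest base weight
DEFAULT_STRENGTH_FACTOR = 10.0

TopologyFamily = Literal["regular", "smallworld", "random", "scalefree"]


@dataclass(frozen=True)
class ConnectivityMatrix:
    """Symmetric nonnegative coupling weights S with an optional embedded
    focal subnetwork.

    ``global_scale`` is a multiplier applied to all weights just before
    simulation (``scaled_weights``), leaving the stored matrix untouched.
    """

    weights: np.ndarray
    focal_indices: tuple[int, ...] = ()
    global_scale: float = 1.0

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        object.__setattr__(self, "weights", w)
        object.__setattr__(self, "focal_indices", tuple(int(i) for i in self.focal_indices))
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ParameterError("weights must be a square matrix")
        if not np.array_equal(w, w.T):
            raise ParameterError("weights must be symmetric")
        if np.any(np.diag(w) != 0):
            raise ParameterError("diagonal must be exactly zero")
        if np.any(w < 0):
            raise ParameterError("weights must be nonnegative")
        if any(not 0 <= i < w.shape[0] for i in self.focal_indices):
            raise ParameterError("focal index out of range")

    @property
    def n(self) -> int:
        return self.weights.shape[0]

    def scaled_weights(self) -> np.ndarray:
        return self.weights * self.global_scale

    def with_scale(self, scale: float) -> "ConnectivityMatrix":
        return replace(self, global_scale=float(scale))


@dataclass(frozen=True)
class FocalTopologySpec:
    """How the focal (lesion) subnetwork is wired.

    ``family`` selects a ring lattice (``regular``), Watts-Strogatz
    rewiring with probability ``p`` (``smallworld``; ``random`` is the p=1
    limit), or a power-law degree-sequence graph with exponent ``gamma_sf``
    (``scalefree``).  ``k`` is the even mean degree of the ring substrate
    and ``strength_factor`` the prominence multiplier K applied on
    embedding.
    """

    n_focal: int
    family: TopologyFamily = "smallworld"
    p: float = 0.3
    gamma_sf: float = 2.5
    k: int = 4
    strength_factor: float = DEFAULT_STRENGTH_FACTOR

    def __post_init__(self) -> None:
        if self.n_focal < 2:
            raise ParameterError("n_focal must be >= 2")
        if not 0.0 <= self.p <= 1.0:
            raise ParameterError("p must lie in [0, 1]")
        if self.family in ("regular", "smallworld", "random"):
            if not (0 < self.k < self.n_focal):
                raise ParameterError("need 0 < k < n_focal")
            if self.k % 2:
                raise ParameterError("k must be even (ring substrate)")
        if self.family == "scalefree" and self.gamma_sf <= 1.0:
            raise ParameterError("gamma_sf must exceed 1")
        if self.strength_factor <= 1.0:
            raise ParameterError("strength_factor must exceed 1")


@dataclass(frozen=True)
class ExcitabilityProfile:
    """Per-node epileptogenicity x0 with its generating distribution."""

    x0_values: np.ndarray
    focal_indices: tuple[int, ...]
    mu: float
    sigma: float
    x0_nonfocal: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "x0_values",
                           np.asarray(self.x0_values, dtype=float))
        object.__setattr__(self, "focal_indices",
                           tuple(int(i) for i in self.focal_indices))

    @property
    def n(self) -> int:
        return self.x0_values.size

    @property
    def nonfocal_indices(self) -> tuple[int, ...]:
        focal = set(self.focal_indices)
        return tuple(i for i in range(self.n) if i not in focal)


def build_base_network(n: int) -> ConnectivityMatrix:
    """Fully connected base network with weights inversely proportional to
    the ring distance between node indices.

    Nodes sit on a circle indexed 0..n-1; d(i, j) = min(|i-j|, n-|i-j|) and
    weight(i, j) = 1/d(i, j).  The strongest base weight is therefore 1
    (adjacent indices) and the weakest 1/floor(n/2).
    """
    if n < 2:
        raise ParameterError("need at least 2 nodes")
    idx = np.arange(n)
    diff = np.abs(idx[:, None] - idx[None, :])
    dist = np.minimum(diff, n - diff).astype(float)
    with np.errstate(divide="ignore"):
        w = np.where(dist > 0, 1.0 / np.where(dist > 0, dist, 1.0), 0.0)
    return ConnectivityMatrix(weights=w)


def build_sparse_random_network(
    n: int, density: float, weight: float = 1.0, seed: int | None = 0
) -> ConnectivityMatrix:
    """Erdős–Rényi-style sparse symmetric network with uniform edge weight.

    Each of the n(n-1)/2 undirected edges is present independently with
    probability ``density``.
    """
    if n < 2:
        raise ParameterError("need at least 2 nodes")
    if not 0.0 < density < 1.0:
        raise ParameterError("density must lie strictly in (0, 1)")
    if weight <= 0:
        raise ParameterError("weight must be positive")
    rng = np.random.default_rng(seed)
    upper = np.triu(rng.random((n, n)) < density, k=1)
    w = np.where(upper | upper.T, float(weight), 0.0)
    np.fill_diagonal(w, 0.0)
    return ConnectivityMatrix(weights=w)


def _powerlaw_degree_sequence(
    n: int, gamma: float, rng: np.random.Generator
) -> np.ndarray:
    """Sample degrees in 1..n-1 with P(k) proportional to k**-gamma."""
    ks = np.arange(1, n)
    pk = ks.astype(float) ** (-gamma)
    pk /= pk.sum()
    return rng.choice(ks, size=n, p=pk)


def build_focal_adjacency(spec: FocalTopologySpec, seed: int | None = 0) -> np.ndarray:
    """Unweighted simple adjacency matrix of the focal subnetwork.

    ``regular``/``smallworld``/``random`` use a Watts-Strogatz ring of mean
    degree k rewired with probability p (0, spec.p, 1 respectively).
    ``scalefree`` draws a power-law degree sequence with exponent gamma_sf
    (minimum degree 1), realizes it as a simple graph via the configuration
    model, and reconnects any disconnected components to a random node so
    the subnetwork is connected.
    """
    n = spec.n_focal
    rng = np.random.default_rng(seed)
    if spec.family in ("regular", "smallworld", "random"):
        p = {"regular": 0.0, "random": 1.0}.get(spec.family, spec.p)
        g = nx.watts_strogatz_graph(
            n, spec.k, p, seed=int(rng.integers(2 ** 31)))
    elif spec.family == "scalefree":
        g = None
        for _ in range(1000):
            degs = _powerlaw_degree_sequence(n, spec.gamma_sf, rng)
            if degs.sum() % 2:
                continue
            g = nx.Graph(nx.configuration_model(
                degs.tolist(), seed=int(rng.integers(2 ** 31))))
            g.remove_edges_from(nx.selfloop_edges(g))
            break
        if g is None:
            raise GenerationError(
                "no feasible power-law degree sequence in 1000 attempts")
        # simple-graph collapse can strand nodes; enforce min degree 1 and
        # connectedness by wiring every extra component into the giant one
        components = sorted(nx.connected_components(g), key=len, reverse=True)
        giant = sorted(components[0])
        for comp in components[1:]:
            a = int(rng.choice(sorted(comp)))
            b = int(rng.choice(giant))
            g.add_edge(a, b)
    else:  # pragma: no cover - guarded by the dataclass
        raise ParameterError(f"unknown family {spec.family!r}")
    return nx.to_numpy_array(g, nodelist=range(n), dtype=int)


def embed_focal(
    base: ConnectivityMatrix,
    focal_adj: np.ndarray,
    focal_indices: Sequence[int],
    strength_factor: float = DEFAULT_STRENGTH_FACTOR,
) -> ConnectivityMatrix:
    """Overlay the focal subnetwork onto a base network with prominent weight.

    Every edge of ``focal_adj`` is written into the base matrix at weight
    K * max(base weights) (replacing the base entry), so all focal-focal
    edges strictly dominate every non-focal weight while the network as a
    whole stays fully connected.
    """
    adj = np.asarray(focal_adj)
    m = adj.shape[0]
    if adj.ndim != 2 or adj.shape[1] != m:
        raise ParameterError("focal_adj must be square")
    if len(focal_indices) != m:
        raise ParameterError("focal_indices length must match focal_adj")
    idx = [int(i) for i in focal_indices]
    if any(not 0 <= i < base.n for i in idx):
        raise ParameterError("focal index out of range")
    if strength_factor <= 1.0:
        raise ParameterError("strength_factor must exceed 1")
    w = base.weights.copy()
    strong = strength_factor * float(base.weights.max())
    for a in range(m):
        for b in range(a + 1, m):
            if adj[a, b]:
                w[idx[a], idx[b]] = w[idx[b], idx[a]] = strong
    return ConnectivityMatrix(weights=w, focal_indices=tuple(idx),
                              global_scale=base.global_scale)


def sample_x0(
    n_total: int,
    focal_indices: Sequence[int],
    mu: float = DEFAULT_MU,
    sigma: float = 0.0,
    x0_nonfocal: float = DEFAULT_X0_NONFOCAL,
    params: ModelParams | None = None,
    seed: int | None = 0,
    max_rejections: int = 10_000,
) -> ExcitabilityProfile:
    """Draw a truncated-normal excitability profile.

    Focal values are i.i.d. N(mu, sigma^2) conditioned on exceeding the
    epileptogenicity threshold (rejection sampling); non-focal nodes share
    the healthy value ``x0_nonfocal``.  sigma = 0 gives every focal node
    exactly mu (the homogeneous case).
    """
    params = params or ModelParams()
    thr = params.x_threshold
    if not mu > thr:
        raise ParameterError("mu must exceed the epileptogenicity threshold")
    if sigma < 0:
        raise ParameterError("sigma must be nonnegative")
    if not x0_nonfocal < thr:
        raise ParameterError("x0_nonfocal must lie below the threshold")
    idx = [int(i) for i in focal_indices]
    if any(not 0 <= i < n_total for i in idx):
        raise ParameterError("focal index out of range")
    rng = np.random.default_rng(seed)
    x0 = np.full(n_total, float(x0_nonfocal))
    for i in idx:
        if sigma == 0.0:
            x0[i] = mu
            continue
        for _ in range(max_rejections):
            draw = rng.normal(mu, sigma)
            if draw > thr:
                x0[i] = draw
                break
        else:
            raise SamplingError(
                f"exceeded {max_rejections} rejections drawing x0 for node {i}; "
                "mu is too close to the threshold for this sigma")
    return ExcitabilityProfile(x0_values=x0, focal_indices=tuple(idx),
                               mu=float(mu), sigma=float(sigma),
                               x0_nonfocal=float(x0_nonfocal))


def build_study_network(
    n: int,
    spec: FocalTopologySpec,
    focal_indices: Sequence[int] | None = None,
    seed: int | None = 0,
) -> ConnectivityMatrix:
    """Convenience: base network + focal topology + prominent embedding.

    Focal indices default to 0..n_focal-1.
    """
    if focal_indices is None:
        focal_indices = tuple(range(spec.n_focal))
    base = build_base_network(n)
    adj = build_focal_adjacency(spec, seed=seed)
    return embed_focal(base, adj, focal_indices, spec.strength_factor)
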