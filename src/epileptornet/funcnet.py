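"""Functional connectivity of simulated seizure signals.

A functional network keeps the strongest fraction of pairwise Pearson
correlations between node signals as unweighted edges.  The headline
statistic of the heterogeneity experiment is the (normalized) average
degree of the focal nodes in this graph: with homogeneous focal
excitability the focal cluster co-oscillates almost perfectly and survives
proportional thresholding as a clique, so its normalized degree sits near
the focal proportion; heterogeneity desynchronizes the cluster and prunes
those edges.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable

import numpy as np

from .errors import InsufficientDataError, ParameterError

__all__ = [
    "FunctionalNetwork",
    "correlation_matrix",
    "threshold_top_fraction",
    "average_degree",
]

#: fraction of strongest correlations retained by default
DEFAULT_KEPT_FRACTION = 0.275


@dataclass(frozen=True)
class FunctionalNetwork:
    """Binarized top-fraction correlation graph."""

    adjacency: np.ndarray
    kept_fraction: float
    source_correlations: np.ndarray

    def __post_init__(self) -> None:
        adj = np.asarray(self.adjacency, dtype=int)
        object.__setattr__(self, "adjacency", adj)
        object.__setattr__(self, "source_correlations",
                           np.asarray(self.source_correlations, dtype=float))
        if not np.array_equal(adj, adj.T) or np.any(np.diag(adj) != 0):
            raise ParameterError("adjacency must be symmetric, zero-diagonal")

    @property
    def n(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum() // 2)

    def degrees(self) -> np.ndarray:
        return self.adjacency.sum(axis=1)


def correlation_matrix(
    signals: np.ndarray, transient_fraction: float = 1.0 / 6.0
) -> np.ndarray:
    """Pairwise Pearson correlations of per-node signals (shape (T, n)),
    computed on the post-transient window, with the diagonal zeroed for
    downstream ranking.

    Zero-variance channels get all-zero correlations (with a warning)
    rather than NaNs.
    """
    sig = np.asarray(signals, dtype=float)
    if sig.ndim != 2 or sig.shape[1] < 2:
        raise ParameterError("signals must be (T, n) with n >= 2")
    if not 0.0 <= transient_fraction < 1.0:
        raise ParameterError("transient_fraction must be in [0, 1)")
    start = int(sig.shape[0] * transient_fraction)
    sig = sig[start:]
    if sig.shape[0] < 100:
        raise InsufficientDataError(
            f"only {sig.shape[0]} post-transient samples (need >= 100)")
    sd = sig.std(axis=0)
    flat = sd == 0
    if np.any(flat):
        warnings.warn(f"{int(flat.sum())} zero-variance channel(s): "
                      "their correlations are set to 0", stacklevel=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(sig, rowvar=False)
    corr[np.isnan(corr)] = 0.0
    corr[flat, :] = 0.0
    corr[:, flat] = 0.0
    np.fill_diagonal(corr, 0.0)
    return corr


def threshold_top_fraction(
    corr: np.ndarray,
    fraction: float = DEFAULT_KEPT_FRACTION,
    ranking: str = "signed",
) -> FunctionalNetwork:
    """Keep the strongest ``fraction`` of the n(n-1)/2 possible edges.

    Upper-triangle entries are ranked descending by signed value (default)
    or by absolute value (``ranking="abs"``); exactly
    round(fraction * n(n-1)/2) edges are retained, rounding half up, with
    ties at the cut broken deterministically by (smaller i, then smaller j).
    """
    c = np.asarray(corr, dtype=float)
    if c.ndim != 2 or c.shape[0] != c.shape[1]:
        raise ParameterError("corr must be square")
    if not 0.0 < fraction <= 1.0:
        raise ParameterError("fraction must lie in (0, 1]")
    if ranking not in ("signed", "abs"):
        raise ParameterError("ranking must be 'signed' or 'abs'")
    n = c.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    vals = c[iu, ju]
    key = np.abs(vals) if ranking == "abs" else vals
    m = vals.size
    n_keep = int(math.floor(fraction * m + 0.5))
    order = np.lexsort((ju, iu, -key))  # primary: value desc; ties: (i, j) asc
    adj = np.zeros((n, n), dtype=int)
    sel = order[:n_keep]
    adj[iu[sel], ju[sel]] = 1
    adj[ju[sel], iu[sel]] = 1
    return FunctionalNetwork(adjacency=adj, kept_fraction=float(fraction),
                             source_correlations=c)


def average_degree(
    net: FunctionalNetwork, subset: Iterable[int], normalized: bool = True
) -> float:
    """Mean degree of a node subset; normalized by (n - 1) if requested so
    that a complete graph scores 1."""
    nodes = [int(i) for i in subset]
    if not nodes:
        raise ParameterError("subset must be non-empty")
    if any(not 0 <= i < net.n for i in nodes):
        raise ParameterError("node index out of range")
    deg = net.degrees()[nodes].mean()
    return float(deg / (net.n - 1)) if normalized else float(deg)
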