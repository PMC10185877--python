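"""Fused lncRNA–lncRNA association network and random-walk list expansion.

The merged embedding rows are correlated pairwise (Pearson) to give a
single lncRNA–lncRNA association network.  A user-chosen *similarity
coefficient* thresholds its edges (strict ``>``; negative correlations
never survive a threshold), and a random walk with restart (RWR) from
the user's seed lncRNAs

    p  <-  (1 - r) * W^T p  +  r * p0

propagates over the column-normalised thresholded network until the L1
change drops below tolerance.  Nodes with non-vanishing stationary
probability join the seeds to form the expanded list.  A similarity
coefficient of ``None`` disables expansion entirely: only the original
list is analysed downstream.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .sdne import EmbeddingMatrix

logger = logging.getLogger(__name__)


class NetworkError(ValueError):
    pass


@dataclass
class AssocNetwork:
    """Symmetric Pearson-correlation network, zero diagonal, |rho| <= 1."""

    nodes: list[str]
    edge_weights: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.edge_weights, dtype=float)
        if w.shape != (len(self.nodes), len(self.nodes)):
            raise NetworkError("weight matrix shape does not match node count")
        if not np.allclose(w, w.T, atol=1e-12):
            raise NetworkError("association network must be symmetric")
        if np.nanmax(np.abs(w)) > 1 + 1e-9:
            raise NetworkError("correlation weights must satisfy |rho| <= 1")
        np.fill_diagonal(w, 0.0)
        self.edge_weights = w
        self._index = {n: i for i, n in enumerate(self.nodes)}

    def __contains__(self, node: str) -> bool:
        return node in self._index


@dataclass
class RWRConfig:
    restart_prob: float = 0.7
    tol: float = 1e-10
    max_iter: int = 1000
    sim_coef: float | None = 0.9     # edge threshold; None disables expansion
    nonzero_eps: float = 1e-12       # probability cutoff treated as "not zero"

    def __post_init__(self) -> None:
        if not 0.0 < self.restart_prob <= 1.0:
            raise ValueError("restart_prob must be in (0, 1]")
        if self.tol <= 0:
            raise ValueError("tol must be positive")
        if self.sim_coef is not None and not 0.0 <= self.sim_coef <= 1.0:
            raise ValueError("sim_coef must be in [0, 1] or None")
        if self.nonzero_eps < 0:
            raise ValueError("nonzero_eps must be nonnegative")


@dataclass
class ExpansionResult:
    seeds_used: list[str]
    seeds_dropped: list[str]
    probabilities: dict[str, float]
    expanded_list: list[str]


def pearson_network(features: EmbeddingMatrix) -> AssocNetwork:
    """Pairwise Pearson correlation of embedding rows."""
    x = features.vectors
    if x.shape[0] < 2:
        raise NetworkError("need at least 2 labels to build a network")
    sd = x.std(axis=1)
    flat = [features.labels[i] for i in np.flatnonzero(sd == 0)]
    if flat:
        raise NetworkError(f"zero-variance embedding rows: {flat}")
    rho = np.corrcoef(x)
    rho = np.clip((rho + rho.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(rho, 0.0)
    return AssocNetwork(nodes=list(features.labels), edge_weights=rho)


def threshold_network(net: AssocNetwork, sim_coef: float | None) -> AssocNetwork:
    """Keep only edges with rho strictly above the similarity coefficient."""
    if sim_coef is None:
        return net
    w = np.where(net.edge_weights > sim_coef, net.edge_weights, 0.0)
    return AssocNetwork(nodes=list(net.nodes), edge_weights=w)


def rwr(net: AssocNetwork, seeds: set[str] | list[str],
        config: RWRConfig | None = None) -> dict[str, float]:
    """Random walk with restart from seed nodes over nonnegative weights.

    The transition matrix column-normalises the edge weights; dangling
    (degree-zero) nodes teleport their mass back to the restart vector,
    preserving stochasticity.  Returns converged per-node probabilities.
    """
    config = config or RWRConfig()
    w = net.edge_weights
    if (w < 0).any():
        raise NetworkError("RWR requires nonnegative weights (threshold first)")
    seeds_used = [s for s in net.nodes if s in set(seeds)]
    if not seeds_used:
        raise NetworkError("no seed is present in the network")
    n = len(net.nodes)
    idx = net._index
    p0 = np.zeros(n)
    p0[[idx[s] for s in seeds_used]] = 1.0 / len(seeds_used)

    col_sums = w.sum(axis=0)
    dangling = col_sums == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        wt = np.where(dangling[None, :], 0.0, w / np.where(dangling, 1.0, col_sums)[None, :])

    r = config.restart_prob
    p = p0.copy()
    for _ in range(config.max_iter):
        dangling_mass = p[dangling].sum()
        p_next = (1 - r) * (wt @ p + dangling_mass * p0) + r * p0
        if np.abs(p_next - p).sum() < config.tol:
            p = p_next
            break
        p = p_next
    else:
        warnings.warn("RWR did not converge within max_iter; returning best iterate",
                      RuntimeWarning)
    return {node: float(p[idx[node]]) for node in net.nodes}


def expand_list(net: AssocNetwork, seeds: set[str] | list[str],
                config: RWRConfig | None = None) -> ExpansionResult:
    """Expand a seed lncRNA list by RWR over the thresholded network.

    With ``sim_coef=None`` no walk is run and the expanded list is just
    the seeds found in the network.
    """
    config = config or RWRConfig()
    seed_set = set(seeds)
    seeds_used = [s for s in net.nodes if s in seed_set]
    seeds_dropped = sorted(seed_set - set(net.nodes))
    if seeds_dropped:
        logger.warning("%d seed lncRNAs not in the network: %s",
                       len(seeds_dropped), seeds_dropped)
    if not seeds_used:
        raise NetworkError("no seed is present in the network")
    if config.sim_coef is None:
        return ExpansionResult(seeds_used=seeds_used, seeds_dropped=seeds_dropped,
                               probabilities={}, expanded_list=sorted(seeds_used))
    thresholded = threshold_network(net, config.sim_coef)
    probs = rwr(thresholded, seeds_used, config)
    expanded = set(seeds_used) | {v for v, p in probs.items() if p > config.nonzero_eps}
    return ExpansionResult(seeds_used=seeds_used, seeds_dropped=seeds_dropped,
                           probabilities=probs, expanded_list=sorted(expanded))
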