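"""Synthetic network generators: power-law configuration model and Erdős–Rényi.

The scale-free generator samples a degree sequence i.i.d. from the normalized
discrete power law ``p(k) ∝ k^-alpha`` on ``[k_min, k_max]`` and wires it with
the configuration model (random half-edge matching).  Self-loops and parallel
edges produced by the matching are removed, yielding a simple graph whose
realized degrees are bounded above by the requested ones; downstream
statistics always recompute the realized ``p(k)``, so the simplification
biases only the generator, not the model.

At heavy-tailed exponents (``alpha`` near 2) the simplification plus the
structural cutoff make the realized graph naturally disassortative — that is
part of the phenomenon being studied, not an artifact to correct.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np

logger = logging.getLogger("netillusion")


@dataclass(frozen=True)
class PowerLawSpec:
    """Parameters of the discrete power-law degree distribution.

    alpha > 1 is the exponent of ``p(k) ∝ k^-alpha``; degrees are supported
    on ``[k_min, k_max]`` (defaults: 1 and N-1).
    """

    alpha: float
    n_nodes: int
    k_min: int = 1
    k_max: int | None = None

    def __post_init__(self):
        k_max = self.k_max if self.k_max is not None else self.n_nodes - 1
        if self.alpha <= 1:
            raise ValueError("alpha must exceed 1")
        if not (1 <= self.k_min <= k_max <= self.n_nodes - 1):
            raise ValueError(f"need 1 <= k_min <= k_max <= N-1, got [{self.k_min}, {k_max}]")

    @property
    def support(self) -> np.ndarray:
        k_max = self.k_max if self.k_max is not None else self.n_nodes - 1
        return np.arange(self.k_min, k_max + 1)

    @property
    def pmf(self) -> np.ndarray:
        w = self.support.astype(float) ** (-self.alpha)
        return w / w.sum()

    @property
    def analytic_mean_degree(self) -> float:
        return float(self.support @ self.pmf)

    @property
    def analytic_degree_variance(self) -> float:
        mu = self.analytic_mean_degree
        return float((self.support.astype(float) ** 2) @ self.pmf - mu**2)


def sample_powerlaw_degrees(spec: PowerLawSpec, rng_seed: int) -> np.ndarray:
    """Draw a degree sequence i.i.d. from *spec*; the total is forced even.

    If the sampled total is odd, one uniformly chosen node's degree is
    incremented by 1 (logged) so the half-edges can be matched.
    """
    rng = np.random.default_rng(rng_seed)
    degrees = rng.choice(spec.support, size=spec.n_nodes, p=spec.pmf)
    if degrees.sum() % 2 == 1:
        i = rng.integers(spec.n_nodes)
        degrees[i] += 1
        logger.debug("sample_powerlaw_degrees: odd total, incremented node %d", i)
    return degrees.astype(np.int64)


def configuration_model(degrees: np.ndarray, rng_seed: int) -> nx.Graph:
    """Wire *degrees* by random half-edge matching, then simplify.

    Self-loops and parallel edges from the matching are discarded (counts
    logged), so realized degrees are <= requested.  Raises on odd degree sum.
    """
    degrees = np.asarray(degrees, dtype=np.int64)
    if degrees.sum() % 2 == 1:
        raise ValueError("degree sequence must have an even sum")
    multi = nx.configuration_model(degrees.tolist(), seed=int(rng_seed))
    g = nx.Graph(multi)  # collapses parallel edges
    loops = nx.number_of_selfloops(g)
    g.remove_edges_from(nx.selfloop_edges(g))
    removed = multi.number_of_edges() - g.number_of_edges()
    if removed:
        logger.debug(
            "configuration_model: removed %d edges (%d self-loops, %d parallel)",
            removed, loops, removed - loops,
        )
    return g


def powerlaw_graph(spec: PowerLawSpec, rng_seed: int) -> nx.Graph:
    """Sample a degree sequence from *spec* and build the simplified configuration model."""
    return configuration_model(sample_powerlaw_degrees(spec, rng_seed), rng_seed)


def erdos_renyi(n: int, p: float, rng_seed: int) -> nx.Graph:
    """G(n, p): every unordered pair is an edge independently with probability *p*."""
    if not 0 <= p <= 1:
        raise ValueError("p must lie in [0, 1]")
    return nx.fast_gnp_random_graph(n, p, seed=int(rng_seed))


def erdos_renyi_mean_degree(n: int, mean_degree: float, rng_seed: int) -> nx.Graph:
    """G(n, p) with p chosen so the expected degree is *mean_degree*."""
    return erdos_renyi(n, mean_degree / (n - 1), rng_seed)
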