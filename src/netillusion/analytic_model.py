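"""Statistical model of the majority illusion.

Given a graph's degree structure (``p(k)``, ``q(k)``, ``e(k, k')``) and the
conditional activation probability ``P(x=1|k)``, the model predicts the
fraction of nodes observing an active strict-``phi`` majority:

1. the probability that a neighbor of a degree-``k`` node is active,

   ``P(x'=1|k) = sum_k' P(x'=1|k') e(k,k') / q(k)``,

   which routes attribute prevalence through the joint degree distribution —
   this is where degree assortativity enters;

2. treating a node's ``k`` neighbors as independent draws with that success
   probability, the per-degree illusion probability is a binomial upper tail

   ``P_{>phi}(k) = P( Binomial(k, P(x'=1|k)) > phi k )``   (strict), and

3. the expected illusion magnitude is the mixture over the degree
   distribution, ``P_{>phi} = sum_k p(k) P_{>phi}(k)``.

``P(x=1|k)`` can be measured empirically from a concrete attribute
configuration, or approximated from the degree–attribute correlation alone
via the Gaussian (multivariate-normal) linearization

   ``P(x'=1|k') = <x> + rho_kx (sigma_x / sigma_k) (k' - <k>)``,

clamped to [0, 1].  The linearization is accurate for Poisson-like degree
distributions near zero assortativity and degrades for heavy tails.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy import stats as sps

from .graph_core import (
    DegreeStats,
    UNDEFINED,
    degree_array,
    degree_attribute_correlation,
    degree_stats,
    is_undefined,
)

__all__ = [
    "NeighborActivationProfile",
    "IllusionPrediction",
    "empirical_conditional_activation",
    "conditional_active_neighbor_prob",
    "paradox_probability",
    "expected_paradox_fraction",
    "gaussian_approx_conditional",
    "gaussian_profile",
    "predict_paradox",
]


@dataclass(frozen=True)
class NeighborActivationProfile:
    """``P(x'=1|k)`` per observer degree, plus the global ``P(x'=1)``."""

    cond_prob: dict[int, float]
    global_prob: float


@dataclass(frozen=True)
class IllusionPrediction:
    """Model-predicted illusion probability per degree and overall."""

    per_degree: dict[int, float]
    overall: float
    phi: float


def empirical_conditional_activation(g: nx.Graph, x: np.ndarray) -> dict[int, float]:
    """``P(x=1|k)``: active share within each degree class present in the graph."""
    k = degree_array(g)
    x = np.asarray(x)
    out: dict[int, float] = {}
    for d in np.unique(k):
        mask = k == d
        out[int(d)] = float(x[mask].mean())
    return out


def conditional_active_neighbor_prob(
    stats: DegreeStats, cond_act: dict[int, float]
) -> NeighborActivationProfile:
    """Mix ``P(x=1|k')`` through ``e(k, k')/q(k)`` to get ``P(x'=1|k)``.

    Degrees with ``q(k) = 0`` (no edge ends) get the undefined sentinel.
    The global probability is the ``p(k)``-mixture of the conditional ones,
    with degree-0 nodes contributing nothing.
    """
    acc: dict[int, float] = {}
    for (ka, kb), w in stats.e.items():  # one pass over e, accumulated per observer degree
        acc[ka] = acc.get(ka, 0.0) + cond_act.get(kb, 0.0) * w
    cond: dict[int, float] = {}
    for k_obs, qk in stats.q.items():
        cond[k_obs] = acc.get(k_obs, 0.0) / qk if qk > 0 else UNDEFINED
    global_prob = sum(
        pk * cond.get(k, 0.0)
        for k, pk in stats.p.items()
        if k > 0 and not is_undefined(cond.get(k, UNDEFINED))
    )
    return NeighborActivationProfile(cond_prob=cond, global_prob=float(global_prob))


def paradox_probability(k: int, pk_active: float, phi: float = 0.5) -> float:
    """Binomial upper tail ``P(Binomial(k, p) > phi k)`` with a strict bound.

    An exact tie (``n = phi k`` integer) does not count.  Degree 0 returns 0.
    """
    if not 0.0 <= pk_active <= 1.0:
        raise ValueError("pk_active must lie in [0, 1]")
    if k < 0:
        raise ValueError("degree must be non-negative")
    if k == 0:
        return 0.0
    # sf(m) = P(X > m); the strict cutoff n > phi*k means n >= floor(phi*k) + 1
    return float(sps.binom.sf(math.floor(phi * k), k, pk_active))


def expected_paradox_fraction(
    stats: DegreeStats,
    profile: NeighborActivationProfile,
    phi: float = 0.5,
) -> IllusionPrediction:
    """``p(k)``-mixture of the per-degree binomial tails."""
    per_degree: dict[int, float] = {}
    overall = 0.0
    for k, pk in stats.p.items():
        if k == 0:
            per_degree[0] = 0.0
            continue
        p_active = profile.cond_prob.get(k, UNDEFINED)
        if is_undefined(p_active):
            per_degree[k] = UNDEFINED
            continue
        tail = paradox_probability(k, p_active, phi)
        per_degree[k] = tail
        overall += pk * tail
    return IllusionPrediction(per_degree=per_degree, overall=float(overall), phi=phi)


def gaussian_approx_conditional(
    mean_x: float,
    rho: float,
    sigma_x: float,
    sigma_k: float,
    mean_k: float,
    k: float,
) -> float:
    """Linearized ``P(x'=1|k') = <x> + rho_kx (sigma_x/sigma_k)(k' - <k>)``, clamped to [0, 1]."""
    if sigma_k <= 0:
        raise ValueError("sigma_k must be positive")
    val = mean_x + rho * (sigma_x / sigma_k) * (k - mean_k)
    return float(min(1.0, max(0.0, val)))


def gaussian_profile(g: nx.Graph, x: np.ndarray) -> dict[int, float]:
    """``P(x=1|k)`` for every degree class, from the Gaussian linearization."""
    joint = degree_attribute_correlation(g, x)
    if is_undefined(joint.correlation):
        raise ValueError("rho_kx undefined for this configuration")
    k = degree_array(g)
    mean_k = float(k.mean())
    return {
        int(d): gaussian_approx_conditional(
            joint.active_fraction, joint.correlation,
            joint.sigma_x, joint.sigma_k, mean_k, int(d),
        )
        for d in np.unique(k)
    }


def predict_paradox(
    g: nx.Graph,
    x: np.ndarray,
    phi: float = 0.5,
    method: str = "empirical",
) -> IllusionPrediction:
    """End-to-end model prediction for one (graph, attributes) pair.

    ``method="empirical"`` measures ``P(x=1|k)`` from the configuration;
    ``method="gaussian"`` uses the correlation-based linearization.
    """
    if method == "empirical":
        cond_act = empirical_conditional_activation(g, x)
    elif method == "gaussian":
        cond_act = gaussian_profile(g, x)
    else:
        raise ValueError("method must be 'empirical' or 'gaussian'")
    stats = degree_stats(g)
    profile = conditional_active_neighbor_prob(stats, cond_act)
    return expected_paradox_fraction(stats, profile, phi)
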