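"""Binary attribute assignment and degree–attribute correlation steering.

Activation is exact-count: ``activate_random`` makes exactly
``round(fraction * N)`` nodes active so repeated sweeps share the same global
prevalence ``P(x=1)``.  ``swap_to_correlation`` then steers the
degree–attribute correlation ``rho_kx`` without touching the active count:
to raise ``rho_kx`` it repeatedly picks a random active node ``v1`` and a
random inactive node ``v0`` and exchanges their attributes whenever
``deg(v0) > deg(v1)``; to lower it, the mirrored rule (``deg(v0) < deg(v1)``)
is used.  Every accepted swap moves ``rho_kx`` monotonically toward the
target, so the procedure is a stochastic exchange sort on degrees.

Since degrees, the active count and therefore ``sigma_x``, ``sigma_k`` and
``<k>`` are all fixed, ``rho_kx`` depends on the configuration only through
``sum_i k_i x_i``, which each swap updates in O(1).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np

from .graph_core import degree_array

logger = logging.getLogger("netillusion")


@dataclass
class SwapResult:
    """Attribute vector after swapping, with achieved correlation."""

    attributes: np.ndarray
    initial_rho: float
    achieved_rho: float
    accepted_swaps: int
    attempts: int
    target_reached: bool


def activate_random(g: nx.Graph, fraction: float, rng_seed: int) -> np.ndarray:
    """Activate exactly ``round(fraction * N)`` uniformly chosen nodes.

    Random placement leaves ``rho_kx`` near zero in expectation.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must lie in [0, 1]")
    n = g.number_of_nodes()
    n_active = int(round(fraction * n))
    rng = np.random.default_rng(rng_seed)
    x = np.zeros(n, dtype=np.int8)
    x[rng.choice(n, size=n_active, replace=False)] = 1
    return x


def _rho_terms(k: np.ndarray, x: np.ndarray):
    n = len(k)
    f = x.mean()
    sigma_x = x.std()
    sigma_k = k.std()
    mean_k = k.mean()
    if sigma_x == 0 or sigma_k == 0:
        raise ValueError("rho_kx undefined: constant attribute or constant degree")
    # rho = cov(k, x) / (sigma_k sigma_x); cov = (1/n) sum k_i x_i - <k> f
    def rho_of(kx_sum: float) -> float:
        return (kx_sum / n - mean_k * f) / (sigma_k * sigma_x)
    return rho_of


def swap_to_correlation(
    g: nx.Graph,
    x: np.ndarray,
    target_rho: float,
    rng_seed: int,
    max_iter: int = 5_000_000,
    tol: float = 0.005,
    stall_factor: int = 50,
) -> SwapResult:
    """Swap attribute values between node pairs until ``rho_kx`` hits *target_rho*.

    Terminates when ``|rho_kx - target_rho| <= tol``, after *max_iter*
    proposals, or once ``stall_factor * N`` consecutive proposals were
    rejected (the fixed point: no swap in the accepted direction exists, or
    is too rare to find — ``rho_kx`` is then at its achievable extreme).
    The number of active nodes is conserved exactly.

    Pass ``target_rho`` of +1 / -1 to drive the correlation to its maximal /
    minimal achievable value.
    """
    x = np.asarray(x, dtype=np.int8).copy()
    if x.min() < 0 or x.max() > 1:
        raise ValueError("attributes must be binary (0/1)")
    if x.sum() == 0 or x.sum() == len(x):
        raise ValueError("need at least one active and one inactive node to swap")
    k = degree_array(g)
    rho_of = _rho_terms(k, x)
    kx_sum = float(k @ x)
    rho0 = rho_of(kx_sum)

    rng = np.random.default_rng(rng_seed)
    active = np.flatnonzero(x == 1)
    inactive = np.flatnonzero(x == 0)
    stall_limit = stall_factor * len(x)

    accepted = 0
    attempts = 0
    consecutive_rejects = 0
    batch = 8192
    rho = rho0
    while (
        attempts < max_iter
        and abs(rho - target_rho) > tol
        and consecutive_rejects < stall_limit
    ):
        ia = rng.integers(0, len(active), size=batch)
        ii = rng.integers(0, len(inactive), size=batch)
        for pa, pi in zip(ia, ii):
            if (
                attempts >= max_iter
                or abs(rho - target_rho) <= tol
                or consecutive_rejects >= stall_limit
            ):
                break
            attempts += 1
            v1, v0 = active[pa], inactive[pi]  # v1 active, v0 inactive
            diff = int(k[v0]) - int(k[v1])  # change in sum k_i x_i if swapped
            increase = target_rho > rho
            if (increase and diff > 0) or (not increase and diff < 0):
                x[v1], x[v0] = 0, 1
                active[pa], inactive[pi] = v0, v1
                kx_sum += diff
                rho = rho_of(kx_sum)
                accepted += 1
                consecutive_rejects = 0
            else:
                consecutive_rejects += 1

    achieved = rho_of(float(k @ x))
    reached = abs(achieved - target_rho) <= tol
    if not reached:
        logger.info(
            "swap_to_correlation: target %.4f unreached, achieved %.4f "
            "(%d accepted / %d attempts)", target_rho, achieved, accepted, attempts,
        )
    return SwapResult(x, rho0, achieved, accepted, attempts, reached)


def max_correlation_attributes(g: nx.Graph, n_active: int) -> np.ndarray:
    """Attribute vector activating the *n_active* highest-degree nodes.

    This is the exact maximizer of ``rho_kx`` at fixed active count (up to
    degree ties) and serves as the closed-form oracle for
    :func:`swap_to_correlation` driven to its maximum.
    """
    k = degree_array(g)
    x = np.zeros(len(k), dtype=np.int8)
    x[np.argsort(k, kind="stable")[::-1][:n_active]] = 1
    return x
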