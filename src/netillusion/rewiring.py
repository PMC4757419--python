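"""Degree-preserving edge rewiring.

Two procedures built on the double-edge swap (take edges ``(a,b)`` and
``(c,d)``, rewire to ``(a,c),(b,d)`` or ``(a,d),(b,c)``):

* :func:`rewire_to_assortativity` steers the degree assortativity ``r_kk``
  toward a target by accepting only swaps that strictly reduce the distance
  to it (greedy hill-climb on ``r_kk``), and
* :func:`rewire_alter_ekk_preserve_r` randomizes the joint degree
  distribution ``e(k, k')`` while pinning ``r_kk`` within a tolerance of its
  initial value, isolating the effect of higher-order degree structure.

Both leave every node's degree — hence ``p(k)`` and ``q(k)`` — untouched.
Because degrees are fixed, ``r_kk`` depends on the edge set only through
``T = sum_edges k_u k_v``; swaps update ``T`` in O(1) and the full Pearson
formula is only used to cross-check.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np

from .graph_core import degree_array, degree_stats, is_undefined

logger = logging.getLogger("netillusion")


@dataclass
class RewireResult:
    """Rewired graph plus bookkeeping of what the swap chain achieved."""

    graph: nx.Graph
    initial_r: float
    achieved_r: float
    accepted_swaps: int
    attempts: int
    target_reached: bool


class _EdgeSet:
    """Mutable edge list with O(1) membership, sampling and replacement."""

    def __init__(self, g: nx.Graph):
        self.edges: list[tuple[int, int]] = [tuple(e) for e in g.edges()]
        self.index = {self._key(u, v): i for i, (u, v) in enumerate(self.edges)}

    @staticmethod
    def _key(u: int, v: int) -> tuple[int, int]:
        return (u, v) if u < v else (v, u)

    def __contains__(self, edge) -> bool:
        return self._key(*edge) in self.index

    def replace(self, i: int, new_edge: tuple[int, int]) -> None:
        old = self.edges[i]
        del self.index[self._key(*old)]
        self.edges[i] = new_edge
        self.index[self._key(*new_edge)] = i

    def to_graph(self, n_nodes: int) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(n_nodes))
        g.add_edges_from(self.edges)
        return g


def _r_from_T(T: float, m: int, mu_q: float, sigma_q_sq: float) -> float:
    # r_kk = (sum_{kk'} k k' e(k,k') - mu_q^2) / sigma_q^2, with
    # sum_{kk'} k k' e(k,k') = T/m for T = sum over edges of k_u k_v.
    return (T / m - mu_q**2) / sigma_q_sq


def _setup(g: nx.Graph):
    stats = degree_stats(g)
    if is_undefined(stats.assortativity):
        raise ValueError("assortativity undefined: all edge ends have equal degree")
    k = degree_array(g)
    mu_q = sum(d * w for d, w in stats.q.items())
    edges = _EdgeSet(g)
    T = float(sum(int(k[u]) * int(k[v]) for u, v in edges.edges))
    return stats, k, mu_q, edges, T


def _candidate_pairings(a, b, c, d):
    # both rewirings of the chosen edge pair; caller picks the better one
    return ((a, c), (b, d)), ((a, d), (b, c))


def _valid(pairing, edges: _EdgeSet) -> bool:
    (p1, p2) = pairing
    if p1[0] == p1[1] or p2[0] == p2[1]:
        return False
    if p1 in edges or p2 in edges:
        return False
    return _EdgeSet._key(*p1) != _EdgeSet._key(*p2)


def rewire_to_assortativity(
    g: nx.Graph,
    target_r: float,
    rng_seed: int,
    max_attempts: int = 500_000,
    tol: float = 0.005,
    debug: bool = False,
) -> RewireResult:
    """Steer ``r_kk`` toward *target_r* by greedy double-edge swaps.

    A proposed swap is accepted iff it keeps the graph simple and strictly
    shrinks ``|r_kk - target_r|``; swaps leaving ``r_kk`` unchanged are
    rejected.  Stops once ``|r_kk - target_r| <= tol`` or after
    *max_attempts* proposals, returning the best-so-far graph with
    ``target_reached`` flagging which.

    Raises ``ValueError`` on graphs whose assortativity is undefined
    (regular graphs).
    """
    if not -1.0 <= target_r <= 1.0:
        raise ValueError("target_r must lie in [-1, 1]")
    stats, k, mu_q, edges, T = _setup(g)
    m = stats.n_edges
    if m < 2:
        raise ValueError("need at least two edges to swap")
    rng = np.random.default_rng(rng_seed)
    initial_r = stats.assortativity
    # the target in T-space: r is an increasing affine function of T
    T_target = (target_r * stats.sigma_q_sq + mu_q**2) * m

    accepted = 0
    attempts = 0
    batch = 8192
    while attempts < max_attempts and abs(T - T_target) / m > tol * stats.sigma_q_sq:
        picks = rng.integers(0, m, size=(batch, 2))
        for i, j in picks:
            if attempts >= max_attempts or abs(T - T_target) / m <= tol * stats.sigma_q_sq:
                break
            attempts += 1
            if i == j:
                continue
            a, b = edges.edges[i]
            c, d = edges.edges[j]
            if len({a, b, c, d}) < 4:
                continue
            ka, kb, kc, kd = int(k[a]), int(k[b]), int(k[c]), int(k[d])
            base = ka * kb + kc * kd
            best = None
            best_dist = abs(T - T_target)
            for pairing in _candidate_pairings(a, b, c, d):
                (p1, p2) = pairing
                dT = int(k[p1[0]]) * int(k[p1[1]]) + int(k[p2[0]]) * int(k[p2[1]]) - base
                dist = abs(T + dT - T_target)
                if dist < best_dist and _valid(pairing, edges):
                    best, best_dist = (pairing, dT), dist
            if best is None:
                continue
            (p1, p2), dT = best
            edges.replace(int(i), p1)
            edges.replace(int(j), p2)
            T += dT
            accepted += 1
            if debug:
                gg = edges.to_graph(g.number_of_nodes())
                assert np.array_equal(degree_array(gg), k), "degree changed by swap"

    out = edges.to_graph(g.number_of_nodes())
    achieved = _r_from_T(T, m, mu_q, stats.sigma_q_sq)
    reached = abs(achieved - target_r) <= tol
    if not reached:
        logger.info(
            "rewire_to_assortativity: target %.4f unreached, achieved %.4f "
            "after %d attempts (%d accepted)", target_r, achieved, attempts, accepted,
        )
    return RewireResult(out, initial_r, achieved, accepted, attempts, reached)


def rewire_alter_ekk_preserve_r(
    g: nx.Graph,
    rng_seed: int,
    max_attempts: int = 200_000,
    r_tol: float = 0.01,
    debug: bool = False,
) -> RewireResult:
    """Randomize ``e(k, k')`` while keeping ``r_kk`` within *r_tol* of its start.

    A swap is accepted iff it changes the multiset of edge degree-pairs
    (hence at least one entry of ``e``), keeps the graph simple, and leaves
    ``|r_kk - r_kk(initial)| <= r_tol``.  ``p(k)`` is untouched by
    construction.
    """
    stats, k, mu_q, edges, T = _setup(g)
    m = stats.n_edges
    if m < 2:
        raise ValueError("need at least two edges to swap")
    rng = np.random.default_rng(rng_seed)
    r0 = stats.assortativity
    accepted = 0
    attempts = 0
    batch = 8192
    while attempts < max_attempts:
        picks = rng.integers(0, m, size=(batch, 2))
        for i, j in picks:
            if attempts >= max_attempts:
                break
            attempts += 1
            if i == j:
                continue
            a, b = edges.edges[i]
            c, d = edges.edges[j]
            if len({a, b, c, d}) < 4:
                continue
            ka, kb, kc, kd = int(k[a]), int(k[b]), int(k[c]), int(k[d])
            old_pairs = sorted((tuple(sorted((ka, kb))), tuple(sorted((kc, kd)))))
            base = ka * kb + kc * kd
            options = []
            for pairing in _candidate_pairings(a, b, c, d):
                (p1, p2) = pairing
                kp = (int(k[p1[0]]), int(k[p1[1]]), int(k[p2[0]]), int(k[p2[1]]))
                new_pairs = sorted((tuple(sorted(kp[:2])), tuple(sorted(kp[2:]))))
                if new_pairs == old_pairs:
                    continue  # e(k,k') would not change
                dT = kp[0] * kp[1] + kp[2] * kp[3] - base
                r_new = _r_from_T(T + dT, m, mu_q, stats.sigma_q_sq)
                if abs(r_new - r0) <= r_tol and _valid(pairing, edges):
                    options.append((pairing, dT))
            if not options:
                continue
            (p1, p2), dT = options[int(rng.integers(len(options)))]
            edges.replace(int(i), p1)
            edges.replace(int(j), p2)
            T += dT
            accepted += 1
            if debug:
                gg = edges.to_graph(g.number_of_nodes())
                assert np.array_equal(degree_array(gg), k), "degree changed by swap"

    out = edges.to_graph(g.number_of_nodes())
    achieved = _r_from_T(T, m, mu_q, stats.sigma_q_sq)
    return RewireResult(out, r0, achieved, accepted, attempts, abs(achieved - r0) <= r_tol)
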