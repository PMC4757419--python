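"""Empirical measurement of the majority illusion.

A node experiences the illusion at threshold ``phi`` when strictly more than
``phi * k`` of its ``k`` neighbors are active.  The magnitude of the illusion
is the fraction of all ``N`` nodes (active, inactive and isolated alike) in
that condition; isolated nodes can never be flagged.  The default
``phi = 0.5`` asks for a strict majority of active neighbors.

The strict inequality follows the binomial-tail definition of the model
(``n > phi k``); for toy demonstrations phrased as "at least half", pass
``observers="inactive"`` and/or use ``phi`` slightly below one half.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .graph_core import degree_array


@dataclass(frozen=True)
class IllusionMeasurement:
    """Per-node illusion flags and their mean."""

    phi: float
    paradox_fraction: float
    per_node_flags: np.ndarray
    active_fraction: float


def active_neighbor_counts(g: nx.Graph, x: np.ndarray) -> np.ndarray:
    """Number of active neighbors of each node."""
    x = np.asarray(x)
    counts = np.zeros(g.number_of_nodes(), dtype=np.int64)
    for u, v in g.edges():
        counts[u] += x[v]
        counts[v] += x[u]
    return counts


def paradox_fraction(
    g: nx.Graph,
    x: np.ndarray,
    phi: float = 0.5,
    observers: str = "all",
) -> IllusionMeasurement:
    """Fraction of nodes whose active neighbors exceed a ``phi`` share.

    Node ``i`` is flagged iff ``k_i >= 1`` and
    ``(# active neighbors of i) > phi * k_i`` (strict).  With
    ``observers="all"`` (default) the denominator is all ``N`` nodes; with
    ``observers="inactive"`` both numerator and denominator are restricted
    to inactive nodes, matching the usual toy narration ("every inactive
    node sees...").
    """
    if not 0.0 <= phi <= 1.0:
        raise ValueError("phi must lie in [0, 1]")
    if observers not in ("all", "inactive"):
        raise ValueError("observers must be 'all' or 'inactive'")
    x = np.asarray(x)
    k = degree_array(g)
    counts = active_neighbor_counts(g, x)
    flags = counts > phi * k
    flags &= k >= 1  # isolated nodes are never flagged (phi=0 edge case)
    if observers == "inactive":
        mask = x == 0
        frac = float(flags[mask].mean()) if mask.any() else 0.0
        flags = flags & mask
    else:
        frac = float(flags.mean())
    return IllusionMeasurement(
        phi=phi, paradox_fraction=frac, per_node_flags=flags,
        active_fraction=float(x.mean()),
    )


def neighbor_active_share(g: nx.Graph, x: np.ndarray) -> np.ndarray:
    """Per-node fraction of neighbors that are active; NaN for isolated nodes.

    The node-average of this vector exceeds the global prevalence
    ``P(x=1)`` whenever the attribute is positively correlated with degree —
    the generalized friendship paradox for binary attributes.
    """
    k = degree_array(g)
    counts = active_neighbor_counts(g, x)
    with np.errstate(divide="ignore", invalid="ignore"):
        share = np.where(k > 0, counts / np.maximum(k, 1), np.nan)
    return share
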