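"""Graph container, file I/O, and the structural statistics the illusion model consumes.

Graphs are undirected simple :class:`networkx.Graph` objects whose nodes are the
integers ``0..N-1``.  Loaders remap arbitrary labels to this canonical range and
return the label map so results can be reported in the caller's vocabulary.

The two node-level summaries defined here are

* the degree statistics ``p(k)``, ``q(k) = k p(k)/<k>``, the joint degree
  distribution ``e(k, k')`` of a randomly chosen edge, and the degree
  assortativity ``r_kk`` (the Pearson correlation of the degrees at the two
  ends of a random edge), and
* the degree-attribute joint ``P(x, k)`` for a binary node attribute
  ``x in {0, 1}`` together with the degree-attribute correlation ``rho_kx``
  (the Pearson correlation of the node-level pairs ``(k_i, x_i)``).

Statistics that are undefined on degenerate inputs (regular graphs, constant
attributes) are reported as ``nan`` so parameter sweeps can skip them.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

logger = logging.getLogger("netillusion")

#: Sentinel for statistics that are undefined on the given input
#: (e.g. assortativity of a regular graph, correlation with a constant attribute).
UNDEFINED = float("nan")


def is_undefined(value: float) -> bool:
    """True if *value* is the undefined-statistic sentinel."""
    return isinstance(value, float) and math.isnan(value)


class NoEdgesError(ValueError):
    """Raised when a statistic requires at least one edge."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DegreeStats:
    """Degree-level structure of one graph.

    Attributes
    ----------
    p : dict
        Degree distribution ``p(k)``: fraction of nodes with degree ``k``
        (isolated nodes contribute to ``p(0)``).
    q : dict
        Neighbor degree distribution ``q(k) = k p(k) / <k>``: probability
        that a random edge end attaches to a degree-``k`` node.
    e : dict
        Joint degree distribution ``e(k, k')`` over ordered edge ends; each
        undirected edge contributes both orientations with weight
        ``1/(2|E|)``, which makes ``sum_k' e(k, k') = q(k)`` exact.
    mean_degree : float
        ``<k>``, the mean node degree.
    sigma_q_sq : float
        Variance of the ``q`` distribution.
    assortativity : float
        ``r_kk``; ``nan`` when every edge end has the same degree.
    n_edges : int
    """

    p: dict[int, float]
    q: dict[int, float]
    e: dict[tuple[int, int], float]
    mean_degree: float
    sigma_q_sq: float
    assortativity: float
    n_edges: int


@dataclass(frozen=True)
class AttributeDegreeJoint:
    """Joint statistics of a binary attribute and degree on one graph."""

    joint: dict[tuple[int, int], float]  # (x, k) -> P(x, k)
    active_fraction: float  # P(x = 1)
    mean_degree_active: float  # <k>_{x=1}; nan if no active nodes
    sigma_x: float
    sigma_k: float
    correlation: float  # rho_kx; nan if sigma_x or sigma_k is 0


# ---------------------------------------------------------------------------
# Statistics
# ---------------------------------------------------------------------------


def degree_array(g: nx.Graph) -> np.ndarray:
    """Degrees of nodes 0..N-1 as an integer array."""
    n = g.number_of_nodes()
    k = np.zeros(n, dtype=np.int64)
    for node, deg in g.degree():
        k[node] = deg
    return k


def degree_stats(g: nx.Graph) -> DegreeStats:
    """Compute ``p(k)``, ``q(k)``, ``e(k, k')`` and the assortativity ``r_kk``.

    ``r_kk`` is the Pearson correlation between the degrees at the two ends
    of a randomly chosen edge,

    ``r_kk = (1/sigma_q^2) * sum_{k,k'} k k' [e(k,k') - q(k) q(k')]``.

    Raises
    ------
    NoEdgesError
        If the graph has no edges (``q`` and ``e`` would be undefined).
    """
    m = g.number_of_edges()
    if m == 0:
        raise NoEdgesError("degree statistics require at least one edge")
    n = g.number_of_nodes()
    k = degree_array(g)
    mean_degree = float(k.mean())

    counts = np.bincount(k)  # index 0 = isolated nodes; they stay in p but not q/e
    p = {int(d): counts[d] / n for d in np.nonzero(counts)[0]}

    # e(k,k'): both orientations of every edge, weight 1/(2|E|)
    w = 1.0 / (2 * m)
    e: dict[tuple[int, int], float] = {}
    for u, v in g.edges():
        ku, kv = int(k[u]), int(k[v])
        e[(ku, kv)] = e.get((ku, kv), 0.0) + w
        e[(kv, ku)] = e.get((kv, ku), 0.0) + w

    q: dict[int, float] = {}
    for (ku, _kv), wt in e.items():
        q[ku] = q.get(ku, 0.0) + wt

    mu_q = sum(d * val for d, val in q.items())
    sigma_q_sq = sum(d * d * val for d, val in q.items()) - mu_q**2

    if sigma_q_sq <= 0:
        r = UNDEFINED
    else:
        s_kk = sum(ku * kv * wt for (ku, kv), wt in e.items())
        r = (s_kk - mu_q**2) / sigma_q_sq
    return DegreeStats(
        p=p, q=q, e=e, mean_degree=mean_degree,
        sigma_q_sq=float(sigma_q_sq), assortativity=float(r), n_edges=m,
    )


def degree_assortativity(g: nx.Graph) -> float:
    """``r_kk`` alone; ``nan`` for regular graphs."""
    return degree_stats(g).assortativity


def degree_attribute_correlation(g: nx.Graph, x: np.ndarray) -> AttributeDegreeJoint:
    """Joint ``P(x, k)`` and the degree-attribute correlation ``rho_kx``.

    Uses the closed form ``rho_kx = P(x=1) (<k>_{x=1} - <k>) / (sigma_x sigma_k)``,
    which equals the Pearson correlation of the node-level pairs ``(k_i, x_i)``
    (population standard deviations).
    """
    x = np.asarray(x)
    n = g.number_of_nodes()
    if x.shape != (n,):
        raise ValueError(f"attribute vector length {x.shape} != number of nodes {n}")
    if not np.isin(x, (0, 1)).all():
        raise ValueError("attributes must be binary (0/1)")
    k = degree_array(g)

    joint: dict[tuple[int, int], float] = {}
    for xi in (0, 1):
        degs, counts = np.unique(k[x == xi], return_counts=True)
        for d, c in zip(degs, counts):
            joint[(xi, int(d))] = c / n

    f = float(x.mean())
    mean_k = float(k.mean())
    mean_k_active = float(k[x == 1].mean()) if f > 0 else UNDEFINED
    sigma_x = float(x.std())
    sigma_k = float(k.std())
    if sigma_x == 0.0 or sigma_k == 0.0:
        rho = UNDEFINED
    else:
        rho = f * (mean_k_active - mean_k) / (sigma_x * sigma_k)
    return AttributeDegreeJoint(
        joint=joint, active_fraction=f, mean_degree_active=mean_k_active,
        sigma_x=sigma_x, sigma_k=sigma_k, correlation=float(rho),
    )


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------


@dataclass
class LoadReport:
    """What the edge-list loader did: label map plus cleanup counts."""

    label_map: dict = field(default_factory=dict)  # original label -> 0..N-1
    self_loops_dropped: int = 0
    duplicates_dropped: int = 0


def canonicalize(g: nx.Graph) -> tuple[nx.Graph, dict]:
    """Relabel nodes to 0..N-1 (sorted original order); return graph + label map."""
    labels = sorted(g.nodes())
    mapping = {lab: i for i, lab in enumerate(labels)}
    return nx.relabel_nodes(g, mapping, copy=True), mapping


def read_edge_list(path) -> tuple[nx.Graph, LoadReport]:
    """Read a whitespace-separated two-column integer edge list.

    Lines starting with ``#`` are ignored.  Self-loops are dropped and
    duplicate edges collapsed (both logged).  Arbitrary integer labels are
    remapped to ``0..N-1``; the mapping is returned in the report.
    """
    report = LoadReport()
    g = nx.Graph()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected two columns, got {line!r}")
            try:
                u, v = int(parts[0]), int(parts[1])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer node id in {line!r}") from exc
            if u == v:
                report.self_loops_dropped += 1
                g.add_node(u)
                continue
            if g.has_edge(u, v):
                report.duplicates_dropped += 1
                continue
            g.add_edge(u, v)
    if report.self_loops_dropped or report.duplicates_dropped:
        logger.info(
            "read_edge_list(%s): dropped %d self-loops, %d duplicate edges",
            path, report.self_loops_dropped, report.duplicates_dropped,
        )
    g, report.label_map = canonicalize(g)
    return g, report


def write_edge_list(g: nx.Graph, path) -> None:
    """Write one ``u v`` line per edge (endpoints in sorted order)."""
    with open(path, "w") as fh:
        for u, v in sorted(tuple(sorted(edge)) for edge in g.edges()):
            fh.write(f"{u} {v}\n")


def read_graphml(path) -> tuple[nx.Graph, LoadReport]:
    """Read GraphML; directed input is symmetrized, loops/duplicates dropped."""
    raw = nx.read_graphml(path)
    report = LoadReport()
    und = nx.Graph()
    und.add_nodes_from(raw.nodes())
    for u, v in raw.edges():
        if u == v:
            report.self_loops_dropped += 1
        elif und.has_edge(u, v):
            report.duplicates_dropped += 1
        else:
            und.add_edge(u, v)
    und, report.label_map = canonicalize(und)
    return und, report


def write_graphml(g: nx.Graph, path) -> None:
    nx.write_graphml(g, path)


def read_attributes(path, n_nodes: int) -> np.ndarray:
    """Read a two-column ``node_id value`` file with value in {0, 1}."""
    x = np.zeros(n_nodes, dtype=np.int8)
    seen = np.zeros(n_nodes, dtype=bool)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected 'node_id value'")
            i, val = int(parts[0]), int(parts[1])
            if val not in (0, 1):
                raise ValueError(f"{path}:{lineno}: attribute value must be 0 or 1")
            if not 0 <= i < n_nodes:
                raise ValueError(f"{path}:{lineno}: node id {i} out of range")
            x[i] = val
            seen[i] = True
    if not seen.all():
        logger.info("read_attributes(%s): %d nodes missing, defaulted to 0", path, int((~seen).sum()))
    return x


def write_attributes(x: np.ndarray, path) -> None:
    with open(path, "w") as fh:
        for i, val in enumerate(np.asarray(x)):
            fh.write(f"{i} {int(val)}\n")


def datasets_info() -> str:
    """Public locations of the real-world networks commonly analysed with this package.

    Nothing is downloaded; this is a pointer for users who want to reproduce
    published real-network measurements.
    """
    return (
        "HepTh co-authorship:        https://snap.stanford.edu/data/ca-HepTh.html\n"
        "Reactome protein-protein:   http://www.reactome.org/pages/download-data/\n"
        "Digg follower graph:        https://doi.org/10.6084/m9.figshare.2062467\n"
        "Enron email network:        http://www.cs.cmu.edu/~enron/\n"
        "Political blogs:            http://www-personal.umich.edu/~mejn/netdata/\n"
    )
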