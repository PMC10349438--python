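"""Directed weighted interaction networks and their parameter panel.

One network is built per behavioral category and period: a *simple*
digraph in which an edge i -> j exists iff animal i directed at least one
interaction of that category at animal j, weighted by the interaction
count.  Two counting conventions coexist deliberately:

* graph-level structure (connections, density, the mutual/asymmetric/null
  dyad census, reciprocity) counts *distinct ordered pairs* — repeated
  events collapse onto one edge;
* node-level degrees are *weighted strengths* — total interaction counts
  authored (out), received (in) and both (all).

By default a network contains only *active* animals (>= 1 event in that
category x period).  This matters for density: with 14 animals on the
roster but only 12 ever engaging in affiliative contact, the number of
possible directed connections is 12*11, not 14*13.  Full-roster graphs are
available via ``active_only=False``.

The node panel follows the study's parameter set: weighted in/out/all
strengths, betweenness and closeness under a configurable edge-distance
convention, and mutually-reinforcing hub ("Authors") and authority
("Receptors") scores, each max-normalised to 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import networkx as nx
import numpy as np
import pandas as pd

from .ethogram import CountMatrix

DISTANCE_MODES = ("unweighted", "weight_as_distance", "inverse_weight")
#: Non-integer betweenness values in the study's node panel indicate weighted
#: shortest paths with raw counts as distances; this is therefore the default.
DEFAULT_DISTANCE_MODE = "weight_as_distance"


class EmptyGraphError(ValueError):
    """No animal interacted: there is no network to analyze."""


class HitsConvergenceError(RuntimeError):
    """The hub/authority power iteration did not reach its fixed point."""

    def __init__(self, iterations: int, residual: float):
        self.iterations = iterations
        self.residual = residual
        super().__init__(
            f"HITS iteration did not converge in {iterations} iterations "
            f"(residual {residual:.3e})"
        )


@dataclass(frozen=True)
class DyadCensus:
    """Counts of unordered pairs by interaction pattern.

    mutual: edges both ways; asym: exactly one direction; null: no edge.
    Satisfies mutual + asym + null = n(n-1)/2 and 2*mutual + asym = E.
    """

    mutual: int
    asym: int
    null: int


@dataclass(frozen=True)
class GraphMetrics:
    density: float
    connections: int
    reciprocity: float


@dataclass(frozen=True)
class PathMetrics:
    diameter: float
    betweenness: dict[str, float]
    closeness: dict[str, float]
    distance_mode: str


@dataclass(frozen=True)
class NetworkPanel:
    """The full graph-level + node-level parameter set for one network."""

    category: str
    period: str
    n_nodes: int
    density: float
    connections: int
    reciprocity: float
    asym: int
    null: int
    mutual: int
    diameter: float
    nodes: pd.DataFrame  # index: animal id; metric columns

    def graph_row(self) -> dict[str, float]:
        return {
            "density": self.density,
            "asym": self.asym,
            "null": self.null,
            "diameter": self.diameter,
            "connections": self.connections,
            "reciprocity": self.reciprocity,
        }


def build_graph(counts: CountMatrix, *, active_only: bool = True) -> nx.DiGraph:
    """Build a simple weighted digraph from a count matrix.

    Edge i -> j exists iff counts(i, j) > 0, with the count as weight.
    Animals with no events in this category x period are excluded unless
    ``active_only=False``.  An all-zero matrix raises :class:`EmptyGraphError`.
    """
    c = counts.counts
    if c.sum() == 0:
        raise EmptyGraphError(
            f"no {counts.category} events in period {counts.period!r}: "
            "cannot build a network from an all-zero matrix"
        )
    active = (c.sum(axis=0) + c.sum(axis=1)) > 0
    g = nx.DiGraph(category=counts.category, period=counts.period)
    for i, a in enumerate(counts.animals):
        if active[i] or not active_only:
            g.add_node(a)
    rows, cols = np.nonzero(c)
    for i, j in zip(rows, cols):
        g.add_edge(counts.animals[i], counts.animals[j], weight=int(c[i, j]))
    return g


def dyad_census(g: nx.DiGraph) -> DyadCensus:
    if g.number_of_nodes() == 0:
        raise EmptyGraphError("empty graph")
    nodes = list(g.nodes)
    mutual = asym = null = 0
    for i, u in enumerate(nodes):
        for v in nodes[i + 1 :]:
            fwd, back = g.has_edge(u, v), g.has_edge(v, u)
            if fwd and back:
                mutual += 1
            elif fwd or back:
                asym += 1
            else:
                null += 1
    return DyadCensus(mutual, asym, null)


def graph_metrics(g: nx.DiGraph) -> GraphMetrics:
    """Density, directed-edge count and reciprocity over active nodes."""
    n = g.number_of_nodes()
    if n == 0:
        raise EmptyGraphError("empty graph")
    e = g.number_of_edges()
    census = dyad_census(g)
    density = e / (n * (n - 1)) if n > 1 else 0.0
    reciprocity = (2 * census.mutual / e) if e else 0.0
    return GraphMetrics(density=density, connections=e, reciprocity=reciprocity)


def _distance_attr(g: nx.DiGraph, mode: str) -> str | None:
    if mode not in DISTANCE_MODES:
        raise ValueError(f"unknown distance_mode {mode!r}; expected one of {DISTANCE_MODES}")
    if mode == "unweighted":
        return None
    if mode == "weight_as_distance":
        return "weight"
    for _, _, d in g.edges(data=True):
        d["inv_weight"] = 1.0 / d["weight"]
    return "inv_weight"


def path_metrics(
    g: nx.DiGraph, distance_mode: str = DEFAULT_DISTANCE_MODE
) -> PathMetrics:
    """Diameter, betweenness and closeness under a chosen edge distance.

    * diameter: longest *finite* directed shortest-path length;
    * betweenness(v): Brandes accumulation — for every ordered pair (s, t),
      the fraction of shortest s->t paths passing through v, all shortest
      paths counted;
    * closeness(v): 1 / sum_u d(v, u), with each unreachable u contributing
      a substitute distance of n (the node count) — the legacy convention
      of common network toolkits on disconnected digraphs.
    """
    if g.number_of_nodes() == 0:
        raise EmptyGraphError("empty graph")
    attr = _distance_attr(g, distance_mode)
    n = g.number_of_nodes()

    betweenness = nx.betweenness_centrality(g, normalized=False, weight=attr)

    if attr is None:
        lengths = dict(nx.all_pairs_shortest_path_length(g))
    else:
        lengths = dict(nx.all_pairs_dijkstra_path_length(g, weight=attr))

    diameter = 0.0
    closeness: dict[str, float] = {}
    for v in g.nodes:
        dist = lengths.get(v, {})
        total = 0.0
        for u in g.nodes:
            if u == v:
                continue
            d = dist.get(u)
            if d is None:
                d = float(n)  # unreachable-distance substitution
            else:
                diameter = max(diameter, float(d))
            total += d
        closeness[v] = 1.0 / total if total > 0 else 0.0
    return PathMetrics(
        diameter=diameter,
        betweenness={v: float(b) for v, b in betweenness.items()},
        closeness=closeness,
        distance_mode=distance_mode,
    )


def hits_scores(
    g: nx.DiGraph, *, tol: float = 1e-12, max_iter: int = 1000
) -> tuple[dict[str, float], dict[str, float]]:
    """Hub ("Authors") and authority ("Receptors") scores, max-normalised.

    Mutually-reinforcing power iteration on the weighted adjacency A:
    authority <- A.T @ hub, hub <- A @ authority, each rescaled so its
    maximum is 1, iterated to a fixed point.  Scores are invariant to a
    uniform rescaling of all edge weights.
    """
    if g.number_of_edges() == 0:
        raise EmptyGraphError("graph has no edges; hub/authority scores undefined")
    nodes = list(g.nodes)
    a_mat = nx.to_numpy_array(g, nodelist=nodes, weight="weight")
    hub = np.ones(len(nodes))
    auth = np.ones(len(nodes))
    residual = np.inf
    for _ in range(max_iter):
        new_auth = a_mat.T @ hub
        if new_auth.max() > 0:
            new_auth /= new_auth.max()
        new_hub = a_mat @ new_auth
        if new_hub.max() > 0:
            new_hub /= new_hub.max()
        residual = max(
            np.abs(new_hub - hub).max(), np.abs(new_auth - auth).max()
        )
        hub, auth = new_hub, new_auth
        if residual < tol:
            break
    else:
        raise HitsConvergenceError(max_iter, residual)
    return (
        dict(zip(nodes, hub.tolist())),
        dict(zip(nodes, auth.tolist())),
    )


def node_strengths(
    g: nx.DiGraph,
) -> tuple[dict[str, float], dict[str, float], dict[str, float]]:
    """Weighted in/out/all strengths (interaction counts, not partner counts)."""
    if g.number_of_nodes() == 0:
        raise EmptyGraphError("empty graph")
    deg_in = dict(g.in_degree(weight="weight"))
    deg_out = dict(g.out_degree(weight="weight"))
    deg_all = {v: deg_in[v] + deg_out[v] for v in g.nodes}
    return deg_in, deg_out, deg_all


def network_panel(
    counts: CountMatrix,
    *,
    distance_mode: str = DEFAULT_DISTANCE_MODE,
    active_only: bool = True,
    display_zero_below: float = 1e-15,
) -> NetworkPanel:
    """Compute the full graph- and node-level parameter panel for one network.

    Hub/authority values below ``display_zero_below`` are reported as 0 —
    they are numerical zeros of the power iteration.
    """
    g = build_graph(counts, active_only=active_only)
    gm = graph_metrics(g)
    census = dyad_census(g)
    pm = path_metrics(g, distance_mode)
    hub, auth = hits_scores(g)
    deg_in, deg_out, deg_all = node_strengths(g)

    def clean(d: Mapping[str, float]) -> dict[str, float]:
        return {k: (0.0 if abs(v) < display_zero_below else v) for k, v in d.items()}

    nodes = pd.DataFrame(
        {
            "degree_in": pd.Series(deg_in, dtype=float),
            "degree_out": pd.Series(deg_out, dtype=float),
            "degree_all": pd.Series(deg_all, dtype=float),
            "betweenness": pd.Series(pm.betweenness, dtype=float),
            "closeness": pd.Series(pm.closeness, dtype=float),
            "hub_score": pd.Series(clean(hub), dtype=float),
            "authority_score": pd.Series(clean(auth), dtype=float),
        }
    ).sort_index()
    nodes.index.name = "animal"
    return NetworkPanel(
        category=counts.category,
        period=counts.period,
        n_nodes=g.number_of_nodes(),
        density=gm.density,
        connections=gm.connections,
        reciprocity=gm.reciprocity,
        asym=census.asym,
        null=census.null,
        mutual=census.mutual,
        diameter=pm.diameter,
        nodes=nodes,
    )


def counts_from_census(
    n_active: int,
    mutual: int,
    asym: int,
    *,
    n_inactive: int = 0,
    category: str = "agonistic",
    period: str = "pre",
) -> CountMatrix:
    """Construct a count matrix whose graph realizes a prescribed dyad census.

    The first ``mutual`` unordered pairs (in lexicographic order) get edges
    both ways, the next ``asym`` pairs one edge; remaining pairs stay null.
    ``n_inactive`` extra roster animals receive no events at all, which
    exercises the active-node convention.  Useful for checking the analytic
    identities density = E/(n(n-1)), mutual + asym + null = n(n-1)/2 and
    reciprocity = 2*mutual/E against published graph-level panels.
    """
    n_pairs = n_active * (n_active - 1) // 2
    if mutual + asym > n_pairs:
        raise ValueError(
            f"{mutual} mutual + {asym} asym pairs exceed C({n_active},2) = {n_pairs}"
        )
    total = n_active + n_inactive
    animals = tuple(f"A{i:02d}" for i in range(total))
    counts = np.zeros((total, total), dtype=int)
    pairs = [(i, j) for i in range(n_active) for j in range(i + 1, n_active)]
    for k, (i, j) in enumerate(pairs[: mutual + asym]):
        counts[i, j] = 1
        if k < mutual:
            counts[j, i] = 1
    cm = CountMatrix(animals, counts, category, period)
    active = (counts.sum(axis=0) + counts.sum(axis=1)) > 0
    if active.sum() != n_active:
        raise ValueError(
            f"census ({mutual}, {asym}) leaves only {active.sum()} of "
            f"{n_active} intended nodes active"
        )
    return cm


def export_edgelist(g: nx.DiGraph) -> pd.DataFrame:
    """Edge list (source, target, weight) for CSV / GraphML export."""
    return pd.DataFrame(
        [(u, v, d["weight"]) for u, v, d in g.edges(data=True)],
        columns=["source", "target", "weight"],
    )
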