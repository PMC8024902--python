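"""Admixture graphs: rooted DAGs of populations with drift and mixing edges.

A graph has one root, drift edges carrying non-negative lengths in f2
units, and admixture nodes that blend exactly two parents with proportion
``alpha`` (left parent) and ``1 - alpha`` (right parent).  Expected
f-statistics are computed from the graph in two ways:

* a linear path-weight model (the qpGraph convention) in which
  f2(A, B) = sum over drift edges of length * (wA - wB)^2, where w is the
  probability that a lineage sampled from the leaf drifts through the edge;
* an exact second-moment recursion under the Balding-Nichols drift law,
  used to validate the frequency simulator against the model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np


class GraphError(ValueError):
    pass


@dataclass
class AdmixtureGraph:
    """Drift edges map (parent, child) -> length; admixture maps
    child -> (left_parent, right_parent, alpha)."""

    drift_edges: dict = field(default_factory=dict)
    admixtures: dict = field(default_factory=dict)

    def __post_init__(self):
        self.validate()

    # -- structure --------------------------------------------------------
    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        for (parent, child), length in self.drift_edges.items():
            g.add_edge(parent, child, length=length, kind="drift")
        for child, (left, right, alpha) in self.admixtures.items():
            g.add_edge(left, child, alpha=alpha, kind="admix")
            g.add_edge(right, child, alpha=1.0 - alpha, kind="admix")
        return g

    def validate(self) -> None:
        g = self.to_networkx()
        if len(g) == 0:
            raise GraphError("empty graph")
        if not nx.is_directed_acyclic_graph(g):
            raise GraphError("graph contains a cycle")
        roots = [n for n in g if g.in_degree(n) == 0]
        if len(roots) != 1:
            raise GraphError(f"expected exactly one root, found {sorted(roots)}")
        for child in self.admixtures:
            if any((p, child) in self.drift_edges for p in g.predecessors(child)):
                raise GraphError(
                    f"admixture node {child} also has a drift parent")
            left, right, alpha = self.admixtures[child]
            if not 0.0 <= alpha <= 1.0:
                raise GraphError(f"alpha {alpha} at {child} outside [0, 1]")
            if left == right:
                raise GraphError(f"admixture node {child} has identical parents")
        for node in g:
            n_drift = sum((p, node) in self.drift_edges
                          for p in g.predecessors(node))
            if node not in self.admixtures and node not in roots and n_drift != 1:
                raise GraphError(f"node {node} needs exactly one drift parent")
        for (parent, child), length in self.drift_edges.items():
            if length < 0:
                raise GraphError(
                    f"negative drift length on {parent}->{child}")
        reachable = nx.descendants(g, roots[0]) | {roots[0]}
        orphans = set(g) - reachable
        if orphans:
            raise GraphError(f"nodes unreachable from root: {sorted(orphans)}")

    @property
    def root(self) -> str:
        g = self.to_networkx()
        return next(n for n in g if g.in_degree(n) == 0)

    @property
    def leaves(self) -> list:
        g = self.to_networkx()
        return sorted(n for n in g if g.out_degree(n) == 0)

    @property
    def nodes(self) -> list:
        return list(nx.topological_sort(self.to_networkx()))

    def copy(self) -> "AdmixtureGraph":
        return AdmixtureGraph(dict(self.drift_edges),
                              {c: tuple(v) for c, v in self.admixtures.items()})

    # -- parameter vector (for fitting) -----------------------------------
    def parameter_names(self) -> list:
        names = [f"drift:{p}->{c}" for p, c in sorted(self.drift_edges)]
        names += [f"alpha:{c}" for c in sorted(self.admixtures)]
        return names

    def get_parameters(self) -> np.ndarray:
        lengths = [self.drift_edges[e] for e in sorted(self.drift_edges)]
        alphas = [self.admixtures[c][2] for c in sorted(self.admixtures)]
        return np.array(lengths + alphas, dtype=float)

    def with_parameters(self, theta) -> "AdmixtureGraph":
        theta = np.asarray(theta, dtype=float)
        n_edges = len(self.drift_edges)
        drift = {e: float(theta[i]) for i, e in
                 enumerate(sorted(self.drift_edges))}
        admix = {}
        for i, c in enumerate(sorted(self.admixtures)):
            left, right, _ = self.admixtures[c]
            admix[c] = (left, right, float(theta[n_edges + i]))
        return AdmixtureGraph(drift, admix)


# ---------------------------------------------------------------------------
# Path weights and expected f-statistics (linear model)
# ---------------------------------------------------------------------------

def lineage_weights(graph: AdmixtureGraph, leaf: str) -> dict:
    """Probability that a lineage from ``leaf`` passes through each node."""
    g = graph.to_networkx()
    if leaf not in g:
        raise GraphError(f"unknown node {leaf!r}")
    w = {n: 0.0 for n in g}
    w[leaf] = 1.0
    for node in reversed(list(nx.topological_sort(g))):
        if w[node] == 0.0:
            continue
        if node in graph.admixtures:
            left, right, alpha = graph.admixtures[node]
            w[left] += alpha * w[node]
            w[right] += (1.0 - alpha) * w[node]
        else:
            for parent in g.predecessors(node):
                w[parent] += w[node]
    return w


def edge_weights(graph: AdmixtureGraph, leaf: str) -> dict:
    """Probability of drifting through each drift edge, keyed by edge."""
    w = lineage_weights(graph, leaf)
    return {(p, c): w[c] for (p, c) in graph.drift_edges}


def expected_f2(graph: AdmixtureGraph, leaf_a: str, leaf_b: str) -> float:
    """Expected f2 between two leaves in drift units (linear model)."""
    wa = edge_weights(graph, leaf_a)
    wb = edge_weights(graph, leaf_b)
    return float(sum(length * (wa[e] - wb[e]) ** 2
                     for e, length in graph.drift_edges.items()))


def expected_f2_matrix(graph: AdmixtureGraph, leaves=None) -> np.ndarray:
    leaves = list(leaves) if leaves is not None else graph.leaves
    ew = {leaf: edge_weights(graph, leaf) for leaf in leaves}
    edges = list(graph.drift_edges)
    lengths = np.array([graph.drift_edges[e] for e in edges])
    W = np.array([[ew[leaf][e] for e in edges] for leaf in leaves])
    diff = W[:, None, :] - W[None, :, :]
    return np.einsum("abe,e->ab", diff ** 2, lengths)


def expected_f3(graph, c, a, b) -> float:
    return 0.5 * (expected_f2(graph, c, a) + expected_f2(graph, c, b)
                  - expected_f2(graph, a, b))


def expected_f4(graph, a, b, c, d) -> float:
    return 0.5 * (expected_f2(graph, a, d) + expected_f2(graph, b, c)
                  - expected_f2(graph, a, c) - expected_f2(graph, b, d))


# ---------------------------------------------------------------------------
# Exact Balding-Nichols second moments
# ---------------------------------------------------------------------------

def bn_moment_matrix(graph: AdmixtureGraph, root_mean: float,
                     root_sq: float) -> tuple:
    """Exact cross-moment matrix E[p_u p_v] over all nodes under the
    Balding-Nichols drift law with given root moments.

    Drift preserves means and is conditionally independent of everything
    but the parent, so E[p_c p_v] = E[p_a p_v] for v != c and
    E[p_c^2] = (1 - d) E[p_a^2] + d E[p_a]; admixture is linear.
    """
    order = graph.nodes
    pos = {n: i for i, n in enumerate(order)}
    g = graph.to_networkx()
    n = len(order)
    S = np.zeros((n, n))
    root = order[0]
    S[0, 0] = root_sq
    for node in order[1:]:
        i = pos[node]
        done = [pos[v] for v in order[:order.index(node)]]
        if node in graph.admixtures:
            left, right, alpha = graph.admixtures[node]
            li, ri = pos[left], pos[right]
            for j in done:
                S[i, j] = S[j, i] = alpha * S[li, j] + (1 - alpha) * S[ri, j]
            S[i, i] = (alpha ** 2 * S[li, li]
                       + 2 * alpha * (1 - alpha) * S[li, ri]
                       + (1 - alpha) ** 2 * S[ri, ri])
        else:
            parent = next(p for p in g.predecessors(node))
            d = graph.drift_edges[(parent, node)]
            ai = pos[parent]
            for j in done:
                S[i, j] = S[j, i] = S[ai, j]
            S[i, i] = (1 - d) * S[ai, ai] + d * root_mean
    _ = root  # root moments enter through S[0, 0] and root_mean
    return S, pos


def expected_f2_bn(graph: AdmixtureGraph, leaf_a: str, leaf_b: str,
                   root_mean: float = 0.5,
                   root_sq: float = 0.3175) -> float:
    """Exact E[(p_A - p_B)^2] under Balding-Nichols drift, raw units.

    Defaults correspond to root frequencies uniform on (0.05, 0.95).
    """
    S, pos = bn_moment_matrix(graph, root_mean, root_sq)
    i, j = pos[leaf_a], pos[leaf_b]
    return float(S[i, i] + S[j, j] - 2 * S[i, j])


# ---------------------------------------------------------------------------
# Line-based graph format
# ---------------------------------------------------------------------------

def parse_graph(text: str) -> AdmixtureGraph:
    """Parse the line-based graph format.

    Lines are ``edge <parent> <child> <length>`` or
    ``admix <child> <left> <right> <alpha>``; ``#`` starts a comment.
    """
    drift, admix = {}, {}
    for lineno, raw in enumerate(text.splitlines(), 1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split()
        try:
            if parts[0] == "edge" and len(parts) == 4:
                drift[(parts[1], parts[2])] = float(parts[3])
            elif parts[0] == "admix" and len(parts) == 5:
                admix[parts[1]] = (parts[2], parts[3], float(parts[4]))
            else:
                raise GraphError(f"line {lineno}: unrecognized record {raw!r}")
        except ValueError as exc:
            raise GraphError(f"line {lineno}: {exc}") from exc
    try:
        return AdmixtureGraph(drift, admix)
    except GraphError as exc:
        raise GraphError(f"invalid graph: {exc}") from exc


def format_graph(graph: AdmixtureGraph) -> str:
    lines = [f"edge {p} {c} {length:.10g}"
             for (p, c), length in sorted(graph.drift_edges.items())]
    lines += [f"admix {c} {left} {right} {alpha:.10g}"
              for c, (left, right, alpha) in sorted(graph.admixtures.items())]
    return "\n".join(lines) + "\n"


def read_graph(path) -> AdmixtureGraph:
    with open(path) as fh:
        return parse_graph(fh.read())


def write_graph(graph: AdmixtureGraph, path) -> None:
    with open(path, "w") as fh:
        fh.write(format_graph(graph))
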