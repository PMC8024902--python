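"""Generalized-least-squares fitting of admixture graphs to f2 bases.

The model object pairs a graph topology with the observed pairwise-f2
basis (and its block-jackknife covariance) computed from genotype data;
``fit`` minimizes the GLS objective over drift lengths and admixture
proportions with seeded multi-start local optimization.  Results report
the residual Z score of every f4 (and f2) among the leaves; a model is
conventionally accepted when the worst |Z| stays below 3.

Model-exploration helpers implement the stepwise protocol used to build
continental admixture graphs: resolving trifurcations, ranking candidate
placements of a new population (unadmixed on an edge versus admixed
between two edges), and re-estimating per-population ancestry
proportions on a frozen final topology.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Optional

import networkx as nx
import numpy as np
import pandas as pd
from scipy import optimize

from .fstats import (BlockDefinition, PopulationFrequencies, f2_basis,
                     jackknife_mean)
from .graph import AdmixtureGraph, lineage_weights

logger = logging.getLogger(__name__)

WORST_Z_ACCEPT = 3.0      # graph-acceptance convention
ZERO_LENGTH = 1e-6        # report threshold for zero-length branches


class _GraphEvaluator:
    """Fast expected-f2 evaluation for a fixed topology.

    Precompiles the reverse-topological update schedule so that repeated
    evaluations inside the optimizer avoid graph-library overhead.
    """

    def __init__(self, topology: AdmixtureGraph, leaves):
        self.topology = topology
        self.leaves = list(leaves)
        order = topology.nodes
        self.pos = {n: i for i, n in enumerate(order)}
        g = topology.to_networkx()
        self.edge_list = sorted(topology.drift_edges)
        self.admix_list = sorted(topology.admixtures)
        self.n_edges = len(self.edge_list)
        # schedule entries: (child, kind, args) in reverse topological order
        self.schedule = []
        for node in reversed(order):
            if node in topology.admixtures:
                left, right, _ = topology.admixtures[node]
                a_idx = self.admix_list.index(node)
                self.schedule.append((self.pos[node], "admix",
                                      (self.pos[left], self.pos[right],
                                       a_idx)))
            elif g.in_degree(node):
                parent = next(iter(g.predecessors(node)))
                self.schedule.append((self.pos[node], "drift",
                                      self.pos[parent]))
        self.edge_child = np.array([self.pos[c] for _, c in self.edge_list])
        self.pairs = [(a, b) for i, a in enumerate(self.leaves)
                      for b in self.leaves[i + 1:]]

    def leaf_edge_weights(self, theta: np.ndarray) -> np.ndarray:
        """(n_leaves, n_edges) probabilities of drifting through each edge."""
        alphas = theta[self.n_edges:]
        n_nodes = len(self.pos)
        W = np.zeros((len(self.leaves), self.n_edges))
        for r, leaf in enumerate(self.leaves):
            w = np.zeros(n_nodes)
            w[self.pos[leaf]] = 1.0
            for child, kind, args in self.schedule:
                if w[child] == 0.0:
                    continue
                if kind == "admix":
                    left, right, a_idx = args
                    w[left] += alphas[a_idx] * w[child]
                    w[right] += (1.0 - alphas[a_idx]) * w[child]
                else:
                    w[args] += w[child]
            W[r] = w[self.edge_child]
        return W

    def f2_pairs(self, theta: np.ndarray) -> np.ndarray:
        lengths = theta[:self.n_edges]
        W = self.leaf_edge_weights(theta)
        i_idx = [self.leaves.index(a) for a, _ in self.pairs]
        j_idx = [self.leaves.index(b) for _, b in self.pairs]
        diff = W[i_idx] - W[j_idx]
        return diff ** 2 @ lengths

    def graph_with(self, theta: np.ndarray) -> AdmixtureGraph:
        drift = {e: float(theta[i]) for i, e in enumerate(self.edge_list)}
        admix = {}
        for i, c in enumerate(self.admix_list):
            left, right, _ = self.topology.admixtures[c]
            admix[c] = (left, right, float(theta[self.n_edges + i]))
        return AdmixtureGraph(drift, admix)


class AdmixtureGraphModel:
    """Admixture graph fitted to an observed pairwise-f2 basis.

    Parameters
    ----------
    topology : AdmixtureGraph — the structure to fit; current parameter
        values are used only as one optimization start.
    pf : PopulationFrequencies over at least the graph's leaves.
    blocks : BlockDefinition for jackknife covariance.
    leaf_populations : optional mapping of graph leaf name to the
        population in ``pf`` carrying its data (defaults to identity),
        which supports swapping a test population onto a fixed topology.
    """

    def __init__(self, topology: AdmixtureGraph, pf: PopulationFrequencies,
                 blocks: BlockDefinition,
                 leaf_populations: Optional[dict] = None):
        self.topology = topology
        self.pf = pf
        self.blocks = blocks
        self.leaves = topology.leaves
        self.leaf_populations = dict(leaf_populations or {})
        data_pops = [self.leaf_populations.get(leaf, leaf)
                     for leaf in self.leaves]
        basis = f2_basis(pf, data_pops, blocks)
        self.f2_obs = basis["estimate"]
        n_leaf = len(self.leaves)
        self.f2_pairs = [(self.leaves[i], self.leaves[j])
                         for i in range(n_leaf)
                         for j in range(i + 1, n_leaf)]
        self.n_snps = basis["n_snps"]
        cov = basis["cov"]
        evals = np.linalg.eigvalsh(cov)
        if evals.min() <= 1e-12 * max(evals.max(), 1e-300):
            logger.warning("f2 covariance near-singular; ridge applied")
            cov = cov + 1e-9 * np.trace(cov) / len(cov) * np.eye(len(cov))
        self.cov = cov
        self.qinv = np.linalg.inv(cov)
        self._eval = _GraphEvaluator(topology, self.leaves)

    # -- fitting ----------------------------------------------------------
    def _objective(self, theta: np.ndarray) -> float:
        r = self.f2_obs - self._eval.f2_pairs(theta)
        return float(r @ self.qinv @ r)

    def fit(self, n_starts: int = 8, seed: int = 0,
            free: Optional[np.ndarray] = None,
            theta0: Optional[np.ndarray] = None,
            maxiter: int = 500) -> "GraphFitResults":
        """Bound-constrained multi-start optimization.

        ``free`` optionally fixes a subset of parameters at ``theta0``
        (used when re-estimating one population on a frozen topology).
        """
        rng = np.random.default_rng(seed)
        n_edges = self._eval.n_edges
        n_par = n_edges + len(self._eval.admix_list)
        if theta0 is None:
            theta0 = self.topology.get_parameters()
        free = np.ones(n_par, dtype=bool) if free is None else free
        bounds = [(0.0, 1.0)] * n_par

        scale = max(float(np.mean(np.abs(self.f2_obs))), 1e-4)

        def full(theta_free):
            theta = theta0.copy()
            theta[free] = theta_free
            return theta

        best_theta, best_obj = None, np.inf
        converged = False
        for start in range(n_starts):
            if start == 0:
                init = theta0.copy()
            else:
                init = np.empty(n_par)
                init[:n_edges] = rng.uniform(0, 2 * scale, n_edges)
                init[n_edges:] = rng.uniform(0.05, 0.95,
                                             n_par - n_edges)
            res = optimize.minimize(
                lambda tf: self._objective(full(tf)), init[free],
                method="L-BFGS-B",
                bounds=[bounds[i] for i in np.flatnonzero(free)],
                options={"maxiter": maxiter, "ftol": 1e-12})
            if res.fun < best_obj:
                best_obj, best_theta = res.fun, full(res.x)
                converged = bool(res.success)
        fitted = self._eval.graph_with(best_theta)
        residuals = self._residual_table(best_theta)
        return GraphFitResults(self, fitted, best_theta, best_obj,
                               residuals, converged)

    # -- residual diagnostics --------------------------------------------
    def _residual_table(self, theta: np.ndarray) -> pd.DataFrame:
        exp_f2 = dict(zip(self.f2_pairs, self._eval.f2_pairs(theta)))
        rows = []
        obs_f2 = dict(zip(self.f2_pairs, self.f2_obs))
        se_f2 = dict(zip(self.f2_pairs, np.sqrt(np.diag(self.cov))))
        for pair in self.f2_pairs:
            obs, exp, se = obs_f2[pair], exp_f2[pair], se_f2[pair]
            rows.append(("f2", pair, obs, exp,
                         (obs - exp) / se if se > 0 else 0.0))

        def f2e(a, b):
            key = (a, b) if (a, b) in exp_f2 else (b, a)
            return exp_f2[key]

        data_pop = {leaf: self.leaf_populations.get(leaf, leaf)
                    for leaf in self.leaves}
        freq = {leaf: self.pf.freq[self.pf.index(data_pop[leaf])]
                for leaf in self.leaves}
        for quad in itertools.combinations(self.leaves, 4):
            a, b, c, d = quad
            for w, x, y, z in ((a, b, c, d), (a, c, b, d), (a, d, b, c)):
                expected = 0.5 * (f2e(w, z) + f2e(x, y)
                                  - f2e(w, y) - f2e(x, z))
                used = np.isfinite(np.vstack([freq[p] for p in
                                              (w, x, y, z)])).all(axis=0)
                terms = ((freq[w] - freq[x]) * (freq[y] - freq[z]))[used]
                obs, se, _, _ = jackknife_mean(terms, used, self.blocks)
                rows.append(("f4", (w, x, y, z), obs, expected,
                             (obs - expected) / se if se > 0 else 0.0))
        return pd.DataFrame(rows, columns=["statistic", "pops", "observed",
                                           "expected", "z"])


@dataclass
class GraphFitResults:
    """Optimized graph with objective, residual table and diagnostics."""

    model: AdmixtureGraphModel
    graph: AdmixtureGraph
    params: np.ndarray
    objective: float
    residuals: pd.DataFrame
    converged: bool

    @property
    def worst_abs_z(self) -> float:
        return float(self.residuals["z"].abs().max())

    @property
    def zero_length_edges(self) -> list:
        return [e for e, length in self.graph.drift_edges.items()
                if length < ZERO_LENGTH]

    @property
    def admixture_proportions(self) -> dict:
        return {c: v[2] for c, v in self.graph.admixtures.items()}

    def accepted(self, z_max: float = WORST_Z_ACCEPT) -> bool:
        return self.worst_abs_z < z_max

    def summary(self) -> str:
        lines = [
            "Admixture graph fit",
            f"  leaves: {', '.join(self.model.leaves)}",
            f"  n_snps: {self.model.n_snps}, "
            f"blocks: {self.model.blocks.n_blocks}",
            f"  objective: {self.objective:.4f}   "
            f"worst |Z|: {self.worst_abs_z:.3f}   "
            f"converged: {self.converged}",
        ]
        for (p, c), length in sorted(self.graph.drift_edges.items()):
            flag = "  (zero-length)" if length < ZERO_LENGTH else ""
            lines.append(f"  edge {p} -> {c}: {length:.5f}{flag}")
        for node, (left, right, alpha) in sorted(
                self.graph.admixtures.items()):
            lines.append(f"  admix {node}: {alpha:.3f} {left} "
                         f"+ {1 - alpha:.3f} {right}")
        worst = self.residuals.loc[self.residuals["z"].abs().idxmax()]
        lines.append(f"  worst residual: {worst['statistic']}"
                     f"{worst['pops']} Z = {worst['z']:.3f}")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# Topology surgery helpers
# ---------------------------------------------------------------------------

def _split_edge(graph: AdmixtureGraph, edge, label: str,
                length_split: float = 0.5) -> tuple:
    """Insert a node in the middle of a drift edge; returns new graph and
    node name."""
    parent, child = edge
    if edge not in graph.drift_edges:
        raise KeyError(f"no drift edge {parent}->{child}")
    mid = f"{label}_{parent}_{child}"
    g = graph.copy()
    length = g.drift_edges.pop(edge)
    g2 = AdmixtureGraph(
        {**g.drift_edges,
         (parent, mid): length * length_split,
         (mid, child): length * (1.0 - length_split)},
        g.admixtures)
    return g2, mid


def resolve_trifurcation(graph: AdmixtureGraph, node: str,
                         pair: tuple) -> AdmixtureGraph:
    """Resolve a three-child node by grouping ``pair`` under a new
    internal branch of initial length 0."""
    g = graph.copy()
    children = [c for (p, c) in g.drift_edges if p == node]
    if len(children) != 3:
        raise ValueError(f"node {node} has {len(children)} drift children, "
                         "expected 3")
    if set(pair) - set(children):
        raise ValueError(f"{pair} are not children of {node}")
    mid = f"{node}_res_{pair[0]}_{pair[1]}"
    drift = dict(g.drift_edges)
    for c in pair:
        drift[(mid, c)] = drift.pop((node, c))
    drift[(node, mid)] = 0.0
    return AdmixtureGraph(drift, g.admixtures)


def trifurcation_test(graph: AdmixtureGraph, node: str,
                      pf: PopulationFrequencies, blocks: BlockDefinition,
                      seed: int = 0, n_starts: int = 6,
                      z_max: float = WORST_Z_ACCEPT,
                      branch_tol: float = 1e-3) -> dict:
    """Fit the three binary resolutions of a trifurcating node.

    The node is declared statistically consistent with a trifurcation when
    every resolution fits (worst |Z| below ``z_max``) and the separating
    branch collapses below ``branch_tol`` in each.  ``branch_tol`` is in
    the raw f2 units of the fitted lengths; the default absorbs the
    sampling noise of a desk-scale panel while staying an order of
    magnitude below any branch the same panel can actually resolve.
    """
    children = sorted(c for (p, c) in graph.drift_edges if p == node)
    fits = {}
    for pair in itertools.combinations(children, 2):
        resolved = resolve_trifurcation(graph, node, pair)
        model = AdmixtureGraphModel(resolved, pf, blocks)
        fit = model.fit(n_starts=n_starts, seed=seed)
        mid = f"{node}_res_{pair[0]}_{pair[1]}"
        fits[pair] = {
            "fit": fit,
            "worst_abs_z": fit.worst_abs_z,
            "separating_branch": fit.graph.drift_edges[(node, mid)],
        }
    consistent = all(v["worst_abs_z"] < z_max
                     and v["separating_branch"] < branch_tol
                     for v in fits.values())
    return {"node": node, "resolutions": fits,
            "trifurcation_consistent": consistent}


def graft_unadmixed(graph: AdmixtureGraph, candidate: str, edge,
                    init_length: float = 0.01) -> AdmixtureGraph:
    g, mid = _split_edge(graph, edge, f"att_{candidate}")
    return AdmixtureGraph({**g.drift_edges, (mid, candidate): init_length},
                          g.admixtures)


def graft_admixed(graph: AdmixtureGraph, candidate: str, edge1, edge2,
                  alpha: float = 0.5,
                  init_length: float = 0.01) -> AdmixtureGraph:
    g, mid1 = _split_edge(graph, edge1, f"src1_{candidate}")
    g, mid2 = _split_edge(g, edge2, f"src2_{candidate}")
    adm = f"adm_{candidate}"
    return AdmixtureGraph(
        {**g.drift_edges, (adm, candidate): init_length},
        {**g.admixtures, adm: (mid1, mid2, alpha)})


def compare_placements(base: AdmixtureGraph, candidate: str,
                       placements: list, pf: PopulationFrequencies,
                       blocks: BlockDefinition, seed: int = 0,
                       n_starts: int = 6,
                       z_max: float = WORST_Z_ACCEPT) -> pd.DataFrame:
    """Graft a candidate population under each proposed placement, refit,
    and rank by worst residual |Z|.

    ``placements`` entries are ``{"kind": "unadmixed", "edge": (p, c)}``
    or ``{"kind": "admixed", "edges": [(p1, c1), (p2, c2)]}``.  Placements
    with worst |Z| below ``z_max`` are marked accepted.
    """
    if not placements:
        raise ValueError("empty placement list")
    rows = []
    for k, placement in enumerate(placements):
        if placement["kind"] == "unadmixed":
            grafted = graft_unadmixed(base, candidate, placement["edge"])
            label = f"unadmixed@{placement['edge']}"
        elif placement["kind"] == "admixed":
            e1, e2 = placement["edges"]
            grafted = graft_admixed(base, candidate, e1, e2)
            label = f"admixed@{e1}+{e2}"
        else:
            raise ValueError(f"unknown placement kind {placement['kind']!r}")
        fit = AdmixtureGraphModel(grafted, pf, blocks).fit(
            n_starts=n_starts, seed=seed + k)
        rows.append({"placement": label, "kind": placement["kind"],
                     "worst_abs_z": fit.worst_abs_z,
                     "objective": fit.objective,
                     "accepted": fit.worst_abs_z < z_max,
                     "fit": fit})
    table = pd.DataFrame(rows).sort_values(
        "worst_abs_z").reset_index(drop=True)
    table["rank"] = np.arange(1, len(table) + 1)
    return table


# ---------------------------------------------------------------------------
# Ancestry proportions on a frozen topology
# ---------------------------------------------------------------------------

def ancestry_proportions(final: AdmixtureGraph, test_population: str,
                         leaf: str, pf: PopulationFrequencies,
                         blocks: BlockDefinition, ancestry_nodes: dict,
                         seed: int = 0, n_starts: int = 6) -> dict:
    """Re-estimate one leaf's ancestry make-up on a frozen final graph.

    ``final`` must carry fitted parameter values on the scale of the
    observed f2 basis (i.e. come from a previous ``fit``), since the
    frozen parameters are used as-is.
    The designated ``leaf`` is re-backed by ``test_population``'s data;
    only the parameters private to that leaf's lineage (its terminal
    drift edges and admixture proportions feeding no other leaf) are
    re-optimized.  Ancestry proportions are the fitted probabilities that
    a lineage sampled from the leaf passes through each node named in
    ``ancestry_nodes`` (label -> node), which must cut every root path.
    """
    g = final.to_networkx()
    private = {n for n in nx.ancestors(g, leaf) | {leaf}
               if not any(other != leaf and nx.has_path(g, n, other)
                          for other in final.leaves)}
    eval_edges = sorted(final.drift_edges)
    eval_admix = sorted(final.admixtures)
    free = np.array([c in private for (_, c) in eval_edges]
                    + [c in private for c in eval_admix])
    if not free.any():
        raise ValueError(f"leaf {leaf} has no private parameters to refit")

    model = AdmixtureGraphModel(final, pf, blocks,
                                leaf_populations={leaf: test_population})
    fit = model.fit(n_starts=n_starts, seed=seed, free=free,
                    theta0=final.get_parameters())

    weights = lineage_weights(fit.graph, leaf)
    proportions = {label: weights[node]
                   for label, node in ancestry_nodes.items()}
    total = sum(proportions.values())
    if abs(total - 1.0) > 1e-6:
        raise ValueError(
            f"ancestry nodes do not cut all lineages (sum {total:.4f}); "
            "choose nodes covering every path to the root")
    return {"proportions": proportions, "worst_abs_z": fit.worst_abs_z,
            "fit": fit}
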