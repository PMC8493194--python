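"""Reaction-graph construction and topology statistics.

CRNs are turned into directed graphs with regular nodes for structures and
special nodes for reactions between more than two structures (1->1
reactions become plain edges).  The module computes the robustness /
modularity / hierarchy bundle: density, degree assortativity, a discrete
power-law fit with a Kolmogorov-Smirnov bootstrap test, average local
clustering, global reaching centrality and flow hierarchy, plus node /
edge betweenness and eigenvector centralities.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import islice

import networkx as nx
import numpy as np
from scipy.optimize import minimize_scalar
from scipy.special import zeta

from .enumerator import CRN, Reaction

__all__ = [
    "ReactionGraph",
    "GraphStats",
    "CentralityReport",
    "build_graph",
    "overlap_network",
    "density_assortativity",
    "fit_discrete_powerlaw",
    "sample_discrete_powerlaw",
    "powerlaw_ks",
    "clustering_stats",
    "hierarchy_metrics",
    "centralities",
    "graph_stats",
    "to_dot",
]

NODE_KINDS = ("source", "wellformed", "intermediary", "reaction")

#: a directed reaction graph; node attribute "kind" is one of NODE_KINDS
ReactionGraph = nx.DiGraph


def build_graph(crn: CRN, wellformed: set[str] | frozenset[str] = frozenset()) -> ReactionGraph:
    """Deterministic reaction graph: structure nodes keyed by kernel string.

    1-reactant-1-product reactions appear as a single direct edge; any
    reaction with more than two participants becomes a reaction node with
    reactant -> reaction and reaction -> product edges.  Reactant
    multiplicity is collapsed to one edge carrying a ``multiplicity``
    attribute.
    """
    g = nx.DiGraph()
    initial = {c.kernel for c in crn.initial}
    for c in crn.structures:
        key = c.kernel
        if key in initial:
            kind = "source"
        elif key in wellformed:
            kind = "wellformed"
        else:
            kind = "intermediary"
        g.add_node(key, kind=kind)
    for r in crn.reactions:
        rk = [c.kernel for c in r.reactants]
        pk = [c.kernel for c in r.products]
        if len(rk) == 1 and len(pk) == 1:
            g.add_edge(rk[0], pk[0], rtype=r.rtype)
            continue
        rnode = f"rxn[{r.rtype}] {' + '.join(rk)} -> {' + '.join(pk)}"
        g.add_node(rnode, kind="reaction", rtype=r.rtype)
        for side, direction in ((rk, "in"), (pk, "out")):
            mult: dict[str, int] = {}
            for key in side:
                mult[key] = mult.get(key, 0) + 1
            for key, m in mult.items():
                if direction == "in":
                    g.add_edge(key, rnode, rtype=r.rtype, multiplicity=m)
                else:
                    g.add_edge(rnode, key, rtype=r.rtype, multiplicity=m)
    return g


def _k_shortest_paths(
    g: ReactionGraph, source: str, target: str, k: int, buffer_cap: int = 1000
) -> list[list[str]]:
    """Up to k shortest simple paths, ties broken lexicographically.

    Collects candidate paths from the length-ordered generator until the
    length strictly exceeds the k-th best (or a hard cap fires), then sorts
    by (length, node sequence) for a deterministic selection.
    """
    if source == target or source not in g or target not in g:
        return []
    paths: list[list[str]] = []
    try:
        gen = nx.shortest_simple_paths(g, source, target)
        for path in islice(gen, buffer_cap):
            if len(paths) >= k and len(path) > len(paths[k - 1]):
                break
            paths.append(path)
            paths.sort(key=lambda p: (len(p), p))
    except nx.NetworkXNoPath:
        return []
    return paths[:k]


def overlap_network(g: ReactionGraph, k_paths: int = 6) -> ReactionGraph:
    """Sub-graph spanning sources, well-formed nodes and up to ``k_paths``
    shortest simple directed paths between every (source, well-formed)
    ordered pair.  Unreachable pairs contribute nothing.
    """
    sources = sorted(n for n, d in g.nodes(data=True) if d.get("kind") == "source")
    targets = sorted(n for n, d in g.nodes(data=True) if d.get("kind") == "wellformed")
    keep_nodes: set[str] = set(sources) | set(targets)
    keep_edges: set[tuple[str, str]] = set()
    for s in sources:
        for t in targets:
            for path in _k_shortest_paths(g, s, t, k_paths):
                keep_nodes.update(path)
                keep_edges.update(zip(path, path[1:]))
    sub = nx.DiGraph()
    for n in sorted(keep_nodes):
        sub.add_node(n, **g.nodes[n])
    for u, v in sorted(keep_edges):
        sub.add_edge(u, v, **g.edges[u, v])
    return sub


# ---------------------------------------------------------------------------
# robustness metrics
# ---------------------------------------------------------------------------


def density_assortativity(g: ReactionGraph) -> dict[str, float]:
    """Directed density m/(n(n-1)); total-degree assortativity (undirected).

    Degenerate degree sequences make the assortativity Pearson coefficient
    undefined; reported as NaN.
    """
    n = g.number_of_nodes()
    if n < 2:
        raise ValueError("need at least 2 nodes")
    density = g.number_of_edges() / (n * (n - 1))
    und = nx.Graph(g.to_undirected())
    try:
        with np.errstate(invalid="ignore", divide="ignore"):
            assort = float(nx.degree_assortativity_coefficient(und))
    except (ZeroDivisionError, ValueError):
        assort = float("nan")
    return {"density": density, "assortativity": assort}


# -- discrete power-law fit (KS minimization + MLE, bootstrap p-value) ------

_ALPHA_RANGE = (1.05, 6.0)


def _alpha_mle(tail: np.ndarray, xmin: int) -> float:
    logs = np.sum(np.log(tail))
    n = len(tail)

    def nll(a: float) -> float:
        return n * math.log(zeta(a, xmin)) + a * logs

    res = minimize_scalar(nll, bounds=_ALPHA_RANGE, method="bounded")
    return float(res.x)


def _ks_stat(tail: np.ndarray, alpha: float, xmin: int) -> float:
    xs = np.arange(xmin, tail.max() + 1)
    denom = zeta(alpha, xmin)
    # model CDF at x: P(X <= x) = 1 - zeta(alpha, x+1)/zeta(alpha, xmin)
    model = 1.0 - zeta(alpha, xs + 1) / denom
    emp = np.searchsorted(np.sort(tail), xs, side="right") / len(tail)
    return float(np.max(np.abs(emp - model)))


def fit_discrete_powerlaw(data: np.ndarray, min_tail: int = 10) -> dict:
    """Clauset-style discrete fit: xmin by KS minimization, alpha by MLE."""
    data = np.asarray(data, dtype=int)
    data = data[data > 0]
    if len(data) < min_tail:
        raise ValueError(f"need at least {min_tail} positive observations")
    candidates = np.unique(data)[:-1] if len(np.unique(data)) > 1 else np.unique(data)
    best: dict | None = None
    for xmin in candidates:
        tail = data[data >= xmin]
        if len(tail) < min_tail:
            continue
        alpha = _alpha_mle(tail, int(xmin))
        d = _ks_stat(tail, alpha, int(xmin))
        if best is None or d < best["D"]:
            best = {"alpha": alpha, "xmin": int(xmin), "D": d, "n_tail": len(tail)}
    if best is None:
        # fall back to the smallest value even if the tail is short
        xmin = int(candidates[0])
        tail = data[data >= xmin]
        alpha = _alpha_mle(tail, xmin)
        best = {"alpha": alpha, "xmin": xmin, "D": _ks_stat(tail, alpha, xmin), "n_tail": len(tail)}
    return best


def sample_discrete_powerlaw(
    alpha: float, xmin: int, size: int, rng: np.random.Generator
) -> np.ndarray:
    """Exact inverse-CDF sampling of P(X = x) ~ x^-alpha for x >= xmin."""
    denom = zeta(alpha, xmin)
    us = rng.random(size)
    out = np.empty(size, dtype=int)
    for i, u in enumerate(us):
        # find smallest x with survival(x+1) = zeta(a, x+1)/denom < 1 - u
        lo, hi = xmin, 2 * xmin + 1
        target = 1.0 - u
        while zeta(alpha, hi + 1) / denom >= target:
            lo, hi = hi, 2 * hi
        while lo < hi:
            mid = (lo + hi) // 2
            if zeta(alpha, mid + 1) / denom < target:
                hi = mid
            else:
                lo = mid + 1
        out[i] = lo
    return out


def powerlaw_ks(
    degrees: np.ndarray,
    bootstrap_reps: int = 100,
    rng: np.random.Generator | None = None,
    min_tail: int = 10,
) -> dict:
    """Power-law test of a degree sequence per the semi-parametric bootstrap.

    Fits (alpha, xmin) to the positive degrees, then compares the observed
    KS distance against distances from synthetic samples drawn from the
    fitted model (tail) mixed with the empirical body.  Declares
    "scale-free" iff p >= 0.1.  Note: the conventional recommendation is
    >= 1000 bootstrap replicates; the default 100 is a desk-scale setting.
    """
    rng = np.random.default_rng(0) if rng is None else rng
    data = np.asarray(degrees, dtype=int)
    data = data[data > 0]
    fit = fit_discrete_powerlaw(data, min_tail=min_tail)
    n = len(data)
    body = data[data < fit["xmin"]]
    p_tail = fit["n_tail"] / n
    worse = 0
    for _ in range(bootstrap_reps):
        from_tail = rng.random(n) < p_tail
        n_t = int(from_tail.sum())
        synth = np.empty(n, dtype=int)
        if n_t:
            synth[:n_t] = sample_discrete_powerlaw(fit["alpha"], fit["xmin"], n_t, rng)
        if n - n_t:
            if len(body):
                synth[n_t:] = rng.choice(body, size=n - n_t, replace=True)
            else:
                synth[n_t:] = sample_discrete_powerlaw(
                    fit["alpha"], fit["xmin"], n - n_t, rng
                )
        try:
            refit = fit_discrete_powerlaw(synth, min_tail=min_tail)
            if refit["D"] >= fit["D"]:
                worse += 1
        except ValueError:
            worse += 1
    p = worse / bootstrap_reps
    return {
        "alpha": fit["alpha"],
        "xmin": fit["xmin"],
        "D": fit["D"],
        "p": p,
        "n_tail": fit["n_tail"],
        "scale_free": p >= 0.1,
        "bootstrap_reps": bootstrap_reps,
    }


# ---------------------------------------------------------------------------
# modularity / hierarchy / centrality
# ---------------------------------------------------------------------------


def clustering_stats(g: ReactionGraph) -> dict[str, float]:
    """Mean and std of per-node local clustering (undirected projection)."""
    if g.number_of_nodes() < 3:
        raise ValueError("need at least 3 nodes")
    vals = np.array(list(nx.clustering(nx.Graph(g.to_undirected())).values()))
    return {"mean": float(vals.mean()), "std": float(vals.std())}


def hierarchy_metrics(g: ReactionGraph) -> dict[str, float]:
    """Global reaching centrality and flow hierarchy of a directed graph.

    GRC aggregates the spread of per-node reachability fractions
    C_R(i) = |descendants(i)| / (n - 1); flow hierarchy is the fraction of
    edges whose endpoints lie in different strongly connected components
    (edges on no cycle).
    """
    n = g.number_of_nodes()
    if n < 2:
        raise ValueError("need at least 2 nodes")
    reach = np.array([len(nx.descendants(g, v)) / (n - 1) for v in g.nodes])
    grc = float(np.sum(reach.max() - reach) / (n - 1))
    m = g.number_of_edges()
    if m == 0:
        fh = 1.0
    else:
        scc_of = {}
        for i, comp in enumerate(nx.strongly_connected_components(g)):
            for v in comp:
                scc_of[v] = i
        acyclic = sum(1 for u, v in g.edges if scc_of[u] != scc_of[v])
        fh = acyclic / m
    return {"global_reaching_centrality": grc, "flow_hierarchy": fh}


@dataclass
class CentralityReport:
    node_betweenness: dict[str, float]
    edge_betweenness: dict[tuple[str, str], float]
    eigenvector_centrality: dict[str, float]
    eigenvector_fallback: bool = False


def _power_iteration(
    g: ReactionGraph, tol: float = 1e-8, max_iter: int = 10_000
) -> dict[str, float] | None:
    """Principal eigenvector of the adjacency matrix (in-edge convention),
    normalized to unit maximum.  None when iteration fails to converge or
    degenerates to the zero vector.
    """
    nodes = sorted(g.nodes)
    index = {v: i for i, v in enumerate(nodes)}
    n = len(nodes)
    a = np.zeros((n, n))
    for u, v in g.edges:
        a[index[u], index[v]] = 1.0
    x = np.full(n, 1.0 / n)
    for _ in range(max_iter):
        nxt = a.T @ x
        norm = np.max(np.abs(nxt))
        if norm == 0:
            return None
        nxt /= norm
        if np.max(np.abs(nxt - x)) < tol:
            return {v: float(nxt[index[v]]) for v in nodes}
        x = nxt
    return None


def centralities(g: ReactionGraph) -> CentralityReport:
    """Betweenness (unnormalized shortest-path counts) and eigenvector
    centrality.  Eigenvector non-convergence on the directed graph falls
    back to the undirected projection, flagged in the report.
    """
    nb = nx.betweenness_centrality(g, normalized=False)
    eb = nx.edge_betweenness_centrality(g, normalized=False)
    ev = _power_iteration(g)
    fallback = ev is None
    if fallback:
        ev = _power_iteration(nx.DiGraph(nx.Graph(g.to_undirected())))
        if ev is None:
            ev = {v: 1.0 for v in g.nodes}
    return CentralityReport(
        {k: float(v) for k, v in nb.items()},
        {k: float(v) for k, v in eb.items()},
        ev,
        eigenvector_fallback=fallback,
    )


@dataclass
class GraphStats:
    """The per-network metric bundle (one row per analysed network)."""

    n_nodes: int
    n_edges: int
    density: float
    assortativity: float
    ks_powerlaw: dict
    clustering: dict
    global_reaching_centrality: float
    flow_hierarchy: float

    def as_row(self) -> dict:
        return {
            "n_nodes": self.n_nodes,
            "n_edges": self.n_edges,
            "density": self.density,
            "assortativity": self.assortativity,
            "ks_D": self.ks_powerlaw.get("D"),
            "ks_p": self.ks_powerlaw.get("p"),
            "alpha": self.ks_powerlaw.get("alpha"),
            "xmin": self.ks_powerlaw.get("xmin"),
            "scale_free": self.ks_powerlaw.get("scale_free"),
            "clustering_mean": self.clustering["mean"],
            "clustering_std": self.clustering["std"],
            "global_reaching_centrality": self.global_reaching_centrality,
            "flow_hierarchy": self.flow_hierarchy,
        }


def graph_stats(
    g: ReactionGraph,
    bootstrap_reps: int = 100,
    rng: np.random.Generator | None = None,
) -> GraphStats:
    da = density_assortativity(g)
    degrees = np.array([d for _, d in nx.Graph(g.to_undirected()).degree()])
    try:
        ks = powerlaw_ks(degrees, bootstrap_reps=bootstrap_reps, rng=rng)
    except ValueError as exc:
        ks = {"error": str(exc), "scale_free": False}
    hier = hierarchy_metrics(g)
    return GraphStats(
        g.number_of_nodes(),
        g.number_of_edges(),
        da["density"],
        da["assortativity"],
        ks,
        clustering_stats(g),
        hier["global_reaching_centrality"],
        hier["flow_hierarchy"],
    )


def to_dot(g: ReactionGraph) -> str:
    """Minimal GraphViz export with node-kind shapes."""
    shapes = {"source": "box", "wellformed": "ellipse", "intermediary": "diamond", "reaction": "point"}
    lines = ["digraph crn {"]
    ids = {n: f"n{i}" for i, n in enumerate(sorted(g.nodes))}
    for n in sorted(g.nodes):
        kind = g.nodes[n].get("kind", "intermediary")
        label = n.replace('"', "'")
        lines.append(f'  {ids[n]} [label="{label}" shape={shapes.get(kind, "ellipse")}];')
    for u, v in sorted(g.edges):
        lines.append(f"  {ids[u]} -> {ids[v]};")
    lines.append("}")
    return "\n".join(lines) + "\n"
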