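"""Interaction-network topology: MCODE module detection and hub ranking.

The MCODE score of a candidate module with N nodes and E edges is graph
density times size, 2E/(N(N-1)) * N = 2E/(N-1); modules with score >= 5 are
reported by default. Vertex weighting and the greedy seeded expansion follow
the published MCODE algorithm on simple undirected graphs; returned modules
are vertex-disjoint (visited-flag semantics). Hub genes are ranked by degree.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

NODE_SCORE_CUTOFF_DEFAULT = 0.2
SCORE_MIN_DEFAULT = 5.0


@dataclass
class GraphModule:
    """A detected module with its MCODE bookkeeping."""

    member_nodes: list[str]
    n_edges: int
    density: float
    mcode_score: float
    member_degrees: dict[str, int] = field(default_factory=dict)


def mcode_score(n_nodes: int, n_edges: int) -> float:
    """density * size = 2E/(N(N-1)) * N for a simple undirected module."""
    if n_nodes < 2:
        raise ValueError("a module needs at least two nodes")
    max_edges = n_nodes * (n_nodes - 1) // 2
    if not (0 <= n_edges <= max_edges):
        raise ValueError(f"edge count {n_edges} outside [0, {max_edges}]")
    density = 2.0 * n_edges / (n_nodes * (n_nodes - 1))
    return density * n_nodes


def _simple(g: nx.Graph) -> nx.Graph:
    h = nx.Graph(g)
    h.remove_edges_from(nx.selfloop_edges(h))
    return h


def mcode_vertex_weights(g: nx.Graph, k_core_min: int = 1) -> dict[str, float]:
    """MCODE vertex weighting.

    For each node, take the subgraph induced by its closed neighborhood, find
    its highest k-core; the weight is that core number times the density of
    the k-core subgraph. Isolated nodes weigh 0; raising ``k_core_min``
    additionally zeroes nodes whose neighborhood supports no core that deep.
    """
    g = _simple(g)
    weights: dict[str, float] = {}
    for v in g.nodes:
        nbhd = set(g[v]) | {v}
        sub = g.subgraph(nbhd)
        if sub.number_of_edges() == 0:
            weights[v] = 0.0
            continue
        core_nums = nx.core_number(sub)
        k_max = max(core_nums.values())
        if k_max < k_core_min:
            weights[v] = 0.0
            continue
        core_nodes = [u for u, c in core_nums.items() if c >= k_max]
        core_sub = sub.subgraph(core_nodes)
        nn = core_sub.number_of_nodes()
        density = (
            2.0 * core_sub.number_of_edges() / (nn * (nn - 1)) if nn > 1 else 0.0
        )
        weights[v] = k_max * density
    return weights


def mcode_find_modules(
    g: nx.Graph,
    node_score_cutoff: float = NODE_SCORE_CUTOFF_DEFAULT,
    score_min: float = SCORE_MIN_DEFAULT,
    haircut: bool = False,
    fluff: bool = False,
    fluff_density_cutoff: float = 0.5,
) -> list[GraphModule]:
    """Greedy MCODE complex prediction.

    Seeds from the highest-weight unvisited vertex and breadth-first includes
    neighbors whose weight is within ``node_score_cutoff`` of the seed weight
    (w >= w_seed * (1 - cutoff)); every included vertex is marked visited, so
    modules are vertex-disjoint. Modules scoring below ``score_min`` are
    dropped; survivors are sorted by score descending (ties by size, then by
    smallest member id). ``haircut`` prunes degree-1 members; ``fluff`` adds
    unvisited neighbors whose neighborhood density passes the fluff cutoff.
    """
    g = _simple(g)
    weights = mcode_vertex_weights(g)
    visited: set = set()
    raw_modules: list[set] = []
    for seed in sorted(g.nodes, key=lambda v: (-weights[v], str(v))):
        if seed in visited or weights[seed] <= 0:
            continue
        threshold = weights[seed] * (1.0 - node_score_cutoff)
        module = {seed}
        visited.add(seed)
        frontier = [seed]
        while frontier:
            nxt = []
            for u in frontier:
                for w in g[u]:
                    if w not in visited and weights[w] >= threshold:
                        visited.add(w)
                        module.add(w)
                        nxt.append(w)
            frontier = nxt
        if len(module) >= 2:
            raw_modules.append(module)

    modules: list[GraphModule] = []
    for nodes in raw_modules:
        if haircut:
            while True:
                sub = g.subgraph(nodes)
                stubs = [v for v in nodes if sub.degree(v) < 2]
                if not stubs or len(nodes) - len(stubs) < 2:
                    break
                nodes = nodes - set(stubs)
        if fluff:
            extra = set()
            for v in list(nodes):
                for w in g[v]:
                    if w in nodes or w in extra:
                        continue
                    nbhd = set(g[w]) | {w}
                    sub = g.subgraph(nbhd)
                    nn = sub.number_of_nodes()
                    dens = 2.0 * sub.number_of_edges() / (nn * (nn - 1)) if nn > 1 else 0.0
                    if dens >= fluff_density_cutoff:
                        extra.add(w)
            nodes = nodes | extra
        if len(nodes) < 2:
            continue
        sub = g.subgraph(nodes)
        n, e = sub.number_of_nodes(), sub.number_of_edges()
        score = mcode_score(n, e)
        if score < score_min:
            continue
        members = sorted(nodes, key=str)
        modules.append(
            GraphModule(
                member_nodes=members,
                n_edges=e,
                density=2.0 * e / (n * (n - 1)),
                mcode_score=score,
                member_degrees={v: g.degree(v) for v in members},
            )
        )
    modules.sort(key=lambda m: (-m.mcode_score, -len(m.member_nodes), m.member_nodes[0]))
    return modules


def degree_ranking(g: nx.Graph, top: int | None = None) -> pd.DataFrame:
    """Nodes ranked by degree descending, ties broken lexicographically."""
    g = _simple(g)
    rows = sorted(((str(v), d) for v, d in g.degree()), key=lambda t: (-t[1], t[0]))
    if top is not None:
        rows = rows[: max(0, int(top))]
    return pd.DataFrame(rows, columns=["node", "degree"])


def modules_table(modules: list[GraphModule]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "module_id": [f"M{i + 1}" for i in range(len(modules))],
            "n_nodes": [len(m.member_nodes) for m in modules],
            "n_edges": [m.n_edges for m in modules],
            "score": [m.mcode_score for m in modules],
            "members": [",".join(m.member_nodes) for m in modules],
        }
    )
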