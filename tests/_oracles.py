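"""Independent brute-force oracles used by the test suite.

These deliberately re-derive expected values by the most direct route
available (recursion, enumeration, permutation), independent of the
package's implementations.
"""

from __future__ import annotations

import itertools
import math
from collections import defaultdict

import numpy as np


# ---------------------------------------------------------------------------
# pathway signal flow: recursive evaluator on explicit node/edge dicts
# ---------------------------------------------------------------------------

def psf_recursive(nodes: dict, edges: list, fc: dict, combine: str = "mean") -> dict:
    """Evaluate PSF by memoised recursion.

    ``nodes``: node -> dict(kind=..., members=[...]); ``edges``: list of
    (source, target, sign) with sign in {activate, inhibit}.
    """
    parents = defaultdict(list)
    for u, v, sign in edges:
        parents[v].append((u, sign))
    memo: dict = {}

    def own_fc(n):
        d = nodes[n]
        if d["kind"] != "gene":
            return 1.0
        vals = [float(fc.get(m, 1.0)) for m in d.get("members", [n])]
        return math.exp(sum(math.log(v) for v in vals) / len(vals))

    def value(n):
        if n in memo:
            return memo[n]
        ps = parents[n]
        if not ps:
            out = own_fc(n)
        else:
            ins = [value(u) if sign == "activate" else 1.0 / value(u)
                   for u, sign in ps]
            if combine == "mean":
                agg = sum(ins) / len(ins)
            elif combine == "sum":
                agg = sum(ins)
            elif combine == "min":
                agg = min(ins)
            else:
                agg = math.prod(ins)
            out = agg * own_fc(n)
        memo[n] = out
        return out

    return {n: value(n) for n in nodes}


def random_dag(rng: np.random.Generator, max_nodes: int = 6):
    """A random signed DAG with gene nodes and one terminal sink node.

    Returns (nodes dict, edges list) in the oracle's own representation.
    """
    n = int(rng.integers(2, max_nodes + 1))
    names = [f"n{i}" for i in range(n)]
    nodes = {}
    for i, name in enumerate(names[:-1]):
        nodes[name] = dict(kind="gene", members=[name])
    nodes[names[-1]] = dict(kind="sink", members=[])
    edges = []
    for i, j in itertools.combinations(range(n), 2):
        if rng.random() < 0.5:
            sign = "activate" if rng.random() < 0.7 else "inhibit"
            edges.append((names[i], names[j], sign))
    # make sure the sink has at least one parent
    if not any(v == names[-1] for _, v, _ in edges):
        edges.append((names[0], names[-1], "activate"))
    return nodes, edges


def to_pathway_graph(nodes: dict, edges: list):
    """Convert the oracle representation into a telomaint PathwayGraph."""
    import networkx as nx

    from telomaint.tmm_pathway import PathwayGraph

    g = nx.DiGraph()
    for name, d in nodes.items():
        g.add_node(name, kind=d["kind"], branch="" if d["kind"] == "sink" else "main",
                   members=tuple(d.get("members", [])))
    for u, v, sign in edges:
        g.add_edge(u, v, sign=sign, priority=1)
    return PathwayGraph(graph=g, name="random")


# ---------------------------------------------------------------------------
# betweenness centrality: shortest-path enumeration from scratch
# ---------------------------------------------------------------------------

def betweenness_bruteforce(vertices: list, edge_list: list) -> dict:
    """Unnormalised betweenness by explicit enumeration of all shortest
    paths between all vertex pairs (endpoints excluded)."""
    adj = defaultdict(set)
    for u, v in edge_list:
        adj[u].add(v)
        adj[v].add(u)

    def shortest_paths(s, t):
        # BFS distances from s, then DFS along decreasing distance to t
        dist = {s: 0}
        frontier = [s]
        while frontier:
            nxt = []
            for u in frontier:
                for w in adj[u]:
                    if w not in dist:
                        dist[w] = dist[u] + 1
                        nxt.append(w)
            frontier = nxt
        if t not in dist:
            return []
        paths = []

        def walk(u, acc):
            if u == s:
                paths.append(list(reversed(acc + [s])))
                return
            for w in adj[u]:
                if dist.get(w, -1) == dist[u] - 1:
                    walk(w, acc + [u])

        walk(t, [])
        return paths

    bc = {v: 0.0 for v in vertices}
    for s, t in itertools.combinations(vertices, 2):
        paths = shortest_paths(s, t)
        if not paths:
            continue
        for p in paths:
            for interior in p[1:-1]:
                bc[interior] += 1.0 / len(paths)
    return bc


def random_graph(rng: np.random.Generator, max_nodes: int = 8):
    n = int(rng.integers(2, max_nodes + 1))
    vertices = [f"v{i}" for i in range(n)]
    p = float(rng.uniform(0.15, 0.7))
    edges = [(vertices[i], vertices[j])
             for i, j in itertools.combinations(range(n), 2)
             if rng.random() < p]
    return vertices, edges


# ---------------------------------------------------------------------------
# Benjamini-Hochberg step-up from its definition
# ---------------------------------------------------------------------------

def bh_bruteforce(pvals) -> np.ndarray:
    p = np.asarray(pvals, dtype=float)
    n = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(n)
    running = 1.0
    for rank in range(n - 1, -1, -1):
        i = order[rank]
        running = min(running, p[i] * n / (rank + 1))
        adj[i] = running
    return adj


# ---------------------------------------------------------------------------
# GSZ permutation null
# ---------------------------------------------------------------------------

def gsz_permutation_z(scores: np.ndarray, k: int, t_obs: float,
                      n_draws: int = 100_000, seed: int = 0) -> float:
    """z-score of an observed set sum against sums of random k-subsets."""
    rng = np.random.default_rng(seed)
    N = len(scores)
    sums = np.empty(n_draws)
    batch = 10_000
    done = 0
    while done < n_draws:
        b = min(batch, n_draws - done)
        keys = rng.random((b, N))
        idx = np.argpartition(keys, k, axis=1)[:, :k]
        sums[done:done + b] = scores[idx].sum(axis=1)
        done += b
    return (t_obs - sums.mean()) / sums.std()
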