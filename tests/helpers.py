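"""Independent oracles used by the test suite.

The reachability oracle classifies bow-tie roles straight from the set
definitions using a BFS all-pairs reachability matrix; it shares no code
with the package's decomposition.
"""

from __future__ import annotations

import networkx as nx
import numpy as np


def reachability_matrix(g: nx.DiGraph, nodes: list) -> np.ndarray:
    """R[i, j] = 1 iff j is reachable from i (trivial self-path included)."""
    n = len(nodes)
    idx = {v: i for i, v in enumerate(nodes)}
    r = np.eye(n, dtype=bool)
    for v in nodes:
        stack = [v]
        seen = {v}
        while stack:
            u = stack.pop()
            for w in g.successors(u):
                if w not in seen:
                    seen.add(w)
                    stack.append(w)
        for w in seen:
            r[idx[v], idx[w]] = True
    return r


def oracle_decompose(g: nx.DiGraph) -> dict:
    """Literal bow-tie classification from the definitions.

    Strongly connected components are the equivalence classes of mutual
    reachability; the largest one (ties broken by the lexicographically
    smallest node id, matching the library contract) is the SCC.
    """
    nodes = sorted(g.nodes, key=str)
    idx = {v: i for i, v in enumerate(nodes)}
    r = reachability_matrix(g, nodes)

    unassigned = set(nodes)
    sccs = []
    while unassigned:
        v = next(iter(unassigned))
        i = idx[v]
        comp = {
            w for w in unassigned if r[i, idx[w]] and r[idx[w], i]
        }
        sccs.append(comp)
        unassigned -= comp
    s = min(sccs, key=lambda c: (-len(c), min(str(v) for v in c)))

    def reach_from_set(t: set, v) -> bool:
        return any(r[idx[w], idx[v]] for w in t)

    def set_reach_from(v, t: set) -> bool:
        return any(r[idx[v], idx[w]] for w in t)

    role = {}
    in_ = {
        v for v in nodes if v not in s and set_reach_from(v, s)
    }
    out = {
        v for v in nodes if v not in s and reach_from_set(s, v)
    }
    for v in nodes:
        if v in s:
            role[v] = "SCC"
        elif v in in_ and v in out:
            # cannot happen: v would be mutually reachable with s
            raise AssertionError("IN/OUT overlap")
        elif v in in_:
            role[v] = "IN"
        elif v in out:
            role[v] = "OUT"
        else:
            from_in = reach_from_set(in_, v)
            to_out = set_reach_from(v, out)
            if from_in and to_out:
                role[v] = "TUBES"
            elif from_in:
                role[v] = "INTENDRILS"
            elif to_out:
                role[v] = "OUTTENDRILS"
            else:
                role[v] = "OTHERS"
    return role


def random_digraph(rng: np.random.Generator, n_max: int = 60) -> nx.DiGraph:
    """Random digraph in the regime used for oracle-equivalence checks."""
    n = int(rng.integers(2, n_max + 1))
    p = float(rng.uniform(0.05, 0.3))
    g = nx.DiGraph()
    g.add_nodes_from(f"v{i:03d}" for i in range(n))
    nodes = list(g.nodes)
    mask = rng.random((n, n)) < p
    for i in range(n):
        for j in range(n):
            if i != j and mask[i, j]:
                g.add_edge(nodes[i], nodes[j])
    return g
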