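"""Bow-tie decomposition of directed graphs, whole-graph and recursive.

The bow-tie view of a directed graph singles out its largest strongly
connected component (SCC) and classifies every other node by how it is
connected to it:

* ``SCC`` — the largest strongly connected component;
* ``IN`` — nodes outside the SCC from which the SCC is reachable
  ("listeners": their recommendations point, possibly indirectly, at the
  core);
* ``OUT`` — nodes outside the SCC reachable from it ("creators": the core
  points at them);
* ``TUBES`` — on IN-to-OUT paths that bypass the SCC;
* ``INTENDRILS`` — reachable from IN but not reaching OUT;
* ``OUTTENDRILS`` — reaching OUT but not reachable from IN;
* ``OTHERS`` — everything else.

These seven sets are mutually disjoint and cover the node set, so the
assignment is a hard partition.  The *recursive* decomposition applies the
same classification independently inside each community of a node
partition, discarding inter-community edges, which exposes the local role
a page plays inside its own discursive community.
"""

from __future__ import annotations

import logging
import random as _random
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import igraph as ig
import networkx as nx

from .network import SnapshotNetwork, WEIGHT_FLOOR

logger = logging.getLogger(__name__)

ROLES = (
    "SCC",
    "IN",
    "OUT",
    "TUBES",
    "INTENDRILS",
    "OUTTENDRILS",
    "OTHERS",
)
REDUCED_ROLES = ("SCC", "IN", "OUT", "NA")

#: reserved community label for nodes in communities below the size cutoff
UNASSIGNED = "UNASSIGNED"


@dataclass
class BowTieAssignment:
    """A hard assignment of nodes to bow-tie roles.

    ``role`` maps every node to one of the seven roles (or to
    ``UNASSIGNED`` in recursive scope, for nodes whose community was too
    small to decompose).  ``partition_id`` is present in recursive scope.
    """

    role: dict
    scope: str  # "whole-graph" | "recursive"
    partition_id: dict | None = None

    def role_sets(self) -> dict:
        sets: dict = {r: set() for r in ROLES}
        sets[UNASSIGNED] = set()
        for n, r in self.role.items():
            sets[r].add(n)
        return sets


@dataclass
class NodePartition:
    """A hard partition of the node set into communities."""

    community: dict
    origin: str  # "polarity" | "detected"

    def groups(self) -> dict:
        out: dict = {}
        for n, c in self.community.items():
            out.setdefault(c, set()).add(n)
        return out


def _as_graph(net) -> nx.DiGraph:
    return net.graph if isinstance(net, SnapshotNetwork) else net


def _largest_scc(g: nx.DiGraph) -> set:
    """Largest strongly connected component, ties broken deterministically.

    When several components share the maximal size, the one containing the
    lexicographically smallest node id (string order) is chosen, so the
    decomposition is reproducible on graphs without a unique giant SCC.
    """
    best = None
    best_key = None
    for comp in nx.strongly_connected_components(g):
        key = (-len(comp), min(str(n) for n in comp))
        if best is None or key < best_key:
            best, best_key = comp, key
    return set(best)


def decompose(net) -> BowTieAssignment:
    """Whole-graph bow-tie decomposition.

    Accepts a :class:`~bowtienet.network.SnapshotNetwork` or a bare
    :class:`networkx.DiGraph`; edge weights are ignored, only presence
    matters.  Raises on an empty graph.
    """
    g = _as_graph(net)
    if g.number_of_nodes() == 0:
        raise ValueError("cannot decompose an empty graph")

    s = _largest_scc(g)
    anchor = next(iter(s))
    # descendants/ancestors of the SCC: reachability from/to any member
    reach_from_s = nx.descendants(g, anchor) | s
    reach_to_s = nx.ancestors(g, anchor) | s
    out = reach_from_s - s
    in_ = reach_to_s - s

    rest = set(g.nodes) - s - in_ - out
    # multi-source reachability for the periphery classification;
    # "reachable from IN" includes IN itself (trivial self-path)
    from_in = set(in_)
    for n in in_:
        from_in |= nx.descendants(g, n)
    to_out = set(out)
    rev = g.reverse(copy=False)
    for n in out:
        to_out |= nx.descendants(rev, n)

    role = {}
    for n in g.nodes:
        if n in s:
            role[n] = "SCC"
        elif n in in_:
            role[n] = "IN"
        elif n in out:
            role[n] = "OUT"
        elif n in from_in and n in to_out:
            role[n] = "TUBES"
        elif n in from_in:
            role[n] = "INTENDRILS"
        elif n in to_out:
            role[n] = "OUTTENDRILS"
        else:
            role[n] = "OTHERS"
    return BowTieAssignment(role=role, scope="whole-graph")


def recursive_decompose(net, partition: NodePartition) -> BowTieAssignment:
    """Bow-tie decomposition applied independently inside each community.

    Each community's node-induced subgraph is decomposed on its own;
    edges that cross communities are disregarded.  Nodes in communities
    labelled :data:`UNASSIGNED` are excluded from decomposition and keep
    the sentinel role ``UNASSIGNED`` (reduced to ``NA``).
    """
    g = _as_graph(net)
    missing = set(g.nodes) - set(partition.community)
    if missing:
        raise ValueError(
            f"partition does not cover {len(missing)} nodes, "
            f"e.g. {sorted(missing, key=str)[:5]}"
        )
    role: dict = {}
    for label, members in partition.groups().items():
        if label == UNASSIGNED:
            for n in members:
                role[n] = UNASSIGNED
            continue
        if not members:
            logger.warning("skipping empty community %r", label)
            continue
        sub = g.subgraph(members)
        for n, r in decompose(sub).role.items():
            role[n] = r
    return BowTieAssignment(
        role=role, scope="recursive", partition_id=dict(partition.community)
    )


def polarity_partition(net: SnapshotNetwork) -> NodePartition:
    """Partition by vaccination stance (anti / pro / neutral)."""
    return NodePartition(community=dict(net.polarity), origin="polarity")


def detect_communities(
    net: SnapshotNetwork,
    seed: int,
    min_size: int = 5,
    trials: int = 10,
) -> NodePartition:
    """Flow-based (map equation) community detection with a size cutoff.

    Runs Infomap — random walks on the weighted directed graph, minimising
    the Shannon-entropy description length of the walk — via igraph, with
    a seeded RNG so the partition is reproducible.  Zero-weight edges are
    floored at a small positive value because the method needs positive
    flow.  Communities with fewer than ``min_size`` nodes are relabelled
    :data:`UNASSIGNED`.

    ``trials`` is the number of Infomap attempts from which the best
    (shortest description length) partition is kept; the two-level map
    equation is used.
    """
    g = net.positive_weight_graph()
    nodes = list(g.nodes)
    index = {n: i for i, n in enumerate(nodes)}
    edges = [(index[u], index[v]) for u, v in g.edges]
    weights = [g.edges[u, v]["weight"] for u, v in g.edges]
    igg = ig.Graph(n=len(nodes), edges=edges, directed=True)

    ig.set_random_number_generator(_random.Random(int(seed)))
    try:
        clustering = igg.community_infomap(
            edge_weights=weights, trials=trials
        )
    finally:
        ig.set_random_number_generator(_random)

    community = {}
    sizes: dict[int, int] = {}
    for i, c in enumerate(clustering.membership):
        sizes[c] = sizes.get(c, 0) + 1
    for i, c in enumerate(clustering.membership):
        label = f"C{c}" if sizes[c] >= min_size else UNASSIGNED
        community[nodes[i]] = label
    n_small = sum(1 for v in community.values() if v == UNASSIGNED)
    if n_small:
        logger.info(
            "%d nodes in communities smaller than %d relabelled %s",
            n_small, min_size, UNASSIGNED,
        )
    return NodePartition(community=community, origin="detected")


def reduce_roles(assignment: BowTieAssignment) -> dict:
    """Collapse the seven roles to the four-role view {SCC, IN, OUT, NA}.

    The main components keep their labels; TUBES, INTENDRILS,
    OUTTENDRILS, OTHERS and UNASSIGNED nodes all become ``NA``.
    """
    keep = {"SCC", "IN", "OUT"}
    return {
        n: (r if r in keep else "NA") for n, r in assignment.role.items()
    }


def role_stability(
    roles_t1: Mapping,
    roles_t2: Mapping,
    subset: Sequence,
) -> float:
    """Percentage of pages in ``subset`` keeping the same role at both times."""
    subset = list(subset)
    if not subset:
        raise ValueError("role stability is undefined on an empty subset")
    same = sum(1 for n in subset if roles_t1[n] == roles_t2[n])
    return 100.0 * same / len(subset)


def transition_counts(
    roles_t1: Mapping, roles_t2: Mapping, subset: Sequence
) -> dict:
    """Role-transition count matrix (early role, late role) -> count."""
    counts: dict = {}
    for n in subset:
        key = (roles_t1[n], roles_t2[n])
        counts[key] = counts.get(key, 0) + 1
    return counts
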