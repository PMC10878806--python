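"""Two-snapshot directed recommendation networks with node metadata.

A snapshot is a directed graph whose nodes are pages carrying a vaccination
polarity (``"r"`` anti, ``"b"`` pro, ``"g"`` neutral) and a fan count, and
whose edges mean "the source page recommends the target page to all its
members".  Edge *presence* is the authoritative datum; the edge *weight* is
a derived quantity, the product of the two endpoint fan counts at the
snapshot ("product kernel").  Because zero-fan pages exist, a present edge
may legitimately have weight 0, so presence and weight are stored
separately.

Snapshots are cumulative: every recommendation present in the early
snapshot is still present in the late one.  :func:`validate_temporal`
enforces this.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import pandas as pd

logger = logging.getLogger(__name__)

POLARITIES = ("r", "b", "g")  # anti, pro, neutral

#: minimal strictly positive weight substituted for zero-weight edges in
#: algorithms that require positive flow (community detection, shortest
#: paths on 1/weight distances)
WEIGHT_FLOOR = 1e-9


class NetworkFormatError(ValueError):
    """Raised when input files violate the snapshot data model."""


@dataclass
class SnapshotNetwork:
    """A single snapshot of the recommendation network.

    Parameters
    ----------
    label:
        Snapshot identifier, e.g. ``"feb"`` or ``"oct"``.
    graph:
        Directed simple graph (self-loops allowed, no parallel edges).
        Node attributes: ``polarity`` in ``{"r","b","g"}``, ``fans`` a
        non-negative integer.  Edge attribute ``weight`` is maintained by
        :meth:`refresh_weights`.
    """

    label: str
    graph: nx.DiGraph

    def __post_init__(self) -> None:
        self.validate()
        self.refresh_weights()

    # -- accessors -----------------------------------------------------
    @property
    def nodes(self) -> list:
        return list(self.graph.nodes)

    @property
    def edges(self) -> list[tuple]:
        return list(self.graph.edges)

    @property
    def polarity(self) -> dict:
        return nx.get_node_attributes(self.graph, "polarity")

    @property
    def fan_count(self) -> dict:
        return nx.get_node_attributes(self.graph, "fans")

    def weight(self, u, v) -> float:
        return self.graph.edges[u, v]["weight"]

    def number_of_nodes(self) -> int:
        return self.graph.number_of_nodes()

    def number_of_edges(self) -> int:
        return self.graph.number_of_edges()

    # -- maintenance ---------------------------------------------------
    def validate(self) -> None:
        fans = nx.get_node_attributes(self.graph, "fans")
        pols = nx.get_node_attributes(self.graph, "polarity")
        for n in self.graph.nodes:
            if n not in pols:
                raise NetworkFormatError(f"node {n!r} has no polarity")
            if pols[n] not in POLARITIES:
                raise NetworkFormatError(
                    f"node {n!r} has unknown polarity {pols[n]!r}; "
                    f"expected one of {POLARITIES}"
                )
            if n not in fans:
                raise NetworkFormatError(f"node {n!r} has no fan count")
            if fans[n] < 0 or int(fans[n]) != fans[n]:
                raise NetworkFormatError(
                    f"node {n!r} has invalid fan count {fans[n]!r}"
                )

    def refresh_weights(self) -> None:
        """Recompute every edge weight as the product of endpoint fans."""
        fans = self.fan_count
        for u, v in self.graph.edges:
            self.graph.edges[u, v]["weight"] = fans[u] * fans[v]

    def positive_weight_graph(self) -> nx.DiGraph:
        """Copy of the graph with zero weights floored at ``WEIGHT_FLOOR``.

        Used by algorithms that require strictly positive flow; the stored
        snapshot is never modified.
        """
        g = self.graph.copy()
        for u, v, w in g.edges(data="weight"):
            if w <= 0:
                g.edges[u, v]["weight"] = WEIGHT_FLOOR
        return g


@dataclass
class TemporalPair:
    """An (early, late) pair of snapshots over the same page set."""

    early: SnapshotNetwork
    late: SnapshotNetwork


@dataclass
class DescriptiveStats:
    """Summary statistics of a snapshot used for dataset validation."""

    snapshot_label: str
    n_nodes: int
    n_edges: int
    reciprocity_pct: float
    selfloop_pct: float
    n_zero_fan: int
    lwcc_node_share: float
    lwcc_edge_share: float
    nodes_per_polarity: dict
    fans_per_polarity: dict
    edges_within_across: dict      # (pol_u, pol_v) -> edge count
    mean_weight_within_across: dict  # (pol_u, pol_v) -> mean edge weight
    degenerate: bool = field(default=False)

    def as_dict(self) -> dict:
        return {
            "snapshot": self.snapshot_label,
            "n_nodes": self.n_nodes,
            "n_edges": self.n_edges,
            "reciprocity_pct": self.reciprocity_pct,
            "selfloop_pct": self.selfloop_pct,
            "n_zero_fan": self.n_zero_fan,
            "lwcc_node_share": self.lwcc_node_share,
            "lwcc_edge_share": self.lwcc_edge_share,
            "nodes_per_polarity": dict(self.nodes_per_polarity),
            "fans_per_polarity": dict(self.fans_per_polarity),
            "degenerate": self.degenerate,
        }


# ---------------------------------------------------------------------
# loading / writing
# ---------------------------------------------------------------------

def _build_snapshot(
    label: str,
    node_rows: Iterable[tuple],
    edge_rows: Iterable[tuple],
) -> SnapshotNetwork:
    g = nx.DiGraph()
    for node, pol, fans in node_rows:
        if pol not in POLARITIES:
            raise NetworkFormatError(
                f"unknown polarity code {pol!r} for node {node!r}"
            )
        if fans < 0:
            raise NetworkFormatError(f"negative fan count for node {node!r}")
        g.add_node(node, polarity=pol, fans=int(fans))

    seen = set()
    n_dup = 0
    for u, v in edge_rows:
        if u not in g or v not in g:
            raise NetworkFormatError(
                f"edge ({u!r}, {v!r}) references an undeclared node"
            )
        if (u, v) in seen:
            n_dup += 1
            continue
        seen.add((u, v))
        g.add_edge(u, v)
    if n_dup:
        logger.warning(
            "%d duplicate edge rows collapsed in snapshot %s", n_dup, label
        )
    return SnapshotNetwork(label=label, graph=g)


def load_snapshot(
    edge_path: str | Path,
    node_path: str | Path,
    snapshot_label: str,
) -> SnapshotNetwork:
    """Load a snapshot from CSV files.

    The node file must have columns ``id``, ``polarity`` and a fan-count
    column ``fan_<label>`` (falling back to a plain ``fans`` column); the
    edge file must have columns ``source``, ``target``.  Duplicate edge
    rows are collapsed with a logged warning; unknown polarity codes,
    negative fan counts and edges touching undeclared nodes are rejected.
    """
    nodes = pd.read_csv(node_path, dtype={"id": str})
    edges = pd.read_csv(edge_path, dtype=str)
    fan_col = f"fan_{snapshot_label}"
    if fan_col not in nodes.columns:
        if "fans" in nodes.columns:
            fan_col = "fans"
        else:
            raise NetworkFormatError(
                f"node file lacks a '{fan_col}' (or 'fans') column"
            )
    for col in ("id", "polarity"):
        if col not in nodes.columns:
            raise NetworkFormatError(f"node file lacks a '{col}' column")
    for col in ("source", "target"):
        if col not in edges.columns:
            raise NetworkFormatError(f"edge file lacks a '{col}' column")
    node_rows = list(
        zip(nodes["id"], nodes["polarity"], nodes[fan_col].astype(int))
    )
    edge_rows = list(zip(edges["source"], edges["target"]))
    return _build_snapshot(snapshot_label, node_rows, edge_rows)


def write_snapshot(
    net: SnapshotNetwork,
    edge_path: str | Path,
    node_path: str | Path,
) -> None:
    """Write a snapshot in the same CSV dialect :func:`load_snapshot` reads."""
    fans = net.fan_count
    pols = net.polarity
    pd.DataFrame(
        {
            "id": net.nodes,
            "polarity": [pols[n] for n in net.nodes],
            f"fan_{net.label}": [fans[n] for n in net.nodes],
        }
    ).to_csv(node_path, index=False)
    pd.DataFrame(net.edges, columns=["source", "target"]).to_csv(
        edge_path, index=False
    )


def write_pair(pair: TemporalPair, directory: str | Path) -> dict[str, Path]:
    """Write both snapshots of a pair into ``directory``.

    The node table carries one fan column per snapshot; each snapshot gets
    its own edge file.  Returns the paths written, keyed by role.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    early, late = pair.early, pair.late
    fans_e, fans_l = early.fan_count, late.fan_count
    pols = early.polarity
    node_path = directory / "nodes.csv"
    pd.DataFrame(
        {
            "id": early.nodes,
            "polarity": [pols[n] for n in early.nodes],
            f"fan_{early.label}": [fans_e[n] for n in early.nodes],
            f"fan_{late.label}": [fans_l[n] for n in early.nodes],
        }
    ).to_csv(node_path, index=False)
    paths = {"nodes": node_path}
    for net in (early, late):
        p = directory / f"edges_{net.label}.csv"
        pd.DataFrame(net.edges, columns=["source", "target"]).to_csv(
            p, index=False
        )
        paths[f"edges_{net.label}"] = p
    return paths


def load_pair(
    directory: str | Path,
    early_label: str = "feb",
    late_label: str = "oct",
) -> TemporalPair:
    """Load and validate a pair written by :func:`write_pair`."""
    directory = Path(directory)
    early = load_snapshot(
        directory / f"edges_{early_label}.csv",
        directory / "nodes.csv",
        early_label,
    )
    late = load_snapshot(
        directory / f"edges_{late_label}.csv",
        directory / "nodes.csv",
        late_label,
    )
    return validate_temporal(early, late)


# ---------------------------------------------------------------------
# statistics and temporal validation
# ---------------------------------------------------------------------

def descriptive_stats(net: SnapshotNetwork) -> DescriptiveStats:
    """Summary statistics of one snapshot.

    Reciprocity is the percentage of all edges (self-loops included in the
    denominator, never counted as mutual) whose reverse edge is also
    present; the self-loop percentage uses the same denominator.  Largest
    weakly-connected-component shares ignore edge direction.
    """
    g = net.graph
    m = g.number_of_edges()
    degenerate = m == 0
    if degenerate:
        recip = selfloop = 0.0
        lwcc_nodes = lwcc_edges = 0.0
        if g.number_of_nodes():
            lwcc_nodes = max(
                (len(c) for c in nx.weakly_connected_components(g)),
                default=0,
            ) / g.number_of_nodes()
    else:
        mutual = sum(
            1 for u, v in g.edges if u != v and g.has_edge(v, u)
        )
        loops = sum(1 for u, v in g.edges if u == v)
        recip = 100.0 * mutual / m
        selfloop = 100.0 * loops / m
        wccs = list(nx.weakly_connected_components(g))
        giant = max(wccs, key=len)
        lwcc_nodes = len(giant) / g.number_of_nodes()
        lwcc_edges = (
            g.subgraph(giant).number_of_edges() / m
        )

    pols = net.polarity
    fans = net.fan_count
    nodes_per = {p: 0 for p in POLARITIES}
    fans_per = {p: 0 for p in POLARITIES}
    for n in g.nodes:
        nodes_per[pols[n]] += 1
        fans_per[pols[n]] += fans[n]

    edge_counts: dict[tuple, int] = {}
    weight_sums: dict[tuple, float] = {}
    for u, v, w in g.edges(data="weight"):
        key = (pols[u], pols[v])
        edge_counts[key] = edge_counts.get(key, 0) + 1
        weight_sums[key] = weight_sums.get(key, 0.0) + w
    mean_weights = {
        k: weight_sums[k] / edge_counts[k] for k in edge_counts
    }

    return DescriptiveStats(
        snapshot_label=net.label,
        n_nodes=g.number_of_nodes(),
        n_edges=m,
        reciprocity_pct=recip,
        selfloop_pct=selfloop,
        n_zero_fan=sum(1 for n in g.nodes if fans[n] == 0),
        lwcc_node_share=lwcc_nodes,
        lwcc_edge_share=lwcc_edges,
        nodes_per_polarity=nodes_per,
        fans_per_polarity=fans_per,
        edges_within_across=edge_counts,
        mean_weight_within_across=mean_weights,
        degenerate=degenerate,
    )


def validate_temporal(
    early: SnapshotNetwork, late: SnapshotNetwork
) -> TemporalPair:
    """Check the cumulative-edge contract and return the validated pair.

    Node sets and polarities must be identical, and every early edge must
    still be present in the late snapshot (recommendations accumulate).
    """
    if set(early.nodes) != set(late.nodes):
        raise NetworkFormatError(
            "node sets differ between snapshots "
            f"({early.label} vs {late.label})"
        )
    pe, pl = early.polarity, late.polarity
    mismatched = [n for n in early.nodes if pe[n] != pl[n]]
    if mismatched:
        raise NetworkFormatError(
            f"polarity changed across snapshots for nodes {mismatched[:5]}"
        )
    missing = sorted(
        set(early.graph.edges) - set(late.graph.edges), key=str
    )
    if missing:
        raise NetworkFormatError(
            f"{len(missing)} early edges absent from the late snapshot, "
            f"e.g. {missing[:5]}"
        )
    return TemporalPair(early=early, late=late)
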