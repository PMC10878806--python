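"""Synthetic two-snapshot recommendation networks with planted structure.

The generator emulates the statistical features the analysis pipeline
relies on, so every stage can be exercised end-to-end without external
data:

* three polarity groups whose *within-group* subgraphs carry planted
  bow-tie roles — the anti group OUT-heavy, the pro group SCC-heavy, the
  neutral group dominated by OTHERS;
* heavy-tailed (log-normal) fan counts with a few injected "mega" pages
  in the pro group and a handful of zero-fan pages;
* sparse inter-group edges, with anti-pro contact near zero and moderate
  traffic between each stance and the neutral group;
* target edge reciprocity reached by adding reverse inter-group edges
  (intra-group plants are never touched, so planted roles stay exact);
* rare self-loops;
* a cumulative late snapshot (early edges plus a fraction of new ones);
* a fan-count-change model ``df = a*f*s + b*k_in + eps`` in which a
  target fraction of non-neutral pages expands and the change magnitude
  scales with the initial fan count (the "snowball" pattern).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .network import SnapshotNetwork, TemporalPair, validate_temporal

ROLE_ORDER = (
    "SCC",
    "IN",
    "OUT",
    "TUBES",
    "INTENDRILS",
    "OUTTENDRILS",
    "OTHERS",
)

DEFAULT_GROUP_SIZES = {"r": 317, "b": 124, "g": 885}

DEFAULT_ROLE_MIX = {
    # anti: information-creator heavy (large OUT)
    "r": {
        "SCC": 0.18, "IN": 0.12, "OUT": 0.40, "TUBES": 0.03,
        "INTENDRILS": 0.07, "OUTTENDRILS": 0.08, "OTHERS": 0.12,
    },
    # pro: information-magnifier heavy (large SCC)
    "b": {
        "SCC": 0.42, "IN": 0.12, "OUT": 0.18, "TUBES": 0.02,
        "INTENDRILS": 0.06, "OUTTENDRILS": 0.06, "OTHERS": 0.14,
    },
    # neutral: weakly engaged within-group (large OTHERS)
    "g": {
        "SCC": 0.10, "IN": 0.08, "OUT": 0.12, "TUBES": 0.02,
        "INTENDRILS": 0.05, "OUTTENDRILS": 0.05, "OTHERS": 0.58,
    },
}

# directed inter-group edge counts as a fraction of the source group size;
# anti<->pro traffic is near zero, each stance talks to the neutral group
DEFAULT_INTERGROUP_RATES = {
    ("r", "g"): 0.50, ("g", "r"): 0.40,
    ("b", "g"): 0.60, ("g", "b"): 0.40,
    ("r", "b"): 0.01, ("b", "r"): 0.01,
}


@dataclass
class FanLaw:
    """Log-normal fan-count law with optional mega-page injection."""

    mu: float = 7.0          # location of log fans
    sigma: float = 1.6       # scale of log fans
    n_mega: int = 3          # pages forced above mega_floor (pro group)
    mega_floor: int = 1_000_000
    n_zero: int = 4          # pages forced to zero fans


@dataclass
class ExpansionModel:
    """Fan-count-change law ``df = a*f*s + b*k_in + eps``.

    ``s`` is +1 with probability ``q`` (the page expands) and -1
    otherwise.  The two sides are deliberately asymmetric, mirroring the
    asymmetry between growth and decline of page audiences: gains follow
    the recommendation structure (``a*f + b*k_in`` plus additive noise of
    standard deviation ``noise_scale * (f + 50)``), while losses are
    smaller (scaled by ``shrink``) and multiplicatively jittered by a
    log-normal factor of log-scale ``loss_jitter`` — fan loss is driven
    largely by exogenous factors, so it is much harder to predict from
    the network than fan gain.  Loss-side changes are clamped at zero so
    a shrinking page never ends up counted as expanding.  All changes are
    rounded to integers and fan counts never go negative.
    """

    a: float = 0.35
    b: float = 2e-7
    q: float = 0.73
    shrink: float = 0.35
    noise_scale: float = 0.05
    loss_jitter: float = 0.75


@dataclass
class SyntheticSpec:
    """Full parameterization of one synthetic study dataset."""

    group_sizes: dict = field(
        default_factory=lambda: dict(DEFAULT_GROUP_SIZES)
    )
    role_mix: dict = field(
        default_factory=lambda: {
            k: dict(v) for k, v in DEFAULT_ROLE_MIX.items()
        }
    )
    fan_law: FanLaw = field(default_factory=FanLaw)
    expansion: ExpansionModel = field(default_factory=ExpansionModel)
    intergroup_rates: dict = field(
        default_factory=lambda: dict(DEFAULT_INTERGROUP_RATES)
    )
    reciprocity_target: float = 0.085
    selfloop_rate: float = 0.0015
    new_edge_fraction: float = 0.45
    #: share of late new edges arriving as mutual pairs, so reciprocity
    #: rises slightly between snapshots instead of being diluted
    new_mutual_fraction: float = 0.06
    scc_extra_arcs_per_node: float = 1.5
    rng_seed: int | None = None

    def __post_init__(self) -> None:
        for pol, mix in self.role_mix.items():
            total = sum(mix.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(
                    f"role mix for {pol!r} sums to {total}, expected 1"
                )
        if not (0.0 < self.expansion.q < 1.0):
            raise ValueError("expanding fraction q must lie in (0, 1)")
        if not (0.0 <= self.reciprocity_target <= 1.0):
            raise ValueError("reciprocity target must lie in [0, 1]")


@dataclass
class GroundTruth:
    """What the generator planted, for downstream recovery checks."""

    planted_role: dict          # node -> within-group bow-tie role
    group: dict                 # node -> polarity group
    s_sign: dict                # node -> +1/-1 expansion sign
    params: dict                # generator coefficients
    realized: dict              # realized reciprocity, expanding share, ...


# ---------------------------------------------------------------------
# planting one bow-tie
# ---------------------------------------------------------------------

def _round_counts(mix: dict, total: int) -> dict:
    """Largest-remainder rounding of a role mix to integer counts."""
    raw = {r: mix.get(r, 0.0) * total for r in ROLE_ORDER}
    counts = {r: int(math.floor(v)) for r, v in raw.items()}
    short = total - sum(counts.values())
    for r in sorted(ROLE_ORDER, key=lambda r: raw[r] - counts[r],
                    reverse=True)[:short]:
        counts[r] += 1
    return counts


def plant_bowtie(
    component_sizes: dict,
    rng: np.random.Generator,
    prefix: str = "n",
    extra_arcs_per_node: float = 1.5,
) -> tuple[nx.DiGraph, dict]:
    """Construct a digraph whose bow-tie decomposition is known exactly.

    The SCC is a directed Hamiltonian cycle plus random chords; every IN
    node sends at least one arc toward the SCC (never receives one from
    it), every OUT node receives at least one, TUBES sit on IN-to-OUT
    paths bypassing the SCC, INTENDRILS hang off IN, OUTTENDRILS feed
    OUT, and OTHERS are isolated.  Node ids are assigned in role order
    (SCC first) so the deterministic largest-SCC tie-break always selects
    the planted core, even for a size-1 SCC.

    Returns the graph and the planted ``node -> role`` map.
    """
    sizes = {r: int(component_sizes.get(r, 0)) for r in ROLE_ORDER}
    if sizes["SCC"] < 1:
        raise ValueError("the planted SCC needs at least one node")
    if sizes["TUBES"] > 0 and (sizes["IN"] == 0 or sizes["OUT"] == 0):
        raise ValueError("TUBES require both IN and OUT to be non-empty")
    if sizes["INTENDRILS"] > 0 and sizes["IN"] == 0:
        raise ValueError("INTENDRILS require a non-empty IN")
    if sizes["OUTTENDRILS"] > 0 and sizes["OUT"] == 0:
        raise ValueError("OUTTENDRILS require a non-empty OUT")

    total = sum(sizes.values())
    width = max(4, len(str(total)))
    role: dict = {}
    members: dict = {}
    counter = 0
    for r in ROLE_ORDER:
        members[r] = []
        for _ in range(sizes[r]):
            node = f"{prefix}{counter:0{width}d}"
            role[node] = r
            members[r].append(node)
            counter += 1

    g = nx.DiGraph()
    g.add_nodes_from(role)
    scc = members["SCC"]
    if len(scc) == 1:
        g.add_edge(scc[0], scc[0])  # self-loop keeps the core non-trivial
    else:
        for i, u in enumerate(scc):
            g.add_edge(u, scc[(i + 1) % len(scc)])
        n_extra = int(round(extra_arcs_per_node * len(scc)))
        for _ in range(n_extra):
            u, v = rng.choice(len(scc), size=2, replace=False)
            g.add_edge(scc[u], scc[v])

    def pick(pool: list) -> str:
        return pool[int(rng.integers(len(pool)))]

    # IN: arcs toward the core; optional forward DAG arcs among IN nodes
    for i, u in enumerate(members["IN"]):
        g.add_edge(u, pick(scc))
        if i > 0 and rng.random() < 0.3:
            g.add_edge(u, members["IN"][int(rng.integers(i))])
    # OUT: arcs from the core; optional DAG arcs among OUT nodes
    for i, v in enumerate(members["OUT"]):
        g.add_edge(pick(scc), v)
        if i > 0 and rng.random() < 0.3:
            g.add_edge(members["OUT"][int(rng.integers(i))], v)
    # TUBES: one arc in from IN, one arc out to OUT, bypassing the core
    for t in members["TUBES"]:
        g.add_edge(pick(members["IN"]), t)
        g.add_edge(t, pick(members["OUT"]))
    # INTENDRILS: fed by IN, lead nowhere
    for t in members["INTENDRILS"]:
        g.add_edge(pick(members["IN"]), t)
    # OUTTENDRILS: feed OUT, fed by nobody
    for t in members["OUTTENDRILS"]:
        g.add_edge(t, pick(members["OUT"]))
    # OTHERS: isolated
    return g, role


# ---------------------------------------------------------------------
# assembling the full dataset
# ---------------------------------------------------------------------

def _add_intergroup_edges(
    g: nx.DiGraph, groups: dict, rates: dict, rng: np.random.Generator
) -> None:
    for (src_pol, dst_pol), rate in rates.items():
        src = groups.get(src_pol, [])
        dst = groups.get(dst_pol, [])
        if not src or not dst:
            continue
        n_edges = int(round(rate * len(src)))
        for _ in range(n_edges):
            u = src[int(rng.integers(len(src)))]
            v = dst[int(rng.integers(len(dst)))]
            if u != v and not g.has_edge(u, v):
                g.add_edge(u, v, intergroup=True)


def _tune_reciprocity(
    g: nx.DiGraph, target: float, rng: np.random.Generator
) -> float:
    """Add reverse inter-group edges until reciprocity reaches ``target``.

    Only edges marked inter-group are mirrored, so the planted intra-group
    structure is untouched.  Returns the realized reciprocity (fraction,
    not percent); if the pool of one-way inter-group edges runs out the
    result is best-effort.
    """
    def mutual_count() -> int:
        return sum(
            1 for u, v in g.edges if u != v and g.has_edge(v, u)
        )

    candidates = [
        (u, v) for u, v, d in g.edges(data=True)
        if d.get("intergroup") and not g.has_edge(v, u)
    ]
    order = rng.permutation(len(candidates))
    m = mutual_count()
    for k in order:
        if m / g.number_of_edges() >= target:
            break
        u, v = candidates[k]
        if not g.has_edge(v, u):
            g.add_edge(v, u, intergroup=True)
            m += 2
    return m / g.number_of_edges()


def _draw_fans(
    nodes: list, groups: dict, law: FanLaw, rng: np.random.Generator
) -> dict:
    fans = {
        n: int(round(v))
        for n, v in zip(
            nodes, np.exp(rng.normal(law.mu, law.sigma, size=len(nodes)))
        )
    }
    pro = groups.get("b", [])
    mega = rng.choice(len(pro), size=min(law.n_mega, len(pro)),
                      replace=False) if pro else []
    mega_nodes = {pro[int(i)] for i in mega}
    for n in mega_nodes:
        fans[n] = int(law.mega_floor * (1.0 + rng.random()))
    eligible = [n for n in nodes if n not in mega_nodes]
    for i in rng.choice(len(eligible), size=min(law.n_zero, len(eligible)),
                        replace=False):
        fans[eligible[int(i)]] = 0
    return fans


def _weighted_in_degree(g: nx.DiGraph, fans: dict) -> dict:
    k_in = {n: 0.0 for n in g.nodes}
    for u, v in g.edges:
        k_in[v] += fans[u] * fans[v]
    return k_in


def generate_dataset(spec: SyntheticSpec) -> tuple[TemporalPair, GroundTruth]:
    """Generate a two-snapshot dataset plus its ground truth.

    All randomness flows from ``spec.rng_seed``; per-stage substreams are
    split off deterministically.
    """
    streams = np.random.SeedSequence(spec.rng_seed).spawn(6)
    rng_plant, rng_inter, rng_fans, rng_exp, rng_late, rng_misc = (
        np.random.default_rng(s) for s in streams
    )

    g = nx.DiGraph()
    planted_role: dict = {}
    group: dict = {}
    groups: dict = {}
    for pol, size in spec.group_sizes.items():
        if size <= 0:
            continue
        counts = _round_counts(spec.role_mix[pol], size)
        sub, roles = plant_bowtie(
            counts, rng_plant, prefix=pol,
            extra_arcs_per_node=spec.scc_extra_arcs_per_node,
        )
        g = nx.union(g, sub)
        planted_role.update(roles)
        for n in roles:
            group[n] = pol
        groups[pol] = list(roles)

    _add_intergroup_edges(g, groups, spec.intergroup_rates, rng_inter)
    realized_recip = _tune_reciprocity(
        g, spec.reciprocity_target, rng_inter
    )

    nodes = list(g.nodes)
    n_loops = int(round(spec.selfloop_rate * g.number_of_edges()))
    for i in rng_misc.choice(len(nodes), size=n_loops, replace=False):
        g.add_edge(nodes[int(i)], nodes[int(i)])

    fans_early = _draw_fans(nodes, groups, spec.fan_law, rng_fans)

    # fan-count changes: df = a*f*s + b*k_in + eps, integer, f stays >= 0
    em = spec.expansion
    k_in = _weighted_in_degree(g, fans_early)
    s_sign: dict = {}
    fans_late: dict = {}
    for n in nodes:
        s = 1 if rng_exp.random() < em.q else -1
        s_sign[n] = s
        f = fans_early[n]
        eps = rng_exp.normal(0.0, em.noise_scale * (f + 50.0))
        if s > 0:
            df = em.a * f + em.b * k_in[n] + eps
        else:
            jitter = math.exp(rng_exp.normal(0.0, em.loss_jitter))
            df = min(0.0, -em.shrink * em.a * f * jitter
                     + em.b * k_in[n] + eps)
        df = max(int(round(df)), -f)
        fans_late[n] = f + df

    # cumulative late snapshot: early edges plus a fraction of new ones
    late_g = g.copy()
    n_new = int(round(spec.new_edge_fraction * g.number_of_edges()))
    pols = list(groups)
    added = 0
    while added < n_new:
        roll = rng_late.random()
        if roll < 0.6:  # within-group
            pol = pols[int(rng_late.integers(len(pols)))]
            pool_u = pool_v = groups[pol]
        elif roll < 0.9:  # stance <-> neutral
            pol = "r" if rng_late.random() < 0.5 else "b"
            if rng_late.random() < 0.5:
                pool_u, pool_v = groups.get(pol, []), groups.get("g", [])
            else:
                pool_u, pool_v = groups.get("g", []), groups.get(pol, [])
        else:  # anti <-> pro pick up late in the period
            pool_u = groups.get("r", [])
            pool_v = groups.get("b", [])
            if rng_late.random() < 0.5:
                pool_u, pool_v = pool_v, pool_u
        if not pool_u or not pool_v:
            continue
        u = pool_u[int(rng_late.integers(len(pool_u)))]
        v = pool_v[int(rng_late.integers(len(pool_v)))]
        if u != v and not late_g.has_edge(u, v):
            late_g.add_edge(u, v)
            added += 1
            if (added < n_new
                    and not late_g.has_edge(v, u)
                    and rng_late.random() < spec.new_mutual_fraction):
                late_g.add_edge(v, u)
                added += 1

    def snapshot(label: str, graph: nx.DiGraph, fans: dict) -> SnapshotNetwork:
        h = nx.DiGraph()
        for n in graph.nodes:
            h.add_node(n, polarity=group[n], fans=fans[n])
        h.add_edges_from((u, v) for u, v in graph.edges)
        return SnapshotNetwork(label=label, graph=h)

    early = snapshot("feb", g, fans_early)
    late = snapshot("oct", late_g, fans_late)
    pair = validate_temporal(early, late)

    non_neutral = [n for n in nodes if group[n] != "g"]
    expanding = sum(
        1 for n in non_neutral if fans_late[n] > fans_early[n]
    )
    truth = GroundTruth(
        planted_role=planted_role,
        group=group,
        s_sign=s_sign,
        params={
            "a": em.a, "b": em.b, "q": em.q,
            "shrink": em.shrink, "noise_scale": em.noise_scale,
        },
        realized={
            "reciprocity": realized_recip,
            "expanding_fraction": expanding / len(non_neutral)
            if non_neutral else float("nan"),
            "n_nodes": len(nodes),
            "n_edges_early": early.number_of_edges(),
            "n_edges_late": late.number_of_edges(),
        },
    )
    return pair, truth


# ---------------------------------------------------------------------
# the worked 12-node toy
# ---------------------------------------------------------------------

#: hand-classified whole-graph bow-tie roles of the early toy snapshot
TOY_ROLES_EARLY = {
    "a": "SCC", "b": "SCC", "c": "SCC",
    "d": "IN", "e": "IN",
    "f": "OUT", "g": "OUT",
    "h": "TUBES",
    "i": "INTENDRILS",
    "j": "OUTTENDRILS",
    "k": "OTHERS", "l": "OTHERS",
}

_TOY_NODES = {
    # id: (polarity, fans_feb, fans_oct)
    "a": ("b", 100, 150),
    "b": ("b", 50, 60),
    "c": ("b", 80, 80),
    "d": ("r", 10, 8),
    "e": ("r", 0, 2),
    "f": ("r", 200, 260),
    "g": ("r", 30, 45),
    "h": ("g", 5, 5),
    "i": ("r", 7, 10),
    "j": ("b", 12, 12),
    "k": ("g", 3, 4),
    "l": ("g", 9, 9),
}

_TOY_EDGES_EARLY = [
    ("a", "b"), ("b", "c"), ("c", "a"), ("b", "a"),
    ("d", "a"), ("e", "d"),
    ("a", "f"), ("f", "g"),
    ("d", "h"), ("h", "g"),
    ("e", "i"),
    ("j", "f"),
    ("k", "l"), ("l", "l"),
]

_TOY_EDGES_LATE = _TOY_EDGES_EARLY + [("g", "c"), ("i", "e"), ("k", "a")]


def worked_toy() -> TemporalPair:
    """Deterministic 12-node fixture exercising all seven bow-tie roles.

    The early snapshot decomposes into SCC {a,b,c}, IN {d,e}, OUT {f,g},
    TUBES {h}, INTENDRILS {i}, OUTTENDRILS {j} and OTHERS {k,l}
    (:data:`TOY_ROLES_EARLY`); it has one mutual pair (a,b) and one
    self-loop (l,l).  The late snapshot adds three edges, one of which
    (g -> c) pulls the OUT pages into the core.
    """
    def build(label: str, edges, fan_idx: int) -> SnapshotNetwork:
        g = nx.DiGraph()
        for n, (pol, f_feb, f_oct) in _TOY_NODES.items():
            g.add_node(n, polarity=pol,
                       fans=f_feb if fan_idx == 0 else f_oct)
        g.add_edges_from(edges)
        return SnapshotNetwork(label=label, graph=g)

    return validate_temporal(
        build("feb", _TOY_EDGES_EARLY, 0),
        build("oct", _TOY_EDGES_LATE, 1),
    )
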