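"""Agent-based SIR information cascades on the recommendation network.

A recommendation edge u -> v means page u recommends page v; the *content*
therefore travelled from v to u.  Cascades consequently spread along
reversed edges by default: an infectious page passes the information to
its susceptible in-neighbours, each with probability ``beta`` per step
(independent Bernoulli contacts), and recovers with probability ``gamma``
after its transmission attempts in that step.  The dynamics are
synchronous and terminate when no infectious page remains; every page
that was ever infected ends recovered, so the impacted set of a piece of
information is the set of ever-infected pages.

Influence accounting follows the seed's stance: a piece seeded at an
anti- or pro- page accrues *within-group* influence from impacted pages
of the same polarity (the seed included) and *across-group* influence
from impacted neutral pages.  Impacted pages of the opposite non-neutral
polarity transmit onward but contribute to neither tally.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .network import SnapshotNetwork

logger = logging.getLogger(__name__)

MAIN_COMPONENTS = ("SCC", "OUT", "IN")


@dataclass
class CascadeConfig:
    """Ensemble parameters for :func:`simulate_ensemble`.

    ``initializer_weights`` maps each reduced bow-tie role to a strictly
    positive weight; each eligible (anti- or pro-) page gets its role's
    weight and the resulting distribution over pages is the seed law
    P_initializer.
    """

    beta: float
    gamma: float
    n_pieces: int
    initializer_weights: Mapping[str, float] = field(
        default_factory=lambda: {"SCC": 1.0, "IN": 1.0, "OUT": 1.0, "NA": 1.0}
    )
    rng_seed: int | None = None

    def __post_init__(self) -> None:
        _check_rates(self.beta, self.gamma)
        if any(w <= 0 for w in self.initializer_weights.values()):
            raise ValueError("initializer weights must be strictly positive")


@dataclass
class CascadeResult:
    """Per-piece and per-page influence tallies of one ensemble run."""

    seeds: list
    impacted: list  # list of frozenset, aligned with seeds
    info_w: np.ndarray
    info_a: np.ndarray
    page_w: dict
    page_a: dict


def _check_rates(beta: float, gamma: float) -> None:
    if not (0.0 <= beta <= 1.0):
        raise ValueError(f"beta must lie in [0, 1], got {beta}")
    if not (0.0 < gamma <= 1.0):
        raise ValueError(
            f"gamma must lie in (0, 1], got {gamma} "
            "(gamma = 0 risks non-termination)"
        )


class _Simulator:
    """CSR transmission structure reused across many cascades."""

    def __init__(self, net: SnapshotNetwork, direction: str = "reverse"):
        if direction not in ("reverse", "forward"):
            raise ValueError("direction must be 'reverse' or 'forward'")
        g = net.graph
        self.nodes = list(g.nodes)
        self.index = {n: i for i, n in enumerate(self.nodes)}
        n = len(self.nodes)
        # contacts[i] = pages that i transmits to; reverse direction means
        # i transmits to its in-neighbours in the recommendation graph
        lists: list[list[int]] = [[] for _ in range(n)]
        for u, v in g.edges:
            if u == v:
                continue  # a page cannot re-expose itself
            iu, iv = self.index[u], self.index[v]
            if direction == "reverse":
                lists[iv].append(iu)
            else:
                lists[iu].append(iv)
        self.indptr = np.zeros(n + 1, dtype=np.int64)
        for i, lst in enumerate(lists):
            self.indptr[i + 1] = self.indptr[i] + len(lst)
        self.indices = np.fromiter(
            (j for lst in lists for j in lst),
            dtype=np.int64,
            count=int(self.indptr[-1]),
        )

    def run(
        self, seed_idx: int, beta: float, gamma: float,
        rng: np.random.Generator,
    ) -> np.ndarray:
        """One cascade; returns the ever-infected node indices."""
        infected = np.zeros(len(self.nodes), dtype=bool)
        infected[seed_idx] = True
        frontier = np.array([seed_idx], dtype=np.int64)
        infectious = frontier
        while infectious.size:
            # transmission from every infectious page, synchronous
            if beta > 0:
                chunks = [
                    self.indices[self.indptr[i]: self.indptr[i + 1]]
                    for i in infectious
                ]
                contacts = (
                    np.concatenate(chunks) if chunks else
                    np.empty(0, dtype=np.int64)
                )
                if contacts.size:
                    if beta >= 1.0:
                        hit = contacts
                    else:
                        hit = contacts[
                            rng.random(contacts.size) < beta
                        ]
                    hit = hit[~infected[hit]]
                    if hit.size:
                        hit = np.unique(hit)
                        infected[hit] = True
                        new = hit
                    else:
                        new = np.empty(0, dtype=np.int64)
                else:
                    new = np.empty(0, dtype=np.int64)
            else:
                new = np.empty(0, dtype=np.int64)
            # recovery after this step's transmission attempts
            if gamma >= 1.0:
                survivors = np.empty(0, dtype=np.int64)
            else:
                survivors = infectious[
                    rng.random(infectious.size) >= gamma
                ]
            infectious = np.concatenate([survivors, new])
        return np.flatnonzero(infected)


def run_cascade(
    net: SnapshotNetwork,
    seed_page,
    beta: float,
    gamma: float,
    rng: np.random.Generator | int | None = None,
    direction: str = "reverse",
) -> frozenset:
    """Simulate one information piece seeded at ``seed_page``.

    Returns the impacted set: every page that entered the infectious
    state (all are recovered by termination).
    """
    _check_rates(beta, gamma)
    sim = _Simulator(net, direction=direction)
    if seed_page not in sim.index:
        raise ValueError(f"seed page {seed_page!r} not in the network")
    rng = np.random.default_rng(rng) if not isinstance(
        rng, np.random.Generator
    ) else rng
    idx = sim.run(sim.index[seed_page], beta, gamma, rng)
    return frozenset(sim.nodes[i] for i in idx)


def info_influence(
    impacted: Sequence,
    seed_polarity: str,
    polarity: Mapping,
    fan_count: Mapping,
) -> tuple[float, float]:
    """Within- and across-group influence of one information piece.

    ``W`` sums fan counts of impacted pages sharing the seed's stance
    (the seed itself included); ``A`` sums fan counts of impacted neutral
    pages.  Impacted pages of the opposite non-neutral stance count
    towards neither — their exclusion is accounting only, they still
    spread the piece.
    """
    if seed_polarity not in ("r", "b"):
        raise ValueError("influence is defined for anti/pro seeds only")
    w = sum(
        fan_count[j] for j in impacted if polarity[j] == seed_polarity
    )
    a = sum(fan_count[j] for j in impacted if polarity[j] == "g")
    return float(w), float(a)


def _eligible_pool(net: SnapshotNetwork) -> list:
    pols = net.polarity
    return [n for n in net.nodes if pols[n] in ("r", "b")]


def simulate_ensemble(
    net: SnapshotNetwork,
    roles: Mapping,
    config: CascadeConfig,
    direction: str = "reverse",
    include_seed: bool = True,
) -> CascadeResult:
    """Run ``config.n_pieces`` cascades with role-weighted seed choice.

    Per-page influences are the sums of the piece influences over the
    pieces seeded at that page, so summed over pages they equal the sums
    over pieces exactly.  ``include_seed=False`` drops the seed's own fan
    count from its pieces' within-group influence.
    """
    pool = _eligible_pool(net)
    if not pool:
        raise ValueError("no anti- or pro- pages to seed from")
    rng = np.random.default_rng(config.rng_seed)
    weights = np.array(
        [config.initializer_weights[roles[n]] for n in pool], dtype=float
    )
    p_init = weights / weights.sum()
    sim = _Simulator(net, direction=direction)
    pols = net.polarity
    fans = net.fan_count

    seed_draws = rng.choice(len(pool), size=config.n_pieces, p=p_init)
    seeds, impacted_sets = [], []
    info_w = np.empty(config.n_pieces)
    info_a = np.empty(config.n_pieces)
    page_w = {n: 0.0 for n in pool}
    page_a = {n: 0.0 for n in pool}
    for k, si in enumerate(seed_draws):
        seed = pool[si]
        idx = sim.run(sim.index[seed], config.beta, config.gamma, rng)
        imp = frozenset(sim.nodes[i] for i in idx)
        w, a = info_influence(imp, pols[seed], pols, fans)
        if not include_seed:
            w -= fans[seed]
        seeds.append(seed)
        impacted_sets.append(imp)
        info_w[k] = w
        info_a[k] = a
        page_w[seed] += w
        page_a[seed] += a
    return CascadeResult(
        seeds=seeds,
        impacted=impacted_sets,
        info_w=info_w,
        info_a=info_a,
        page_w=page_w,
        page_a=page_a,
    )


def component_influence_distributions(
    net: SnapshotNetwork,
    roles: Mapping,
    beta: float = 0.5,
    gamma: float = 0.3,
    pieces_per_component: int = 1000,
    seed: int | None = None,
    components: Sequence[str] = MAIN_COMPONENTS,
    direction: str = "reverse",
) -> dict:
    """Influence distributions of pieces seeded in each main component.

    For each reduced role in ``components``, ``pieces_per_component``
    cascades are seeded uniformly over the anti-/pro- pages holding that
    role; returns ``{role: {"W": samples, "A": samples}}``.  Empty
    components are skipped with a warning.
    """
    _check_rates(beta, gamma)
    rng = np.random.default_rng(seed)
    pols = net.polarity
    fans = net.fan_count
    sim = _Simulator(net, direction=direction)
    out: dict = {}
    for comp in components:
        members = [
            n for n in net.nodes
            if roles[n] == comp and pols[n] in ("r", "b")
        ]
        if not members:
            logger.warning("component %s has no eligible pages; skipped", comp)
            continue
        w_samples = np.empty(pieces_per_component)
        a_samples = np.empty(pieces_per_component)
        draws = rng.integers(len(members), size=pieces_per_component)
        for k, mi in enumerate(draws):
            s = members[mi]
            idx = sim.run(sim.index[s], beta, gamma, rng)
            imp = [sim.nodes[i] for i in idx]
            w_samples[k], a_samples[k] = info_influence(
                imp, pols[s], pols, fans
            )
        out[comp] = {"W": w_samples, "A": a_samples}
    return out


def initializer_sweep(
    net: SnapshotNetwork,
    roles: Mapping,
    axis_x: str,
    axis_y: str,
    delta_f: Mapping,
    grid: Sequence[float] | None = None,
    n_pieces: int = 3000,
    beta: float = 0.5,
    gamma: float = 0.3,
    stratum: str = "expanding",
    seed: int | None = None,
    direction: str = "reverse",
) -> list[dict]:
    """Correlation between page influence and fan-count change, per seed law.

    For each grid cell ``(x, y)`` the pages of the ``axis_x`` role get
    seeding weight ``x``, the ``axis_y`` role ``y`` and every other
    eligible page weight 1; one ensemble of ``n_pieces`` cascades is run
    and the Pearson correlation between per-page influence (both the
    within- and across-group variant) and the fan-count change ``delta_f``
    is computed over the chosen page stratum.  Returns long-format rows
    ``{"x", "y", "variant", "stratum", "cc", "n_pages"}``.
    """
    if axis_x == axis_y:
        raise ValueError("axis roles must be distinct")
    for r in (axis_x, axis_y):
        if r not in MAIN_COMPONENTS:
            raise ValueError(f"axis role {r!r} not one of {MAIN_COMPONENTS}")
    if grid is None:
        grid = np.geomspace(0.1, 10.0, 7)
    if any(w <= 0 for w in grid):
        raise ValueError("grid weights must be strictly positive")
    if stratum not in ("all", "expanding", "non-expanding"):
        raise ValueError(f"unknown stratum {stratum!r}")

    rng = np.random.default_rng(seed)
    pool = _eligible_pool(net)
    if stratum == "all":
        strat_pages = pool
    elif stratum == "expanding":
        strat_pages = [n for n in pool if delta_f[n] > 0]
    else:
        strat_pages = [n for n in pool if delta_f[n] <= 0]
    df = np.array([delta_f[n] for n in strat_pages], dtype=float)

    rows = []
    for x in grid:
        for y in grid:
            weights = {"SCC": 1.0, "IN": 1.0, "OUT": 1.0, "NA": 1.0}
            weights[axis_x] = float(x)
            weights[axis_y] = float(y)
            cfg = CascadeConfig(
                beta=beta,
                gamma=gamma,
                n_pieces=n_pieces,
                initializer_weights=weights,
                rng_seed=int(rng.integers(2**31 - 1)),
            )
            res = simulate_ensemble(net, roles, cfg, direction=direction)
            for variant, per_page in (("W", res.page_w), ("A", res.page_a)):
                infl = np.array(
                    [per_page[n] for n in strat_pages], dtype=float
                )
                if infl.std() == 0 or df.std() == 0:
                    cc = 0.0
                else:
                    cc = float(stats.pearsonr(infl, df).statistic)
                rows.append(
                    {
                        "x": float(x),
                        "y": float(y),
                        "variant": variant,
                        "stratum": stratum,
                        "cc": cc,
                        "n_pages": len(strat_pages),
                    }
                )
    return rows
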