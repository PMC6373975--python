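"""Constrained permutation null model for per-taxon transfer excess.

The question "does this host order show more transfers than expected?"
cannot be answered from raw counts: orders differ in sample size, in how
many of their species carry the TE superfamily at all, and in phylogenetic
structure.  The null model therefore relabels the *observed* network of
species sharing horizontally transferred TEs: a uniform bijection maps its
nodes onto a random same-size subset of the carrier species (species
carrying at least one family of the superfamily).  This preserves the
degree distribution and the network topology exactly, while destroying any
association with particular taxa.

Relabelings are rejected while any edge lands on a *forbidden* pair — a
pair that could never have been detected in the real data because no
reference dS distribution exists at or below its MRCA.  When rejection
stalls (dense networks), each forbidden edge is instead replaced by an edge
between a random authorized, previously unconnected node pair: the total
number of links is preserved at the cost of a slightly different topology.

Each simulated network is analyzed exactly like the observed one (minimal
event counting, scenario endpoint sampling, per-order aggregation).
Because phylogenetically clustered observed networks concentrate links
below few nodes, simulations tend to infer *more* events than observed;
per-simulation totals are therefore rescaled multiplicatively to match the
observed total before envelope quantiles are computed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

from .events import FamilyEventCount, ScenarioSet, minimal_events, sample_scenarios
from .reference import HTNetwork, ReferencePanel, eligible_reference_nodes, match_reference
from .tree import HostTree

__all__ = [
    "RepairRequired",
    "SimulationError",
    "NullComparison",
    "compute_forbidden_pairs",
    "network_event_counts",
    "permute_network",
    "repair_forbidden",
    "simulate_null",
    "distance_profile",
]

RETRY_CAP = 1000


class RepairRequired(RuntimeError):
    """Rejection sampling exhausted its retry cap; switch to repair mode."""


class SimulationError(RuntimeError):
    """No authorized replacement exists for a forbidden edge."""


def compute_forbidden_pairs(
    tree: HostTree,
    panel: ReferencePanel,
    species: Iterable[str],
) -> frozenset[tuple[str, str]]:
    """Unordered species pairs with no usable reference node (untestable in
    the real data, hence forbidden in simulated networks)."""
    eligible = eligible_reference_nodes(tree) & panel.nodes
    sp = sorted(set(species))
    forbidden = set()
    for i, a in enumerate(sp):
        for b in sp[i + 1 :]:
            if match_reference(tree, a, b, eligible) is None:
                forbidden.add((a, b))
    return frozenset(forbidden)


def network_event_counts(
    network: HTNetwork, tree: HostTree
) -> list[FamilyEventCount]:
    """Minimal events per family of a (possibly relabeled) network.

    Each family's events are counted on the subtree induced by the species
    its links touch; event nodes are identical to those obtained from the
    full occurrence subtree, because an event node is always the MRCA of at
    least one link.
    """
    out: list[FamilyEventCount] = []
    for fam, edges in network.families_edges().items():
        species = sorted({s for e in edges for s in e})
        if len(species) < 2:
            continue
        sub = tree.extract_subtree(species)
        out.append(minimal_events(sub, edges, family_id=fam))
    return out


def _relabel(
    network: HTNetwork,
    carriers: list[str],
    rng: np.random.Generator,
) -> tuple[HTNetwork, dict[str, str]]:
    nodes = list(network.species)
    picks = rng.choice(len(carriers), size=len(nodes), replace=False)
    mapping = {n: carriers[int(k)] for n, k in zip(nodes, picks)}
    return network.copy_relabeled(mapping), mapping


def permute_network(
    network: HTNetwork,
    carriers: Iterable[str],
    forbidden: frozenset[tuple[str, str]],
    seed: int | np.random.SeedSequence = 0,
    retry_cap: int = RETRY_CAP,
) -> HTNetwork:
    """Uniform degree-preserving relabeling onto the carrier species,
    rejection-sampled until no edge is forbidden.

    Raises :class:`RepairRequired` when ``retry_cap`` consecutive draws all
    contain a forbidden edge; dense networks are then handled by
    :func:`repair_forbidden`.
    """
    carrier_list = sorted(set(carriers))
    missing = set(network.species) - set(carrier_list)
    if missing:
        raise ValueError(f"network nodes not in carrier set: {sorted(missing)}")
    rng = np.random.default_rng(seed)
    if len(network) == 0:
        return HTNetwork(network.superfamily)
    for _ in range(retry_cap):
        candidate, _mapping = _relabel(network, carrier_list, rng)
        if not any(e in forbidden for e in candidate.edges):
            return candidate
    raise RepairRequired(
        f"{network.superfamily}: no forbidden-free relabeling in "
        f"{retry_cap} attempts"
    )


def repair_forbidden(
    network: HTNetwork,
    carriers: Iterable[str],
    forbidden: frozenset[tuple[str, str]],
    seed: int | np.random.SeedSequence = 0,
) -> HTNetwork:
    """Replace each forbidden edge by a random authorized edge between
    previously unconnected node pairs of the network.

    Replacements are drawn sequentially, with connectivity updated after
    every replacement, so the total edge count is preserved exactly while
    the topology may change slightly.  The replacement edge inherits the
    family annotation of the edge it replaces.
    """
    rng = np.random.default_rng(seed)
    out = HTNetwork(network.superfamily)
    out.graph = network.graph.copy()
    nodes = list(out.species)
    bad = [e for e in out.edges if e in forbidden]
    for edge in bad:
        families = out.graph.edges[edge]["families"]
        out.graph.remove_edge(*edge)
        candidates = [
            (a, b)
            for i, a in enumerate(nodes)
            for b in nodes[i + 1 :]
            if (a, b) not in forbidden and not out.graph.has_edge(a, b)
        ]
        if not candidates:
            raise SimulationError(
                f"{network.superfamily}: no authorized replacement for "
                f"forbidden link {edge}"
            )
        a, b = candidates[int(rng.integers(len(candidates)))]
        out.graph.add_edge(a, b, families=set(families))
    return out


@dataclass
class NullComparison:
    """Observed per-order endpoint counts against the simulated envelope."""

    superfamily: str
    table: pd.DataFrame  # order, observed, sim_mean, q025, q975, flag
    normalization: np.ndarray  # per-simulation factor obs_total / sim_total
    observed_total: int
    observed_scenarios: ScenarioSet
    sim_scenarios: list[ScenarioSet] = field(default_factory=list, repr=False)
    sim_networks: list[HTNetwork] = field(default_factory=list, repr=False)
    n_repaired: int = 0

    def flagged_high(self) -> tuple[str, ...]:
        t = self.table
        return tuple(t.loc[t["flag"] == "high", "order"])


def simulate_null(
    observed: HTNetwork,
    tree: HostTree,
    carriers: Iterable[str],
    forbidden: frozenset[tuple[str, str]],
    n_sims: int = 1000,
    seed: int | np.random.SeedSequence = 0,
    n_scenarios: int = 1000,
    n_scenarios_per_sim: int = 100,
    retry_cap: int = RETRY_CAP,
    keep_networks: bool = False,
) -> NullComparison:
    """Full null comparison for one superfamily.

    For every simulation a relabeled network is produced (rejection first,
    repair fallback), events are re-counted per family, endpoints are
    re-assigned by scenario sampling, and per-order endpoint counts are
    rescaled so that the simulation's event total matches the observed
    total.  The per-order 2.5% and 97.5% quantiles over simulations form
    the envelope; observed counts outside it are flagged.

    One master seed spawns an independent child stream per simulation, so
    simulation *i* depends only on child seed *i* regardless of execution
    order or thread count.
    """
    master = (
        seed
        if isinstance(seed, np.random.SeedSequence)
        else np.random.SeedSequence(seed)
    )
    obs_seed, *sim_seeds = master.spawn(n_sims + 1)
    obs_counts = network_event_counts(observed, tree)
    obs_total = sum(c.minimal_events for c in obs_counts)
    obs_scen = sample_scenarios(
        obs_counts, tree, n_scenarios=n_scenarios, seed=obs_seed,
        keep_scenarios=False,
    )

    orders = list(tree.order_labels) or ["unassigned"]
    sim_matrix = np.zeros((n_sims, len(orders)))
    factors = np.ones(n_sims)
    sim_sets: list[ScenarioSet] = []
    sim_nets: list[HTNetwork] = []
    n_repaired = 0
    for i in range(n_sims):
        perm_seed, repair_seed, scen_seed = sim_seeds[i].spawn(3)
        try:
            net = permute_network(
                observed, carriers, forbidden, seed=perm_seed, retry_cap=retry_cap
            )
        except RepairRequired:
            net = permute_network(
                observed, carriers, frozenset(), seed=repair_seed, retry_cap=1
            )
            net = repair_forbidden(net, carriers, forbidden, seed=repair_seed)
            n_repaired += 1
        counts = network_event_counts(net, tree)
        total = sum(c.minimal_events for c in counts)
        scen = sample_scenarios(
            counts, tree, n_scenarios=n_scenarios_per_sim, seed=scen_seed,
            keep_scenarios=False,
        )
        factors[i] = obs_total / total if total else 1.0
        sim_matrix[i] = [scen.order_mean.get(o, 0.0) * factors[i] for o in orders]
        sim_sets.append(scen)
        if keep_networks:
            sim_nets.append(net)

    rows = []
    for j, order in enumerate(orders):
        observed_count = obs_scen.order_mean.get(order, 0.0)
        q025, q975 = np.quantile(sim_matrix[:, j], [0.025, 0.975])
        flag = ""
        if observed_count > q975:
            flag = "high"
        elif observed_count < q025:
            flag = "low"
        rows.append(
            {
                "order": order,
                "observed": observed_count,
                "sim_mean": float(sim_matrix[:, j].mean()),
                "q025": float(q025),
                "q975": float(q975),
                "flag": flag,
            }
        )
    return NullComparison(
        superfamily=observed.superfamily,
        table=pd.DataFrame(rows),
        normalization=factors,
        observed_total=obs_total,
        observed_scenarios=obs_scen,
        sim_scenarios=sim_sets,
        sim_networks=sim_nets,
        n_repaired=n_repaired,
    )


def distance_profile(
    observed: ScenarioSet,
    simulated: Iterable[ScenarioSet],
    tree: HostTree,
    window: float = 25.0,
    factors: np.ndarray | None = None,
) -> pd.DataFrame:
    """Observed vs expected event counts binned by MRCA age of the assigned
    species pair, in consecutive windows of ``window`` My.

    ``factors`` optionally rescales each simulation's counts (the same
    normalization applied in :func:`simulate_null`).  The ratio column is
    NaN where the expectation is zero.
    """
    sims = list(simulated)
    root_age = tree.age(tree.root)
    n_bins = max(int(np.ceil(root_age / window)), 1)

    def binned(scen: ScenarioSet) -> np.ndarray:
        counts = np.zeros(n_bins)
        for (a, b), mean_count in scen.pair_mean.items():
            age = tree.age(tree.mrca(a, b))
            k = min(int(age // window), n_bins - 1)
            counts[k] += mean_count
        return counts

    obs = binned(observed)
    if sims:
        f = np.ones(len(sims)) if factors is None else np.asarray(factors)
        expected = np.mean([f[i] * binned(s) for i, s in enumerate(sims)], axis=0)
    else:
        expected = np.zeros(n_bins)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(expected > 0, obs / expected, np.nan)
    return pd.DataFrame(
        {
            "window_start": np.arange(n_bins) * window,
            "window_end": (np.arange(n_bins) + 1) * window,
            "observed": obs,
            "expected": expected,
            "ratio": ratio,
        }
    )
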