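"""Minimal transfer-event counting and plausible scenario sampling.

A TE family shared horizontally among several species need not reflect one
transfer per species pair: a single ancient transfer into the ancestor of a
clade explains every link between that clade and the donor side.  The
minimal number of events for a family is counted on the subtree of the host
tree induced by the family's species: each internal node contributes one
event when at least one horizontal link crosses between two of its child
clades.  Equivalently, the event nodes are the distinct MRCAs of the
family's horizontal links — the brute-force oracle used in the tests.

Because an event at an internal node only brackets the transfer between two
ancestral lineages, the species-level attribution is not unique.  Scenario
sampling resolves each event to one concrete extant species pair, drawn
uniformly among the links crossing the event node, and repeats the draw
(1000 times by default) to obtain mean per-species endpoint counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .clustering import TEFamily
from .tree import HostTree

__all__ = [
    "FamilyEventCount",
    "Scenario",
    "ScenarioSet",
    "family_subtree",
    "minimal_events",
    "sample_scenarios",
]


@dataclass
class FamilyEventCount:
    """Minimal event count for one family, with per-node crossing links."""

    family_id: str
    event_nodes: frozenset[str]
    crossing: dict[str, list[tuple[str, str]]] = field(default_factory=dict)

    @property
    def minimal_events(self) -> int:
        return len(self.event_nodes)


@dataclass
class Scenario:
    """One concrete assignment of every event to an extant species pair."""

    index: int
    assignment: dict[tuple[str, str], tuple[str, str]]  # (family, node) -> pair
    species_counts: dict[str, int]


@dataclass
class ScenarioSet:
    """A sample of plausible event-to-species assignments for one
    superfamily, with per-species means and per-order aggregates."""

    scenarios: list[Scenario]
    species_mean: dict[str, float]
    order_mean: dict[str, float]
    order_matrix: dict[str, np.ndarray]  # order -> per-scenario counts
    pair_mean: dict[tuple[str, str], float]  # species pair -> mean assigned events
    total_events: int
    distinct_species_mean: float

    @property
    def n_scenarios(self) -> int:
        return len(self.scenarios)


def family_subtree(tree: HostTree, family: TEFamily) -> HostTree:
    """Subtree of the host tree spanned by the family's species, with
    degree-2 nodes suppressed and original node ids/ages preserved."""
    return tree.extract_subtree(family.species)


def minimal_events(
    subtree: HostTree,
    ht_edges: list[tuple[str, str]],
    family_id: str = "",
) -> FamilyEventCount:
    """Count one event per subtree node whose two (or more) child clades are
    connected by at least one horizontal link."""
    tips = set(subtree.tips)
    for a, b in ht_edges:
        if a not in tips or b not in tips:
            raise ValueError(f"link ({a}, {b}) has endpoint outside the subtree")
    crossing: dict[str, list[tuple[str, str]]] = {}
    for node in subtree.internal_nodes:
        child_sets = [subtree.subtree_tips(c) for c in subtree.children[node]]
        hits = []
        for a, b in ht_edges:
            ia = next((k for k, s in enumerate(child_sets) if a in s), None)
            ib = next((k for k, s in enumerate(child_sets) if b in s), None)
            if ia is not None and ib is not None and ia != ib:
                hits.append(tuple(sorted((a, b))))
        if hits:
            crossing[node] = sorted(set(hits))
    return FamilyEventCount(family_id, frozenset(crossing), crossing)


def sample_scenarios(
    counts: list[FamilyEventCount],
    tree: HostTree,
    n_scenarios: int = 1000,
    seed: int | np.random.SeedSequence = 0,
    keep_scenarios: bool = True,
) -> ScenarioSet:
    """Sample event-to-species assignments across all families of one
    superfamily and aggregate endpoint counts.

    Every event node independently draws one of its crossing links,
    uniformly, in each scenario; both endpoint species are credited one
    transfer.  Per-species means over scenarios and per-order sums of those
    means are returned, together with the full per-scenario per-order count
    matrix (for envelope quantiles) and, as a companion statistic, the mean
    number of distinct species involved.
    """
    rng = np.random.default_rng(seed)
    events: list[tuple[tuple[str, str], list[tuple[str, str]]]] = []
    for fec in sorted(counts, key=lambda f: f.family_id):
        for node in sorted(fec.event_nodes):
            events.append(((fec.family_id, node), fec.crossing[node]))
    total_events = len(events)

    orders = list(tree.order_labels) or ["unassigned"]
    order_idx = {o: i for i, o in enumerate(orders)}
    order_counts = np.zeros((n_scenarios, len(orders)), dtype=float)
    species_total: dict[str, float] = {}
    pair_total: dict[tuple[str, str], float] = {}
    distinct_total = 0.0
    scenarios: list[Scenario] = []
    for i in range(n_scenarios):
        assignment: dict[tuple[str, str], tuple[str, str]] = {}
        sp_counts: dict[str, int] = {}
        for key, links in events:
            pick = links[int(rng.integers(len(links)))] if len(links) > 1 else links[0]
            assignment[key] = pick
            pair_total[pick] = pair_total.get(pick, 0.0) + 1.0
            for sp in pick:
                sp_counts[sp] = sp_counts.get(sp, 0) + 1
        for sp, c in sp_counts.items():
            species_total[sp] = species_total.get(sp, 0.0) + c
            order_counts[i, order_idx.get(tree.order_of(sp), 0)] += c
        distinct_total += len(sp_counts)
        if keep_scenarios:
            scenarios.append(Scenario(i, assignment, sp_counts))

    species_mean = {sp: v / n_scenarios for sp, v in sorted(species_total.items())}
    order_mean = {o: float(order_counts[:, j].mean()) for o, j in order_idx.items()}
    order_matrix = {o: order_counts[:, j].copy() for o, j in order_idx.items()}
    pair_mean = {p: v / n_scenarios for p, v in sorted(pair_total.items())}
    return ScenarioSet(
        scenarios=scenarios,
        species_mean=species_mean,
        order_mean=order_mean,
        order_matrix=order_matrix,
        pair_mean=pair_mean,
        total_events=total_events,
        distinct_species_mean=distinct_total / n_scenarios if n_scenarios else 0.0,
    )
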