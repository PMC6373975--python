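"""Conservative dS outlier test against MRCA-matched genomic references.

For every species pair sharing a TE family, the TE dS is compared with an
empirical distribution of housekeeping-gene dS values attached to a node of
the dated host tree.  Reference distributions exist only at nodes that
separate at least two full-genome reference species; for a given pair the
node of maximal age *within the subtree rooted at their MRCA* is chosen.
That node is never older than the pair's MRCA, so the expected genomic dS
it represents is never larger than the pair's true genomic divergence —
rejecting vertical inheritance against it is conservative.  Vertical
inheritance is rejected when the TE dS falls strictly below the 5% quantile
of the matched distribution.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx

from .divergence import PairwiseDS
from .tree import HostTree, TreeError

__all__ = [
    "ReferencePanel",
    "PanelError",
    "HTLink",
    "HTNetwork",
    "DetectionSummary",
    "eligible_reference_nodes",
    "match_reference",
    "quantile_lower",
    "quantile05",
    "detect_ht_links",
]


class PanelError(ValueError):
    """Raised for empty samples or panels keyed on ineligible nodes."""


@dataclass
class ReferencePanel:
    """Per-node empirical dS samples from housekeeping-gene comparisons."""

    samples: dict[str, list[float]]
    q05: dict[str, float] = field(init=False)

    def __post_init__(self) -> None:
        for node, sample in self.samples.items():
            if not len(sample):
                raise PanelError(f"empty dS sample for node {node!r}")
        self.q05 = {n: quantile05(s) for n, s in self.samples.items()}

    @property
    def nodes(self) -> frozenset[str]:
        return frozenset(self.samples)


@dataclass(frozen=True)
class HTLink:
    """Verdict for one (family, species pair) dS comparison."""

    family_id: str
    species_a: str
    species_b: str
    te_ds: float | None
    matched_node: str | None
    q05: float | None
    verdict: str  # "horizontal" | "vertical" | "untestable"


class HTNetwork:
    """Undirected graph of species pairs sharing horizontally transferred
    TEs of one superfamily; each edge remembers its contributing families."""

    def __init__(self, superfamily: str) -> None:
        self.superfamily = superfamily
        self.graph = nx.Graph()

    def add_link(self, a: str, b: str, family_id: str) -> None:
        if a == b:
            raise ValueError(f"self-loop on species {a!r}")
        key = tuple(sorted((a, b)))
        if self.graph.has_edge(*key):
            self.graph.edges[key]["families"].add(family_id)
        else:
            self.graph.add_edge(*key, families={family_id})

    @property
    def species(self) -> tuple[str, ...]:
        return tuple(sorted(self.graph.nodes))

    @property
    def edges(self) -> list[tuple[str, str]]:
        return sorted(tuple(sorted(e)) for e in self.graph.edges)

    def edge_families(self, a: str, b: str) -> frozenset[str]:
        return frozenset(self.graph.edges[tuple(sorted((a, b)))]["families"])

    def families_edges(self) -> dict[str, list[tuple[str, str]]]:
        """family id -> the species-pair edges it contributes to."""
        out: dict[str, list[tuple[str, str]]] = {}
        for a, b in self.edges:
            for fam in self.graph.edges[(a, b)]["families"]:
                out.setdefault(fam, []).append((a, b))
        return {f: sorted(v) for f, v in sorted(out.items())}

    def degree_multiset(self) -> tuple[int, ...]:
        return tuple(sorted(d for _, d in self.graph.degree))

    def copy_relabeled(self, mapping: dict[str, str]) -> "HTNetwork":
        new = HTNetwork(self.superfamily)
        for a, b in self.edges:
            new.add_link(mapping[a], mapping[b], "_")
            new.graph.edges[tuple(sorted((mapping[a], mapping[b])))][
                "families"
            ] = set(self.graph.edges[(a, b)]["families"])
        return new

    def __len__(self) -> int:
        return self.graph.number_of_edges()


@dataclass
class DetectionSummary:
    n_pairs: int
    n_testable: int
    n_horizontal: int


def eligible_reference_nodes(tree: HostTree) -> frozenset[str]:
    """Internal nodes with reference-genome tips in >= 2 child subtrees.

    These are exactly the nodes at which a pair of reference genomes
    diverges, i.e. the nodes for which an empirical inter-genome dS
    distribution can exist.
    """
    eligible = set()
    for node in tree.internal_nodes:
        n_child_with_ref = sum(
            1
            for child in tree.children[node]
            if tree.subtree_tips(child) & tree.references
        )
        if n_child_with_ref >= 2:
            eligible.add(node)
    return frozenset(eligible)


def match_reference(
    tree: HostTree,
    species_a: str,
    species_b: str,
    eligible: frozenset[str],
) -> str | None:
    """Most conservative usable reference node for a species pair.

    Among eligible nodes inside the subtree rooted at MRCA(a, b) — the MRCA
    itself included — the one of maximal age is returned; this age can
    never exceed the MRCA's own age.  Ties prefer nodes on the a-b path,
    then the smallest node id, for determinism.  ``None`` marks the pair
    untestable (no reference distribution at or below its MRCA).
    """
    for sp in (species_a, species_b):
        if sp not in tree.tips:
            raise TreeError(f"unknown species {sp!r}")
    mrca = tree.mrca(species_a, species_b)
    in_scope = tree.subtree_tips(mrca)
    candidates = [
        n for n in eligible if n == mrca or (tree.subtree_tips(n) <= in_scope)
    ]
    if not candidates:
        return None
    on_path = tree.path_nodes(species_a, species_b)
    candidates.sort(key=lambda n: (-tree.age(n), n not in on_path, n))
    return candidates[0]


def quantile_lower(sample: list[float], q: float) -> float:
    """Lower empirical order statistic: smallest sample value v such that at
    least a fraction ``q`` of the sample is <= v.  No interpolation; this
    convention never exceeds any interpolating convention's value, keeping
    the rejection threshold conservative."""
    if not len(sample):
        raise PanelError("empty sample")
    if not 0.0 < q <= 1.0:
        raise PanelError(f"quantile level {q} outside (0, 1]")
    ordered = sorted(sample)
    idx = max(math.ceil(q * len(ordered)), 1) - 1
    return float(ordered[idx])


def quantile05(sample: list[float]) -> float:
    return quantile_lower(sample, 0.05)


def detect_ht_links(
    pairwise: list[PairwiseDS],
    tree: HostTree,
    panel: ReferencePanel,
    superfamily_of: dict[str, str],
    quantile: float = 0.05,
) -> tuple[list[HTLink], dict[str, HTNetwork], DetectionSummary]:
    """Classify every (family, species pair) dS and build per-superfamily
    networks of species sharing horizontally transferred TEs.

    Verdicts: *horizontal* iff the pair is testable and its TE dS falls
    strictly below the matched distribution's quantile; *untestable* when
    the dS is undefined (saturated) or no reference node exists at or below
    the pair's MRCA — an undefined (saturated) dS argues for, not against,
    vertical inheritance; *vertical* otherwise, including exact equality
    with the threshold ("lower than" is strict).
    """
    eligible = eligible_reference_nodes(tree) & panel.nodes
    thresholds = (
        panel.q05
        if quantile == 0.05
        else {n: quantile_lower(s, quantile) for n, s in panel.samples.items()}
    )
    links: list[HTLink] = []
    networks: dict[str, HTNetwork] = {}
    n_testable = n_horizontal = 0
    for pds in pairwise:
        node = match_reference(tree, pds.species_a, pds.species_b, eligible)
        if pds.ds is None or node is None:
            links.append(
                HTLink(pds.family_id, pds.species_a, pds.species_b,
                       pds.ds, node, thresholds.get(node) if node else None,
                       "untestable")
            )
            continue
        n_testable += 1
        q = thresholds[node]
        verdict = "horizontal" if pds.ds < q else "vertical"
        if verdict == "horizontal":
            n_horizontal += 1
            superfamily = superfamily_of[pds.family_id]
            net = networks.setdefault(superfamily, HTNetwork(superfamily))
            net.add_link(pds.species_a, pds.species_b, pds.family_id)
        links.append(
            HTLink(pds.family_id, pds.species_a, pds.species_b,
                   pds.ds, node, q, verdict)
        )
    summary = DetectionSummary(len(pairwise), n_testable, n_horizontal)
    return links, networks, summary
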