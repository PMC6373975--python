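"""Single-linkage clustering of TE sequences into families.

Two sequences of the same superfamily belong to the same family when they
are connected — directly or transitively — by pairwise hits with at least
80% nucleotide identity over at least 80% of the shorter sequence.  After
clustering, species represented by fewer than two specimens are dropped
from each family: requiring two independent specimens per species is the
contamination guard of the whole survey design.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

__all__ = [
    "SequenceRecord",
    "TEFamily",
    "InputError",
    "HIT_COLUMNS",
    "cluster_single_linkage",
    "filter_family_occurrences",
    "shared_family_pairs",
]

#: BLAST outfmt-6 leading fields with query/subject lengths appended
HIT_COLUMNS = ("qseqid", "sseqid", "pident", "length", "qlen", "slen")

MIN_SEQUENCE_LENGTH = 100


class InputError(ValueError):
    """Raised when hits reference unknown sequence ids or records clash."""


@dataclass(frozen=True)
class SequenceRecord:
    """One TE amplicon/consensus sequence with its provenance."""

    seq_id: str
    specimen: str
    species: str
    superfamily: str
    sequence: str

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class TEFamily:
    """A cross-species cluster of TE sequences.

    ``occurrence`` maps species id -> set of specimen ids in which the
    family was observed; after :func:`filter_family_occurrences` every
    species listed has at least two specimens.
    """

    family_id: str
    superfamily: str
    members: frozenset[str]
    occurrence: dict[str, set[str]] = field(default_factory=dict)

    @property
    def species(self) -> tuple[str, ...]:
        return tuple(sorted(self.occurrence))

    @property
    def n_species(self) -> int:
        return len(self.occurrence)


def _edge_passes(
    pident: float, length: float, qlen: float, slen: float,
    min_identity: float, min_overlap_frac: float,
) -> bool:
    return pident >= min_identity and length >= min_overlap_frac * min(qlen, slen)


def cluster_single_linkage(
    hits: pd.DataFrame,
    sequences: dict[str, SequenceRecord],
    min_identity: float = 80.0,
    min_overlap_frac: float = 0.80,
) -> list[TEFamily]:
    """Families as connected components of the thresholded hit graph.

    Clustering runs independently within each superfamily; a hit pairing
    sequences of different superfamilies is ignored (the all-vs-all search
    producing the hit table is run per superfamily anyway).  Singletons
    form their own family.  Thresholds are inclusive (``>=``), matching an
    "at least 80%" rule exactly at the boundary.  An asymmetric hit pair
    creates an edge when *either* direction passes: single linkage is
    symmetric even when local-alignment hits are not.

    Family ids ``<superfamily>_F<k>`` are assigned by sorting families on
    their smallest member sequence id, making output independent of hit
    row order.
    """
    known = set(sequences)
    graph: dict[str, nx.Graph] = {}
    for rec in sequences.values():
        graph.setdefault(rec.superfamily, nx.Graph()).add_node(rec.seq_id)
    if len(hits):
        for col in HIT_COLUMNS:
            if col not in hits.columns:
                raise InputError(f"hit table lacks column {col!r}")
        for q, s, pident, length, qlen, slen in hits[list(HIT_COLUMNS)].itertuples(
            index=False
        ):
            for sid in (q, s):
                if sid not in known:
                    raise InputError(f"hit references unknown sequence id {sid!r}")
            if q == s:
                continue
            if sequences[q].superfamily != sequences[s].superfamily:
                continue
            if _edge_passes(
                float(pident), float(length), float(qlen), float(slen),
                min_identity, min_overlap_frac,
            ):
                graph[sequences[q].superfamily].add_edge(q, s)

    families: list[TEFamily] = []
    for superfamily in sorted(graph):
        comps = sorted(
            (sorted(c) for c in nx.connected_components(graph[superfamily])),
            key=lambda c: c[0],
        )
        for k, comp in enumerate(comps, start=1):
            occurrence: dict[str, set[str]] = {}
            for sid in comp:
                rec = sequences[sid]
                occurrence.setdefault(rec.species, set()).add(rec.specimen)
            families.append(
                TEFamily(
                    family_id=f"{superfamily}_F{k:04d}",
                    superfamily=superfamily,
                    members=frozenset(comp),
                    occurrence=occurrence,
                )
            )
    return families


def filter_family_occurrences(
    families: list[TEFamily],
    sequences: dict[str, SequenceRecord] | None = None,
) -> list[TEFamily]:
    """Drop, within each family, species seen in fewer than two specimens.

    Member sequences of dropped species are removed with them; families
    left without any species disappear entirely.  Passing ``sequences``
    allows member pruning; without it only the occurrence maps are edited.
    """
    out: list[TEFamily] = []
    for fam in families:
        keep_species = {
            sp: specs for sp, specs in fam.occurrence.items() if len(specs) >= 2
        }
        if not keep_species:
            continue
        members = fam.members
        if sequences is not None:
            members = frozenset(
                sid for sid in fam.members if sequences[sid].species in keep_species
            )
        out.append(
            TEFamily(fam.family_id, fam.superfamily, members,
                     {sp: set(specs) for sp, specs in keep_species.items()})
        )
    return out


def shared_family_pairs(
    families: list[TEFamily],
) -> list[tuple[str, tuple[str, str]]]:
    """All (family, unordered species pair) co-occurrences.

    Families observed in a single species emit nothing; these pairs are the
    horizontal-transfer candidates fed to the dS test.
    """
    out: list[tuple[str, tuple[str, str]]] = []
    for fam in families:
        for a, b in itertools.combinations(fam.species, 2):
            out.append((fam.family_id, (a, b)))
    return out
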