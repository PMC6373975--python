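"""Synonymous divergence (dS) between TE coding sequences.

The detection of horizontal transfer rests on comparing the synonymous
divergence of a TE shared by two species with the genome-wide synonymous
divergence expected from their host split.  dS is estimated with the
Nei-Gojobori (1986) counting method:

* each codon contributes a fractional number of synonymous sites, the
  fraction of its nine possible point changes that preserve the amino acid;
* observed differences between two codons are classified by enumerating all
  orderings of the changed positions (mutational pathways), excluding
  pathways that pass through a stop codon, and averaging the synonymous /
  nonsynonymous step counts over the remaining pathways;
* the proportion of synonymous differences per synonymous site, pS = Sd/S,
  is corrected for multiple hits with the Jukes-Cantor formula
  dS = -(3/4) * ln(1 - (4/3) * pS).

The estimate is reported as *undefined* (rather than raising) when the
correction leaves its domain (pS >= 3/4, saturation) or when fewer than
``MIN_SYN_SITES`` synonymous sites are comparable — short amplicons make the
log correction unstable otherwise.

Columns containing a gap or an ambiguous base in either sequence are
skipped, as are codons that are stop codons in either sequence.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
from Bio.Data import CodonTable

__all__ = [
    "CodonAlignment",
    "PairwiseDS",
    "AlignmentError",
    "ds_ng86",
    "collapse_specimen_redundancy",
    "min_pairwise_ds",
    "MIN_SYN_SITES",
]

MIN_SYN_SITES = 10.0

#: single-linkage identity threshold used when collapsing near-identical
#: sequences from the same specimen (within-specimen PCR/sequencing copies)
COLLAPSE_IDENTITY = 0.99


class AlignmentError(ValueError):
    """Raised on frame violations or row-length mismatches."""


# ----------------------------------------------------------------------
# genetic-code tables (standard code), precomputed once
# ----------------------------------------------------------------------
_BASES = "ACGT"
_TABLE = CodonTable.unambiguous_dna_by_id[1]
_STOPS = frozenset(_TABLE.stop_codons)
_CODONS = tuple("".join(c) for c in itertools.product(_BASES, repeat=3))
_CODON_INDEX = {c: i for i, c in enumerate(_CODONS)}


def _aa(codon: str) -> str:
    return "*" if codon in _STOPS else _TABLE.forward_table[codon]


def _syn_sites(codon: str) -> float:
    """Fractional synonymous sites of one codon (changes to stops count as
    nonsynonymous, the classical NG86 convention)."""
    if codon in _STOPS:
        return 0.0
    s = 0.0
    for pos in range(3):
        for b in _BASES:
            if b == codon[pos]:
                continue
            mutant = codon[:pos] + b + codon[pos + 1 :]
            if mutant not in _STOPS and _aa(mutant) == _aa(codon):
                s += 1.0 / 3.0
    return s


def _pair_differences(c1: str, c2: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) difference counts between two codons.

    Averages over all orderings of the changed positions; pathways crossing
    a stop codon are excluded.  If every pathway crosses a stop (possible
    only for some 2-3 position differences) all pathways are used, treating
    the stop as a distinct residue.
    """
    diff = [i for i in range(3) if c1[i] != c2[i]]
    if not diff:
        return 0.0, 0.0
    paths: list[tuple[float, float]] = []
    fallback: list[tuple[float, float]] = []
    for perm in itertools.permutations(diff):
        cur = c1
        sd = nd = 0.0
        through_stop = False
        for pos in perm:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if nxt in _STOPS and nxt != c2:
                through_stop = True
            if _aa(nxt) == _aa(cur):
                sd += 1.0
            else:
                nd += 1.0
            cur = nxt
        (fallback if through_stop else paths).append((sd, nd))
    pool = paths or fallback
    sd = sum(p[0] for p in pool) / len(pool)
    nd = sum(p[1] for p in pool) / len(pool)
    return sd, nd


# dense lookup tables over codon indices, built once at import
_S_SITES = np.array([_syn_sites(c) for c in _CODONS])
_SD = np.zeros((64, 64))
for _i, _c1 in enumerate(_CODONS):
    for _j, _c2 in enumerate(_CODONS):
        _SD[_i, _j] = _pair_differences(_c1, _c2)[0]
_VALID = np.array([c not in _STOPS for c in _CODONS])


def _encode_codons(seq: str) -> np.ndarray:
    """Codon index array; -1 marks codons with gaps/ambiguity or stops."""
    n = len(seq) // 3
    out = np.full(n, -1, dtype=np.int64)
    up = seq.upper()
    for k in range(n):
        codon = up[3 * k : 3 * k + 3]
        idx = _CODON_INDEX.get(codon, -1)
        if idx >= 0 and _VALID[idx]:
            out[k] = idx
    return out


def ds_ng86(row_a: str, row_b: str) -> tuple[float | None, float]:
    """Nei-Gojobori (1986) synonymous divergence between two aligned
    coding sequences.

    Parameters
    ----------
    row_a, row_b:
        Equal-length, frame-consistent nucleotide strings (gap ``-``
        allowed; gapped or ambiguous columns are skipped codon-wise).

    Returns
    -------
    (dS, S):
        ``dS`` is ``None`` when undefined (saturation pS >= 3/4, or fewer
        than 10 comparable synonymous sites); ``S`` is the average number
        of synonymous sites actually compared.
    """
    if len(row_a) != len(row_b):
        raise AlignmentError(
            f"aligned rows differ in length ({len(row_a)} vs {len(row_b)})"
        )
    if len(row_a) % 3 != 0:
        raise AlignmentError(f"alignment length {len(row_a)} not divisible by 3")
    a = _encode_codons(row_a)
    b = _encode_codons(row_b)
    use = (a >= 0) & (b >= 0)
    if not use.any():
        return None, 0.0
    av, bv = a[use], b[use]
    s = 0.5 * (_S_SITES[av].sum() + _S_SITES[bv].sum())
    if s < MIN_SYN_SITES:
        return None, float(s)
    sd = _SD[av, bv].sum()
    ps = sd / s
    if ps >= 0.75:
        return None, float(s)
    ds = -0.75 * math.log1p(-4.0 * ps / 3.0)
    return float(ds), float(s)


# ----------------------------------------------------------------------
# alignment container and specimen-redundancy collapse
# ----------------------------------------------------------------------
@dataclass
class CodonAlignment:
    """Frame-consistent alignment of the sequences of one TE family.

    ``rows`` maps sequence id -> aligned nucleotide string; metadata map
    each sequence id to its specimen and species.
    """

    family_id: str
    rows: dict[str, str]
    specimen_of: dict[str, str]
    species_of: dict[str, str]

    def __post_init__(self) -> None:
        lengths = {len(s) for s in self.rows.values()}
        if len(lengths) > 1:
            raise AlignmentError(f"{self.family_id}: unequal row lengths {lengths}")
        if lengths and next(iter(lengths)) % 3 != 0:
            raise AlignmentError(
                f"{self.family_id}: alignment length not a codon multiple"
            )


@dataclass
class PairwiseDS:
    """Minimal dS for one (family, species pair), with provenance."""

    family_id: str
    species_a: str
    species_b: str
    ds: float | None
    n_syn_sites: float
    seq_a: str = ""
    seq_b: str = ""

    @property
    def defined(self) -> bool:
        return self.ds is not None


def _shared_identity(x: str, y: str) -> float:
    """Nucleotide identity over columns where both rows are ungapped."""
    shared = matches = 0
    for cx, cy in zip(x, y):
        if cx == "-" or cy == "-":
            continue
        shared += 1
        if cx.upper() == cy.upper():
            matches += 1
    return matches / shared if shared else 0.0


def _ungapped_len(x: str) -> int:
    return sum(1 for c in x if c != "-")


def collapse_specimen_redundancy(aln: CodonAlignment) -> CodonAlignment:
    """Collapse near-identical within-specimen copies to a single row.

    Within each specimen, rows are grouped by single linkage at >= 99%
    identity on shared columns; each group is represented by its longest
    member (ties broken by sequence id).  Rows from different specimens are
    never merged, because two specimens carrying the same sequence is the
    signal the downstream test relies on.
    """
    by_specimen: dict[str, list[str]] = {}
    for sid in sorted(aln.rows):
        by_specimen.setdefault(aln.specimen_of[sid], []).append(sid)
    kept: list[str] = []
    for ids in by_specimen.values():
        # single linkage via union-find over >=99% identity pairs
        root = {i: i for i in ids}

        def find(i: str) -> str:
            while root[i] != i:
                root[i] = root[root[i]]
                i = root[i]
            return i

        for i, j in itertools.combinations(ids, 2):
            if _shared_identity(aln.rows[i], aln.rows[j]) >= COLLAPSE_IDENTITY:
                root[find(i)] = find(j)
        groups: dict[str, list[str]] = {}
        for i in ids:
            groups.setdefault(find(i), []).append(i)
        for members in groups.values():
            members.sort(key=lambda i: (-_ungapped_len(aln.rows[i]), i))
            kept.append(members[0])
    kept.sort()
    return CodonAlignment(
        aln.family_id,
        {i: aln.rows[i] for i in kept},
        {i: aln.specimen_of[i] for i in kept},
        {i: aln.species_of[i] for i in kept},
    )


def min_pairwise_ds(
    aln: CodonAlignment,
    estimator=ds_ng86,
) -> list[PairwiseDS]:
    """Minimal defined dS over all cross-species row pairs, per species pair.

    A pair whose row comparisons are all undefined (saturated or too few
    sites) is reported with ``ds=None`` so callers can mark it untested.
    The estimator is pluggable; any callable with the ``ds_ng86`` signature
    can be swapped in.
    """
    by_species: dict[str, list[str]] = {}
    for sid in sorted(aln.rows):
        by_species.setdefault(aln.species_of[sid], []).append(sid)
    out: list[PairwiseDS] = []
    for sp_a, sp_b in itertools.combinations(sorted(by_species), 2):
        best: PairwiseDS | None = None
        undef_sites = 0.0
        for ia in by_species[sp_a]:
            for ib in by_species[sp_b]:
                ds, s = estimator(aln.rows[ia], aln.rows[ib])
                if ds is None:
                    undef_sites = max(undef_sites, s)
                    continue
                if best is None or ds < best.ds:  # type: ignore[operator]
                    best = PairwiseDS(aln.family_id, sp_a, sp_b, ds, s, ia, ib)
        if best is None:
            out.append(PairwiseDS(aln.family_id, sp_a, sp_b, None, undef_sites))
        else:
            out.append(best)
    return out
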