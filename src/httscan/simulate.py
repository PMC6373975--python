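"""Synthetic multi-species TE survey generator with known ground truth.

The generator produces every input of the analysis pipeline — a dated host
tree partitioned into taxonomic orders, per-node reference dS
distributions, TE amplicon sequences for several superfamilies, and an
all-vs-all hit table — together with a truth table recording which species
pairs share TEs vertically and which through planted horizontal transfers.

The statistical structure mirrors the assumptions of the analysis:

* the host tree is a pure-birth (Yule) tree rescaled to a chosen root age,
  with orders assigned to monophyletic clades of unequal size;
* housekeeping-gene dS samples at a node of age ``a`` are gamma distributed
  with mean ``2 * ds_rate * a`` and coefficient of variation
  ``ds_noise_cv``;
* each TE family evolves from a random in-frame ancestral sequence along
  the host subtree it occupies.  Only third positions of fourfold-
  degenerate codons change (Jukes-Cantor), so realized divergence is purely
  synonymous and directly controllable.  Each family carries a gamma rate
  multiplier with the same coefficient of variation as the reference
  panels, so that vertically inherited TE dS values are draws from the
  same distribution family as the housekeeping references — the null
  hypothesis of the dS outlier test is true by construction for vertical
  pairs;
* planted horizontal transfers copy the donor's sequence into a recipient
  species at a dS drawn uniformly from [0, 0.2 x the pair's expected
  genomic dS], far below any plausible vertical divergence; a hotspot
  order can receive an elevated share of transfer endpoints.

All randomness flows from the single integer seed in :class:`SimConfig`
through named, purpose-specific generator streams, so regenerating with
the same configuration is byte-identical.
"""

from __future__ import annotations

import itertools
import random as _random
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import Align

from .clustering import HIT_COLUMNS, SequenceRecord
from .reference import PanelError, ReferencePanel, eligible_reference_nodes, match_reference
from .tree import HostTree

__all__ = [
    "SimConfig",
    "ConfigError",
    "TruthRecord",
    "TruthTable",
    "generate_host_tree",
    "generate_reference_panel",
    "generate_te_dataset",
    "generate_hit_table",
]


class ConfigError(ValueError):
    """Raised on inconsistent simulation parameters."""


DEFAULT_SUPERFAMILIES = ("Copia", "Jockey", "Mariner")

#: codon prefixes whose third position is fourfold degenerate and whose
#: first/second-position changes are all nonsynonymous (Ala, Gly, Pro,
#: Thr, Val, Ser) — no stop codon is reachable by a third-position change
_FOURFOLD_PREFIXES = ("GC", "GG", "CC", "AC", "GT", "TC")
_BASES = "ACGT"

#: pident floor below which a pairwise hit is not reported (mimicking the
#: sparse output of a local-similarity search)
HIT_REPORT_FLOOR = 50.0


@dataclass(frozen=True)
class SimConfig:
    """All knobs of the synthetic survey.

    Ages in My, rates in substitutions per synonymous site per My.  The
    defaults describe an arthropod-like survey: a root age of 300 My, a
    synonymous clock of 0.0025 /My (root-to-root divergence 1.5), three TE
    superfamilies, and two specimens per species (the replication level the
    occurrence filter requires).
    """

    n_species: int = 60
    n_orders: int = 6
    specimens_per_species: int = 2
    n_ref_species: int = 20
    tree_age: float = 300.0
    ds_rate: float = 0.0025
    ds_noise_cv: float = 0.3
    n_families_per_superfamily: int = 30
    superfamily_labels: tuple[str, ...] = DEFAULT_SUPERFAMILIES
    p_vertical_presence: float = 0.4
    te_rate_factor: float = 1.15
    n_planted_ht: int = 0
    hotspot_order: str | None = None
    hotspot_multiplier: float = 1.0
    seed: int = 0
    panel_size: int = 1000
    n_codons: int = 150
    intra_species_ds: float = 0.002

    def __post_init__(self) -> None:
        counts = {
            "n_species": self.n_species,
            "n_orders": self.n_orders,
            "specimens_per_species": self.specimens_per_species,
            "n_ref_species": self.n_ref_species,
            "n_families_per_superfamily": self.n_families_per_superfamily,
            "n_codons": self.n_codons,
        }
        for name, v in counts.items():
            if v < 1:
                raise ConfigError(f"{name} must be >= 1, got {v}")
        if self.n_species < 2:
            raise ConfigError("n_species must be >= 2")
        if self.n_orders > self.n_species:
            raise ConfigError("n_orders cannot exceed n_species")
        if self.n_ref_species > self.n_species:
            raise ConfigError("n_ref_species cannot exceed n_species")
        if self.n_ref_species < 2:
            raise ConfigError("n_ref_species must be >= 2")
        if not 0.0 <= self.p_vertical_presence <= 1.0:
            raise ConfigError("p_vertical_presence must be in [0, 1]")
        if self.hotspot_multiplier < 1.0:
            raise ConfigError("hotspot_multiplier must be >= 1")
        if self.n_planted_ht < 0:
            raise ConfigError("n_planted_ht must be >= 0")
        if self.tree_age <= 0:
            raise ConfigError("tree_age must be positive")
        if self.ds_rate < 0 or self.ds_noise_cv < 0:
            raise ConfigError("rates and noise must be non-negative")
        if self.te_rate_factor <= 0:
            raise ConfigError("te_rate_factor must be positive")
        if self.panel_size < 100:
            raise ConfigError("panel_size must be >= 100")


@dataclass(frozen=True)
class TruthRecord:
    family_id: str
    species_a: str
    species_b: str
    mechanism: str  # "vertical" | "horizontal"
    event_node: str = ""
    note: str = ""
    planted_ds: float = float("nan")  # target dS of a planted transfer
    genomic_ds: float = float("nan")  # expected genomic dS of the pair


@dataclass
class TruthTable:
    """Ground truth for recovery tests: one record per species pair and
    family, horizontal records carrying the true event node (the pair's
    MRCA)."""

    records: list[TruthRecord] = field(default_factory=list)

    def horizontal(self, testable_only: bool = False) -> list[TruthRecord]:
        out = [r for r in self.records if r.mechanism == "horizontal"]
        if testable_only:
            out = [r for r in out if r.note != "untestable-by-design"]
        return out

    def vertical(self) -> list[TruthRecord]:
        return [r for r in self.records if r.mechanism == "vertical"]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "family_id": r.family_id,
                    "species_a": r.species_a,
                    "species_b": r.species_b,
                    "mechanism": r.mechanism,
                    "event_node": r.event_node,
                    "note": r.note,
                    "planted_ds": r.planted_ds,
                    "genomic_ds": r.genomic_ds,
                }
                for r in self.records
            ],
            columns=["family_id", "species_a", "species_b", "mechanism",
                     "event_node", "note", "planted_ds", "genomic_ds"],
        )


def _stream(config: SimConfig, *tag: int) -> np.random.Generator:
    """Named child stream of the master seed."""
    return np.random.default_rng(np.random.SeedSequence([config.seed, *tag]))


# ----------------------------------------------------------------------
# host tree
# ----------------------------------------------------------------------
def generate_host_tree(config: SimConfig) -> HostTree:
    """Yule tree conditioned on ``n_species``, rescaled to ``tree_age``,
    with monophyletic order labels and reference-species flags.

    Orders are carved by repeatedly splitting the largest remaining clade
    until ``n_orders`` clades partition the tips — sizes are naturally
    unequal, as in real ordinal samples.  Reference species are a uniform
    random subset of tips; any two of them guarantee at least one internal
    node separating references into two child subtrees.
    """
    from dendropy.simulate import treesim

    rng = _stream(config, 1)
    if config.n_species == 2:
        base = HostTree({"N0001": ("SP0001", "SP0002")},
                        {"N0001": 1.0, "SP0001": 0.0, "SP0002": 0.0})
    else:
        py_rng = _random.Random(int(rng.integers(2**31)))
        dtree = treesim.birth_death_tree(
            birth_rate=1.0,
            death_rate=0.0,
            num_extant_tips=config.n_species,
            rng=py_rng,
        )
        leaves = sorted(dtree.leaf_node_iter(), key=lambda l: l.taxon.label)
        for i, leaf in enumerate(leaves):
            leaf.taxon.label = f"SP{i + 1:04d}"
        base = HostTree.from_dendropy(dtree)
    scale = config.tree_age / base.age(base.root)
    ages = {n: a * scale for n, a in base.ages.items()}

    tree = HostTree(base.children, ages)
    clades: list[str] = [tree.root]
    while len(clades) < config.n_orders:
        splittable = [c for c in clades if not tree.is_tip(c)]
        target = max(splittable, key=lambda c: (len(tree.subtree_tips(c)), c))
        clades.remove(target)
        clades.extend(tree.children[target])
    orders: dict[str, str] = {}
    for k, clade in enumerate(sorted(clades), start=1):
        for tip in tree.subtree_tips(clade):
            orders[tip] = f"ORD{k:02d}"

    ref = sorted(
        rng.choice(tree.tips, size=config.n_ref_species, replace=False).tolist()
    )
    return HostTree(base.children, ages, orders=orders, references=ref)


# ----------------------------------------------------------------------
# reference panel
# ----------------------------------------------------------------------
def _estimated_ds(
    true_ds: np.ndarray, n_sites: int, rng: np.random.Generator
) -> np.ndarray:
    """Finite-alignment dS estimates for given true synonymous distances.

    The observed proportion of synonymous differences is binomial over
    ``n_sites`` sites around its Jukes-Cantor expectation, then inverted
    back to a distance — the same sampling noise a counting estimator
    incurs on a real alignment.  Saturated draws (pS at or above 3/4,
    impossible to invert) are clamped just below the boundary, landing in
    the far upper tail where they cannot affect low quantiles.
    """
    p = 0.75 * (1.0 - np.exp(-4.0 * true_ds / 3.0))
    k = rng.binomial(n_sites, p)
    ps = np.minimum(k / n_sites, (3.0 * n_sites / 4.0 - 0.5) / n_sites)
    return -0.75 * np.log1p(-4.0 * ps / 3.0)


def generate_reference_panel(tree: HostTree, config: SimConfig) -> ReferencePanel:
    """Empirical dS samples for every node separating reference genomes.

    Each sample emulates one housekeeping gene: a true per-gene distance
    drawn from a gamma distribution with mean ``2 * ds_rate * node_age``
    and CV ``ds_noise_cv`` (per-gene rate variation), then *estimated* on a
    finite alignment of ``n_codons`` synonymous sites.  Real reference
    distributions are collections of such finite-alignment estimates, and
    reproducing their estimation noise is what makes the vertical null
    hold exactly for synthetic TE dS values, which carry the same noise.
    With ``ds_noise_cv=0`` the panel degenerates to the exact expected
    values (an idealized, fully deterministic mode).
    """
    eligible = sorted(eligible_reference_nodes(tree))
    if not eligible:
        raise PanelError("tree has no node separating two reference genomes")
    rng = _stream(config, 2)
    cv = config.ds_noise_cv
    samples: dict[str, list[float]] = {}
    for node in eligible:
        mean = 2.0 * config.ds_rate * tree.age(node)
        if cv == 0.0 or mean == 0.0:
            vals = np.full(config.panel_size, mean)
        else:
            shape = 1.0 / cv**2
            true = rng.gamma(shape, mean * cv**2, size=config.panel_size)
            vals = _estimated_ds(true, config.n_codons, rng)
        samples[node] = [float(v) for v in vals]
    return ReferencePanel(samples)


# ----------------------------------------------------------------------
# sequence evolution machinery
# ----------------------------------------------------------------------
def _random_ancestral(n_codons: int, rng: np.random.Generator) -> np.ndarray:
    """(n_codons, 3) base-index array built from fourfold-degenerate codons."""
    prefixes = rng.integers(len(_FOURFOLD_PREFIXES), size=n_codons)
    out = np.empty((n_codons, 3), dtype=np.uint8)
    for i, p in enumerate(prefixes):
        pre = _FOURFOLD_PREFIXES[p]
        out[i, 0] = _BASES.index(pre[0])
        out[i, 1] = _BASES.index(pre[1])
    out[:, 2] = rng.integers(4, size=n_codons)
    return out


def _mutate(seq: np.ndarray, ds: float, rng: np.random.Generator) -> np.ndarray:
    """Jukes-Cantor evolution of third positions at synonymous distance
    ``ds`` (expected substitutions per synonymous site)."""
    out = seq.copy()
    if ds <= 0:
        return out
    p_diff = 0.75 * (1.0 - np.exp(-4.0 * ds / 3.0))
    hit = rng.random(seq.shape[0]) < p_diff
    if hit.any():
        shift = rng.integers(1, 4, size=int(hit.sum())).astype(np.uint8)
        out[hit, 2] = (out[hit, 2] + shift) % 4
    return out


def _to_string(seq: np.ndarray) -> str:
    return "".join(_BASES[b] for b in seq.reshape(-1))


@dataclass
class _Family:
    superfamily: str
    index: int
    rate_mult: float
    species_seq: dict[str, np.ndarray]  # species -> species-level sequence
    vertical_species: set[str]
    ht_species: set[str] = field(default_factory=set)

    @property
    def family_id(self) -> str:
        return f"{self.superfamily}_T{self.index:04d}"

    @property
    def species(self) -> set[str]:
        return self.vertical_species | self.ht_species


def _evolve_family(
    tree: HostTree,
    origin: str,
    present: set[str],
    ancestral: np.ndarray,
    rate: float,
    rng: np.random.Generator,
) -> dict[str, np.ndarray]:
    """Evolve the ancestral sequence along the host subtree below
    ``origin``; return per-present-tip species sequences."""
    seqs: dict[str, np.ndarray] = {}

    def rec(node: str, seq: np.ndarray) -> None:
        if tree.is_tip(node):
            if node in present:
                seqs[node] = seq
            return
        for child in tree.children[node]:
            branch = tree.age(node) - tree.age(child)
            rec(child, _mutate(seq, rate * branch, rng))

    if tree.is_tip(origin):
        seqs[origin] = ancestral
    else:
        rec(origin, ancestral)
    return seqs


# ----------------------------------------------------------------------
# TE dataset
# ----------------------------------------------------------------------
def generate_te_dataset(
    tree: HostTree,
    panel: ReferencePanel,
    config: SimConfig,
) -> tuple[dict[str, SequenceRecord], TruthTable]:
    """TE sequences for all superfamilies plus the ground-truth table.

    Families occupy a random clade (internal nodes weighted by subtree
    size, so both narrow and sweeping distributions occur); within the
    clade each species is present with probability ``p_vertical_presence``.
    Planted transfers are distributed round-robin over superfamilies; both
    endpoints are drawn with hotspot weighting when configured, and only
    pairs testable under the reference panel are planted (a pair that
    cannot be tested is recorded as ``untestable-by-design`` instead).
    """
    rng = _stream(config, 3)
    cv = config.ds_noise_cv
    eligible = eligible_reference_nodes(tree) & panel.nodes
    # family origins are drawn uniformly over ALL nodes, tips included:
    # most families end up confined to one or two species, the occasional
    # deep origin sweeps a large clade — the size mix real surveys show
    origins = sorted(tree.tips) + list(tree.internal_nodes)

    families: list[_Family] = []
    for superfamily in config.superfamily_labels:
        for k in range(1, config.n_families_per_superfamily + 1):
            origin = origins[int(rng.integers(len(origins)))]
            candidates = sorted(tree.subtree_tips(origin))
            present = {
                t for t in candidates if rng.random() < config.p_vertical_presence
            }
            if not present:
                present = {candidates[int(rng.integers(len(candidates)))]}
            # per-family synonymous rate multiplier: mean te_rate_factor
            # (TEs are not slowed by the codon-usage selection acting on
            # housekeeping genes, making the reference test conservative),
            # CV shared with the reference panel's per-gene dispersion
            rate_mult = (
                rng.gamma(1.0 / cv**2, config.te_rate_factor * cv**2)
                if cv > 0
                else config.te_rate_factor
            )
            ancestral = _random_ancestral(config.n_codons, rng)
            seqs = _evolve_family(
                tree, origin, present, ancestral,
                rate_mult * config.ds_rate, rng,
            )
            families.append(
                _Family(superfamily, k, rate_mult, seqs, set(seqs)),
            )

    truth = TruthTable()
    by_superfamily: dict[str, list[_Family]] = {}
    for fam in families:
        by_superfamily.setdefault(fam.superfamily, []).append(fam)

    def endpoint_weight(sp: str) -> float:
        if config.hotspot_order and tree.order_of(sp) == config.hotspot_order:
            return config.hotspot_multiplier
        return 1.0

    def weighted_pick(pool: list[str]) -> str:
        w = np.array([endpoint_weight(s) for s in pool])
        return pool[int(rng.choice(len(pool), p=w / w.sum()))]

    sf_cycle = itertools.cycle(config.superfamily_labels)
    for _ in range(config.n_planted_ht):
        superfamily = next(sf_cycle)
        pool = by_superfamily[superfamily]
        planted = False
        for _attempt in range(200):
            fam = pool[int(rng.integers(len(pool)))]
            donors = sorted(fam.species)
            outside = sorted(set(tree.tips) - fam.species)
            if not outside:
                continue
            donor = weighted_pick(donors)
            recipient = weighted_pick(outside)
            if match_reference(tree, donor, recipient, eligible) is None:
                continue
            mrca = tree.mrca(donor, recipient)
            genomic = 2.0 * config.ds_rate * tree.age(mrca)
            ds_ht = float(rng.uniform(0.0, 0.2 * genomic))
            fam.species_seq[recipient] = _mutate(
                fam.species_seq[donor], ds_ht, rng
            )
            fam.ht_species.add(recipient)
            a, b = sorted((donor, recipient))
            truth.records.append(
                TruthRecord(fam.family_id, a, b, "horizontal", event_node=mrca,
                            planted_ds=ds_ht, genomic_ds=genomic)
            )
            planted = True
            break
        if not planted:
            fam = pool[int(rng.integers(len(pool)))]
            donor = sorted(fam.species)[0]
            outside = sorted(set(tree.tips) - fam.species)
            recipient = outside[0] if outside else donor
            a, b = sorted((donor, recipient))
            truth.records.append(
                TruthRecord(fam.family_id, a, b, "horizontal",
                            note="untestable-by-design")
            )

    # vertical truth records: all cross-species pairs not created by a
    # planted transfer
    horizontal_pairs = {
        (r.family_id, r.species_a, r.species_b)
        for r in truth.horizontal()
    }
    for fam in families:
        for a, b in itertools.combinations(sorted(fam.species), 2):
            if (fam.family_id, a, b) not in horizontal_pairs:
                truth.records.append(TruthRecord(fam.family_id, a, b, "vertical"))

    # emit specimen-level sequences
    records: dict[str, SequenceRecord] = {}
    half_intra = config.intra_species_ds / 2.0
    for fam in families:
        for species in sorted(fam.species):
            base_seq = fam.species_seq[species]
            for j in range(1, config.specimens_per_species + 1):
                specimen = f"{species}.{j}"
                seq = _mutate(base_seq, half_intra, rng)
                seq_id = (
                    f"SPEC{specimen}|OTU{species}|{fam.superfamily}"
                    f"|F{fam.family_id}"
                )
                records[seq_id] = SequenceRecord(
                    seq_id=seq_id,
                    specimen=specimen,
                    species=species,
                    superfamily=fam.superfamily,
                    sequence=_to_string(seq),
                )
    return records, truth


# ----------------------------------------------------------------------
# pairwise hit table
# ----------------------------------------------------------------------
_ALIGNER = Align.PairwiseAligner(
    match_score=1, mismatch_score=-1, open_gap_score=-2, extend_gap_score=-2,
    mode="global",
)


def _align_pair(a: str, b: str) -> tuple[float, int]:
    """(percent identity, alignment length) by exact global alignment."""
    if len(a) == len(b):
        matches = sum(1 for x, y in zip(a, b) if x == y)
        return 100.0 * matches / len(a), len(a)
    aln = _ALIGNER.align(a, b)[0]
    counts = aln.counts()
    return 100.0 * counts.identities / aln.length, aln.length


def generate_hit_table(records: dict[str, SequenceRecord]) -> pd.DataFrame:
    """All-vs-all within-superfamily hit table (BLAST outfmt-6 dialect).

    Both orientations of every qualifying pair are reported, as a
    reciprocal search would; pairs below ``HIT_REPORT_FLOOR`` percent
    identity are omitted.  Self-hits are excluded.  Equal-length pairs are
    compared column-wise (the generator emits ungapped alignments);
    unequal-length pairs fall back to exact global alignment with match
    +1, mismatch -1, gap -2.
    """
    cols = list(HIT_COLUMNS)
    if len(records) < 2:
        return pd.DataFrame(columns=cols)
    by_superfamily: dict[str, list[SequenceRecord]] = {}
    for sid in sorted(records):
        rec = records[sid]
        by_superfamily.setdefault(rec.superfamily, []).append(rec)

    rows: list[tuple] = []
    for superfamily in sorted(by_superfamily):
        recs = by_superfamily[superfamily]
        lengths = {r.length for r in recs}
        if len(lengths) == 1 and len(recs) > 2:
            ids = [r.seq_id for r in recs]
            arr = np.frombuffer(
                "".join(r.sequence for r in recs).encode(), dtype=np.uint8
            ).reshape(len(recs), -1)
            n, L = arr.shape
            for i in range(n):
                ident = 100.0 * (arr[i] == arr[i + 1 :]).mean(axis=1)
                for off, pid in enumerate(ident):
                    j = i + 1 + off
                    if pid >= HIT_REPORT_FLOOR:
                        rows.append((ids[i], ids[j], round(pid, 3), L, L, L))
                        rows.append((ids[j], ids[i], round(pid, 3), L, L, L))
        else:
            for ra, rb in itertools.combinations(recs, 2):
                pid, length = _align_pair(ra.sequence, rb.sequence)
                if pid >= HIT_REPORT_FLOOR:
                    rows.append(
                        (ra.seq_id, rb.seq_id, round(pid, 3), length,
                         ra.length, rb.length)
                    )
                    rows.append(
                        (rb.seq_id, ra.seq_id, round(pid, 3), length,
                         rb.length, ra.length)
                    )
    df = pd.DataFrame(rows, columns=cols)
    return df.sort_values(["qseqid", "sseqid"], kind="mergesort").reset_index(
        drop=True
    )
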