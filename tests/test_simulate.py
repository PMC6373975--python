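"""Synthetic-data generator: tree shape, panel moments, dataset structure,
hit table and reproducibility."""

import numpy as np
import pytest

from httscan import (
    SimConfig,
    generate_hit_table,
    generate_host_tree,
    generate_reference_panel,
    generate_te_dataset,
)
from httscan.clustering import SequenceRecord
from httscan.simulate import ConfigError


def _cfg(**kw):
    base = dict(n_species=24, n_orders=4, n_ref_species=8,
                n_families_per_superfamily=6, seed=5)
    base.update(kw)
    return SimConfig(**base)


# ----------------------------------------------------------------------
# host tree
# ----------------------------------------------------------------------
def test_smallest_tree_two_tips():
    cfg = _cfg(n_species=2, n_orders=1, n_ref_species=2, tree_age=100.0)
    tree = generate_host_tree(cfg)
    assert len(tree.tips) == 2
    assert tree.age(tree.root) == pytest.approx(100.0)
    assert set(tree.internal_nodes) == {tree.root}


def test_nineteen_monophyletic_orders():
    cfg = _cfg(n_species=40, n_orders=19, n_ref_species=10)
    tree = generate_host_tree(cfg)
    assert len(tree.order_labels) == 19
    for order in tree.order_labels:
        members = [t for t in tree.tips if tree.order_of(t) == order]
        mrca = members[0]
        for m in members[1:]:
            mrca = tree.mrca(mrca, m)
        assert tree.subtree_tips(mrca) == frozenset(members)


@pytest.mark.parametrize("seed", [0, 1, 17])
def test_tree_is_ultrametric_with_root_at_tree_age(seed):
    tree = generate_host_tree(_cfg(seed=seed, tree_age=250.0))
    assert tree.age(tree.root) == pytest.approx(250.0, rel=1e-9)
    # every root-to-tip path sums to the root age
    for tip in tree.tips:
        depth = 0.0
        node = tip
        while tree.parent[node] is not None:
            parent = tree.parent[node]
            depth += tree.age(parent) - tree.age(node)
            node = parent
        assert depth == pytest.approx(250.0, rel=1e-9)


def test_reference_placement_creates_eligible_node():
    from httscan import eligible_reference_nodes

    tree = generate_host_tree(_cfg())
    assert len(tree.references) == 8
    assert eligible_reference_nodes(tree)


def test_invalid_configurations_rejected():
    with pytest.raises(ConfigError):
        _cfg(n_ref_species=30)  # more references than species
    with pytest.raises(ConfigError):
        _cfg(n_orders=30)
    with pytest.raises(ConfigError):
        _cfg(p_vertical_presence=1.5)
    with pytest.raises(ConfigError):
        _cfg(hotspot_multiplier=0.5)
    with pytest.raises(ConfigError):
        _cfg(n_ref_species=1)


# ----------------------------------------------------------------------
# reference panel
# ----------------------------------------------------------------------
def test_panel_zero_age_and_zero_noise_gives_zeros():
    cfg = _cfg(ds_noise_cv=0.0)
    tree = generate_host_tree(cfg)
    panel = generate_reference_panel(tree, cfg)
    for node, sample in panel.samples.items():
        expected = 2.0 * cfg.ds_rate * tree.age(node)
        assert np.allclose(sample, expected)


def test_panel_means_scale_linearly_with_node_age():
    cfg = _cfg(ds_noise_cv=0.0, n_ref_species=24)  # all tips are references
    tree = generate_host_tree(cfg)
    panel = generate_reference_panel(tree, cfg)
    nodes = sorted(panel.samples, key=tree.age)
    ages = np.array([tree.age(n) for n in nodes])
    means = np.array([np.mean(panel.samples[n]) for n in nodes])
    nz = ages > 0
    assert np.allclose(means[nz] / ages[nz], 2.0 * cfg.ds_rate)


def test_panel_monte_carlo_mean_matches_stated_moments():
    """Root node at 100 My with ds_rate 0.005: mean dS 1.0 within 3 SE."""
    cfg = SimConfig(n_species=2, n_orders=1, n_ref_species=2, tree_age=100.0,
                    ds_rate=0.005, ds_noise_cv=0.2, panel_size=1000, seed=42)
    tree = generate_host_tree(cfg)
    panel = generate_reference_panel(tree, cfg)
    sample = np.array(panel.samples[tree.root])
    se = sample.std(ddof=1) / np.sqrt(len(sample))
    assert abs(sample.mean() - 1.0) < 3 * se
    assert (sample >= 0).all()


# ----------------------------------------------------------------------
# TE dataset
# ----------------------------------------------------------------------
def test_null_configuration_has_only_vertical_truth():
    cfg = _cfg(n_planted_ht=0)
    tree = generate_host_tree(cfg)
    panel = generate_reference_panel(tree, cfg)
    _, truth = generate_te_dataset(tree, panel, cfg)
    assert truth.horizontal() == []
    assert all(r.mechanism == "vertical" for r in truth.records)
    assert all(r.event_node == "" for r in truth.records)


def test_every_occurrence_has_exactly_two_specimens():
    cfg = _cfg(specimens_per_species=2, n_planted_ht=5)
    tree = generate_host_tree(cfg)
    panel = generate_reference_panel(tree, cfg)
    records, _ = generate_te_dataset(tree, panel, cfg)
    per_occurrence: dict[tuple, set] = {}
    for rec in records.values():
        fam = rec.seq_id.split("|F")[1]
        per_occurrence.setdefault((fam, rec.species), set()).add(rec.specimen)
    assert per_occurrence
    assert all(len(v) == 2 for v in per_occurrence.values())


def test_planted_ds_below_fifth_of_genomic_ds():
    cfg = _cfg(n_planted_ht=12)
    tree = generate_host_tree(cfg)
    panel = generate_reference_panel(tree, cfg)
    _, truth = generate_te_dataset(tree, panel, cfg)
    planted = truth.horizontal(testable_only=True)
    assert planted
    for rec in planted:
        assert rec.planted_ds < 0.2 * rec.genomic_ds
        assert rec.event_node == tree.mrca(rec.species_a, rec.species_b)


def test_planted_pairs_appear_exactly_once():
    cfg = _cfg(n_planted_ht=12)
    tree = generate_host_tree(cfg)
    panel = generate_reference_panel(tree, cfg)
    _, truth = generate_te_dataset(tree, panel, cfg)
    keys = [(r.family_id, r.species_a, r.species_b) for r in truth.records]
    assert len(keys) == len(set(keys))


def test_hotspot_order_holds_plurality_of_planted_endpoints():
    counts: dict[str, int] = {}
    for seed in range(4):
        cfg = _cfg(n_species=36, n_orders=6, n_ref_species=18,
                   n_planted_ht=30, hotspot_order="ORD03",
                   hotspot_multiplier=5.0, seed=seed)
        tree = generate_host_tree(cfg)
        panel = generate_reference_panel(tree, cfg)
        _, truth = generate_te_dataset(tree, panel, cfg)
        for rec in truth.horizontal(testable_only=True):
            for sp in (rec.species_a, rec.species_b):
                order = tree.order_of(sp)
                counts[order] = counts.get(order, 0) + 1
    assert max(counts, key=counts.get) == "ORD03"


def test_vertical_min_ds_tracks_genomic_ds():
    """Median realized family dS per species pair stays within 20% of the
    pair's expected genomic dS (times the TE rate factor's median)."""
    from httscan import CodonAlignment, min_pairwise_ds

    cfg = _cfg(n_species=12, n_orders=2, n_ref_species=12,
               n_families_per_superfamily=30, p_vertical_presence=0.8,
               superfamily_labels=("Copia",), seed=9)
    tree = generate_host_tree(cfg)
    panel = generate_reference_panel(tree, cfg)
    records, _ = generate_te_dataset(tree, panel, cfg)
    by_family: dict[str, list] = {}
    for rec in records.values():
        by_family.setdefault(rec.seq_id.split("|F")[1], []).append(rec)
    ratio_by_pair: dict[tuple, list[float]] = {}
    for fam, recs in by_family.items():
        aln = CodonAlignment(
            fam,
            {r.seq_id: r.sequence for r in recs},
            {r.seq_id: r.specimen for r in recs},
            {r.seq_id: r.species for r in recs},
        )
        for pds in min_pairwise_ds(aln):
            if pds.ds is None:
                continue
            genomic = 2 * cfg.ds_rate * tree.age(
                tree.mrca(pds.species_a, pds.species_b)
            )
            if genomic > 0.05:  # skip pairs too shallow for a stable ratio
                ratio_by_pair.setdefault(
                    (pds.species_a, pds.species_b), []
                ).append(pds.ds / genomic)
    assert ratio_by_pair
    medians = [np.median(v) for v in ratio_by_pair.values() if len(v) >= 5]
    assert medians
    # families evolve at te_rate_factor times the reference rate on average
    assert np.median(medians) == pytest.approx(cfg.te_rate_factor, rel=0.2)


def test_regeneration_is_byte_identical():
    cfg = _cfg(n_planted_ht=4)
    outputs = []
    for _ in range(2):
        tree = generate_host_tree(cfg)
        panel = generate_reference_panel(tree, cfg)
        records, truth = generate_te_dataset(tree, panel, cfg)
        hits = generate_hit_table(records)
        outputs.append(
            (
                tree.to_newick(),
                {n: tuple(s) for n, s in panel.samples.items()},
                {k: r.sequence for k, r in records.items()},
                truth.to_frame().to_csv(),
                hits.to_csv(),
            )
        )
    assert outputs[0] == outputs[1]


# ----------------------------------------------------------------------
# hit table
# ----------------------------------------------------------------------
def _rec(seq_id, sequence, species="S1", specimen="p1", superfamily="Copia"):
    return SequenceRecord(seq_id, specimen, species, superfamily, sequence)


def test_identical_pair_gives_reciprocal_full_identity_hits():
    seq = "ACGT" * 75
    hits = generate_hit_table({"a": _rec("a", seq), "b": _rec("b", seq)})
    assert len(hits) == 2
    assert set(zip(hits.qseqid, hits.sseqid)) == {("a", "b"), ("b", "a")}
    assert (hits.pident == 100.0).all()
    assert (hits.length == 300).all()


def test_thirty_percent_mismatch_falls_below_clustering_threshold():
    a = "GCT" * 100
    b = "".join(
        ("GGT" if i < 30 else "GCT") for i in range(100)
    )  # 30% of codons differ at one position -> 10% overall, use positions
    # build exactly 90 mismatching positions out of 300 (30%)
    b = "A" * 90 + a[90:]
    assert sum(x != y for x, y in zip(a, b)) == 90
    hits = generate_hit_table({"a": _rec("a", a), "b": _rec("b", b)})
    assert len(hits) == 2
    assert (hits.pident < 80.0).all()
    assert hits.pident.iloc[0] == pytest.approx(70.0)


def test_single_or_empty_input_gives_empty_table():
    assert generate_hit_table({}).empty
    assert generate_hit_table({"a": _rec("a", "ACGT" * 75)}).empty


def test_self_hits_excluded_and_cross_superfamily_not_compared():
    seq = "ACGT" * 75
    hits = generate_hit_table(
        {
            "a": _rec("a", seq, superfamily="Copia"),
            "b": _rec("b", seq, superfamily="Jockey"),
        }
    )
    assert hits.empty
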