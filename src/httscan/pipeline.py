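"""End-to-end orchestration: simulate/ingest -> cluster -> dS -> detect ->
events -> null model -> report.

Every stage persists its outputs as TSV/FASTA/Newick in the run directory
and can be re-run idempotently from the persisted inputs of the previous
stage; the manifest records configuration, seeds, package version and
per-stage record counts.  All numbers are persisted at full precision;
rounding happens only in display tables.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as hio
from .clustering import (
    TEFamily,
    cluster_single_linkage,
    filter_family_occurrences,
)
from .divergence import CodonAlignment, PairwiseDS, collapse_specimen_redundancy, min_pairwise_ds
from .events import FamilyEventCount, family_subtree, minimal_events, sample_scenarios
from .nullmodel import compute_forbidden_pairs, distance_profile, simulate_null
from .reference import HTNetwork, ReferencePanel, detect_ht_links
from .simulate import (
    SimConfig,
    generate_hit_table,
    generate_host_tree,
    generate_reference_panel,
    generate_te_dataset,
)
from .tree import HostTree

__all__ = [
    "PipelineConfig",
    "PipelineError",
    "SummaryTable",
    "run_pipeline",
    "summarize",
    "summary_from_counts",
    "STAGES",
]

STAGES = ("simulate", "cluster", "divergence", "detect", "events", "null", "report")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and offending record."""


@dataclass
class PipelineConfig:
    """One auditable record of every knob of a run."""

    outdir: Path = Path("httscan_out")
    synthetic: SimConfig | None = None
    # external inputs (ignored in synthetic mode)
    fasta: Path | None = None
    newick: Path | None = None
    orders: Path | None = None
    references: Path | None = None
    panel: Path | None = None
    hits: Path | None = None
    # thresholds
    min_identity: float = 80.0
    min_overlap: float = 0.80
    quantile: float = 0.05
    n_scenarios: int = 1000
    n_sims: int = 1000
    n_scenarios_per_sim: int = 100
    distance_window: float = 25.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.outdir = Path(self.outdir)
        if not 0 < self.min_identity <= 100:
            raise PipelineError(f"min_identity {self.min_identity} outside (0, 100]")
        if not 0 < self.min_overlap <= 1:
            raise PipelineError(f"min_overlap {self.min_overlap} outside (0, 1]")
        if not 0 < self.quantile <= 1:
            raise PipelineError(f"quantile {self.quantile} outside (0, 1]")
        for name in ("n_scenarios", "n_sims", "n_scenarios_per_sim"):
            if getattr(self, name) < 1:
                raise PipelineError(f"{name} must be >= 1")

    @property
    def is_synthetic(self) -> bool:
        return self.synthetic is not None

    @classmethod
    def from_yaml(cls, path: Path | str, **overrides) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        synthetic = raw.pop("synthetic", None)
        raw.update(overrides)
        if synthetic is not None:
            if "seed" in raw and "seed" not in synthetic:
                synthetic["seed"] = raw["seed"]
            raw["synthetic"] = SimConfig(**synthetic)
        for key in ("outdir", "fasta", "newick", "orders", "references",
                    "panel", "hits"):
            if raw.get(key) is not None:
                raw[key] = Path(raw[key])
        return cls(**raw)

    # resolved locations of the stage inputs
    def path(self, name: str) -> Path:
        return self.outdir / name

    def input_paths(self) -> dict[str, Path]:
        if self.is_synthetic:
            return {
                "fasta": self.path("sequences.fasta"),
                "newick": self.path("tree.nwk"),
                "orders": self.path("orders.tsv"),
                "references": self.path("references.tsv"),
                "panel": self.path("panel.tsv"),
                "hits": self.path("hits.tsv"),
            }
        paths = {
            "fasta": self.fasta, "newick": self.newick, "orders": self.orders,
            "references": self.references, "panel": self.panel, "hits": self.hits,
        }
        for key, p in paths.items():
            if key != "hits" and p is None:
                raise PipelineError(f"non-synthetic mode requires an input path for {key!r}")
            if p is not None and not Path(p).exists():
                raise PipelineError(f"input file not found: {p}")
        return {k: Path(p) for k, p in paths.items() if p is not None}


def _load_tree(cfg: PipelineConfig) -> HostTree:
    p = cfg.input_paths()
    return hio.read_tree(p["newick"], p["orders"], p["references"])


def _load_panel(cfg: PipelineConfig) -> ReferencePanel:
    return ReferencePanel(hio.read_panel(cfg.input_paths()["panel"]))


def _load_families(cfg: PipelineConfig) -> list[TEFamily]:
    df = hio.read_tsv(cfg.path("families.tsv"), dtype=str)
    fams: dict[str, TEFamily] = {}
    for fam_id, grp in df.groupby("family_id", sort=True):
        occurrence: dict[str, set[str]] = {}
        for sp, spec in zip(grp["species"], grp["specimen"]):
            occurrence.setdefault(sp, set()).add(spec)
        fams[fam_id] = TEFamily(
            family_id=str(fam_id),
            superfamily=str(grp["superfamily"].iloc[0]),
            members=frozenset(grp["seq_id"]),
            occurrence=occurrence,
        )
    return [fams[k] for k in sorted(fams)]


def _load_networks(cfg: PipelineConfig) -> dict[str, HTNetwork]:
    links = hio.read_tsv(cfg.path("ht_links.tsv"), dtype={"family_id": str})
    superfamily_of = dict(
        zip(
            hio.read_tsv(cfg.path("families.tsv"), dtype=str)["family_id"],
            hio.read_tsv(cfg.path("families.tsv"), dtype=str)["superfamily"],
        )
    )
    networks: dict[str, HTNetwork] = {}
    hl = links[links["verdict"] == "horizontal"]
    for fam, a, b in zip(hl["family_id"], hl["species_a"], hl["species_b"]):
        sf = superfamily_of[str(fam)]
        networks.setdefault(sf, HTNetwork(sf)).add_link(str(a), str(b), str(fam))
    return networks


# ----------------------------------------------------------------------
# stages
# ----------------------------------------------------------------------
def stage_simulate(cfg: PipelineConfig) -> dict[str, int]:
    if cfg.synthetic is None:
        raise PipelineError("simulate stage requires a synthetic configuration")
    sim = cfg.synthetic
    cfg.outdir.mkdir(parents=True, exist_ok=True)
    tree = generate_host_tree(sim)
    panel = generate_reference_panel(tree, sim)
    records, truth = generate_te_dataset(tree, panel, sim)
    hits = generate_hit_table(records)
    hio.write_tree(tree, cfg.path("tree.nwk"), cfg.path("orders.tsv"),
                   cfg.path("references.tsv"))
    n_panel = hio.write_panel(panel.samples, cfg.path("panel.tsv"), seed=sim.seed)
    n_seq = hio.write_fasta(records, cfg.path("sequences.fasta"))
    n_hits = hio.write_hits(hits, cfg.path("hits.tsv"), seed=sim.seed)
    n_truth = hio.write_tsv(truth.to_frame(), cfg.path("truth.tsv"), seed=sim.seed)
    return {"sequences": n_seq, "hits": n_hits, "panel_rows": n_panel,
            "truth_rows": n_truth, "species": len(tree.tips)}


def stage_cluster(cfg: PipelineConfig) -> dict[str, int]:
    paths = cfg.input_paths()
    sequences = hio.read_fasta(paths["fasta"])
    if "hits" in paths:
        hits = hio.read_hits(paths["hits"])
    else:
        hits = generate_hit_table(sequences)
    families = cluster_single_linkage(
        hits, sequences, cfg.min_identity, cfg.min_overlap
    )
    filtered = filter_family_occurrences(families, sequences)
    rows = [
        {
            "family_id": fam.family_id,
            "superfamily": fam.superfamily,
            "species": sequences[sid].species,
            "specimen": sequences[sid].specimen,
            "seq_id": sid,
        }
        for fam in filtered
        for sid in sorted(fam.members)
    ]
    hio.write_tsv(
        pd.DataFrame(rows, columns=["family_id", "superfamily", "species",
                                    "specimen", "seq_id"]),
        cfg.path("families.tsv"), seed=cfg.seed,
    )
    return {"families_raw": len(families), "families": len(filtered),
            "member_sequences": len(rows)}


def stage_divergence(cfg: PipelineConfig) -> dict[str, int]:
    sequences = hio.read_fasta(cfg.input_paths()["fasta"])
    families = _load_families(cfg)
    rows = []
    for fam in families:
        if fam.n_species < 2:
            continue
        members = sorted(fam.members)
        aln = CodonAlignment(
            fam.family_id,
            {sid: sequences[sid].sequence for sid in members},
            {sid: sequences[sid].specimen for sid in members},
            {sid: sequences[sid].species for sid in members},
        )
        aln = collapse_specimen_redundancy(aln)
        for pds in min_pairwise_ds(aln):
            rows.append(
                {
                    "family_id": pds.family_id,
                    "species_a": pds.species_a,
                    "species_b": pds.species_b,
                    "ds": "" if pds.ds is None else repr(pds.ds),
                    "n_syn_sites": pds.n_syn_sites,
                    "seq_a": pds.seq_a,
                    "seq_b": pds.seq_b,
                    "defined": int(pds.defined),
                }
            )
    df = pd.DataFrame(
        rows, columns=["family_id", "species_a", "species_b", "ds",
                       "n_syn_sites", "seq_a", "seq_b", "defined"],
    )
    hio.write_tsv(df, cfg.path("pairwise_ds.tsv"), seed=cfg.seed)
    return {"species_pairs": len(df),
            "defined_pairs": int(df["defined"].sum()) if len(df) else 0}


def stage_detect(cfg: PipelineConfig) -> dict[str, int]:
    tree = _load_tree(cfg)
    panel = _load_panel(cfg)
    fam_df = hio.read_tsv(cfg.path("families.tsv"), dtype=str)
    superfamily_of = dict(zip(fam_df["family_id"], fam_df["superfamily"]))
    pds_df = hio.read_tsv(cfg.path("pairwise_ds.tsv"))
    pairwise = [
        PairwiseDS(
            str(r.family_id), str(r.species_a), str(r.species_b),
            None if pd.isna(r.ds) else float(r.ds),
            float(r.n_syn_sites),
        )
        for r in pds_df.itertuples(index=False)
    ]
    links, networks, summary = detect_ht_links(
        pairwise, tree, panel, superfamily_of, quantile=cfg.quantile
    )
    link_df = pd.DataFrame(
        [
            {
                "family_id": l.family_id,
                "species_a": l.species_a,
                "species_b": l.species_b,
                "te_ds": "" if l.te_ds is None else repr(l.te_ds),
                "matched_node": l.matched_node or "",
                "q05": "" if l.q05 is None else repr(l.q05),
                "verdict": l.verdict,
            }
            for l in links
        ],
        columns=["family_id", "species_a", "species_b", "te_ds",
                 "matched_node", "q05", "verdict"],
    )
    hio.write_tsv(link_df, cfg.path("ht_links.tsv"), seed=cfg.seed)
    edge_rows = [
        {
            "superfamily": sf,
            "species_a": a,
            "species_b": b,
            "families": ",".join(sorted(networks[sf].edge_families(a, b))),
        }
        for sf in sorted(networks)
        for a, b in networks[sf].edges
    ]
    hio.write_tsv(
        pd.DataFrame(edge_rows, columns=["superfamily", "species_a",
                                         "species_b", "families"]),
        cfg.path("networks.tsv"), seed=cfg.seed,
    )
    return {"pairs": summary.n_pairs, "testable": summary.n_testable,
            "horizontal": summary.n_horizontal}


def _event_counts_by_superfamily(
    cfg: PipelineConfig, tree: HostTree
) -> dict[str, list[FamilyEventCount]]:
    families = {f.family_id: f for f in _load_families(cfg)}
    links = hio.read_tsv(cfg.path("ht_links.tsv"), dtype={"family_id": str})
    hl = links[links["verdict"] == "horizontal"]
    edges_by_family: dict[str, list[tuple[str, str]]] = {}
    for fam, a, b in zip(hl["family_id"], hl["species_a"], hl["species_b"]):
        edges_by_family.setdefault(str(fam), []).append(
            tuple(sorted((str(a), str(b))))
        )
    out: dict[str, list[FamilyEventCount]] = {}
    for fam_id in sorted(edges_by_family):
        fam = families[fam_id]
        subtree = family_subtree(tree, fam)
        fec = minimal_events(subtree, edges_by_family[fam_id], family_id=fam_id)
        out.setdefault(fam.superfamily, []).append(fec)
    return out


def stage_events(cfg: PipelineConfig) -> dict[str, int]:
    tree = _load_tree(cfg)
    by_sf = _event_counts_by_superfamily(cfg, tree)
    event_rows, species_rows, order_rows = [], [], []
    for i, sf in enumerate(sorted(by_sf)):
        counts = by_sf[sf]
        for fec in counts:
            for node in sorted(fec.event_nodes):
                event_rows.append(
                    {"superfamily": sf, "family_id": fec.family_id,
                     "event_node": node, "node_age": tree.age(node),
                     "n_crossing_links": len(fec.crossing[node])}
                )
        scen = sample_scenarios(
            counts, tree, n_scenarios=cfg.n_scenarios,
            seed=np.random.SeedSequence([cfg.seed, 4, i]), keep_scenarios=False,
        )
        for sp, mean in scen.species_mean.items():
            species_rows.append(
                {"superfamily": sf, "species": sp,
                 "order": tree.order_of(sp), "mean_htt": mean}
            )
        for order, mean in sorted(scen.order_mean.items()):
            order_rows.append(
                {"superfamily": sf, "order": order, "observed_mean_htt": mean}
            )
    hio.write_tsv(
        pd.DataFrame(event_rows, columns=["superfamily", "family_id",
                                          "event_node", "node_age",
                                          "n_crossing_links"]),
        cfg.path("events.tsv"), seed=cfg.seed,
    )
    hio.write_tsv(
        pd.DataFrame(species_rows, columns=["superfamily", "species", "order",
                                            "mean_htt"]),
        cfg.path("species_htt.tsv"), seed=cfg.seed,
    )
    hio.write_tsv(
        pd.DataFrame(order_rows, columns=["superfamily", "order",
                                          "observed_mean_htt"]),
        cfg.path("order_totals.tsv"), seed=cfg.seed,
    )
    return {"events": len(event_rows)}


def stage_null(cfg: PipelineConfig) -> dict[str, int]:
    tree = _load_tree(cfg)
    panel = _load_panel(cfg)
    networks = _load_networks(cfg)
    families = _load_families(cfg)
    carriers_by_sf: dict[str, set[str]] = {}
    for fam in families:
        carriers_by_sf.setdefault(fam.superfamily, set()).update(fam.species)
    comp_rows, profile_rows = [], []
    n_repaired = 0
    for i, sf in enumerate(sorted(networks)):
        net = networks[sf]
        carriers = sorted(carriers_by_sf[sf])
        forbidden = compute_forbidden_pairs(tree, panel, carriers)
        nc = simulate_null(
            net, tree, carriers, forbidden,
            n_sims=cfg.n_sims, seed=np.random.SeedSequence([cfg.seed, 5, i]),
            n_scenarios=cfg.n_scenarios,
            n_scenarios_per_sim=cfg.n_scenarios_per_sim,
        )
        n_repaired += nc.n_repaired
        tbl = nc.table.copy()
        tbl.insert(0, "superfamily", sf)
        tbl["normalization_mean"] = float(nc.normalization.mean())
        comp_rows.append(tbl)
        prof = distance_profile(
            nc.observed_scenarios, nc.sim_scenarios, tree,
            window=cfg.distance_window, factors=nc.normalization,
        )
        prof.insert(0, "superfamily", sf)
        profile_rows.append(prof)
    comp = (
        pd.concat(comp_rows, ignore_index=True)
        if comp_rows
        else pd.DataFrame(columns=["superfamily", "order", "observed",
                                   "sim_mean", "q025", "q975", "flag",
                                   "normalization_mean"])
    )
    prof = (
        pd.concat(profile_rows, ignore_index=True)
        if profile_rows
        else pd.DataFrame(columns=["superfamily", "window_start", "window_end",
                                   "observed", "expected", "ratio"])
    )
    hio.write_tsv(comp, cfg.path("null_comparison.tsv"), seed=cfg.seed)
    hio.write_tsv(prof, cfg.path("distance_profile.tsv"), seed=cfg.seed)
    return {"null_rows": len(comp), "repaired_simulations": n_repaired}


# ----------------------------------------------------------------------
# summary
# ----------------------------------------------------------------------
@dataclass
class SummaryTable:
    """Per-superfamily family counts, minimal transfer counts and rates.

    ``table`` keeps full precision; :meth:`display` applies the
    publication-style rounding (rates to 2 decimals, shares to integer
    percent)."""

    table: pd.DataFrame
    total_events: int

    def display(self) -> pd.DataFrame:
        d = self.table.copy()
        d["htt_rate"] = d["htt_rate"].round(2)
        for col in ("event_share_pct", "family_share_pct", "prevalence_pct"):
            d[col] = d[col].round(0)
        d["families_per_species"] = d["families_per_species"].round(1)
        return d


def summary_from_counts(
    rows: list[dict],
    n_total_species: int | None = None,
) -> SummaryTable:
    """Build the summary from plain per-superfamily counts.

    Each row needs ``superfamily``, ``n_families``, ``min_htt`` and
    optionally ``n_species_present``.  Rates are events per family; shares
    are percentages of the across-superfamily totals; prevalence is the
    fraction of surveyed species carrying the superfamily; families per
    species is the family count divided by the number of carrier species.
    """
    total_events = sum(r["min_htt"] for r in rows)
    total_families = sum(r["n_families"] for r in rows)
    out = []
    for r in sorted(rows, key=lambda r: r["superfamily"]):
        present = r.get("n_species_present")
        out.append(
            {
                "superfamily": r["superfamily"],
                "n_families": r["n_families"],
                "min_htt": r["min_htt"],
                "htt_rate": r["min_htt"] / r["n_families"],
                "event_share_pct": 100.0 * r["min_htt"] / total_events
                if total_events else 0.0,
                "family_share_pct": 100.0 * r["n_families"] / total_families
                if total_families else 0.0,
                "prevalence_pct": 100.0 * present / n_total_species
                if present is not None and n_total_species else float("nan"),
                "families_per_species": r["n_families"] / present
                if present else float("nan"),
            }
        )
    out.append(
        {
            "superfamily": "total",
            "n_families": total_families,
            "min_htt": total_events,
            "htt_rate": total_events / total_families if total_families else 0.0,
            "event_share_pct": 100.0 if total_events else 0.0,
            "family_share_pct": 100.0 if total_families else 0.0,
            "prevalence_pct": float("nan"),
            "families_per_species": float("nan"),
        }
    )
    return SummaryTable(pd.DataFrame(out), total_events)


def summarize(
    families: list[TEFamily],
    event_counts: dict[str, list[FamilyEventCount]],
    n_total_species: int | None = None,
) -> SummaryTable:
    """Summary computed from pipeline objects (families + event counts)."""
    superfamilies = sorted({f.superfamily for f in families})
    rows = []
    for sf in superfamilies:
        sf_fams = [f for f in families if f.superfamily == sf]
        present: set[str] = set()
        for f in sf_fams:
            present.update(f.species)
        rows.append(
            {
                "superfamily": sf,
                "n_families": len(sf_fams),
                "min_htt": sum(
                    fec.minimal_events for fec in event_counts.get(sf, [])
                ),
                "n_species_present": len(present),
            }
        )
    return summary_from_counts(rows, n_total_species)


def stage_report(cfg: PipelineConfig) -> dict[str, int]:
    tree = _load_tree(cfg)
    families = _load_families(cfg)
    by_sf = _event_counts_by_superfamily(cfg, tree)
    summary = summarize(families, by_sf, n_total_species=len(tree.tips))
    hio.write_tsv(summary.table, cfg.path("summary.tsv"), seed=cfg.seed)
    return {"superfamilies": len(summary.table) - 1,
            "total_events": summary.total_events}


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "cluster": stage_cluster,
    "divergence": stage_divergence,
    "detect": stage_detect,
    "events": stage_events,
    "null": stage_null,
    "report": stage_report,
}


def run_stage(cfg: PipelineConfig, name: str) -> dict[str, int]:
    cfg.outdir.mkdir(parents=True, exist_ok=True)
    try:
        counts = _STAGE_FUNCS[name](cfg)
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001 - annotate with stage context
        raise PipelineError(f"stage {name!r} failed: {exc}") from exc
    _update_manifest(cfg, name, counts)
    return counts


def run_pipeline(cfg: PipelineConfig) -> dict[str, dict[str, int]]:
    """Execute all stages in order; returns per-stage record counts."""
    stages = list(STAGES)
    if not cfg.is_synthetic:
        cfg.input_paths()  # validate before any computation
        stages.remove("simulate")
    results = {}
    for name in stages:
        results[name] = run_stage(cfg, name)
    return results


def _update_manifest(cfg: PipelineConfig, stage: str, counts: dict[str, int]) -> None:
    from . import __version__

    path = cfg.path("manifest.json")
    manifest = json.loads(path.read_text()) if path.exists() else {}
    config_dict = dataclasses.asdict(cfg)
    config_dict["outdir"] = str(config_dict["outdir"])
    for key in ("fasta", "newick", "orders", "references", "panel", "hits"):
        if config_dict[key] is not None:
            config_dict[key] = str(config_dict[key])
    manifest["config"] = config_dict
    manifest["seed"] = cfg.seed
    manifest["version"] = __version__
    manifest.setdefault("stages", {})[stage] = counts
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
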