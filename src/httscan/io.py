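"""Readers and writers for the pipeline's on-disk formats.

Everything is plain text: FASTA for sequences (header dialect
``>SPEC<specimen>|OTU<species>|<superfamily>|F<family>``), Newick for the
chronogram (branch lengths in My, internal nodes labeled), and TSV for
tables.  TSV files written here carry ``#``-prefixed header comments
(including the generating seed where applicable) and are read back with
``comment='#'``.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as BioSeqRecord

from .clustering import HIT_COLUMNS, MIN_SEQUENCE_LENGTH, InputError, SequenceRecord
from .tree import HostTree

__all__ = [
    "write_fasta",
    "read_fasta",
    "parse_header",
    "write_tree",
    "read_tree",
    "write_hits",
    "read_hits",
    "write_panel",
    "read_panel",
    "write_tsv",
    "read_tsv",
]


def parse_header(header: str) -> tuple[str, str, str]:
    """(specimen, species, superfamily) from the FASTA header dialect."""
    parts = header.split("|")
    if len(parts) < 3 or not parts[0].startswith("SPEC") or not parts[1].startswith("OTU"):
        raise InputError(f"unparseable sequence header {header!r}")
    return parts[0][4:], parts[1][3:], parts[2]


def write_fasta(records: dict[str, SequenceRecord], path: Path | str) -> int:
    bio = [
        BioSeqRecord(Seq(records[sid].sequence), id=sid, description="")
        for sid in sorted(records)
    ]
    return SeqIO.write(bio, str(path), "fasta")


def read_fasta(path: Path | str) -> dict[str, SequenceRecord]:
    """Parse sequences, dropping any shorter than 100 bp (too short for a
    stable dS estimate; mirrors the upstream read-length filter)."""
    out: dict[str, SequenceRecord] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq)
        if len(seq) < MIN_SEQUENCE_LENGTH:
            continue
        specimen, species, superfamily = parse_header(rec.id)
        out[rec.id] = SequenceRecord(
            seq_id=rec.id,
            specimen=specimen,
            species=species,
            superfamily=superfamily,
            sequence=seq,
        )
    return out


def write_tree(tree: HostTree, newick_path: Path | str,
               orders_path: Path | str | None = None,
               references_path: Path | str | None = None) -> None:
    Path(newick_path).write_text(tree.to_newick() + "\n")
    if orders_path is not None:
        pd.DataFrame(
            sorted(tree.orders.items()), columns=["species", "order"]
        ).to_csv(orders_path, sep="\t", index=False)
    if references_path is not None:
        pd.DataFrame(
            [(t, int(t in tree.references)) for t in tree.tips],
            columns=["species", "is_reference"],
        ).to_csv(references_path, sep="\t", index=False)


def read_tree(newick_path: Path | str,
              orders_path: Path | str | None = None,
              references_path: Path | str | None = None) -> HostTree:
    orders = {}
    references: Iterable[str] = ()
    if orders_path is not None:
        df = pd.read_csv(orders_path, sep="\t", comment="#", dtype=str)
        orders = dict(zip(df["species"], df["order"]))
    if references_path is not None:
        df = pd.read_csv(references_path, sep="\t", comment="#")
        references = [str(s) for s, flag in zip(df["species"], df["is_reference"]) if flag]
    return HostTree.from_newick(
        Path(newick_path).read_text(), orders=orders, references=references
    )


def write_hits(hits: pd.DataFrame, path: Path | str, seed: int | None = None) -> int:
    with open(path, "w") as fh:
        if seed is not None:
            fh.write(f"# seed={seed}\n")
        fh.write("# " + "\t".join(HIT_COLUMNS) + "\n")
        hits.to_csv(fh, sep="\t", index=False, header=False)
    return len(hits)


def read_hits(path: Path | str) -> pd.DataFrame:
    return pd.read_csv(
        path, sep="\t", comment="#", names=list(HIT_COLUMNS), dtype={
            "qseqid": str, "sseqid": str,
        },
    )


def write_panel(samples: dict[str, list[float]], path: Path | str,
                seed: int | None = None) -> int:
    rows = [(node, v) for node in sorted(samples) for v in samples[node]]
    with open(path, "w") as fh:
        if seed is not None:
            fh.write(f"# seed={seed}\n")
        fh.write("node_id\tds\n")
        for node, v in rows:
            fh.write(f"{node}\t{v!r}\n")
    return len(rows)


def read_panel(path: Path | str) -> dict[str, list[float]]:
    df = pd.read_csv(path, sep="\t", comment="#")
    out: dict[str, list[float]] = {}
    for node, v in zip(df["node_id"], df["ds"]):
        out.setdefault(str(node), []).append(float(v))
    return out


def write_tsv(df: pd.DataFrame, path: Path | str, seed: int | None = None) -> int:
    with open(path, "w") as fh:
        if seed is not None:
            fh.write(f"# seed={seed}\n")
        df.to_csv(fh, sep="\t", index=False)
    return len(df)


def read_tsv(path: Path | str, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", **kwargs)
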