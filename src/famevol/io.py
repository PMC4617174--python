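"""Readers and writers for the pipeline's plain-text interchange formats.

Everything is TSV with documented headers (UTF-8, Unix newlines), FASTA via
biopython, Newick via the footprint module, plus SIF and JSON summaries for
network consumers.  Every writer's output round-trips through the matching
reader.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .expression import _validate_ct_table
from .retention import validate_synteny_table

__all__ = [
    "read_synteny_table", "write_synteny_table",
    "read_gene_order", "write_gene_order",
    "read_ct_table", "write_ct_table",
    "read_presence_matrix", "write_presence_matrix",
    "read_fasta", "write_fasta",
    "write_edge_list", "read_edge_list", "write_sif",
    "write_json", "read_json",
]


def read_synteny_table(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t", float_precision="round_trip")
    return validate_synteny_table(table)


def write_synteny_table(table: pd.DataFrame, path: str | Path) -> None:
    validate_synteny_table(table)
    table.to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_gene_order(path: str | Path) -> pd.DataFrame:
    order = pd.read_csv(path, sep="\t", float_precision="round_trip")
    missing = {"chrom", "position", "gene_id"} - set(order.columns)
    if missing:
        raise ValueError(f"gene order missing columns: {sorted(missing)}")
    return order


def write_gene_order(order: pd.DataFrame, path: str | Path) -> None:
    order.to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_ct_table(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t", float_precision="round_trip")
    _validate_ct_table(table)
    return table


def write_ct_table(table: pd.DataFrame, path: str | Path) -> None:
    _validate_ct_table(table)
    table.to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_presence_matrix(path: str | Path) -> pd.DataFrame:
    matrix = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    matrix.index.name = "member"
    return matrix


def write_presence_matrix(matrix: pd.DataFrame, path: str | Path) -> None:
    matrix.to_csv(path, sep="\t", lineterminator="\n")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: Mapping[str, str], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="")
        for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def write_edge_list(edges: pd.DataFrame, path: str | Path) -> None:
    edges.to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_edge_list(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", float_precision="round_trip")


def write_sif(edges: pd.DataFrame, path: str | Path, interaction: str = "pcc") -> None:
    """Simple interaction format: gene_a <interaction><sign> gene_b."""
    lines = [
        f"{row.gene_a}\t{interaction}{row.sign}\t{row.gene_b}"
        for row in edges.itertuples()
    ]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def read_json(path: str | Path):
    return json.loads(Path(path).read_text())
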