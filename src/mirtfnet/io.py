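"""Readers and writers for the pipeline's standard file formats.

Expression matrices, sample annotations, probe maps and pair tables travel as
plain TSV; promoters as FASTA (Biopython SeqIO); TF motifs as JASPAR PFM text
(Biopython Bio.motifs); networks as edge-list TSV or GraphML for Cytoscape.
"""

from __future__ import annotations

import io as _io

import networkx as nx
import numpy as np
import pandas as pd
from Bio import SeqIO, motifs
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from mirtfnet.motifscan import ALPHABET, PFMRecord
from mirtfnet.preprocess import ExpressionProfile

__all__ = [
    "write_expression",
    "read_expression",
    "write_annotation",
    "read_annotation",
    "read_profile",
    "write_fasta",
    "read_fasta",
    "write_jaspar",
    "read_jaspar",
    "write_pairs",
    "read_pairs",
    "write_graphml",
]


def write_expression(values: pd.DataFrame, path) -> None:
    """Feature x sample matrix as TSV: header of sample ids, first column id."""
    values.to_csv(path, sep="\t", index_label="feature_id")


def read_expression(path) -> pd.DataFrame:
    values = pd.read_csv(path, sep="\t", index_col="feature_id")
    values.index.name = None
    return values


def write_annotation(group: pd.Series, path) -> None:
    """Sample annotation TSV: sample id and group in {tumor, normal}."""
    table = pd.DataFrame(
        {
            "sample_id": group.index,
            "group": np.where(group.to_numpy() == 1, "tumor", "normal"),
        }
    )
    table.to_csv(path, sep="\t", index=False)


def read_annotation(path) -> pd.Series:
    table = pd.read_csv(path, sep="\t")
    group = pd.Series(
        (table["group"] == "tumor").astype(int).to_numpy(), index=table["sample_id"]
    )
    group.index.name = None
    return group


def read_profile(expression_path, annotation_path) -> ExpressionProfile:
    """Load a matrix + annotation pair into an ExpressionProfile."""
    return ExpressionProfile(
        read_expression(expression_path), read_annotation(annotation_path)
    )


def write_fasta(sequences: dict[str, str], path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    SeqIO.write(records, path, "fasta")


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(path, "fasta")}


def write_jaspar(pfms: list[PFMRecord], path) -> None:
    """Write PFMs as JASPAR text (">ID NAME" header, 4 labelled count rows)."""
    with open(path, "w") as handle:
        for pfm in pfms:
            handle.write(f">{pfm.tf_id} {pfm.tf_id}\n")
            for i, base in enumerate(ALPHABET):
                counts = " ".join(
                    f"{c:g}" for c in np.asarray(pfm.counts, dtype=float)[i]
                )
                handle.write(f"{base} [ {counts} ]\n")


def read_jaspar(path) -> list[PFMRecord]:
    """Read JASPAR PFM text into PFMRecords via Bio.motifs."""
    with open(path) as handle:
        parsed = motifs.parse(handle, "jaspar")
    out = []
    for motif in parsed:
        counts = np.array([list(motif.counts[base]) for base in ALPHABET], dtype=float)
        out.append(PFMRecord(tf_id=motif.matrix_id or motif.name, counts=counts))
    return out


def write_pairs(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_pairs(path, columns=("mirna", "tf")) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in columns if c not in table.columns]
    if missing:
        raise ValueError(f"pair table {path} lacks columns {missing}")
    return table


def write_graphml(g: nx.Graph, path) -> None:
    nx.write_graphml(g, path)


def jaspar_roundtrip(pfms: list[PFMRecord]) -> list[PFMRecord]:
    """Serialize PFMs to JASPAR text in memory and parse them back."""
    buf = _io.StringIO()
    for pfm in pfms:
        buf.write(f">{pfm.tf_id} {pfm.tf_id}\n")
        for i, base in enumerate(ALPHABET):
            counts = " ".join(f"{c:g}" for c in np.asarray(pfm.counts, dtype=float)[i])
            buf.write(f"{base} [ {counts} ]\n")
    buf.seek(0)
    parsed = motifs.parse(buf, "jaspar")
    return [
        PFMRecord(
            tf_id=m.matrix_id or m.name,
            counts=np.array([list(m.counts[b]) for b in ALPHABET], dtype=float),
        )
        for m in parsed
    ]
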