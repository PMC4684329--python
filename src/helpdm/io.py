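"""Readers and writers for the pipeline's plain-text interchange formats.

BED is 0-based half-open and round-trips natively.  The gene TSV dialect is
declared 1-based inclusive on disk (the convention of most gene-model
dumps) and converted to the internal 0-based representation on read.
Matrices are TSV with a header row of sample ids and feature ids in the
first column; missing values are written as ``.``.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from helpdm.paired import PairedDesign

NA_REP = "."


def read_bed(path) -> pd.DataFrame:
    """Read BED3/BED6 into (locus_id, chrom, start, end[, name fields]).

    Malformed lines (too few columns, non-integer or inverted coordinates)
    raise a ``ValueError`` naming the line number.  When the BED has no
    name column, ids are synthesized as ``chrom:start-end``.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: expected >= 3 BED columns")
            chrom = parts[0]
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates")
            if start < 0 or start >= end:
                raise ValueError(
                    f"{path}:{lineno}: require 0 <= start < end, got {start}, {end}"
                )
            name = parts[3] if len(parts) > 3 and parts[3] != NA_REP else None
            rows.append(
                {
                    "locus_id": name or f"{chrom}:{start}-{end}",
                    "chrom": chrom,
                    "start": start,
                    "end": end,
                }
            )
    return pd.DataFrame(rows, columns=["locus_id", "chrom", "start", "end"])


def write_bed(df: pd.DataFrame, path, name_col: str = "locus_id") -> None:
    out = df[["chrom", "start", "end"]].copy()
    out["name"] = df[name_col] if name_col in df.columns else NA_REP
    out.to_csv(path, sep="\t", header=False, index=False)


def read_genes_tsv(path) -> pd.DataFrame:
    """Read a gene-model TSV (chrom, strand, tss, tes, gene_id; 1-based).

    Positions are converted to the internal 0-based convention by
    subtracting 1 from both ``tss`` and ``tes``.
    """
    df = pd.read_csv(path, sep="\t")
    required = {"gene_id", "chrom", "strand", "tss", "tes"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing gene columns {sorted(missing)}")
    df = df.copy()
    df["tss"] = df["tss"].astype(int) - 1
    df["tes"] = df["tes"].astype(int) - 1
    return df[["gene_id", "chrom", "strand", "tss", "tes"]]


def write_genes_tsv(genes: pd.DataFrame, path) -> None:
    out = genes.copy()
    out["tss"] = out["tss"].astype(int) + 1
    out["tes"] = out["tes"].astype(int) + 1
    out.to_csv(path, sep="\t", index=False)


def read_matrix(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=[NA_REP])
    df.index = df.index.astype(str)
    return df


def write_matrix(matrix: pd.DataFrame, path) -> None:
    matrix.to_csv(path, sep="\t", na_rep=NA_REP)


def read_sample_sheet(path) -> tuple[pd.DataFrame, PairedDesign]:
    """Read and validate the sample sheet; returns (sheet, design)."""
    sheet = pd.read_csv(path, sep="\t", dtype=str)
    design = PairedDesign.from_sample_sheet(sheet)
    return sheet, design


def write_sample_sheet(design: PairedDesign, path) -> None:
    rows = []
    for s, t, n in zip(design.subjects, design.tumor, design.normal):
        rows.append({"sample_id": t, "subject_id": s, "tissue": "T"})
        rows.append({"sample_id": n, "subject_id": s, "tissue": "NT"})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: Mapping[str, str], path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def write_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, na_rep=NA_REP)
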