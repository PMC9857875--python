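"""File-format helpers: FASTA/FASTQ via Biopython, TSV tables via pandas."""

from __future__ import annotations

from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

SEGMENT_COLUMNS = ["sample", "chrom", "start", "end", "total_cn", "minor_cn"]
MAF_COLUMNS = ["sample", "chrom", "pos", "ref", "alt", "variant_classification", "gene"]


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: dict[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fastq_sequences(path: str | Path) -> list[str]:
    return [str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fastq")]


def write_fastq(reads: list[tuple[str, str]], path: str | Path) -> None:
    """Write (read_id, sequence) pairs with uniform placeholder qualities."""
    with open(path, "w") as fh:
        for read_id, seq in reads:
            fh.write(f"@{read_id}\n{seq}\n+\n{'I' * len(seq)}\n")


def read_segments(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(SEGMENT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"segment file missing columns: {sorted(missing)}")
    return df[SEGMENT_COLUMNS].astype(
        {"start": int, "end": int, "total_cn": int, "minor_cn": int}
    )


def write_segments(df: pd.DataFrame, path: str | Path) -> None:
    df[SEGMENT_COLUMNS].to_csv(path, sep="\t", index=False)


def read_maf(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(MAF_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"mutation file missing columns: {sorted(missing)}")
    return df[MAF_COLUMNS]


def write_maf(df: pd.DataFrame, path: str | Path) -> None:
    df[MAF_COLUMNS].to_csv(path, sep="\t", index=False)


def read_clinical(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="sample_id")


def write_clinical(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index_label="sample_id")
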