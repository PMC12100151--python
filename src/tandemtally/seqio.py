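"""FASTA/FASTQ/TSV readers and writers shared by all stages.

Gzip is transparent on read and write (by ``.gz`` extension). FASTQ is
4-line Phred+33. Tabular outputs carry ``#``-prefixed header comment lines
(tool version, config hash, seed) that pandas skips on read.
"""

from __future__ import annotations

import gzip
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .simulate import SimBatch, SimRead

__all__ = [
    "open_text",
    "read_fasta",
    "write_fasta",
    "read_fastq",
    "write_fastq",
    "write_truth",
    "read_table",
    "write_table",
]


def open_text(path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return path.open(mode)


def read_fasta(path) -> dict[str, str]:
    """id -> sequence for every record (order-preserving dict)."""
    with open_text(path) as fh:
        return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(fh, "fasta")}


def write_fasta(records: dict[str, str], path, width: int = 60) -> None:
    recs = [SeqRecord(Seq(s), id=name, description="") for name, s in records.items()]
    with open_text(path, "wt") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(recs)


def read_fastq(path) -> list[tuple[str, str]]:
    """(read_id, sequence) pairs; qualities are not needed downstream."""
    with open_text(path) as fh:
        return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(fh, "fastq")]


def write_fastq(batch: SimBatch | list[SimRead], path) -> None:
    reads = batch.reads if isinstance(batch, SimBatch) else batch
    with open_text(path, "wt") as fh:
        for r in reads:
            fh.write(f"@{r.read_id}\n{r.sequence}\n+\n{r.quality}\n")


def write_truth(batch: SimBatch, path, header_lines: list[str] | None = None) -> None:
    df = batch.truth.reset_index()
    write_table(df, path, header_lines)


def write_table(df: pd.DataFrame, path, header_lines: list[str] | None = None) -> None:
    with open_text(path, "wt") as fh:
        for line in header_lines or []:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")
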