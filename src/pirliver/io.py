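"""Readers/writers for the plain-text formats the pipeline exchanges.

FASTA/FASTQ go through Biopython; tables are tab-separated pandas frames.
All coordinates on disk are BED-style 0-based half-open.
"""
from __future__ import annotations

from pathlib import Path
from typing import Iterable, Iterator, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


class FastqParseError(ValueError):
    """Raised when a FASTQ record cannot be parsed; names the record index."""


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an ordered {id: sequence} dict."""
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        out[rec.id] = str(rec.seq).upper()
    return out


def write_fasta(records: Mapping[str, str] | Iterable[tuple[str, str]],
                path: str | Path) -> None:
    items = records.items() if isinstance(records, Mapping) else records
    recs = [SeqRecord(Seq(seq), id=name, description="") for name, seq in items]
    with open(path, "w") as fh:
        SeqIO.write(recs, fh, "fasta")


def iter_fastq(path: str | Path) -> Iterator[tuple[str, str]]:
    """Yield (read id, sequence) from a FASTQ file, wrapping parse failures."""
    with open(path) as fh:
        it = SeqIO.parse(fh, "fastq")
        i = 0
        while True:
            try:
                rec = next(it)
            except StopIteration:
                return
            except ValueError as exc:
                raise FastqParseError(f"{path}: record {i}: {exc}") from exc
            yield rec.id, str(rec.seq).upper()
            i += 1


def write_fastq(records: Iterable[tuple[str, str]], path: str | Path,
                quality_char: str = "I") -> int:
    """Write (id, sequence) records as 4-line FASTQ with constant quality."""
    n = 0
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f"@{name}\n{seq}\n+\n{quality_char * len(seq)}\n")
            n += 1
    return n


BED6_COLUMNS = ["contig", "start", "end", "name", "score", "strand"]


def read_bed(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df.columns = BED6_COLUMNS[: df.shape[1]]
    return df


def write_bed(df: pd.DataFrame, path: str | Path) -> None:
    cols = [c for c in BED6_COLUMNS if c in df.columns]
    df[cols].to_csv(path, sep="\t", header=False, index=False)


def read_table(path: str | Path, index_col=None) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col)


def write_table(df: pd.DataFrame, path: str | Path, index: bool = True) -> None:
    df.to_csv(path, sep="\t", index=index)
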