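"""FASTA/FASTQ and tabular I/O (gzip-aware) for the pipeline.

Sequence parsing is delegated to Biopython; this layer adds alphabet
validation, uppercasing and error messages that point at the offending
record/line.
"""

from __future__ import annotations

import gzip
import logging
import warnings
from pathlib import Path
from typing import Iterable

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .core import ReadRecord
from .seq import validate_alphabet

logger = logging.getLogger(__name__)

_GZIP_MAGIC = b"\x1f\x8b"


def _open_text(path: str | Path):
    path = Path(path)
    with open(path, "rb") as fh:
        magic = fh.read(2)
    if magic == _GZIP_MAGIC:
        return gzip.open(path, "rt")
    return open(path, "rt")


def _line_of_record(path: Path, index: int, fmt: str) -> int:
    # best-effort line estimate for error messages
    return index * (4 if fmt == "fastq" else 2) + 1


def _parse(path: str | Path, fmt: str) -> list[ReadRecord]:
    path = Path(path)
    records: list[ReadRecord] = []
    with _open_text(path) as handle:
        try:
            for i, rec in enumerate(SeqIO.parse(handle, fmt)):
                seq = str(rec.seq).upper()
                try:
                    validate_alphabet(seq, name=f"record {rec.id!r}")
                except ValueError as exc:
                    raise ValueError(
                        f"{path}: near line {_line_of_record(path, i, fmt)}: {exc}"
                    ) from exc
                qual = None
                if fmt == "fastq":
                    phred = rec.letter_annotations["phred_quality"]
                    qual = "".join(chr(q + 33) for q in phred)
                records.append(ReadRecord(rec.id, seq, quality=qual))
        except ValueError as exc:
            raise ValueError(f"{path}: malformed {fmt.upper()} record: {exc}") from exc
    if not records:
        warnings.warn(f"{path}: no records found", stacklevel=2)
    return records


def read_fasta(path: str | Path) -> list[ReadRecord]:
    """Read a (possibly gzipped) FASTA file into ``ReadRecord`` objects."""
    return _parse(path, "fasta")


def read_fastq(path: str | Path) -> list[ReadRecord]:
    """Read a (possibly gzipped) FASTQ file into ``ReadRecord`` objects."""
    return _parse(path, "fastq")


def read_sequences(path: str | Path) -> list[ReadRecord]:
    """Read FASTA or FASTQ, sniffing the format from the first character."""
    with _open_text(path) as fh:
        first = fh.read(1)
    if first == "@":
        return read_fastq(path)
    return read_fasta(path)


def write_fasta(records: Iterable[ReadRecord], path: str | Path) -> None:
    recs = [
        SeqRecord(Seq(r.sequence), id=r.read_id, description="") for r in records
    ]
    SeqIO.write(recs, str(path), "fasta")


def write_fastq(records: Iterable[ReadRecord], path: str | Path) -> None:
    recs = []
    for r in records:
        qual = r.quality if r.quality is not None else "5" * len(r.sequence)
        rec = SeqRecord(Seq(r.sequence), id=r.read_id, description="")
        rec.letter_annotations["phred_quality"] = [ord(c) - 33 for c in qual]
        recs.append(rec)
    SeqIO.write(recs, str(path), "fastq")


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)
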