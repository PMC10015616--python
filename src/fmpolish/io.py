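"""FASTA/FASTQ input and output (plain or gzipped) and TSV reports."""

from __future__ import annotations

import gzip
from typing import Iterable, Sequence

from Bio import SeqIO

from .bwt import ShortReadSet
from .simulate import ManifestRecord


def _open_text(path, mode="rt"):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def _guess_format(path) -> str:
    name = str(path)
    if name.endswith(".gz"):
        name = name[:-3]
    if name.endswith((".fq", ".fastq")):
        return "fastq"
    return "fasta"


def read_sequences(path) -> list[tuple[str, str]]:
    """All records of a FASTA/FASTQ file as (name, sequence) pairs."""
    fmt = _guess_format(path)
    with _open_text(path) as fh:
        records = [(rec.id, str(rec.seq)) for rec in SeqIO.parse(fh, fmt)]
    if not records:
        raise ValueError(f"{path}: no sequences found")
    return records


def read_short_reads(paths: Sequence) -> ShortReadSet:
    """Load one or more FASTA/FASTQ files into a ShortReadSet."""
    reads: list[str] = []
    names: list[str] = []
    for path in paths:
        for name, seq in read_sequences(path):
            names.append(name)
            reads.append(seq)
    return ShortReadSet(reads, names)


def write_fasta(path, records: Iterable[tuple[str, str]], width: int = 70) -> None:
    with _open_text(path, "wt") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_fastq(path, read_set: ShortReadSet, quality_char: str = "I") -> None:
    names = read_set.source_names or [f"read_{i}" for i in range(len(read_set.reads))]
    with _open_text(path, "wt") as fh:
        for name, seq in zip(names, read_set.reads):
            fh.write(f"@{name}\n{seq}\n+\n{quality_char * len(seq)}\n")


def write_manifest_tsv(path, manifest: Sequence[ManifestRecord]) -> None:
    with _open_text(path, "wt") as fh:
        fh.write("position\ttype\tref\talt\n")
        for rec in manifest:
            fh.write(f"{rec.position}\t{rec.type}\t{rec.ref}\t{rec.alt}\n")


def read_manifest_tsv(path) -> list[ManifestRecord]:
    records: list[ManifestRecord] = []
    with _open_text(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != ["position", "type", "ref", "alt"]:
            raise ValueError(f"{path}: not a manifest TSV")
        for line in fh:
            pos, typ, ref, alt = (line.rstrip("\n").split("\t") + ["", ""])[:4]
            records.append(ManifestRecord(int(pos), typ, ref, alt))
    return records


def write_tsv(path, rows: Sequence[dict]) -> None:
    """Write homogeneous dict rows as a TSV with a header line."""
    rows = list(rows)
    if not rows:
        raise ValueError("no rows to write")
    cols = list(rows[0])
    with _open_text(path, "wt") as fh:
        fh.write("\t".join(cols) + "\n")
        for row in rows:
            fh.write("\t".join(str(row[c]) for c in cols) + "\n")
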