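"""Read-set container and FASTQ/FASTA input/output.

A :class:`ReadSet` is an in-memory, order-preserving collection of
single-end reads stored as parallel lists, cheap to slice and subsample
(selection copies references, not strings). Streaming FASTQ iteration is
available for inputs that should not be held in memory.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Iterator, NamedTuple

from Bio import SeqIO
from Bio.SeqIO.QualityIO import FastqGeneralIterator

#: Reserved delimiter separating a read id from its provenance tag
#: (the id of the gene the read was simulated from).
PROVENANCE_DELIMITER = "|"


class ReadRecord(NamedTuple):
    """One single-end read: identifier, nucleotide string, quality string."""

    id: str
    seq: str
    qual: str


@dataclass
class ReadSet:
    """An ordered collection of reads held as parallel lists."""

    ids: list[str] = field(default_factory=list)
    seqs: list[str] = field(default_factory=list)
    quals: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not (len(self.ids) == len(self.seqs) == len(self.quals)):
            raise ValueError("ids, seqs and quals must have equal length")

    def __len__(self) -> int:
        return len(self.ids)

    def __iter__(self) -> Iterator[ReadRecord]:
        return map(ReadRecord, self.ids, self.seqs, self.quals)

    def __getitem__(self, i: int) -> ReadRecord:
        return ReadRecord(self.ids[i], self.seqs[i], self.quals[i])

    def select(self, indices: Iterable[int]) -> "ReadSet":
        """New ReadSet containing the records at ``indices``, in that order."""
        idx = list(indices)
        return ReadSet(
            [self.ids[i] for i in idx],
            [self.seqs[i] for i in idx],
            [self.quals[i] for i in idx],
        )

    @classmethod
    def from_records(cls, records: Iterable[ReadRecord]) -> "ReadSet":
        rs = cls()
        for r in records:
            rs.ids.append(r.id)
            rs.seqs.append(r.seq)
            rs.quals.append(r.qual)
        return rs

    @classmethod
    def from_fastq(cls, path: str | os.PathLike) -> "ReadSet":
        return cls.from_records(iter_fastq(path))

    def to_fastq(self, path: str | os.PathLike) -> None:
        write_fastq(self, path)

    def provenance_tags(self) -> list[str]:
        """Source-gene tags parsed from read ids (``readNNN|geneNNN``)."""
        tags = []
        for rid in self.ids:
            if PROVENANCE_DELIMITER not in rid:
                raise ValueError(f"read id {rid!r} carries no provenance tag")
            tags.append(rid.rsplit(PROVENANCE_DELIMITER, 1)[1])
        return tags


def iter_fastq(path: str | os.PathLike) -> Iterator[ReadRecord]:
    """Stream FASTQ records (Phred+33) without loading the file."""
    with open(path) as fh:
        it = FastqGeneralIterator(fh)
        i = 0
        while True:
            try:
                title, seq, qual = next(it)
            except StopIteration:
                return
            except ValueError as e:
                raise ValueError(f"malformed FASTQ record {i}: {e}") from e
            yield ReadRecord(title.split()[0], seq, qual)
            i += 1


def write_fastq(reads: Iterable[ReadRecord], path: str | os.PathLike) -> None:
    # Plain 4-line records; the Biopython writer is needlessly slow at
    # millions of reads for a format this simple.
    with open(path, "w") as fh:
        buf: list[str] = []
        for r in reads:
            buf.append(f"@{r.id}\n{r.seq}\n+\n{r.qual}\n")
            if len(buf) >= 10_000:
                fh.write("".join(buf))
                buf.clear()
        fh.write("".join(buf))


def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    """FASTA file -> ordered mapping of sequence id to sequence."""
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(os.fspath(path), "fasta")}


def write_fasta(sequences: dict[str, str], path: str | os.PathLike, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
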