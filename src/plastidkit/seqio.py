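"""FASTA/FASTQ input and output and read quality filtering.

Sequence records are lightweight carriers for both genomes (plastome-scale,
~160 kb) and short shotgun reads.  Parsing is delegated to Biopython's
low-level iterators; gzip compression is handled transparently by the
``.gz`` suffix.  The quality filter implements a median-Phred rule: a read
is kept iff its length is at least ``min_len`` and the median of its Phred
scores is at least ``min_median_q`` (both comparisons inclusive).
"""

from __future__ import annotations

import gzip
import statistics
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Iterator, Optional, Sequence

from Bio.SeqIO.FastaIO import SimpleFastaParser
from Bio.SeqIO.QualityIO import FastqGeneralIterator

__all__ = [
    "SeqRecord",
    "SeqParseError",
    "read_sequences",
    "write_fasta",
    "write_fastq",
    "quality_filter",
]

PHRED_OFFSET = 33  # Sanger / Illumina 1.8+


class SeqParseError(ValueError):
    """Raised on malformed FASTA/FASTQ input; names the offending record."""


@dataclass
class SeqRecord:
    """A named DNA sequence with optional per-base Phred qualities.

    Parameters
    ----------
    id:
        Record identifier (first whitespace-delimited token of the header).
    sequence:
        Uppercase string over ``{A, C, G, T, N}`` (other IUPAC codes are
        tolerated but treated as ambiguous downstream).
    qualities:
        Per-base Phred scores, same length as ``sequence``, or ``None`` for
        FASTA input.
    """

    id: str
    sequence: str
    qualities: Optional[list[int]] = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"record {self.id!r}: empty sequence")
        if self.qualities is not None and len(self.qualities) != len(self.sequence):
            raise SeqParseError(
                f"record {self.id!r}: sequence length {len(self.sequence)} != "
                f"quality length {len(self.qualities)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


def _open_text(path: Path, mode: str = "rt") -> IO[str]:
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def _detect_format(path: Path) -> str:
    suffixes = [s.lower() for s in path.suffixes]
    if suffixes and suffixes[-1] == ".gz":
        suffixes = suffixes[:-1]
    ext = suffixes[-1] if suffixes else ""
    if ext in (".fa", ".fasta", ".fna", ".ffn"):
        return "fasta"
    if ext in (".fq", ".fastq"):
        return "fastq"
    raise ValueError(f"cannot detect sequence format from {path.name!r}")


def read_sequences(path: str | Path, format: str = "auto") -> Iterator[SeqRecord]:
    """Yield :class:`SeqRecord` from a FASTA or FASTQ file (plain or gzip).

    ``format`` is ``"fasta"``, ``"fastq"`` or ``"auto"`` (detect from the
    extension).  Lowercase bases are uppercased.  A FASTQ record whose
    quality string length differs from its sequence length raises
    :class:`SeqParseError` naming the record.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = _detect_format(path) if format == "auto" else format
    if fmt not in ("fasta", "fastq"):
        raise ValueError(f"unknown format {fmt!r}")

    with _open_text(path) as handle:
        if fmt == "fasta":
            for title, seq in SimpleFastaParser(handle):
                rid = title.split()[0] if title.split() else title
                yield SeqRecord(rid, seq.upper())
        else:
            try:
                for title, seq, qual in FastqGeneralIterator(handle):
                    rid = title.split()[0] if title.split() else title
                    if len(seq) != len(qual):
                        raise SeqParseError(
                            f"record {rid!r}: sequence/quality length mismatch"
                        )
                    quals = [ord(c) - PHRED_OFFSET for c in qual]
                    yield SeqRecord(rid, seq.upper(), quals)
            except ValueError as exc:
                if isinstance(exc, SeqParseError):
                    raise
                raise SeqParseError(str(exc)) from exc


def write_fasta(records: Iterable[SeqRecord], path: str | Path, width: int = 80) -> None:
    path = Path(path)
    with _open_text(path, "wt") as handle:
        for rec in records:
            handle.write(f">{rec.id}\n")
            for i in range(0, len(rec.sequence), width):
                handle.write(rec.sequence[i : i + width] + "\n")


def write_fastq(records: Iterable[SeqRecord], path: str | Path) -> None:
    path = Path(path)
    with _open_text(path, "wt") as handle:
        for rec in records:
            if rec.qualities is None:
                raise ValueError(f"record {rec.id!r} has no qualities")
            qual = "".join(chr(q + PHRED_OFFSET) for q in rec.qualities)
            handle.write(f"@{rec.id}\n{rec.sequence}\n+\n{qual}\n")


def quality_filter(
    reads: Iterable[SeqRecord],
    min_median_q: int = 25,
    min_len: int = 100,
) -> Iterator[SeqRecord]:
    """Keep reads with length >= ``min_len`` and median Phred >= ``min_median_q``.

    Both thresholds are inclusive.  The median of an even-length quality
    list is the arithmetic mean of the two central order statistics.  Reads
    without qualities (FASTA input) are subject to the length rule only.
    Order is preserved and the filter is idempotent.
    """
    for read in reads:
        if len(read) < min_len:
            continue
        if read.qualities is not None:
            if statistics.median(read.qualities) < min_median_q:
                continue
        yield read
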