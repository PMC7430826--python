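"""SNP and indel calling from a multi-FASTA whole-genome alignment.

The caller scans alignment columns once per query sequence against a
designated reference.  Maximal runs of query gaps opposite reference bases
become a single deletion call; maximal runs of reference gaps become a
single insertion anchored at the preceding reference position; mismatched
bases become SNPs.  Coordinates are 1-based inclusive positions on the
reference's ungapped sequence, so a 17 bp deletion starting at reference
position 58,399 spans 58,399-58,415 (end - start + 1 = 17).  ``N`` in
either sequence is treated as missing data: no call is emitted and any
open indel run is closed.

Alignment construction is upstream (e.g. MAFFT); this module never aligns.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

__all__ = ["VariantCall", "call_variants", "variant_table", "read_variant_table"]


@dataclass(frozen=True)
class VariantCall:
    """A SNP, deletion, or insertion in reference coordinates.

    For a SNP ``length == 1`` and ``ref_start == ref_end``.  For a deletion
    ``length == ref_end - ref_start + 1`` and ``query_allele`` is empty.
    For an insertion the call is anchored at the reference position
    immediately before the inserted bases (``ref_start == ref_end``) and
    ``ref_allele`` is empty.  Alleles never contain gap characters.
    """

    kind: str  # "snp" | "deletion" | "insertion"
    ref_id: str
    query_id: str
    ref_start: int  # 1-based inclusive
    ref_end: int  # 1-based inclusive
    length: int
    ref_allele: str
    query_allele: str

    def __post_init__(self) -> None:
        if self.kind not in ("snp", "deletion", "insertion"):
            raise ValueError(f"unknown variant kind {self.kind!r}")
        if "-" in self.ref_allele or "-" in self.query_allele:
            raise ValueError("alleles must be gap-free")
        if self.kind == "snp" and not (self.length == 1 and self.ref_start == self.ref_end):
            raise ValueError("snp must have length 1 and ref_start == ref_end")
        if self.kind == "deletion" and self.length != self.ref_end - self.ref_start + 1:
            raise ValueError("deletion length inconsistent with coordinates")


def _pairwise_calls(ref_id: str, ref: str, query_id: str, query: str) -> list[VariantCall]:
    calls: list[VariantCall] = []
    ref_pos = 0  # count of reference non-gap characters seen so far

    del_start = None  # ref position of first deleted base
    del_bases: list[str] = []
    ins_anchor = None  # ref position preceding the insertion
    ins_bases: list[str] = []

    def flush_del() -> None:
        nonlocal del_start, del_bases
        if del_start is not None:
            calls.append(
                VariantCall(
                    kind="deletion",
                    ref_id=ref_id,
                    query_id=query_id,
                    ref_start=del_start,
                    ref_end=del_start + len(del_bases) - 1,
                    length=len(del_bases),
                    ref_allele="".join(del_bases),
                    query_allele="",
                )
            )
            del_start, del_bases = None, []

    def flush_ins() -> None:
        nonlocal ins_anchor, ins_bases
        if ins_anchor is not None:
            calls.append(
                VariantCall(
                    kind="insertion",
                    ref_id=ref_id,
                    query_id=query_id,
                    ref_start=ins_anchor,
                    ref_end=ins_anchor,
                    length=len(ins_bases),
                    ref_allele="",
                    query_allele="".join(ins_bases),
                )
            )
            ins_anchor, ins_bases = None, []

    for r, q in zip(ref, query):
        if r == "-" and q == "-":
            continue
        if r == "-":
            flush_del()
            if q == "N":
                flush_ins()
                continue
            if ins_anchor is None:
                ins_anchor = ref_pos
            ins_bases.append(q)
            continue
        # reference base
        ref_pos += 1
        flush_ins()
        if q == "-":
            if r == "N":
                flush_del()
                continue
            if del_start is None:
                del_start = ref_pos
            del_bases.append(r)
            continue
        flush_del()
        if r == "N" or q == "N":
            continue
        if r != q:
            calls.append(
                VariantCall(
                    kind="snp",
                    ref_id=ref_id,
                    query_id=query_id,
                    ref_start=ref_pos,
                    ref_end=ref_pos,
                    length=1,
                    ref_allele=r,
                    query_allele=q,
                )
            )
    flush_del()
    flush_ins()
    return calls


def call_variants(alignment: Sequence, ref_id: str) -> dict[str, list[VariantCall]]:
    """Call variants of every non-reference sequence against ``ref_id``.

    ``alignment`` is a list of aligned records (equal gapped lengths,
    ``-`` gaps).  Returns a mapping query_id -> calls in reference-position
    order.  Calls for one query are unaffected by the other sequences in
    the alignment.
    """
    by_id = {rec.id: rec.sequence.upper() for rec in alignment}
    if ref_id not in by_id:
        raise KeyError(f"reference {ref_id!r} not in alignment")
    lengths = {len(s) for s in by_id.values()}
    if len(lengths) > 1:
        raise ValueError(f"ragged alignment: lengths {sorted(lengths)}")
    ref = by_id[ref_id]
    return {
        qid: _pairwise_calls(ref_id, ref, qid, qseq)
        for qid, qseq in by_id.items()
        if qid != ref_id
    }


_COLUMNS = ["ref_id", "query_id", "kind", "ref_start", "ref_end", "length", "ref_allele", "query_allele"]


def variant_table(calls: Iterable[VariantCall], path: str | Path) -> None:
    """Write calls as a TSV with a stable column order."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(_COLUMNS)
        for c in calls:
            w.writerow(
                [c.ref_id, c.query_id, c.kind, c.ref_start, c.ref_end, c.length, c.ref_allele, c.query_allele]
            )


def read_variant_table(path: str | Path) -> list[VariantCall]:
    calls = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            calls.append(
                VariantCall(
                    kind=row["kind"],
                    ref_id=row["ref_id"],
                    query_id=row["query_id"],
                    ref_start=int(row["ref_start"]),
                    ref_end=int(row["ref_end"]),
                    length=int(row["length"]),
                    ref_allele=row["ref_allele"],
                    query_allele=row["query_allele"],
                )
            )
    return calls
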