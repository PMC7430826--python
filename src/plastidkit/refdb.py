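"""Kmer reference databases over labeled genomes.

A :class:`ReferenceDatabase` stores, for every reference genome, the sorted
set of distinct packed kmers it contains (presence sets, not counts), plus
the taxon each genome belongs to.  Multiple accessions may share a taxon —
e.g. several conspecific plastome assemblies — and the detection layer
pools their evidence at the taxon level.

The take-one-out derivation removes a single genome and rebuilds the
inverted index, supporting the cross-validation design in which reads from
an accession are only ever queried against databases that exclude that
accession's own assembly.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np

from .kmers import packed_kmers
from .seqio import SeqRecord

__all__ = ["ReferenceDatabase", "build_database", "take_one_out", "save_database", "load_database"]

FORMAT_VERSION = 1


class DatabaseFormatError(ValueError):
    """Raised when an on-disk database is corrupt or incompatible."""


@dataclass
class ReferenceDatabase:
    """Per-genome distinct-kmer sets with taxon labels and a global index.

    ``kmer_sets`` maps genome_id -> sorted ``uint64`` array of distinct
    packed kmers; ``taxon_of`` maps genome_id -> taxon_id.  The inverted
    kmer -> genomes index is implied by the per-genome sets and
    materialized lazily where needed (:meth:`genomes_with_kmer`); the
    union of all sets is cached for fast first-pass read screening.
    """

    k: int
    canonical: bool
    kmer_sets: dict[str, np.ndarray]
    taxon_of: dict[str, str]
    _union: Optional[np.ndarray] = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if set(self.kmer_sets) != set(self.taxon_of):
            raise ValueError("kmer_sets and taxon_of must cover the same genome ids")

    @property
    def genome_ids(self) -> list[str]:
        return sorted(self.kmer_sets)

    @property
    def taxa(self) -> list[str]:
        return sorted(set(self.taxon_of.values()))

    def genomes_of_taxon(self, taxon_id: str) -> list[str]:
        return sorted(g for g, t in self.taxon_of.items() if t == taxon_id)

    def union_kmers(self) -> np.ndarray:
        """Sorted distinct kmers over all genomes (cached)."""
        if self._union is None:
            arrays = list(self.kmer_sets.values())
            if arrays:
                self._union = np.unique(np.concatenate(arrays))
            else:
                self._union = np.empty(0, dtype=np.uint64)
        return self._union

    def taxon_union(self, taxon_id: str) -> np.ndarray:
        """Sorted distinct kmers over all genomes of one taxon."""
        arrays = [self.kmer_sets[g] for g in self.genomes_of_taxon(taxon_id)]
        if not arrays:
            return np.empty(0, dtype=np.uint64)
        return np.unique(np.concatenate(arrays))

    def genomes_with_kmer(self, kmer: int) -> list[str]:
        """Inverted-index lookup: genome ids whose set contains ``kmer``."""
        km = np.uint64(kmer)
        hits = []
        for gid, arr in self.kmer_sets.items():
            i = np.searchsorted(arr, km)
            if i < arr.size and arr[i] == km:
                hits.append(gid)
        return sorted(hits)


def build_database(
    genomes: Iterable[tuple[str, str, SeqRecord]],
    k: int = 31,
    canonical: bool = True,
    circular: bool = True,
) -> ReferenceDatabase:
    """Build a database from ``(taxon_id, genome_id, record)`` triples.

    Each genome contributes its set of distinct kmers; ``circular=True``
    includes the k-1 wrap-around windows (plastomes are circular
    molecules).  Duplicate genome ids are a build error.
    """
    kmer_sets: dict[str, np.ndarray] = {}
    taxon_of: dict[str, str] = {}
    for taxon_id, genome_id, rec in genomes:
        if genome_id in kmer_sets:
            raise ValueError(f"duplicate genome_id {genome_id!r}")
        if not rec.sequence:
            raise ValueError(f"genome {genome_id!r}: empty sequence")
        kms = packed_kmers(rec.sequence, k, canonical=canonical, circular=circular)
        kmer_sets[genome_id] = np.unique(kms)
        taxon_of[genome_id] = taxon_id
    return ReferenceDatabase(k=k, canonical=canonical, kmer_sets=kmer_sets, taxon_of=taxon_of)


def take_one_out(db: ReferenceDatabase, genome_id: str) -> ReferenceDatabase:
    """A new database with ``genome_id`` removed; the original is untouched."""
    if genome_id not in db.kmer_sets:
        raise KeyError(f"unknown genome_id {genome_id!r}")
    kmer_sets = {g: a for g, a in db.kmer_sets.items() if g != genome_id}
    taxon_of = {g: t for g, t in db.taxon_of.items() if g != genome_id}
    return ReferenceDatabase(k=db.k, canonical=db.canonical, kmer_sets=kmer_sets, taxon_of=taxon_of)


def save_database(db: ReferenceDatabase, path: str | Path) -> None:
    """Serialize to a single ``.npz``: JSON metadata header plus one sorted
    packed-kmer array per genome.  Round-trips bit-exactly."""
    path = Path(path)
    meta = {
        "format": "plastidkit-refdb",
        "version": FORMAT_VERSION,
        "k": db.k,
        "canonical": db.canonical,
        "genomes": [[g, db.taxon_of[g]] for g in db.genome_ids],
    }
    arrays = {f"kmers_{i}": db.kmer_sets[g] for i, g in enumerate(db.genome_ids)}
    with open(path, "wb") as fh:
        np.savez_compressed(fh, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **arrays)


def load_database(path: str | Path, expect_k: Optional[int] = None) -> ReferenceDatabase:
    path = Path(path)
    try:
        with np.load(path) as data:
            meta = json.loads(bytes(data["__meta__"]).decode())
            if meta.get("format") != "plastidkit-refdb":
                raise DatabaseFormatError(f"{path}: not a plastidkit reference database")
            if meta.get("version") != FORMAT_VERSION:
                raise DatabaseFormatError(f"{path}: unsupported version {meta.get('version')}")
            if expect_k is not None and meta["k"] != expect_k:
                raise DatabaseFormatError(f"{path}: database k={meta['k']} but k={expect_k} expected")
            kmer_sets = {}
            taxon_of = {}
            for i, (gid, taxon) in enumerate(meta["genomes"]):
                kmer_sets[gid] = data[f"kmers_{i}"].astype(np.uint64)
                taxon_of[gid] = taxon
    except DatabaseFormatError:
        raise
    except Exception as exc:
        raise DatabaseFormatError(f"{path}: cannot read database ({exc})") from exc
    return ReferenceDatabase(k=meta["k"], canonical=meta["canonical"], kmer_sets=kmer_sets, taxon_of=taxon_of)
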