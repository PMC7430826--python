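"""Read classification against a kmer reference database and detection calls.

Every read is decomposed into its (canonical, if the database is
canonical) packed kmers; a read's evidence for a genome is the number of
its kmers present in that genome's distinct-kmer set.  The read is
assigned to the genome with the most matching kmers provided that genome
covers at least ``min_fraction`` of the read's kmers (ties broken by
lexicographic genome id).  Evidence from multiple accessions of the same
taxon is pooled at the taxon level: a kmer supports a taxon if it occurs
in any of the taxon's genomes.

A taxon is *detected* when it accumulates at least ``min_reads`` assigned
reads and ``min_unique_kmers`` distinct matching kmers, and *supported*
when in addition the binomial tail probability of its total matched-kmer
count under the null rate ``p0 = |taxon kmer set| / 4^k`` per queried kmer
falls below ``alpha``.  A taxon passing the count thresholds but not the
tail test is reported detected but poorly supported.

The dilution series builds spiked mixtures over a fraction grid with
nested spike subsets per replicate (a larger fraction always includes the
reads of a smaller one), runs detection on each, and reports the limit of
detection: the smallest fraction supported in every replicate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .kmers import packed_kmers_matrix
from .refdb import ReferenceDatabase
from .seqio import SeqRecord
from .synthetic import MixtureComponent, MixtureSpec, build_mixture

__all__ = [
    "ReadAssignment",
    "TaxonResult",
    "DetectionReport",
    "assign_read",
    "assign_reads",
    "detect",
    "dilution_series",
    "take_one_out_accuracy",
]


@dataclass
class ReadAssignment:
    read_id: str
    n_kmers: int
    matches_per_genome: dict[str, int]
    best_genome: Optional[str]
    best_fraction: float


@dataclass
class TaxonResult:
    taxon_id: str
    total_matched_kmers: int
    assigned_reads: int
    unique_matched_kmers: int
    support_p: float
    detected: bool
    supported: bool


@dataclass
class DetectionReport:
    per_taxon: dict[str, TaxonResult]
    params: dict
    total_reads: int

    def detected_taxa(self) -> list[str]:
        return [t for t, r in self.per_taxon.items() if r.detected]

    def top_taxon(self) -> Optional[str]:
        """Detected taxon with the most matched kmers (ties: lexicographic)."""
        det = [(r.total_matched_kmers, t) for t, r in self.per_taxon.items() if r.detected]
        if not det:
            return None
        det.sort(key=lambda x: (-x[0], x[1]))
        return det[0][1]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "taxon": t,
                "assigned_reads": r.assigned_reads,
                "total_matched_kmers": r.total_matched_kmers,
                "unique_matched_kmers": r.unique_matched_kmers,
                "support_p": r.support_p,
                "detected": r.detected,
                "supported": r.supported,
            }
            for t, r in sorted(self.per_taxon.items())
        ]
        return pd.DataFrame(rows, columns=[
            "taxon", "assigned_reads", "total_matched_kmers", "unique_matched_kmers",
            "support_p", "detected", "supported",
        ])

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def _isin_sorted(values: np.ndarray, sorted_arr: np.ndarray) -> np.ndarray:
    """Membership of ``values`` in a sorted array, via binary search."""
    if sorted_arr.size == 0 or values.size == 0:
        return np.zeros(values.shape, dtype=bool)
    idx = np.searchsorted(sorted_arr, values)
    idx[idx == sorted_arr.size] = 0
    return sorted_arr[idx] == values


def _read_kmer_arrays(reads: Sequence[SeqRecord], db: ReferenceDatabase):
    """Packed kmers of all reads concatenated, with per-read ownership."""
    kmers, owner = packed_kmers_matrix([r.sequence for r in reads], db.k, canonical=db.canonical)
    n_kmers = np.bincount(owner, minlength=len(reads)) if owner.size else np.zeros(len(reads), dtype=int)
    return kmers, owner, n_kmers


def assign_reads(
    reads: Sequence[SeqRecord], db: ReferenceDatabase, min_fraction: float = 0.5
) -> list[ReadAssignment]:
    """Classify a batch of reads; vectorized over all reads at once."""
    if not db.kmer_sets:
        raise ValueError("empty reference database")
    genome_ids = db.genome_ids
    kmers, owner, n_kmers = _read_kmer_arrays(reads, db)

    # first pass: screen against the union of all genome sets, then resolve
    # per-genome membership only for kmers that hit anything at all
    union = db.union_kmers()
    hit = _isin_sorted(kmers, union)
    hk, ho = kmers[hit], owner[hit]

    n_reads, n_gen = len(reads), len(genome_ids)
    match_counts = np.zeros((n_reads, n_gen), dtype=np.int64)
    for gi, gid in enumerate(genome_ids):
        member = _isin_sorted(hk, db.kmer_sets[gid])
        if member.any():
            match_counts[:, gi] += np.bincount(ho[member], minlength=n_reads)

    best_idx = match_counts.argmax(axis=1)  # argmax takes the first max: lexicographic tie-break
    best_counts = match_counts[np.arange(n_reads), best_idx]
    out = []
    for i, read in enumerate(reads):
        nk = int(n_kmers[i])
        frac = best_counts[i] / nk if nk else 0.0
        assigned = nk > 0 and best_counts[i] > 0 and frac >= min_fraction
        out.append(
            ReadAssignment(
                read_id=read.id,
                n_kmers=nk,
                matches_per_genome={
                    gid: int(match_counts[i, gi])
                    for gi, gid in enumerate(genome_ids)
                    if match_counts[i, gi]
                },
                best_genome=genome_ids[best_idx[i]] if assigned else None,
                best_fraction=float(frac),
            )
        )
    return out


def assign_read(read: SeqRecord, db: ReferenceDatabase, min_fraction: float = 0.5) -> ReadAssignment:
    """Classify a single read (see :func:`assign_reads`)."""
    return assign_reads([read], db, min_fraction=min_fraction)[0]


def detect(
    reads: Sequence[SeqRecord],
    db: ReferenceDatabase,
    min_fraction: float = 0.5,
    min_reads: int = 10,
    min_unique_kmers: int = 100,
    alpha: float = 1e-6,
) -> DetectionReport:
    """Run the per-taxon detection test over a query read set."""
    if not db.kmer_sets:
        raise ValueError("empty reference database")
    params = {
        "k": db.k,
        "canonical": db.canonical,
        "min_fraction": min_fraction,
        "min_reads": min_reads,
        "min_unique_kmers": min_unique_kmers,
        "alpha": alpha,
    }
    genome_ids = db.genome_ids
    taxa = db.taxa
    kmers, owner, n_kmers = _read_kmer_arrays(reads, db)
    total_queried = int(kmers.size)

    union = db.union_kmers()
    hit = _isin_sorted(kmers, union)
    hk, ho = kmers[hit], owner[hit]

    n_reads, n_gen = len(reads), len(genome_ids)
    # per-genome per-read counts for read assignment
    match_counts = np.zeros((n_reads, n_gen), dtype=np.int64)
    for gi, gid in enumerate(genome_ids):
        member = _isin_sorted(hk, db.kmer_sets[gid])
        if member.any():
            match_counts[:, gi] += np.bincount(ho[member], minlength=n_reads)
    best_idx = match_counts.argmax(axis=1)
    best_counts = match_counts[np.arange(n_reads), best_idx] if n_reads else np.empty(0, int)
    assigned_mask = (n_kmers > 0) & (best_counts > 0) & (best_counts >= min_fraction * n_kmers)

    per_taxon: dict[str, TaxonResult] = {}
    gi_of = {g: i for i, g in enumerate(genome_ids)}
    for taxon in taxa:
        t_union = db.taxon_union(taxon)
        member = _isin_sorted(hk, t_union)
        total_matched = int(member.sum())
        unique_matched = int(np.unique(hk[member]).size) if total_matched else 0
        tax_gis = [gi_of[g] for g in db.genomes_of_taxon(taxon)]
        assigned = int(np.sum(assigned_mask & np.isin(best_idx, tax_gis))) if n_reads else 0
        p0 = min(1.0, t_union.size / float(4**db.k))
        if total_matched == 0 or total_queried == 0:
            support_p = 1.0
        else:
            support_p = float(stats.binom.sf(total_matched - 1, total_queried, p0))
        counts_ok = assigned >= min_reads and unique_matched >= min_unique_kmers
        per_taxon[taxon] = TaxonResult(
            taxon_id=taxon,
            total_matched_kmers=total_matched,
            assigned_reads=assigned,
            unique_matched_kmers=unique_matched,
            support_p=support_p,
            detected=counts_ok,
            supported=counts_ok and support_p < alpha,
        )
    return DetectionReport(per_taxon=per_taxon, params=params, total_reads=len(reads))


def dilution_series(
    db: ReferenceDatabase,
    background: Sequence[MixtureComponent],
    target_reads: Sequence[SeqRecord],
    target_taxon: str,
    fractions: Sequence[float],
    total_reads: int,
    seed: int = 0,
    replicates: int = 3,
    with_replacement: bool = False,
    **detect_kwargs,
) -> pd.DataFrame:
    """Spike-in dilution series with nested spike subsets per replicate.

    For each replicate r (seeded ``seed + r``) the target pool is shuffled
    once and the spike for every fraction is a prefix of that shuffle, so
    a larger fraction's spike is a superset of a smaller one's — the
    matched-kmer count is then monotone in the fraction by construction.
    Returns a tidy table (fraction, replicate, n_spike, detected,
    supported, assigned_reads, total_matched_kmers, unique_matched_kmers,
    support_p).  The limit of detection is the smallest fraction with
    ``supported`` true in all replicates (see :func:`limit_of_detection`).
    """
    if total_reads <= 0:
        raise ValueError("total_reads must be positive")
    if any(not (0 < f < 100) for f in fractions):
        raise ValueError("fractions must be in (0, 100)")
    rows = []
    for rep in range(replicates):
        rep_seed = seed + rep
        rng = np.random.default_rng(rep_seed)
        spike_order = rng.permutation(len(target_reads))
        for frac in sorted(fractions, reverse=True):
            n_spike = int(round(total_reads * frac / 100.0))
            if n_spike > len(target_reads) and not with_replacement:
                raise ValueError(
                    f"fraction {frac}% needs {n_spike} target reads but pool has {len(target_reads)}"
                )
            spike = [target_reads[i] for i in spike_order[:n_spike]]
            spec = MixtureSpec(
                components=list(background),
                spike_label=target_taxon,
                spike_reads=spike,
                spike_fraction=frac,
                total_reads=total_reads,
                seed=rep_seed,
                with_replacement=with_replacement,
            )
            # the spike subset is already chosen; sample exactly all of it
            mixture = build_mixture(spec)
            report = detect(mixture, db, **detect_kwargs)
            res = report.per_taxon.get(target_taxon)
            rows.append(
                {
                    "fraction": frac,
                    "replicate": rep,
                    "n_spike": n_spike,
                    "detected": bool(res.detected) if res else False,
                    "supported": bool(res.supported) if res else False,
                    "assigned_reads": res.assigned_reads if res else 0,
                    "total_matched_kmers": res.total_matched_kmers if res else 0,
                    "unique_matched_kmers": res.unique_matched_kmers if res else 0,
                    "support_p": res.support_p if res else 1.0,
                }
            )
    return pd.DataFrame(rows).sort_values(["fraction", "replicate"]).reset_index(drop=True)


def limit_of_detection(table: pd.DataFrame) -> Optional[float]:
    """Smallest fraction supported in all replicates, or None."""
    ok = table.groupby("fraction")["supported"].all()
    supported = ok[ok].index
    return float(supported.min()) if len(supported) else None


def take_one_out_accuracy(
    dbs: Sequence[ReferenceDatabase],
    held_out_read_sets: Sequence[Sequence[SeqRecord]],
    true_taxon: str,
    **detect_kwargs,
) -> tuple[float, list[DetectionReport]]:
    """Percent of (database, read set) trials ranking ``true_taxon`` first.

    Each read set must come from the accession omitted from its paired
    database.  Returns the percent correct and the per-trial reports.
    """
    if len(dbs) != len(held_out_read_sets):
        raise ValueError("dbs and read sets must pair one-to-one")
    reports = []
    correct = 0
    for db, reads in zip(dbs, held_out_read_sets):
        rep = detect(reads, db, **detect_kwargs)
        reports.append(rep)
        if rep.top_taxon() == true_taxon:
            correct += 1
    pct = 100.0 * correct / len(dbs) if dbs else 0.0
    return pct, reports
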