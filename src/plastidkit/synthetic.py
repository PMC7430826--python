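"""Synthetic genomes, reads, and read mixtures.

This module generates the study inputs at desk scale: circular
plastome-sized genomes at controlled divergence (conspecific accessions at
<= 0.1% pairwise divergence, congeners and other families at increasing
divergence), fixed-length 125 bp shotgun reads with an i.i.d. substitution
error model and constant quality strings, and background mixtures emulating
a metagenomic sample — three plant read pools at 30% each plus three
bacterial pools at 3.3% each — into which target plastome reads are spiked
at a chosen fraction.

All randomness flows through :class:`numpy.random.Generator` objects
seeded explicitly; the same seed reproduces byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from .seqio import SeqRecord
from .variants import VariantCall

__all__ = [
    "MixtureSpec",
    "MixtureComponent",
    "simulate_genome",
    "mutate_genome",
    "simulate_reads",
    "build_mixture",
    "true_alignment",
    "simulate_panel",
    "normalize_proportions",
    "PAPER_BACKGROUND",
    "DILUTION_FRACTIONS",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_CODE_OF = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE_OF[_b] = _i

# Background design of the mixture experiments: three plant genomes at 30%
# each and three bacterial "contaminant" genomes at 3.3% each.  These sum
# to 99.9; normalize_proportions() rescales them to exactly 100 while
# keeping the 30:30:30:3.3:3.3:3.3 ratios.
PAPER_BACKGROUND: list[tuple[str, float]] = [
    ("plantA", 30.0),
    ("plantB", 30.0),
    ("plantC", 30.0),
    ("bactA", 3.3),
    ("bactB", 3.3),
    ("bactC", 3.3),
]

# Spike-in dilution series (percent of total reads).
DILUTION_FRACTIONS: list[float] = [5.0, 2.5, 1.25, 0.6, 0.3, 0.15, 0.07, 0.03, 0.01]

READ_QUALITY = 37  # constant per-base Phred score; comfortably above the Q25 filter


def normalize_proportions(design: Sequence[tuple[str, float]]) -> list[tuple[str, float]]:
    """Rescale (label, percent) pairs to sum to exactly 100."""
    total = sum(p for _, p in design)
    if total <= 0:
        raise ValueError("proportions must have a positive sum")
    return [(label, 100.0 * p / total) for label, p in design]


def simulate_genome(length: int, seed: int, gc: float = 0.37, id: str = "genome") -> SeqRecord:
    """An i.i.d. random circular genome with expected GC content ``gc``.

    The default GC of 0.37 matches typical plastomes.  Deterministic for a
    given seed.
    """
    if length <= 0:
        raise ValueError("length must be positive")
    if not 0 < gc < 1:
        raise ValueError("gc must be in (0, 1)")
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    codes = rng.choice(4, size=length, p=p).astype(np.uint8)
    return SeqRecord(id, _BASES[codes].tobytes().decode("ascii"))


def _apply_explicit_variants(
    genome: SeqRecord, variants: Sequence[VariantCall], new_id: str
) -> SeqRecord:
    """Apply a list of variants (reference coordinates, 1-based inclusive)."""
    ordered = sorted(variants, key=lambda v: v.ref_start)
    for a, b in zip(ordered, ordered[1:]):
        if a.kind != "insertion" and b.ref_start <= a.ref_end:
            raise ValueError(f"overlapping variants at {a.ref_start} and {b.ref_start}")
    seq = genome.sequence
    out = []
    pos = 0  # 0-based cursor into reference
    for v in ordered:
        start0 = v.ref_start - 1
        if v.kind == "snp":
            out.append(seq[pos:start0])
            out.append(v.query_allele)
            pos = start0 + 1
        elif v.kind == "deletion":
            out.append(seq[pos:start0])
            pos = v.ref_end  # skip deleted bases
        elif v.kind == "insertion":
            # anchored after reference position ref_start
            out.append(seq[pos : v.ref_start])
            out.append(v.query_allele)
            pos = v.ref_start
        else:
            raise ValueError(f"unknown variant kind {v.kind!r}")
    out.append(seq[pos:])
    return SeqRecord(new_id, "".join(out))


def mutate_genome(
    genome: SeqRecord,
    sub_rate: float = 0.0,
    indel_rate: float = 0.0,
    max_indel: int = 10,
    seed: int = 0,
    variants: Optional[Sequence[VariantCall]] = None,
    new_id: Optional[str] = None,
) -> tuple[SeqRecord, list[VariantCall]]:
    """Derive an accession from ``genome`` and return it with ground truth.

    Either draw random substitutions/indels at the given per-base rates, or
    apply an explicit ``variants`` list (e.g. to plant a single 17 bp
    deletion at a known position).  The returned :class:`VariantCall` list
    uses 1-based inclusive reference coordinates and is exactly the truth
    set the alignment-column variant screen should recover.
    """
    if not (0 <= sub_rate < 1 and 0 <= indel_rate < 1):
        raise ValueError("rates must be in [0, 1)")
    new_id = new_id or f"{genome.id}_mut"
    if variants is not None:
        if sub_rate or indel_rate:
            raise ValueError("give either rates or an explicit variant list, not both")
        calls = [
            VariantCall(
                kind=v.kind,
                ref_id=genome.id,
                query_id=new_id,
                ref_start=v.ref_start,
                ref_end=v.ref_end,
                length=v.length,
                ref_allele=v.ref_allele,
                query_allele=v.query_allele,
            )
            for v in variants
        ]
        return _apply_explicit_variants(genome, calls, new_id), sorted(
            calls, key=lambda v: v.ref_start
        )

    rng = np.random.default_rng(seed)
    seq = genome.sequence
    L = len(seq)
    calls: list[VariantCall] = []

    # substitutions: binomial thinning of positions, forced base change
    n_sub = rng.binomial(L, sub_rate) if sub_rate > 0 else 0
    sub_pos = np.sort(rng.choice(L, size=n_sub, replace=False)) if n_sub else np.empty(0, int)
    codes = _CODE_OF[np.frombuffer(seq.encode(), dtype=np.uint8)].copy()
    for p in sub_pos:
        if codes[p] == 255:
            continue
        new = (codes[p] + rng.integers(1, 4)) % 4
        calls.append(
            VariantCall(
                kind="snp",
                ref_id=genome.id,
                query_id=new_id,
                ref_start=int(p) + 1,
                ref_end=int(p) + 1,
                length=1,
                ref_allele=seq[p],
                query_allele="ACGT"[new],
            )
        )
        codes[p] = new

    # indels: sample non-overlapping sites, deletion or insertion with equal odds
    if indel_rate > 0:
        n_indel = rng.binomial(L, indel_rate)
        taken: list[tuple[int, int]] = []
        attempts = 0
        while len(taken) < n_indel and attempts < 20 * max(1, n_indel):
            attempts += 1
            length = int(rng.integers(1, max_indel + 1))
            start = int(rng.integers(1, L - length))  # 1-based
            span = (start, start + length - 1)
            if any(s <= span[1] + 1 and span[0] <= e + 1 for s, e in taken):
                continue
            if any(span[0] <= c.ref_end + 1 and c.ref_start - 1 <= span[1] for c in calls if c.kind == "snp"):
                continue
            taken.append(span)
            if rng.random() < 0.5:
                calls.append(
                    VariantCall(
                        kind="deletion",
                        ref_id=genome.id,
                        query_id=new_id,
                        ref_start=start,
                        ref_end=start + length - 1,
                        length=length,
                        ref_allele=seq[start - 1 : start - 1 + length],
                        query_allele="",
                    )
                )
            else:
                ins = "".join("ACGT"[c] for c in rng.integers(0, 4, size=length))
                calls.append(
                    VariantCall(
                        kind="insertion",
                        ref_id=genome.id,
                        query_id=new_id,
                        ref_start=start,
                        ref_end=start,
                        length=length,
                        ref_allele="",
                        query_allele=ins,
                    )
                )

    mutated_seq = _BASES[np.clip(codes, 0, 3)].tobytes().decode("ascii")
    # restore any ambiguous bases untouched
    if (codes == 255).any():
        chars = list(mutated_seq)
        for p in np.nonzero(codes == 255)[0]:
            chars[p] = seq[p]
        mutated_seq = "".join(chars)
    base = SeqRecord(new_id, mutated_seq)
    indels = [c for c in calls if c.kind != "snp"]
    if indels:
        base = _apply_explicit_variants(base, indels, new_id)
    return base, sorted(calls, key=lambda v: (v.ref_start, v.kind))


def true_alignment(
    reference: SeqRecord, query: SeqRecord, variants: Sequence[VariantCall]
) -> tuple[SeqRecord, SeqRecord]:
    """The construction-true pairwise alignment implied by a variant list.

    Reference gaps are inserted opposite insertions and query gaps opposite
    deletions; substitutions align base-to-base.  The result is the exact
    alignment the variant caller should invert back to ``variants``.
    """
    ref = reference.sequence
    ra, qa = [], []
    pos = 0
    for v in sorted(variants, key=lambda v: (v.ref_start, 0 if v.kind != "insertion" else 1)):
        start0 = v.ref_start - 1
        if v.kind == "snp":
            ra.append(ref[pos : start0 + 1])
            qa.append(ref[pos:start0] + v.query_allele)
            pos = start0 + 1
        elif v.kind == "deletion":
            ra.append(ref[pos : v.ref_end])
            qa.append(ref[pos:start0] + "-" * v.length)
            pos = v.ref_end
        elif v.kind == "insertion":
            ra.append(ref[pos : v.ref_start] + "-" * v.length)
            qa.append(ref[pos : v.ref_start] + v.query_allele)
            pos = v.ref_start
    ra.append(ref[pos:])
    qa.append(ref[pos:])
    ref_aln = "".join(ra)
    qry_aln = "".join(qa)
    assert len(ref_aln) == len(qry_aln)
    return SeqRecord(reference.id, ref_aln), SeqRecord(query.id, qry_aln)


def simulate_reads(
    genome: SeqRecord,
    n_reads: int,
    read_len: int = 125,
    error_rate: float = 0.002,
    seed: int = 0,
    id_prefix: Optional[str] = None,
) -> list[SeqRecord]:
    """Fixed-length shotgun reads from a circular genome.

    Start positions are uniform over the circle, strands random, and
    substitution errors i.i.d. at ``error_rate`` per base.  Every read
    carries a constant quality string (Q37) so the whole set passes the
    median-Q25 / 100 bp filter; error simulation is independent of the
    quality model, as after upstream trimming.
    """
    if n_reads == 0:
        return []
    if len(genome) < read_len:
        raise ValueError("genome shorter than read length")
    rng = np.random.default_rng(seed)
    prefix = id_prefix or genome.id
    L = len(genome)
    doubled = np.frombuffer((genome.sequence + genome.sequence[: read_len - 1]).encode(), dtype=np.uint8)
    codes = _CODE_OF[doubled]
    starts = rng.integers(0, L, size=n_reads)
    mat = codes[starts[:, None] + np.arange(read_len)[None, :]].astype(np.uint8)
    # reverse-complement half the reads
    rev = rng.random(n_reads) < 0.5
    sub = mat[rev]
    mat[rev] = np.where(sub[:, ::-1] == 255, 255, 3 - sub[:, ::-1])
    # substitution errors (applied to ACGT positions only)
    if error_rate > 0:
        err = rng.random(mat.shape) < error_rate
        err &= mat != 255
        shift = rng.integers(1, 4, size=int(err.sum()))
        mat[err] = (mat[err] + shift) % 4
    chars = np.where(mat == 255, ord("N"), _BASES[np.clip(mat, 0, 3)]).astype(np.uint8)
    quals = [READ_QUALITY] * read_len
    reads = []
    for i in range(n_reads):
        reads.append(
            SeqRecord(
                f"{prefix}_r{i:07d}",
                chars[i].tobytes().decode("ascii"),
                list(quals),
            )
        )
    return reads


@dataclass
class MixtureComponent:
    label: str
    reads: list[SeqRecord]
    proportion: float  # percent of the background


@dataclass
class MixtureSpec:
    """Design of one spiked mixture.

    Background proportions must sum to 100; they are renormalized to
    ``100 - spike_fraction`` once the spike is added, so the output always
    totals ``total_reads``.
    """

    components: list[MixtureComponent]
    spike_label: str
    spike_reads: list[SeqRecord]
    spike_fraction: float  # percent of total
    total_reads: int
    seed: int = 0
    with_replacement: bool = False

    def __post_init__(self) -> None:
        s = sum(c.proportion for c in self.components)
        if abs(s - 100.0) > 1e-9:
            raise ValueError(f"background proportions sum to {s}, expected 100")
        if self.spike_fraction < 0:
            raise ValueError("spike fraction must be >= 0")
        if self.total_reads <= 0:
            raise ValueError("total_reads must be positive")


def _sample(pool: list[SeqRecord], n: int, rng: np.random.Generator, with_replacement: bool) -> list[SeqRecord]:
    if n == 0:
        return []
    if n > len(pool):
        if not with_replacement:
            raise ValueError(f"need {n} reads but pool has {len(pool)} (set with_replacement)")
        idx = rng.integers(0, len(pool), size=n)
    else:
        idx = rng.permutation(len(pool))[:n]
    return [pool[i] for i in idx]


def build_mixture(spec: MixtureSpec) -> list[SeqRecord]:
    """Assemble the spiked mixture described by ``spec``.

    The spike contributes ``round(total * fraction / 100)`` reads; the
    background components fill the remainder in their stated ratios
    (largest-remainder rounding, so component tallies are within one read
    of exact).  Read ids are prefixed with the component label and the
    final list is shuffled deterministically by the spec seed.
    """
    rng = np.random.default_rng(spec.seed)
    n_spike = int(round(spec.total_reads * spec.spike_fraction / 100.0))
    n_back = spec.total_reads - n_spike
    # largest-remainder apportionment of the background
    exact = np.array([c.proportion for c in spec.components]) / 100.0 * n_back
    counts = np.floor(exact).astype(int)
    rem = n_back - counts.sum()
    order = np.argsort(-(exact - counts))
    counts[order[:rem]] += 1

    out: list[SeqRecord] = []
    for comp, n in zip(spec.components, counts):
        for r in _sample(comp.reads, int(n), rng, spec.with_replacement):
            out.append(SeqRecord(f"{comp.label}|{r.id}", r.sequence, r.qualities))
    for r in _sample(spec.spike_reads, n_spike, rng, spec.with_replacement):
        out.append(SeqRecord(f"{spec.spike_label}|{r.id}", r.sequence, r.qualities))
    perm = rng.permutation(len(out))
    return [out[i] for i in perm]


# ---------------------------------------------------------------------------
# Study panel: conspecific accessions nested inside genus/family divergence
# ---------------------------------------------------------------------------

def simulate_panel(
    seed: int,
    genome_len: int = 158_900,
    n_accessions: int = 3,
    accession_div: float = 4e-4,
    genus_div: float = 0.01,
    family_div: float = 0.05,
    outgroup_div: float = 0.12,
) -> dict[str, list[tuple[str, str, SeqRecord]]]:
    """Simulate the reference panel used across the analyses.

    Returns a dict with keys ``target`` (``n_accessions`` conspecific
    accessions, pairwise divergence about ``2 * accession_div`` <= 0.1%),
    ``relatives`` (two congeners, two same-family species and two
    other-family species at nested divergence) and ``outgroup`` (one
    distant taxon), each a list of ``(taxon_id, genome_id, record)``
    triples ready for :func:`plastidkit.refdb.build_database`.

    Divergences are per-branch substitution rates from the shared
    ancestors, so sister taxa differ by roughly twice the stated rate.
    """
    rng = np.random.default_rng(seed)

    def sub_seed() -> int:
        return int(rng.integers(0, 2**31 - 1))

    ancestor = simulate_genome(genome_len, sub_seed(), id="anc")

    def derive(base: SeqRecord, rate: float, name: str) -> SeqRecord:
        rec, _ = mutate_genome(base, sub_rate=rate, seed=sub_seed(), new_id=name)
        return rec

    fam_anc = derive(ancestor, family_div, "famA_anc")
    genus_anc = derive(fam_anc, genus_div, "genusA_anc")
    species_anc = derive(genus_anc, accession_div, "target_anc")

    target = [
        ("target", f"target_acc{i+1}", derive(species_anc, accession_div, f"target_acc{i+1}"))
        for i in range(n_accessions)
    ]
    relatives = [
        ("congener1", "congener1", derive(genus_anc, genus_div, "congener1")),
        ("congener2", "congener2", derive(genus_anc, genus_div, "congener2")),
        ("famA_sp1", "famA_sp1", derive(fam_anc, family_div, "famA_sp1")),
        ("famA_sp2", "famA_sp2", derive(fam_anc, family_div, "famA_sp2")),
        ("famB_sp1", "famB_sp1", derive(ancestor, family_div, "famB_sp1")),
        ("famB_sp2", "famB_sp2", derive(ancestor, family_div, "famB_sp2")),
    ]
    outgroup = [("outgroup", "outgroup", derive(ancestor, outgroup_div, "outgroup"))]
    return {"target": target, "relatives": relatives, "outgroup": outgroup}
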