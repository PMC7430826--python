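# Methods

## Overview

`plastidkit` treats a chloroplast genome as a bag of kmers and asks three
questions: can a species be recognized from shotgun reads by kmer
membership against reference plastomes (identification); how small a
fraction of a mixed sample can still be recognized (limit of detection);
and do whole-genome kmer distances recover the expected relationships
among accessions and relatives (alignment-free phylogeny). A fourth,
auxiliary component screens aligned whole genomes for SNPs and indels.

All experiments run on synthetic data generated in-package, so every
claim is checked against a known ground truth. The generator's defaults
encode the study conditions; they are not tuning knobs.

## Sequence handling and quality filtering

Reads and genomes are plain `{A,C,G,T,N}` strings with optional Phred
scores (offset 33). The read filter keeps a read iff its length is
≥ 100 bp and the median of its Phred scores is ≥ 25, both inclusive; the
median of an even-length list is the mean of the two central order
statistics. Whole reads are filtered (no truncation). FASTA input has no
qualities and is subject to the length rule only. `N` bases pass the
filter; the kmer layer is responsible for ambiguity, and its single rule
is: any window containing a non-ACGT character is skipped.

## Kmer representation

Kmers are packed 2 bits per base (A=0 < C=1 < G=2 < T=3, most significant
base first), which preserves lexicographic order, so the canonical form —
the smaller of a kmer and its reverse complement, making counting
strand-agnostic — is an integer `min`. Packing supports k ≤ 31 (62 bits).
Identification defaults to canonical k=31: a random 31-mer has a 4⁻³¹
chance of a spurious match, so membership is essentially diagnostic, and
shotgun reads have unknown strand. The phylogeny defaults to stranded
(non-canonical) k=8 counting of whole genomes; both modes are exposed
everywhere. Circular molecules contribute their k−1 wrap-around windows.

## Reference databases and take-one-out

A database stores, per genome, the sorted array of *distinct* kmers
(presence, not multiplicity — detection scoring uses set membership only)
plus a genome → taxon map; several accessions may share a taxon. The
union array is cached for first-pass screening. `take_one_out` removes
one genome and rebuilds, leaving the original untouched: reads from an
accession are only ever scored against databases that exclude that
accession's own assembly, which removes the circularity of testing reads
against the genome assembled from them. Serialization is a single `.npz`
with a JSON metadata header and one packed-kmer array per genome;
round-trips are bit-exact.

## Read classification and detection calls

Each read's kmers are screened against the union set (binary search);
only hits are resolved per genome. A read is assigned to the genome with
the most matching kmers if that count covers ≥ 50% of the read's kmers
(`min_fraction`); exact ties go to the lexicographically smallest genome
id, a deterministic rule that can split tied reads toward whichever name
sorts first — taxon *ranking* therefore uses pooled matched-kmer totals,
not assignment counts, and is insensitive to the tie-break. Reads shorter
than k contribute zero kmers and stay unassigned but are counted in the
total.

Evidence is pooled per taxon: a kmer supports a taxon if it occurs in any
of the taxon's genomes. A taxon is **detected** when assigned reads ≥ 10
and distinct matched kmers ≥ 100; it is additionally **supported** when
the binomial tail probability of its total matched-kmer count — n = total
kmers queried across all reads, per-kmer null rate p₀ = |taxon kmer set| /
4^k — is below α = 10⁻⁶. Taxa passing the count thresholds but not the
tail test are reported "detected, poorly supported". The three thresholds
are exposed on every entry point; the defaults are deliberate
round numbers at the scale where chance matching at k=31 is negligible.

## Synthetic data

- **Genomes**: i.i.d. bases at 37% GC (typical plastome composition),
  158,900 bp by default (plastome scale), circular. Background
  "bacterial" genomes are 1 Mb — large enough that their reads are an
  effectively inexhaustible non-plastome background; their exact size is
  immaterial to detection since they share no kmers with the reference
  panel beyond chance.
- **Accessions and relatives**: derived by per-base substitution from
  shared ancestors. The default panel nests three conspecific accessions
  (4×10⁻⁴ per branch → ~0.07–0.08% pairwise, under the 0.1% conspecific
  ceiling) inside two congeners (~1% per branch), two same-family and two
  other-family species (~5% per branch), and one outgroup (~12%).
  Substitution-only derivation keeps sequences colinear so pairwise
  divergence is directly measurable; indels are available separately and
  carry exact ground truth for the variant screen.
- **Reads**: fixed 125 bp, uniform circular start, random strand, i.i.d.
  substitution errors at 0.2% per base, constant Q37 quality strings
  (the generator emulates post-trimming reads, so quality is flat and
  error is independent of it).
- **Mixtures**: background components at 30/30/30/3.3/3.3/3.3 (ratios
  normalized to sum to 100), spike at `round(total × f/100)` reads,
  largest-remainder apportionment of the rest, deterministic shuffle.
  Component labels are kept as read-id prefixes for ground-truth tallies.

One `numpy.random.Generator` per operation, seeded explicitly; fixed
seeds give byte-identical FASTQ output.

## Study designs and problem sizes

- **Take-one-out identification**: 3 conspecific accessions among 7
  relatives; three k=31 databases, each omitting one accession; 10,000
  125 bp reads at 0.2% error per held-out accession; accuracy = percent
  of trials whose top-ranked detected taxon (by pooled matched kmers) is
  the true taxon. ~1 min on one CPU.
- **Dilution series**: 220,000-read mixtures, spike fractions 5, 2.5,
  1.25, 0.6, 0.3, 0.15, 0.07, 0.03, 0.01%, three replicates, classified
  against a take-one-out database (the spiked accession is absent from
  it). Per replicate the target pool is shuffled once and every spike is
  a prefix of that shuffle, so spikes are nested and matched-kmer counts
  are monotone in the fraction by construction. LOD = smallest fraction
  supported in all replicates. ~10 min on one CPU; the read depth is a
  deliberate desk-scale design one order below sequencing-run scale.
- **Phylogeny**: stranded D2 at k=8 over the ten panel genomes, NJ,
  rooting on the outgroup's pendant edge, monophyly check on the three
  accessions. < 1 min.

## D2 / D2* numerical choices

The D2 similarity is self-normalized (cosine form) and mapped to
d = (1−s)/2 ∈ [0, 0.5]. D2* centers counts under a zeroth-order
(independent-base) model estimated from each sequence's own composition;
higher-order Markov backgrounds are out of scope. The statistic sums over
all 4^k words: the sparse implementation iterates only words observed in
either sequence and adds the unobserved remainder in closed form,
Σ_w √(m_X p_w m_Y q_w) over all words = √(m_X m_Y)(Σ_b √(p_b q_b))^k for
stranded counting. With canonical counting the strand-folded word
probabilities (p_w + p_rc(w)) admit no product closed form, so the
remainder is evaluated from a dense probability array, limiting canonical
D2* to k ≤ 12 — ample for the k=8 use case. D2* of identical inputs is 0
by construction; for unrelated same-composition sequences the normalized
similarity fluctuates around 0 at scale ~2⁻ᵏ independent of length, so
dissimilarities plateau at 0.5 ± that fluctuation (and can slightly
exceed 0.5; values are not clamped).

## Neighbor joining and rooting

Standard Saitou–Nei agglomeration on the Q-criterion. Ties in Q are
broken by the lexicographically smallest pair of cluster labels (each
cluster keyed by its smallest leaf). Negative branch lengths are clamped
to zero with the deficit moved to the sibling branch, preserving path
lengths; on additive matrices the input distances are reproduced to
machine precision. The final three clusters join at an unrooted
trifurcation. Outgroup rooting bisects the outgroup's pendant edge;
suppressed degree-2 nodes fold their length into the adjacent edge, so
patristic distances are invariant under rooting. Monophyly of a label set
means some edge of the tree separates exactly that set (on unrooted trees
complement splits count).

## Variant screen

One pass over alignment columns per query. Maximal runs of query gaps
opposite reference bases → one deletion; maximal runs of reference gaps →
one insertion anchored at the preceding reference position; base
mismatches → SNPs. Coordinates are 1-based inclusive on the reference's
ungapped sequence (a 17 bp deletion starting at 58,399 spans
58,399–58,415). `N` is missing data: it produces no call and closes any
open indel run. Adjacent SNPs and indels stay separate calls (no
complex-variant merging). Descending printed coordinates occasionally
seen in the wild are normalized to ascending.

## What the synthetic emulation does and does not show

The generator produces i.i.d. genomes and uniform reads: no repeats or
inverted-repeat structure, no real phylogenetic signal beyond the planted
divergence, no coverage or GC bias, no quality-correlated or indel
errors, no adapter or host contamination. Passing tests therefore
demonstrate the *algorithmic* claims — correctness of counting, scoring,
tie-breaking and tree building, and the qualitative detection behavior at
realistic divergences, error rates and depths — not performance on real
sequencing runs. In particular, real plastomes share the ~25 kb inverted
repeat across distant taxa, which inflates cross-taxon kmer sharing
relative to this emulation; real LODs will depend on library depth and
the reference panel's density.

## Known limitations

- k ≤ 31 for packed kmers (64-bit packing); larger k falls back to slow
  string counting in the count-vector path only.
- Detection is flat per-taxon; no lowest-common-ancestor resolution or
  abundance estimation.
- The classifier is single-end and unpaired; paired-end evidence is not
  combined.
- The binomial support test assumes independent kmer draws; overlapping
  kmers within a read are positively correlated, making the test
  anti-conservative in principle — immaterial at k=31 where p₀ ≈ 10⁻¹³,
  but not a calibrated p-value for marginal calls.
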