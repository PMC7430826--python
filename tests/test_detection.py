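"""Read classification, detection calls, dilution series, take-one-out."""

import numpy as np
import pytest

from plastidkit.detection import (
    assign_read,
    assign_reads,
    detect,
    dilution_series,
    limit_of_detection,
    take_one_out_accuracy,
)
from plastidkit.kmers import packed_kmers, reverse_complement
from plastidkit.refdb import build_database, load_database, save_database, take_one_out
from plastidkit.seqio import SeqRecord
from plastidkit.synthetic import (
    MixtureComponent,
    mutate_genome,
    simulate_genome,
    simulate_reads,
)

K = 21


@pytest.fixture(scope="module")
def db(small_panel=None):
    gA = simulate_genome(20_000, seed=1, id="gA")
    gB = simulate_genome(20_000, seed=2, id="gB")
    gC = simulate_genome(20_000, seed=3, id="gC")
    return build_database([("taxA", "gA", gA), ("taxB", "gB", gB), ("taxC", "gC", gC)], k=K)


@pytest.fixture(scope="module")
def genomes():
    return {
        "gA": simulate_genome(20_000, seed=1, id="gA"),
        "gB": simulate_genome(20_000, seed=2, id="gB"),
        "gC": simulate_genome(20_000, seed=3, id="gC"),
    }


def test_exact_read_fully_matches_source(db, genomes):
    read = SeqRecord("r", genomes["gA"].sequence[1000:1125])
    a = assign_read(read, db)
    assert a.n_kmers == 125 - K + 1
    assert a.matches_per_genome["gA"] == a.n_kmers
    assert a.best_genome == "gA"
    assert a.best_fraction == 1.0


def test_random_read_unassigned(db, rng):
    seq = "".join("ACGT"[i] for i in rng.integers(0, 4, size=125))
    a = assign_read(SeqRecord("r", seq), db)
    assert a.best_genome is None
    assert sum(a.matches_per_genome.values()) <= 2  # chance collisions only


def test_read_shorter_than_k_unassigned(db):
    a = assign_read(SeqRecord("r", "ACGT"), db)
    assert a.n_kmers == 0 and a.best_genome is None


def test_empty_database_rejected():
    empty = build_database([], k=K)
    with pytest.raises(ValueError, match="empty"):
        assign_read(SeqRecord("r", "ACGT" * 40), empty)


def test_match_counts_equal_brute_force_membership(db, genomes, rng):
    reads = []
    for gid in ("gA", "gB", "gC"):
        reads.extend(simulate_reads(genomes[gid], 40, error_rate=0.01, seed=50))
    assignments = assign_reads(reads, db)
    kmer_sets = {g: set(map(int, db.kmer_sets[g])) for g in db.genome_ids}
    for read, a in zip(reads, assignments):
        kms = [int(c) for c in packed_kmers(read.sequence, K, canonical=True)]
        for gid, kset in kmer_sets.items():
            expect = sum(1 for km in kms if km in kset)
            assert a.matches_per_genome.get(gid, 0) == expect


def test_detect_pure_source_reads(db, genomes):
    reads = simulate_reads(genomes["gB"], 200, seed=60)
    report = detect(reads, db)
    assert report.per_taxon["taxB"].detected and report.per_taxon["taxB"].supported
    assert not report.per_taxon["taxA"].detected
    assert not report.per_taxon["taxC"].detected
    assert report.top_taxon() == "taxB"
    total_assigned = sum(r.assigned_reads for r in report.per_taxon.values())
    assert total_assigned <= report.total_reads


def test_detect_zero_reads(db):
    report = detect([], db)
    assert report.total_reads == 0
    assert report.detected_taxa() == []


def test_conspecific_pooling():
    base = simulate_genome(20_000, seed=4, id="base")
    acc1, _ = mutate_genome(base, sub_rate=4e-4, seed=5, new_id="acc1")
    acc2, _ = mutate_genome(base, sub_rate=4e-4, seed=6, new_id="acc2")
    other = simulate_genome(20_000, seed=7, id="other")
    db2 = build_database(
        [("sp", "acc1", acc1), ("sp", "acc2", acc2), ("oth", "other", other)], k=K
    )
    reads = simulate_reads(base, 100, error_rate=0.002, seed=8)
    report = detect(reads, db2)
    res = report.per_taxon["sp"]
    # pooled taxon evidence >= either accession alone
    assert res.detected and res.supported
    assert res.assigned_reads >= 90


def test_match_counts_invariant_to_read_order_and_serialization(db, genomes, tmp_path):
    reads = simulate_reads(genomes["gA"], 100, error_rate=0.005, seed=70)
    rep1 = detect(reads, db)
    rep2 = detect(list(reversed(reads)), db)
    save_database(db, tmp_path / "db.npz")
    rep3 = detect(reads, load_database(tmp_path / "db.npz"))
    for t in db.taxa:
        assert rep1.per_taxon[t].total_matched_kmers == rep2.per_taxon[t].total_matched_kmers
        assert rep1.per_taxon[t].total_matched_kmers == rep3.per_taxon[t].total_matched_kmers
        assert rep1.per_taxon[t].unique_matched_kmers == rep3.per_taxon[t].unique_matched_kmers


def test_adding_unrelated_genome_keeps_target_counts(db, genomes):
    reads = simulate_reads(genomes["gA"], 100, error_rate=0.005, seed=71)
    before = detect(reads, db).per_taxon["taxA"].total_matched_kmers
    extra = simulate_genome(20_000, seed=99, id="gX")
    db2 = build_database(
        [("taxA", "gA", genomes["gA"]), ("taxB", "gB", genomes["gB"]),
         ("taxC", "gC", genomes["gC"]), ("taxX", "gX", extra)], k=K
    )
    after = detect(reads, db2).per_taxon["taxA"].total_matched_kmers
    assert before == after


def _mixture_fixtures(total=4_000):
    base = simulate_genome(20_000, seed=4, id="target")
    other1 = simulate_genome(20_000, seed=21, id="o1")
    other2 = simulate_genome(20_000, seed=22, id="o2")
    db = build_database(
        [("target", "target", base), ("o1", "o1", other1), ("o2", "o2", other2)], k=K
    )
    bg1 = simulate_genome(50_000, seed=23, id="bg1")
    bg2 = simulate_genome(50_000, seed=24, id="bg2")
    background = [
        MixtureComponent("bg1", simulate_reads(bg1, total, seed=25), 50.0),
        MixtureComponent("bg2", simulate_reads(bg2, total, seed=26), 50.0),
    ]
    target_reads = simulate_reads(base, total, error_rate=0.002, seed=27)
    return db, background, target_reads


def test_dilution_series_monotone_and_lod():
    db, background, target_reads = _mixture_fixtures()
    fractions = [10.0, 3.0, 1.0, 0.3]
    table = dilution_series(db, background, target_reads, "target", fractions,
                            total_reads=4_000, seed=5, replicates=2)
    assert len(table) == len(fractions) * 2
    # monotone matched kmers in fraction, per replicate (nested spikes)
    for rep in (0, 1):
        sub = table[table.replicate == rep].sort_values("fraction")
        counts = sub.total_matched_kmers.to_numpy()
        assert (np.diff(counts) >= 0).all()
    # high fractions detected with support
    top = table[table.fraction == 10.0]
    assert top.detected.all() and top.supported.all()
    lod = limit_of_detection(table)
    assert lod is not None and lod <= 10.0


def test_dilution_series_argument_errors():
    db, background, target_reads = _mixture_fixtures()
    with pytest.raises(ValueError):
        dilution_series(db, background, target_reads, "target", [1.0], total_reads=0, seed=1)
    with pytest.raises(ValueError):
        dilution_series(db, background, target_reads, "target", [150.0], total_reads=100, seed=1)


def test_take_one_out_accuracy_and_negative_control():
    base = simulate_genome(20_000, seed=30, id="anc")
    accs = [mutate_genome(base, sub_rate=4e-4, seed=31 + i, new_id=f"acc{i}")[0] for i in range(3)]
    rel = simulate_genome(20_000, seed=40, id="rel")
    triples = [("target", a.id, a) for a in accs] + [("rel", "rel", rel)]
    full = build_database(triples, k=K)
    dbs = [take_one_out(full, a.id) for a in accs]
    read_sets = [simulate_reads(a, 300, error_rate=0.002, seed=50 + i) for i, a in enumerate(accs)]
    acc_pct, reports = take_one_out_accuracy(dbs, read_sets, "target")
    assert acc_pct == 100.0
    # recount oracle: accuracy equals mean of per-trial indicators
    indicators = [rep.top_taxon() == "target" for rep in reports]
    assert acc_pct == 100.0 * np.mean(indicators)
    # negative control: unrelated reads queried as the target
    rel_reads = [simulate_reads(rel, 300, seed=60) for _ in range(3)]
    neg, _ = take_one_out_accuracy(dbs, rel_reads, "target")
    assert neg == 0.0
    with pytest.raises(ValueError):
        take_one_out_accuracy(dbs, read_sets[:2], "target")


def test_report_tsv_roundtrip(tmp_path, db, genomes):
    import pandas as pd

    reads = simulate_reads(genomes["gC"], 100, seed=80)
    report = detect(reads, db)
    p = tmp_path / "report.tsv"
    report.write_tsv(p)
    back = pd.read_csv(p, sep="\t")
    assert list(back.columns) == [
        "taxon", "assigned_reads", "total_matched_kmers", "unique_matched_kmers",
        "support_p", "detected", "supported",
    ]
    assert back.set_index("taxon").loc["taxC", "detected"]
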