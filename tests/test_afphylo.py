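"""D2/D2* statistics, p-distance, neighbor joining, rooting, monophyly."""

import itertools
import math

import numpy as np
import pytest

from plastidkit.afphylo import (
    DistanceMatrix,
    d2_distance,
    d2_distance_matrix,
    d2_similarity,
    d2star_distance,
    is_monophyletic,
    nj_tree,
    p_distance_matrix,
    root_with_outgroup,
    write_phylip,
)
from plastidkit.kmers import KmerCountVector, extract_kmers
from plastidkit.seqio import SeqRecord
from plastidkit.synthetic import simulate_genome


def vec(k, counts, freqs=(0.25, 0.25, 0.25, 0.25), canonical=False):
    return KmerCountVector(k, dict(counts), sum(counts.values()), 100, freqs, canonical)


# ---------------------------------------------------------------------------
# D2
# ---------------------------------------------------------------------------

def test_d2_self_similarity_is_one():
    X = vec(2, {"AA": 2, "AT": 1})
    assert d2_similarity(X, X) == pytest.approx(1.0)
    assert d2_distance(X, X) == pytest.approx(0.0)


def test_d2_disjoint_supports():
    X = vec(2, {"AA": 5})
    Y = vec(2, {"CC": 7})
    assert d2_similarity(X, Y) == 0.0
    assert d2_distance(X, Y) == 0.5


def test_d2_hand_enumeration():
    X = vec(2, {"AA": 2, "AT": 1})
    Y = vec(2, {"AA": 1, "TT": 3})
    # raw D2 = 2*1 = 2; selfs are 5 and 10
    assert d2_similarity(X, Y) == pytest.approx(2 / math.sqrt(50))
    assert d2_distance(X, Y) == pytest.approx(0.5 * (1 - 2 / math.sqrt(50)))


def test_d2_k_mismatch_and_empty_vector_errors():
    X = vec(2, {"AA": 1})
    with pytest.raises(ValueError):
        d2_similarity(X, vec(3, {"AAA": 1}))
    with pytest.raises(ValueError):
        d2_similarity(X, vec(2, {}))


def test_d2_symmetry_and_range(rng):
    for _ in range(20):
        sa = "".join("ACGT"[i] for i in rng.integers(0, 4, size=400))
        sb = "".join("ACGT"[i] for i in rng.integers(0, 4, size=400))
        X, Y = extract_kmers(sa, 4), extract_kmers(sb, 4)
        d = d2_distance(X, Y)
        assert d == pytest.approx(d2_distance(Y, X))
        assert 0.0 <= d <= 0.5


# ---------------------------------------------------------------------------
# D2* — dense enumeration oracle
# ---------------------------------------------------------------------------

def dense_d2star(X, Y):
    """Brute-force D2* over all 4**k words (independent oracle)."""
    k = X.k
    idx = {"A": 0, "C": 1, "G": 2, "T": 3}
    total = 0.0
    for word in map("".join, itertools.product("ACGT", repeat=k)):
        p = math.prod(X.base_freqs[idx[c]] for c in word)
        q = math.prod(Y.base_freqs[idx[c]] for c in word)
        xs = X.counts.get(word, 0) - X.n_kmers_total * p
        ys = Y.counts.get(word, 0) - Y.n_kmers_total * q
        total += xs * ys / math.sqrt(X.n_kmers_total * p * Y.n_kmers_total * q)
    return total


def dense_d2star_distance(X, Y):
    s = dense_d2star(X, Y) / math.sqrt(dense_d2star(X, X) * dense_d2star(Y, Y))
    return 0.5 * (1 - s)


def test_d2star_identity():
    seq = "ACGTTGCAACGTAGCTAGGCTTAAGCGC"
    X = extract_kmers(seq, 3)
    assert d2star_distance(X, X) == pytest.approx(0.0, abs=1e-12)


def test_d2star_sparse_matches_dense_enumeration_k3(rng):
    for trial in range(5):
        sa = "".join("ACGT"[i] for i in rng.integers(0, 4, size=300))
        sb = "".join("ACGT"[i] for i in rng.integers(0, 4, size=250))
        X, Y = extract_kmers(sa, 3), extract_kmers(sb, 3)
        assert d2star_distance(X, Y) == pytest.approx(dense_d2star_distance(X, Y), abs=1e-12)


def test_d2star_skewed_composition_matches_dense(rng):
    # unequal base frequencies exercise the background model properly
    pa = np.array([0.5, 0.1, 0.1, 0.3])
    sa = "".join("ACGT"[i] for i in rng.choice(4, size=400, p=pa))
    sb = "".join("ACGT"[i] for i in rng.choice(4, size=400, p=pa[::-1]))
    X, Y = extract_kmers(sa, 3), extract_kmers(sb, 3)
    assert d2star_distance(X, Y) == pytest.approx(dense_d2star_distance(X, Y), abs=1e-12)


def test_d2star_random_sequences_near_half():
    # for independent i.i.d. same-composition sequences the centered
    # statistics decorrelate: the normalized similarity fluctuates around 0
    # at scale ~2**-k (independent of length), so the dissimilarity sits at
    # 0.5 up to that fluctuation at every length
    for L in (1_000, 10_000, 100_000):
        a = simulate_genome(L, seed=L, gc=0.5)
        b = simulate_genome(L, seed=L + 1, gc=0.5)
        d = d2star_distance(extract_kmers(a.sequence, 5), extract_kmers(b.sequence, 5))
        assert abs(d - 0.5) < 0.1
    # related sequences stay well below the decorrelation plateau
    a = simulate_genome(50_000, seed=7, gc=0.5)
    from plastidkit.synthetic import mutate_genome

    b, _ = mutate_genome(a, sub_rate=0.01, seed=8)
    d_rel = d2star_distance(extract_kmers(a.sequence, 5), extract_kmers(b.sequence, 5))
    assert d_rel < 0.1


# ---------------------------------------------------------------------------
# p-distance
# ---------------------------------------------------------------------------

def test_p_distance_examples():
    dm = p_distance_matrix([SeqRecord("a", "ACGT"), SeqRecord("b", "ACGT")])
    assert dm["a", "b"] == 0.0
    dm = p_distance_matrix([SeqRecord("a", "ACGT"), SeqRecord("b", "ACGA")])
    assert dm["a", "b"] == 0.25
    # gap column excluded: 3 compared, 0 mismatches
    dm = p_distance_matrix([SeqRecord("a", "AC-T"), SeqRecord("b", "ACGT")])
    assert dm["a", "b"] == 0.0


def test_p_distance_errors():
    with pytest.raises(ValueError, match="length"):
        p_distance_matrix([SeqRecord("a", "ACGT"), SeqRecord("b", "ACG")])
    with pytest.raises(ValueError, match="comparable"):
        p_distance_matrix([SeqRecord("a", "--AA"), SeqRecord("b", "AA--")])


# ---------------------------------------------------------------------------
# Neighbor joining
# ---------------------------------------------------------------------------

def test_nj_three_taxon_closed_form():
    dm = DistanceMatrix(["A", "B", "C"], np.array([[0, 5, 9], [5, 0, 10], [9, 10, 0]], float))
    tree = nj_tree(dm)
    lengths = {child.name: bl for child, bl in tree.root.children}
    assert lengths == {"A": pytest.approx(2), "B": pytest.approx(3), "C": pytest.approx(7)}


def test_nj_requires_three_taxa():
    with pytest.raises(ValueError):
        nj_tree(DistanceMatrix(["A", "B"], np.array([[0, 1], [1, 0]], float)))


def test_nj_recovers_additive_four_taxon_tree():
    # tree ((A:1,B:2):1,(C:3,D:4)) -> AB=3 AC=5 AD=6 BC=6 BD=7 CD=7
    labels = ["A", "B", "C", "D"]
    d = np.array(
        [[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]], float
    )
    tree = nj_tree(DistanceMatrix(labels, d))
    got = tree.leaf_distances()
    for i, j in itertools.combinations(range(4), 2):
        assert got[labels[i], labels[j]] == pytest.approx(d[i, j], abs=1e-12)
    # topology: A-B form a cherry on the unrooted tree
    assert is_monophyletic(tree, ["A", "B"])
    assert is_monophyletic(tree, ["C", "D"])
    assert not is_monophyletic(tree, ["A", "C"])


def random_additive_matrix(rng, n):
    """Distances from a random binary tree with random branch lengths
    (independent oracle: path lengths on an explicitly built tree)."""
    # random topology by sequential attachment; store as edge list
    import networkx as nx

    g = nx.Graph()
    g.add_edge("L0", "L1", w=float(rng.uniform(0.1, 2)))
    internal = 0
    for i in range(2, n):
        edge = list(g.edges)[rng.integers(0, g.number_of_edges())]
        w = g.edges[edge]["w"]
        g.remove_edge(*edge)
        mid = f"I{internal}"
        internal += 1
        split = float(rng.uniform(0.2, 0.8))
        g.add_edge(edge[0], mid, w=w * split)
        g.add_edge(mid, edge[1], w=w * (1 - split))
        g.add_edge(mid, f"L{i}", w=float(rng.uniform(0.1, 2)))
    labels = [f"L{i}" for i in range(n)]
    d = np.zeros((n, n))
    paths = dict(nx.all_pairs_dijkstra_path_length(g, weight="w"))
    for i, j in itertools.combinations(range(n), 2):
        d[i, j] = d[j, i] = paths[labels[i]][labels[j]]
    return DistanceMatrix(labels, d)


@pytest.mark.parametrize("n", [4, 5])
def test_nj_exact_on_random_additive_matrices(n, rng):
    for _ in range(100):
        dm = random_additive_matrix(rng, n)
        got = nj_tree(dm).leaf_distances()
        order = [got.labels.index(l) for l in dm.labels]
        assert np.allclose(got.d[np.ix_(order, order)], dm.d, atol=1e-9)


def test_nj_invariant_to_label_order(rng):
    dm = random_additive_matrix(rng, 6)
    perm = rng.permutation(6)
    dm2 = DistanceMatrix([dm.labels[i] for i in perm], dm.d[np.ix_(perm, perm)])
    t1, t2 = nj_tree(dm), nj_tree(dm2)
    d1, d2 = t1.leaf_distances(), t2.leaf_distances()
    order = [d2.labels.index(l) for l in d1.labels]
    assert np.allclose(d1.d, d2.d[np.ix_(order, order)], atol=1e-9)


def test_nj_matches_scikit_bio_on_random_matrices(rng):
    """Independent cross-check against scikit-bio's neighbor joining."""
    skbio = pytest.importorskip("skbio")
    from skbio import DistanceMatrix as SkDM
    from skbio.tree import nj as sk_nj

    for _ in range(10):
        dm = random_additive_matrix(rng, 6)
        ours = nj_tree(dm).leaf_distances()
        sk_tree = sk_nj(SkDM(dm.d, ids=dm.labels))
        for a, b in itertools.combinations(dm.labels, 2):
            sk_d = sk_tree.find(a).distance(sk_tree.find(b))
            assert ours[a, b] == pytest.approx(sk_d, abs=1e-6)


# ---------------------------------------------------------------------------
# Rooting and monophyly
# ---------------------------------------------------------------------------

def test_root_three_taxon_tree_makes_cherry():
    dm = DistanceMatrix(["A", "B", "C"], np.array([[0, 5, 9], [5, 0, 10], [9, 10, 0]], float))
    rooted = root_with_outgroup(nj_tree(dm), "C")
    assert rooted.rooted
    assert is_monophyletic(rooted, ["A", "B"])
    # outgroup pendant edge split at its midpoint
    lengths = {(child.name or "internal"): bl for child, bl in rooted.root.children}
    assert lengths["C"] == pytest.approx(3.5)
    assert lengths["internal"] == pytest.approx(3.5)


def test_rooting_preserves_patristic_distances(rng):
    dm = random_additive_matrix(rng, 7)
    tree = nj_tree(dm)
    rooted = root_with_outgroup(tree, dm.labels[0])
    d1, d2 = tree.leaf_distances(), rooted.leaf_distances()
    order = [d2.labels.index(l) for l in d1.labels]
    assert np.allclose(d1.d, d2.d[np.ix_(order, order)], atol=1e-9)


def test_unknown_outgroup_label():
    dm = DistanceMatrix(["A", "B", "C"], np.array([[0, 5, 9], [5, 0, 10], [9, 10, 0]], float))
    with pytest.raises(KeyError):
        root_with_outgroup(nj_tree(dm), "Z")


def test_all_leaves_are_trivially_monophyletic():
    dm = DistanceMatrix(["A", "B", "C"], np.array([[0, 5, 9], [5, 0, 10], [9, 10, 0]], float))
    tree = nj_tree(dm)
    assert is_monophyletic(tree, ["A", "B", "C"])


def test_newick_parses_with_dendropy():
    dendropy = pytest.importorskip("dendropy")
    dm = DistanceMatrix(["A", "B", "C", "D"],
                        np.array([[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]], float))
    nwk = nj_tree(dm).to_newick()
    tree = dendropy.Tree.get(data=nwk, schema="newick")
    assert {l.taxon.label for l in tree.leaf_node_iter()} == {"A", "B", "C", "D"}


def test_phylip_writer_format(tmp_path):
    dm = DistanceMatrix(["alpha", "beta", "gammagammagamma"],
                        np.array([[0, 0.1, 0.2], [0.1, 0, 0.3], [0.2, 0.3, 0]], float))
    p = tmp_path / "dm.phy"
    write_phylip(dm, p)
    lines = p.read_text().splitlines()
    assert lines[0].strip() == "3"
    assert lines[1].startswith("alpha     ")  # padded to 10 chars
    assert lines[3].startswith("gammagamma")  # truncated to 10
    vals = [float(x) for x in lines[2].split()[1:]]
    assert vals == pytest.approx([0.1, 0.0, 0.3])
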