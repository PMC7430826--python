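"""Alignment-free distances, neighbor joining, and tree utilities.

The D2 statistic between two kmer count vectors X and Y is the inner
product sum_w X_w * Y_w over shared words.  It is converted to a
dissimilarity by self-normalization:

    s = D2(X, Y) / sqrt(D2(X, X) * D2(Y, Y))        in [0, 1]
    d = 0.5 * (1 - s)                               in [0, 0.5]

D2* centers each count by its expectation under a zeroth-order background
model estimated from each sequence's own base composition:

    D2* = sum_w (X_w - mX p_w)(Y_w - mY q_w) / sqrt(mX p_w * mY q_w)

where m is the total kmer count and p_w (q_w) is the product of the base
frequencies of w's letters.  The sum runs over ALL 4^k words; words
unobserved in both sequences contribute sqrt(mX p_w * mY q_w), whose total
has the closed form sqrt(mX mY) * (sum_b sqrt(p_b q_b))^k, so the sparse
implementation needs only the union of observed words plus that analytic
remainder.  D2* is normalized to a dissimilarity exactly as D2.

The neighbor-joining implementation follows Saitou-Nei with the standard
Q-criterion; ties in Q are broken by the smallest label-sorted pair and
negative branch lengths are clamped to zero with the deficit moved to the
sibling branch, which keeps path lengths additive.  On an additive
distance matrix the input distances are recovered exactly.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np

from .kmers import KmerCountVector, reverse_complement

__all__ = [
    "DistanceMatrix",
    "PhyloNode",
    "PhyloTree",
    "d2_similarity",
    "d2_distance",
    "d2star_distance",
    "d2_distance_matrix",
    "p_distance_matrix",
    "nj_tree",
    "root_with_outgroup",
    "is_monophyletic",
    "write_phylip",
]


# ---------------------------------------------------------------------------
# Distance matrix
# ---------------------------------------------------------------------------

@dataclass
class DistanceMatrix:
    """Symmetric labeled distance matrix with zero diagonal."""

    labels: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.labels)
        if len(set(self.labels)) != n:
            raise ValueError("labels must be unique")
        if self.d.shape != (n, n):
            raise ValueError("matrix shape must match label count")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("matrix must be symmetric")
        if not np.allclose(np.diag(self.d), 0):
            raise ValueError("diagonal must be zero")
        if not np.isfinite(self.d).all():
            raise ValueError("entries must be finite")

    def __getitem__(self, pair: tuple[str, str]) -> float:
        i = self.labels.index(pair[0])
        j = self.labels.index(pair[1])
        return float(self.d[i, j])


def write_phylip(dm: DistanceMatrix, path: str | Path, relaxed: bool = False) -> None:
    """Square PHYLIP distance matrix; labels padded to 10 characters
    (``relaxed=True`` keeps long labels, tab-separated)."""
    with open(path, "w") as fh:
        fh.write(f"{len(dm.labels):5d}\n")
        for i, label in enumerate(dm.labels):
            row = " ".join(f"{x:.6f}" for x in dm.d[i])
            name = label if relaxed else f"{label[:10]:<10s}"
            sep = "\t" if relaxed else ""
            fh.write(f"{name}{sep}{row}\n")


# ---------------------------------------------------------------------------
# D2 family
# ---------------------------------------------------------------------------

def _check_pair(X: KmerCountVector, Y: KmerCountVector) -> None:
    if X.k != Y.k:
        raise ValueError(f"k mismatch: {X.k} != {Y.k}")
    if X.canonical != Y.canonical:
        raise ValueError("canonical flags differ")


def _d2_raw(X: KmerCountVector, Y: KmerCountVector) -> float:
    small, large = (X.counts, Y.counts) if len(X.counts) <= len(Y.counts) else (Y.counts, X.counts)
    return float(sum(c * large[w] for w, c in small.items() if w in large))


def d2_similarity(X: KmerCountVector, Y: KmerCountVector) -> float:
    """Self-normalized D2 similarity in [0, 1]."""
    _check_pair(X, Y)
    if not X.counts or not Y.counts:
        raise ValueError("D2 similarity undefined for an empty kmer vector")
    num = _d2_raw(X, Y)
    return num / math.sqrt(_d2_raw(X, X) * _d2_raw(Y, Y))


def d2_distance(X: KmerCountVector, Y: KmerCountVector) -> float:
    """D2 dissimilarity 0.5 * (1 - similarity), in [0, 0.5]."""
    return 0.5 * (1.0 - d2_similarity(X, Y))


def _word_prob(word: str, freqs: Sequence[float], canonical: bool) -> float:
    idx = {"A": 0, "C": 1, "G": 2, "T": 3}
    p = 1.0
    for ch in word:
        p *= freqs[idx[ch]]
    if canonical:
        rc = reverse_complement(word)
        if rc != word:
            q = 1.0
            for ch in rc:
                q *= freqs[idx[ch]]
            p += q
    return p


def _d2star_raw(X: KmerCountVector, Y: KmerCountVector) -> float:
    """Centered D2* statistic, sparse with analytic remainder."""
    mX, mY = X.n_kmers_total, Y.n_kmers_total
    if mX == 0 or mY == 0:
        raise ValueError("D2* undefined for an empty kmer vector")
    k = X.k
    canonical = X.canonical
    support = set(X.counts) | set(Y.counts)
    acc = 0.0
    observed_cross = 0.0
    for w in support:
        p = _word_prob(w, X.base_freqs, canonical)
        q = _word_prob(w, Y.base_freqs, canonical)
        if p <= 0 or q <= 0:
            raise ValueError(f"zero background probability for counted word {w!r}")
        ex, ey = mX * p, mY * q
        xs = X.counts.get(w, 0) - ex
        ys = Y.counts.get(w, 0) - ey
        denom = math.sqrt(ex * ey)
        acc += xs * ys / denom
        observed_cross += denom
    if canonical:
        # no product closed form once strands are folded; enumerate densely
        if k > 12:
            raise ValueError("canonical D2* supported for k <= 12 only")
        total_cross = math.sqrt(mX * mY) * _canonical_prob_overlap(X.base_freqs, Y.base_freqs, k)
    else:
        s = sum(
            math.sqrt(pb * qb) for pb, qb in zip(X.base_freqs, Y.base_freqs)
        )
        total_cross = math.sqrt(mX * mY) * s**k
    # words unobserved in both contribute +sqrt(mX p_w mY q_w)
    return acc + (total_cross - observed_cross)


def _canonical_prob_overlap(fx: Sequence[float], fy: Sequence[float], k: int) -> float:
    """sum over canonical words w of sqrt(p_w q_w) with strand-folded probs."""
    px = np.array(fx)
    py = np.array(fy)
    dense_x = px.copy()
    dense_y = py.copy()
    for _ in range(k - 1):
        dense_x = np.kron(dense_x, px)
        dense_y = np.kron(dense_y, py)
    # fold each word with its reverse complement
    n = 4**k
    codes = np.arange(n, dtype=np.uint64)
    rc = np.zeros(n, dtype=np.uint64)
    tmp = codes.copy()
    for _ in range(k):
        rc = (rc << np.uint64(2)) | (np.uint64(3) - (tmp & np.uint64(3)))
        tmp >>= np.uint64(2)
    canon = np.minimum(codes, rc)
    is_canon = canon == codes
    fold_x = dense_x + np.where(rc != codes, dense_x[rc], 0.0)
    fold_y = dense_y + np.where(rc != codes, dense_y[rc], 0.0)
    return float(np.sum(np.sqrt(fold_x[is_canon] * fold_y[is_canon])))


def d2star_similarity(X: KmerCountVector, Y: KmerCountVector) -> float:
    _check_pair(X, Y)
    num = _d2star_raw(X, Y)
    den = math.sqrt(_d2star_raw(X, X) * _d2star_raw(Y, Y))
    if den == 0:
        raise ValueError("D2* similarity undefined: zero self-statistic")
    return num / den


def d2star_distance(X: KmerCountVector, Y: KmerCountVector) -> float:
    """Centered-statistic dissimilarity 0.5 * (1 - s*)."""
    return 0.5 * (1.0 - d2star_similarity(X, Y))


def d2_distance_matrix(
    vectors: dict[str, KmerCountVector], metric: str = "d2"
) -> DistanceMatrix:
    """Pairwise D2 or D2* dissimilarities over labeled kmer vectors."""
    fn = {"d2": d2_distance, "d2star": d2star_distance}[metric]
    labels = list(vectors)
    n = len(labels)
    d = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        d[i, j] = d[j, i] = fn(vectors[labels[i]], vectors[labels[j]])
    return DistanceMatrix(labels, d)


# ---------------------------------------------------------------------------
# p-distance over a supplied alignment
# ---------------------------------------------------------------------------

def p_distance_matrix(alignment: Sequence) -> DistanceMatrix:
    """Pairwise p-distance (mismatches / compared sites) over aligned records.

    Sites with a gap or N in either sequence of a pair are excluded; a pair
    with zero comparable sites is an error.
    """
    labels = [rec.id for rec in alignment]
    seqs = [rec.sequence.upper() for rec in alignment]
    lengths = {len(s) for s in seqs}
    if len(lengths) > 1:
        raise ValueError("aligned sequences must have equal length")
    arrs = [np.frombuffer(s.encode(), dtype=np.uint8) for s in seqs]
    bad = [(a == ord("-")) | (a == ord("N")) for a in arrs]
    n = len(labels)
    d = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        ok = ~(bad[i] | bad[j])
        comparable = int(ok.sum())
        if comparable == 0:
            raise ValueError(f"no comparable sites between {labels[i]!r} and {labels[j]!r}")
        mism = int(np.sum(arrs[i][ok] != arrs[j][ok]))
        d[i, j] = d[j, i] = mism / comparable
    return DistanceMatrix(labels, d)


# ---------------------------------------------------------------------------
# Trees
# ---------------------------------------------------------------------------

@dataclass
class PhyloNode:
    name: Optional[str] = None  # leaf label; internal nodes unnamed
    children: list[tuple["PhyloNode", float]] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaf_names(self) -> set[str]:
        if self.is_leaf:
            return {self.name}
        out: set[str] = set()
        for child, _ in self.children:
            out |= child.leaf_names()
        return out


@dataclass
class PhyloTree:
    """A (possibly unrooted) tree; unrooted trees have a trifurcating root."""

    root: PhyloNode
    rooted: bool = False

    def leaf_names(self) -> set[str]:
        return self.root.leaf_names()

    def to_newick(self) -> str:
        def render(node: PhyloNode, length: Optional[float]) -> str:
            if node.is_leaf:
                body = node.name
            else:
                inner = ",".join(render(c, bl) for c, bl in node.children)
                body = f"({inner})"
            return body if length is None else f"{body}:{length:.10g}"

        return render(self.root, None) + ";"

    # --- path metrics -----------------------------------------------------

    def leaf_distances(self) -> DistanceMatrix:
        """Patristic (path-length) distances between all leaf pairs."""
        leaves = sorted(self.leaf_names())
        idx = {l: i for i, l in enumerate(leaves)}
        n = len(leaves)
        d = np.zeros((n, n))

        def walk(node: PhyloNode) -> dict[str, float]:
            if node.is_leaf:
                return {node.name: 0.0}
            partials: list[dict[str, float]] = []
            for child, bl in node.children:
                sub = walk(child)
                partials.append({name: dist + bl for name, dist in sub.items()})
            for a, b in itertools.combinations(range(len(partials)), 2):
                for la, da in partials[a].items():
                    for lb, db in partials[b].items():
                        d[idx[la], idx[lb]] = d[idx[lb], idx[la]] = da + db
            merged: dict[str, float] = {}
            for p in partials:
                merged.update(p)
            return merged

        walk(self.root)
        return DistanceMatrix(leaves, d)


def nj_tree(dm: DistanceMatrix) -> PhyloTree:
    """Saitou-Nei neighbor joining (deterministic tie-breaks, see module doc)."""
    n = len(dm.labels)
    if n < 3:
        raise ValueError("neighbor joining requires at least 3 taxa")
    nodes: list[PhyloNode] = [PhyloNode(name=l) for l in dm.labels]
    # sort key of a cluster: lexicographically smallest leaf beneath it
    keys: list[str] = list(dm.labels)
    D = dm.d.astype(float).copy()
    active = list(range(n))

    while len(active) > 3:
        m = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        Q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        qmin = Q.min()
        ties = np.argwhere(np.isclose(Q, qmin, rtol=0, atol=1e-12))
        best = min(
            ((a, b) for a, b in ties if a < b),
            key=lambda ab: tuple(sorted((keys[active[ab[0]]], keys[active[ab[1]]]))),
        )
        ai, bi = best
        i, j = active[ai], active[bi]
        dij = D[i, j]
        bl_i = 0.5 * dij + (r[ai] - r[bi]) / (2 * (m - 2))
        bl_j = dij - bl_i
        if bl_i < 0:
            bl_j += bl_i
            bl_i = 0.0
        if bl_j < 0:
            bl_i += bl_j
            bl_j = 0.0
        new = PhyloNode(children=[(nodes[i], bl_i), (nodes[j], bl_j)])
        # distances to the new node
        dnew = 0.5 * (D[i, :] + D[j, :] - dij)
        D = np.vstack([D, dnew])
        D = np.hstack([D, np.append(dnew, 0.0)[:, None]])
        nodes.append(new)
        keys.append(min(keys[i], keys[j]))
        active = [x for x in active if x not in (i, j)] + [len(nodes) - 1]

    # final three clusters join at an unrooted trifurcation (closed form)
    a, b, c = active
    la = 0.5 * (D[a, b] + D[a, c] - D[b, c])
    lb = 0.5 * (D[a, b] + D[b, c] - D[a, c])
    lc = 0.5 * (D[a, c] + D[b, c] - D[a, b])
    lens = [max(0.0, x) for x in (la, lb, lc)]
    root = PhyloNode(children=[(nodes[a], lens[0]), (nodes[b], lens[1]), (nodes[c], lens[2])])
    return PhyloTree(root=root, rooted=False)


def _edges(tree: PhyloTree) -> tuple[list[tuple[int, int, float]], dict[int, str]]:
    """Undirected edge list with integer node ids; leaves carry names."""
    edges: list[tuple[int, int, float]] = []
    names: dict[int, str] = {}
    counter = itertools.count()

    def walk(node: PhyloNode) -> int:
        nid = next(counter)
        if node.is_leaf:
            names[nid] = node.name
        for child, bl in node.children:
            cid = walk(child)
            edges.append((nid, cid, bl))
        return nid

    walk(tree.root)
    return edges, names


def root_with_outgroup(tree: PhyloTree, outgroup_label: str) -> PhyloTree:
    """Root on the midpoint of the outgroup's pendant edge."""
    if outgroup_label not in tree.leaf_names():
        raise KeyError(f"unknown outgroup label {outgroup_label!r}")
    edges, names = _edges(tree)
    leaf_id = next(i for i, n in names.items() if n == outgroup_label)
    adj: dict[int, list[tuple[int, float]]] = {}
    for a, b, bl in edges:
        adj.setdefault(a, []).append((b, bl))
        adj.setdefault(b, []).append((a, bl))
    (pendant_parent, pendant_len), = adj[leaf_id]

    # build the ingroup side rooted at pendant_parent, excluding the outgroup
    # leaf; suppressed degree-2 nodes fold their length into the edge above
    def build2(nid: int, parent: int) -> tuple[PhyloNode, float]:
        """Returns (node, extra_length) where extra absorbs suppressed unaries."""
        kids = [(c, bl) for c, bl in adj[nid] if c != parent]
        if not kids:
            return PhyloNode(name=names[nid]), 0.0
        built = []
        for c, bl in kids:
            sub, extra = build2(c, nid)
            built.append((sub, bl + extra))
        if len(built) == 1:
            return built[0][0], built[0][1]
        return PhyloNode(children=built), 0.0

    ingroup, extra = build2(pendant_parent, leaf_id)
    half = pendant_len / 2.0
    root = PhyloNode(
        children=[(PhyloNode(name=outgroup_label), half), (ingroup, half + extra)]
    )
    return PhyloTree(root=root, rooted=True)


def is_monophyletic(tree: PhyloTree, labels: Iterable[str]) -> bool:
    """True iff the smallest clade containing ``labels`` contains no others.

    On an unrooted tree this asks whether some edge separates ``labels``
    from everything else; we test clades of the tree as stored plus the
    complement splits, which covers all bipartitions.
    """
    want = set(labels)
    all_leaves = tree.leaf_names()
    unknown = want - all_leaves
    if unknown:
        raise KeyError(f"labels not in tree: {sorted(unknown)}")
    if want == all_leaves:
        return True

    found = False

    def walk(node: PhyloNode) -> set[str]:
        nonlocal found
        leaves = set()
        if node.is_leaf:
            leaves = {node.name}
        else:
            for child, _ in node.children:
                leaves |= walk(child)
        if leaves == want or (not tree.rooted and all_leaves - leaves == want):
            found = True
        return leaves

    walk(tree.root)
    return found
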