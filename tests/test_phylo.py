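"""Distances, neighbor-joining correctness, bootstrap, and newick output."""
import itertools
import math

import dendropy
import numpy as np
import pytest

from gliadinkit import (DistanceMatrix, SequenceRecord, bootstrap_support,
                        nj_tree, pairwise_distance, simulate_clade_alignment,
                        to_newick, write_newick)


def random_additive_matrix(rng, n_taxa):
    """Distances induced by a random binary tree with positive branch lengths
    (built by sequential leaf attachment; additivity holds by construction)."""
    # leaf-to-leaf distances via explicit tree: build with dendropy-free code
    # nodes: dict id -> (parent, branch_length)
    labels = [f"t{i}" for i in range(n_taxa)]
    parent = {0: None}
    blen = {0: 0.0}
    children = {0: []}
    nodes = [0]
    nxt = 1
    leaf_of = {}
    # start: node 0 is root with two leaves
    for lab in labels[:2]:
        parent[nxt] = 0
        blen[nxt] = float(rng.uniform(0.05, 1.0))
        children[0].append(nxt)
        children[nxt] = []
        leaf_of[lab] = nxt
        nodes.append(nxt)
        nxt += 1
    for lab in labels[2:]:
        # split a random existing edge (any non-root node's parent edge)
        edge_child = int(rng.choice([n for n in nodes if parent[n] is not None]))
        mid, leaf = nxt, nxt + 1
        nxt += 2
        p = parent[edge_child]
        children[p].remove(edge_child)
        children[p].append(mid)
        parent[mid] = p
        split = float(rng.uniform(0.1, 0.9))
        blen[mid] = blen[edge_child] * split
        blen[edge_child] = blen[edge_child] * (1 - split)
        parent[edge_child] = mid
        children[mid] = [edge_child, leaf]
        parent[leaf] = mid
        blen[leaf] = float(rng.uniform(0.05, 1.0))
        children[leaf] = []
        leaf_of[lab] = leaf
        nodes.extend([mid, leaf])

    def depth_chain(node):
        chain = {}
        d = 0.0
        while node is not None:
            chain[node] = d
            d += blen[node]
            node = parent[node]
        # chain maps node -> distance from leaf up to that node
        return chain

    d = np.zeros((n_taxa, n_taxa))
    for i, j in itertools.combinations(range(n_taxa), 2):
        ca = depth_chain(leaf_of[labels[i]])
        node = leaf_of[labels[j]]
        dist = 0.0
        while node not in ca:
            dist += blen[node]
            node = parent[node]
        d[i, j] = d[j, i] = dist + ca[node]
    return DistanceMatrix(labels, d), leaf_of, parent, blen


def true_bipartitions(labels, leaf_of, parent, blen):
    """Splits of the generating tree (oracle, independent of NJ)."""
    children = {}
    for n, p in parent.items():
        if p is not None:
            children.setdefault(p, []).append(n)
    leaves_below = {}

    def collect(node):
        kids = children.get(node, [])
        if not kids:
            name = [l for l, n in leaf_of.items() if n == node]
            leaves_below[node] = frozenset(name)
            return leaves_below[node]
        below = frozenset().union(*(collect(k) for k in kids))
        leaves_below[node] = below
        return below

    root = [n for n, p in parent.items() if p is None][0]
    collect(root)
    all_leaves = frozenset(labels)
    anchor = min(all_leaves)
    splits = set()
    for node, below in leaves_below.items():
        if 1 < len(below) < len(all_leaves) - 1:
            side = below if anchor not in below else all_leaves - below
            splits.add(side)
    return splits


def test_p_distance_identical_and_simple():
    a = SequenceRecord("a", "AAAA")
    b = SequenceRecord("b", "AAAT")
    dm = pairwise_distance([a, b, SequenceRecord("c", "AAAA")], "p_distance")
    assert dm.d[0, 2] == 0.0
    assert dm.d[0, 1] == pytest.approx(0.25)


def test_jukes_cantor_closed_form():
    # JC at p=0.25: -(3/4) ln(1 - 1/3) = 0.3041 to 4 d.p.
    a = SequenceRecord("a", "AAAA")
    b = SequenceRecord("b", "AAAT")
    dm = pairwise_distance([a, b], "jukes_cantor")
    assert dm.d[0, 1] == pytest.approx(-0.75 * math.log(1 - 1 / 3))
    assert round(float(dm.d[0, 1]), 4) == 0.3041


def test_pairwise_deletion_of_gap_and_n_columns():
    a = SequenceRecord("a", "A-CGTN")
    b = SequenceRecord("b", "AACGAA")
    dm = pairwise_distance([a, b], "p_distance")
    # compared sites: positions 0,2,3,4 -> one mismatch (T vs A)
    assert dm.d[0, 1] == pytest.approx(1 / 4)


def test_jc_saturation_errors_name_pair():
    a = SequenceRecord("sat1", "AAAA")
    b = SequenceRecord("sat2", "TTTT")
    with pytest.raises(ValueError, match="sat1.*sat2|sat2.*sat1"):
        pairwise_distance([a, b], "jukes_cantor")


def test_zero_comparable_sites_errors():
    a = SequenceRecord("a", "NNNN")
    b = SequenceRecord("b", "AAAA")
    with pytest.raises(ValueError, match="comparable"):
        pairwise_distance([a, b], "p_distance")


def test_distance_matrix_invariant_under_reordering():
    aln = simulate_clade_alignment(seed=1, n_per_clade=3, length=200)
    dm = pairwise_distance(aln, "p_distance")
    perm = aln[::-1]
    dm2 = pairwise_distance(perm, "p_distance")
    for i, a in enumerate(aln):
        for j, b in enumerate(aln):
            i2, j2 = dm2.labels.index(a.id), dm2.labels.index(b.id)
            assert dm.d[i, j] == pytest.approx(dm2.d[i2, j2])


def test_nj_three_taxa_closed_form():
    d = np.array([[0.0, 0.3, 0.5], [0.3, 0.0, 0.4], [0.5, 0.4, 0.0]])
    tree = nj_tree(DistanceMatrix(["a", "b", "c"], d))
    assert sorted(tree.leaf_names()) == ["a", "b", "c"]
    # closed form: l_a = (d_ab + d_ac - d_bc)/2 etc.
    lens = {c.name: c.branch_length for c in tree.root.children}
    assert lens["a"] == pytest.approx(0.2)
    assert lens["b"] == pytest.approx(0.1)
    assert lens["c"] == pytest.approx(0.3)


def test_nj_fewer_than_three_taxa_errors():
    with pytest.raises(ValueError):
        nj_tree(DistanceMatrix(["a", "b"], np.array([[0.0, 1.0], [1.0, 0.0]])))


@pytest.mark.parametrize("n_taxa", range(4, 13))
def test_nj_recovers_additive_matrices(n_taxa):
    """On additive matrices NJ must recover the generating topology exactly
    and every leaf-to-leaf path length must equal the input distance."""
    rng = np.random.default_rng(100 + n_taxa)
    dm, leaf_of, parent, blen = random_additive_matrix(rng, n_taxa)
    tree = nj_tree(dm)
    assert tree.bipartitions() == true_bipartitions(dm.labels, leaf_of, parent, blen)
    for i, j in itertools.combinations(range(n_taxa), 2):
        assert tree.path_length(dm.labels[i], dm.labels[j]) == \
               pytest.approx(dm.d[i, j], abs=1e-9)


def test_nj_four_taxa_beats_alternative_topologies():
    """NJ's 4-taxon split matches the least-squares-best of the three
    possible unrooted topologies (brute-force oracle)."""
    rng = np.random.default_rng(5)
    dm, *_ = random_additive_matrix(rng, 4)
    tree = nj_tree(dm)
    splits = tree.bipartitions()
    assert len(splits) == 1
    got = next(iter(splits))
    # brute force: for each pairing, additivity residual via four-point条件
    labels = dm.labels
    d = dm.d
    best = None
    for (i, j) in itertools.combinations(range(4), 2):
        k, l = [x for x in range(4) if x not in (i, j)]
        # four-point-condition residual of topology ij|kl
        resid = abs((d[i, k] + d[j, l]) - (d[i, l] + d[j, k]))
        side = frozenset([labels[i], labels[j]])
        anchor = min(labels)
        side = side if anchor not in side else frozenset(labels) - side
        if best is None or resid < best[0]:
            best = (resid, side)
    assert got == best[1]


def test_nj_matches_scikit_bio(recwarn):
    """Independent implementation cross-check on a noisy (non-additive)
    distance matrix."""
    from skbio import DistanceMatrix as SkbioDM
    from skbio.tree import nj as skbio_nj

    rng = np.random.default_rng(8)
    dm, *_ = random_additive_matrix(rng, 8)
    noisy = dm.d + rng.uniform(0, 0.02, size=dm.d.shape)
    noisy = (noisy + noisy.T) / 2
    np.fill_diagonal(noisy, 0.0)
    ours = nj_tree(DistanceMatrix(dm.labels, noisy))
    sk_tree = skbio_nj(SkbioDM(noisy, ids=dm.labels))
    anchor = min(dm.labels)
    all_leaves = frozenset(dm.labels)
    sk_splits = set()
    for node in sk_tree.non_tips():
        below = frozenset(t.name for t in node.tips())
        if 1 < len(below) < len(all_leaves) - 1:
            side = below if anchor not in below else all_leaves - below
            sk_splits.add(side)
    assert ours.bipartitions() == sk_splits


def test_bootstrap_deep_clades_high_support():
    aln = simulate_clade_alignment(seed=13, n_per_clade=5, length=600,
                                   between=0.15, within=0.01)
    tree = bootstrap_support(aln, "p_distance", n_replicates=200, seed=13)
    clade_a = frozenset(r.id for r in aln if r.id.startswith("cladeA"))
    clade_b = frozenset(r.id for r in aln if r.id.startswith("cladeB"))
    anchor = min(tree.leaf_names())
    split = clade_a if anchor not in clade_a else clade_b
    # locate the support annotated on the clade split
    found = []

    def collect(node):
        if node.is_leaf:
            return frozenset([node.name])
        below = frozenset().union(*(collect(c) for c in node.children))
        if node.support is not None:
            side = below if anchor not in below else frozenset(tree.leaf_names()) - below
            if side == split:
                found.append(node.support)
        return below

    collect(tree.root)
    assert found and found[0] >= 95.0


def test_bootstrap_single_replicate_binary_supports():
    aln = simulate_clade_alignment(seed=2, n_per_clade=3, length=300)
    tree = bootstrap_support(aln, "p_distance", n_replicates=1, seed=0)

    def supports(node):
        out = []
        for c in node.children:
            if not c.is_leaf:
                if c.support is not None:
                    out.append(c.support)
                out.extend(supports(c))
        return out

    assert all(s in (0.0, 100.0) for s in supports(tree.root))


def test_bootstrap_seed_reproducible():
    aln = simulate_clade_alignment(seed=4, n_per_clade=4, length=300)
    t1 = bootstrap_support(aln, "p_distance", 50, seed=21)
    t2 = bootstrap_support(aln, "p_distance", 50, seed=21)
    assert to_newick(t1) == to_newick(t2)


def test_newick_three_leaf_star(tmp_path):
    d = np.array([[0.0, 0.3, 0.5], [0.3, 0.0, 0.4], [0.5, 0.4, 0.0]])
    tree = nj_tree(DistanceMatrix(["A", "B", "C"], d))
    s = to_newick(tree)
    assert s.startswith("(") and s.endswith(");")
    assert all(name in s for name in "ABC")


@pytest.mark.parametrize("n_taxa", [8, 40])
def test_newick_round_trip_preserves_bipartitions(tmp_path, n_taxa):
    rng = np.random.default_rng(n_taxa)
    dm, *_ = random_additive_matrix(rng, n_taxa)
    tree = nj_tree(dm)
    path = tmp_path / "t.nwk"
    write_newick(tree, path)
    parsed = dendropy.Tree.get(path=str(path), schema="newick")
    parsed.encode_bipartitions()
    anchor = min(dm.labels)
    all_leaves = frozenset(dm.labels)
    got = set()
    for node in parsed.preorder_node_iter():
        if node.is_leaf() or node.parent_node is None:
            continue
        below = frozenset(l.taxon.label for l in node.leaf_iter())
        if 1 < len(below) < len(all_leaves) - 1:
            side = below if anchor not in below else all_leaves - below
            got.add(side)
    assert got == tree.bipartitions()
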