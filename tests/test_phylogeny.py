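"""Distance transform, neighbor joining, bootstrap supports, collapsing and
monophyly."""

import itertools

import numpy as np
import pytest
from skbio import DistanceMatrix
from skbio.tree import nj as skbio_nj

from rtphylo.core import AlignedRecord, Msa
from rtphylo.derep import IdentityMatrix
from rtphylo.phylogeny import (SupportTree, bootstrap_support, collapse,
                               distance_from_identity, nj_tree)
from rtphylo.phylogeny import test_monophyly as check_monophyly


# -- distance transform -----------------------------------------------------

def _identity(ids, values, overlap=None):
    values = np.array(values, dtype=float)
    if overlap is None:
        overlap = np.full_like(values, 10, dtype=np.int64)
    return IdentityMatrix(list(ids), values, np.array(overlap))


def test_distance_is_one_minus_identity_fraction():
    im = _identity("ab", [[100, 40], [40, 100]])
    dm = distance_from_identity(im)
    assert dm["a", "b"] == pytest.approx(0.60)
    assert dm["a", "a"] == 0.0


def test_zero_overlap_pairs_capped_at_095():
    overlap = [[10, 0], [0, 10]]
    im = _identity("ab", [[100, 0], [0, 100]], overlap)
    assert distance_from_identity(im)["a", "b"] == 0.95


def test_triangle_violation_logged_not_repaired(caplog):
    values = [[100, 95, 10], [95, 100, 95], [10, 95, 100]]
    with caplog.at_level("INFO"):
        dm = distance_from_identity(_identity("abc", values))
    # d(a,c)=0.90 > d(a,b)+d(b,c)=0.10: violation kept as-is
    assert dm["a", "c"] == pytest.approx(0.90)
    assert any("triangle" in r.message for r in caplog.records)


# -- neighbor joining -------------------------------------------------------

def _tree_distances(tree: SupportTree):
    """Leaf-to-leaf path lengths of a SupportTree."""
    tips = list(tree.root.tips())
    names = [t.name for t in tips]
    out = {}
    for a, b in itertools.combinations(tips, 2):
        out[frozenset((a.name, b.name))] = a.distance(b)
    return names, out


def test_four_taxon_additive_matrix_recovers_tree_and_lengths():
    # ((A:1,B:2):1,(C:3,D:4)) as an additive distance matrix
    dm = DistanceMatrix(np.array([
        [0, 3, 5, 6],
        [3, 0, 6, 7],
        [5, 6, 0, 7],
        [6, 7, 7, 0]], dtype=float), ["A", "B", "C", "D"])
    tree = nj_tree(dm)
    truth = SupportTree.from_newick("((A:1,B:2):1,(C:3,D:4));")
    assert tree.rf_distance(truth) == 0.0
    _, dist = _tree_distances(tree)
    for pair, d in dist.items():
        a, b = sorted(pair)
        assert d == pytest.approx(dm[a, b])


def test_three_taxa_closed_form():
    dm = DistanceMatrix(np.array([
        [0, 3, 4], [3, 0, 5], [4, 5, 0]], dtype=float), ["A", "B", "C"])
    tree = nj_tree(dm)
    lengths = {t.name: t.length for t in tree.root.tips()}
    assert lengths == pytest.approx({"A": 1.0, "B": 2.0, "C": 3.0})


def test_fewer_than_three_taxa_is_error():
    dm = DistanceMatrix(np.array([[0, 1.0], [1.0, 0]]), ["A", "B"])
    with pytest.raises(ValueError):
        nj_tree(dm)


def test_negative_branch_lengths_clamped():
    # strongly non-additive matrix that would produce a negative branch
    dm = DistanceMatrix(np.array([
        [0, 1, 9, 9], [1, 0, 1, 9], [9, 1, 0, 1], [9, 9, 1, 0]],
        dtype=float), list("ABCD"))
    tree = nj_tree(dm)
    assert all(t.length >= 0 for t in tree.root.traverse() if t.length is not None)


def _random_additive(rng, n):
    """Random binary tree on n taxa; returns (ids, matrix, SupportTree)."""
    from skbio import TreeNode

    nodes = [TreeNode(name=f"t{i}") for i in range(n)]
    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), 2, replace=False))
        a, b = nodes[i], nodes[j]
        a.length = float(rng.uniform(0.1, 1.0))
        b.length = float(rng.uniform(0.1, 1.0))
        nodes = [nodes[k] for k in range(len(nodes)) if k not in (i, j)]
        nodes.append(TreeNode(children=[a, b]))
    for c in nodes:
        c.length = float(rng.uniform(0.1, 1.0))
    tree = SupportTree(TreeNode(children=nodes))
    tips = list(tree.root.tips())
    ids = [t.name for t in tips]
    D = np.zeros((n, n))
    for x, y in itertools.combinations(range(n), 2):
        D[x, y] = D[y, x] = tips[x].distance(tips[y])
    return ids, D, tree


@pytest.mark.parametrize("seed", range(15))
def test_nj_recovers_random_additive_topologies(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(4, 9))
    ids, D, truth = _random_additive(rng, n)
    tree = nj_tree(DistanceMatrix(D, ids))
    assert tree.rf_distance(truth) == 0.0


@pytest.mark.parametrize("seed", range(5))
def test_nj_topology_invariant_under_taxon_permutation(seed):
    rng = np.random.default_rng(100 + seed)
    ids, D, _ = _random_additive(rng, 8)
    tree = nj_tree(DistanceMatrix(D, ids))
    perm = rng.permutation(len(ids))
    tree_p = nj_tree(DistanceMatrix(D[np.ix_(perm, perm)],
                                    [ids[p] for p in perm]))
    assert tree.rf_distance(tree_p) == 0.0


@pytest.mark.parametrize("seed", range(5))
def test_nj_agrees_with_independent_library_implementation(seed):
    rng = np.random.default_rng(200 + seed)
    ids, D, _ = _random_additive(rng, 7)
    ours = nj_tree(DistanceMatrix(D, ids))
    theirs = SupportTree(skbio_nj(DistanceMatrix(D, ids)))
    assert ours.rf_distance(theirs) == 0.0


# -- bootstrap --------------------------------------------------------------

def _two_block_msa(rng, n_per=4, length=120, d_within=1, d_between=30):
    """Two clearly separated blocks of rows differing in ~d sites."""
    aa = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
    base1 = rng.integers(0, 20, size=length)
    base2 = base1.copy()
    base2[rng.choice(length, d_between, replace=False)] = \
        rng.integers(0, 20, size=d_between)
    rows = []
    for g, base in (("g1", base1), ("g2", base2)):
        for i in range(n_per):
            row = base.copy()
            sites = rng.choice(length, d_within, replace=False)
            row[sites] = rng.integers(0, 20, size=d_within)
            rows.append(AlignedRecord(f"{g}_{i}", "".join(aa[row])))
    return Msa(rows)


def test_central_edge_of_separated_groups_has_full_support():
    rng = np.random.default_rng(5)
    msa = _two_block_msa(rng)
    tree = bootstrap_support(msa, n_reps=100, seed=17)
    ok, support = check_monophyly(tree, [f"g1_{i}" for i in range(4)])
    assert ok and support == 1.0


def test_bootstrap_reproducible_under_seed():
    rng = np.random.default_rng(6)
    msa = _two_block_msa(rng)
    t1 = bootstrap_support(msa, n_reps=25, seed=99)
    t2 = bootstrap_support(msa, n_reps=25, seed=99)
    assert t1.to_newick() == t2.to_newick()


def test_zero_replicates_leaves_supports_unset(caplog):
    rng = np.random.default_rng(7)
    msa = _two_block_msa(rng)
    with caplog.at_level("WARNING"):
        tree = bootstrap_support(msa, n_reps=0)
    assert all(n.support is None for n in tree.internal_nodes())
    assert any("0 replicates" in r.message for r in caplog.records)


def test_bootstrap_supports_in_unit_interval(benchmark_truth):
    msa = benchmark_truth.msa.subset(
        [r.id for r in benchmark_truth.records[:24]])
    tree = bootstrap_support(msa, n_reps=20, seed=3)
    sups = [n.support for n in tree.internal_nodes() if n.support is not None]
    assert sups and all(0.0 <= s <= 1.0 for s in sups)


# -- collapse ---------------------------------------------------------------

def _supported_tree(newick):
    return SupportTree.from_newick(newick)


def test_collapse_keeps_fully_supported_tree():
    tree = _supported_tree("((A:1,B:1)1.0:1,(C:1,D:1)1.0:1,E:1);")
    out = collapse(tree, 0.96)
    assert out.n_internal_edges() == 2
    assert tree.rf_distance(out) == 0.0


def test_collapse_all_zero_supports_gives_star():
    tree = _supported_tree("((A:1,B:1)0.0:1,(C:1,D:1)0.0:1,E:1);")
    out = collapse(tree, 0.75)
    assert out.n_internal_edges() == 0
    assert out.leaf_names == {"A", "B", "C", "D", "E"}


def test_collapse_threshold_is_inclusive():
    # support exactly at the threshold survives; below is contracted
    tree = _supported_tree("((A:1,B:1)0.96:1,(C:1,D:1)0.5:1,E:1);")
    out = collapse(tree, 0.96)
    assert out.n_internal_edges() == 1
    [kept] = out.internal_nodes()
    assert {t.name for t in kept.tips()} == {"A", "B"}


def test_collapse_preserves_leaf_path_lengths():
    tree = _supported_tree("((A:1,B:1)0.5:2,(C:1,D:1)1.0:1,E:1);")
    tips = {t.name: t for t in tree.root.tips()}
    before = tips["A"].distance(tips["E"])
    out = collapse(tree, 0.96)
    tips2 = {t.name: t for t in out.root.tips()}
    assert tips2["A"].distance(tips2["E"]) == pytest.approx(before)


def test_collapse_is_monotone_in_threshold():
    tree = _supported_tree(
        "(((A:1,B:1)0.3:1,C:1)0.6:1,((D:1,E:1)0.8:1,F:1)0.97:1,G:1);")
    edges = [collapse(tree, t).n_internal_edges()
             for t in (0.0, 0.3, 0.6, 0.8, 0.97, 1.01)]
    assert edges == sorted(edges, reverse=True)


# -- monophyly --------------------------------------------------------------

def test_planted_clade_is_monophyletic(benchmark_truth):
    msa = benchmark_truth.msa
    tree = bootstrap_support(msa, n_reps=30, seed=8)
    retron = benchmark_truth.members("retron")
    ok, support = check_monophyly(tree, retron)
    assert ok
    assert support == pytest.approx(1.0)


def test_interleaved_groups_are_not_monophyletic():
    tree = _supported_tree("((A:1,C:1):1,(B:1,D:1):1,E:1);")
    ok, _ = check_monophyly(tree, ["A", "B"])
    assert not ok


def test_singleton_is_monophyletic_by_convention():
    tree = _supported_tree("((A:1,B:1):1,C:1,D:1);")
    ok, support = check_monophyly(tree, ["A"])
    assert ok and support is None


def test_empty_and_full_label_sets_are_errors():
    tree = _supported_tree("((A:1,B:1):1,C:1,D:1);")
    with pytest.raises(ValueError):
        check_monophyly(tree, [])
    with pytest.raises(ValueError):
        check_monophyly(tree, ["A", "B", "C", "D"])
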