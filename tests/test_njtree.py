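"""Neighbor joining, bootstrap supports and polytomy collapsing.

Additive-matrix recovery is checked against the generating tree itself
(four-point condition: the tree metric determines the topology uniquely)
and cross-checked against an independent library NJ implementation.
"""

import itertools
import random

import dendropy
import numpy as np
import pytest

from barcodekit.distmat import DistanceMatrix, PairDistance, build_matrix
from barcodekit.njtree import (
    SupportTree,
    bootstrap_supports,
    collapse,
    internal_bipartitions,
    nj,
    prune_leaves,
    root_tree,
)
from barcodekit.synthetic_data import SimConfig, simulate

from conftest import make_record


def matrix_from_array(ids, arr, min_overlap=1):
    entries = {}
    for i, a in enumerate(ids):
        for j in range(i + 1, len(ids)):
            entries[frozenset((a, ids[j]))] = PairDistance(
                id_a=a, id_b=ids[j], model="k2p", n_sites=1000,
                n_transitions=0, n_transversions=0, d=float(arr[i][j]),
            )
    return DistanceMatrix(
        ids=list(ids), model="k2p", min_overlap=min_overlap, entries=entries
    )


def leaf_splits(tree: dendropy.Tree):
    return internal_bipartitions(tree)


def random_additive(n_taxa: int, rng: np.random.Generator):
    """Random binary tree with positive branch lengths and its metric."""
    ids = [f"t{i}" for i in range(n_taxa)]
    taxa = dendropy.TaxonNamespace(ids)
    tree = dendropy.simulate.treesim.birth_death_tree(
        birth_rate=1.0, death_rate=0.0, num_extant_tips=n_taxa,
        taxon_namespace=taxa, rng=random.Random(int(rng.integers(2**31))),
    )
    for edge in tree.preorder_edge_iter():
        if edge.tail_node is not None:
            edge.length = float(rng.uniform(0.05, 1.0))
    pdm = tree.phylogenetic_distance_matrix()
    arr = np.zeros((n_taxa, n_taxa))
    for i, j in itertools.combinations(range(n_taxa), 2):
        d = pdm.patristic_distance(taxa.get_taxon(ids[i]), taxa.get_taxon(ids[j]))
        arr[i, j] = arr[j, i] = d
    tree.is_rooted = False
    return ids, arr, tree


def test_four_taxon_additive_recovery_by_hand():
    # Tree ((a:1,b:2):1,(c:3,d:4)); additive distances built by hand.
    ids = ["a", "b", "c", "d"]
    arr = [
        [0, 3, 5, 6],
        [3, 0, 6, 7],
        [5, 6, 0, 7],
        [6, 7, 7, 0],
    ]
    stree = nj(matrix_from_array(ids, arr))
    splits = leaf_splits(stree.tree)
    assert splits == {frozenset({"a", "b"})} or splits == {frozenset({"c", "d"})}
    # Path lengths reproduce the input metric exactly.
    pdm = stree.tree.phylogenetic_distance_matrix()
    tns = stree.tree.taxon_namespace
    for i, j in itertools.combinations(range(4), 2):
        assert pdm.patristic_distance(
            tns.get_taxon(ids[i]), tns.get_taxon(ids[j])
        ) == pytest.approx(arr[i][j], abs=1e-9)


def test_three_taxa_closed_form():
    ids = ["a", "b", "c"]
    arr = [[0, 3, 4], [3, 0, 5], [4, 5, 0]]
    stree = nj(matrix_from_array(ids, arr))
    lengths = {
        lf.taxon.label: lf.edge.length for lf in stree.tree.leaf_node_iter()
    }
    assert lengths == pytest.approx({"a": 1.0, "b": 2.0, "c": 3.0})


@pytest.mark.parametrize("n_taxa", [5, 6, 8])
def test_random_additive_recovery_vs_generating_tree(n_taxa):
    rng = np.random.default_rng(100 + n_taxa)
    for _ in range(5):
        ids, arr, true_tree = random_additive(n_taxa, rng)
        stree = nj(matrix_from_array(ids, arr))
        assert leaf_splits(stree.tree) == internal_bipartitions(true_tree)


def test_additive_recovery_cross_checked_against_skbio():
    skbio = pytest.importorskip("skbio")
    rng = np.random.default_rng(77)
    ids, arr, true_tree = random_additive(7, rng)
    ours = nj(matrix_from_array(ids, arr))
    dm = skbio.DistanceMatrix(arr, ids)
    theirs = skbio.tree.nj(dm)
    their_splits = set()
    n = len(ids)
    for node in theirs.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        other = frozenset(ids) - side
        if 1 < len(side) < n - 1:
            key = side if (len(side), sorted(side)) <= (len(other), sorted(other)) else other
            their_splits.add(key)
    assert leaf_splits(ours.tree) == their_splits


def test_input_order_permutation_invariance():
    rng = np.random.default_rng(5)
    ids, arr, _ = random_additive(6, rng)
    base_splits = leaf_splits(nj(matrix_from_array(ids, arr)).tree)
    perm = rng.permutation(len(ids))
    ids_p = [ids[i] for i in perm]
    arr_p = np.asarray(arr)[np.ix_(perm, perm)]
    assert leaf_splits(nj(matrix_from_array(ids_p, arr_p)).tree) == base_splits


def test_nj_requires_defined_matrix_and_three_taxa():
    ids = ["a", "b"]
    with pytest.raises(ValueError, match="3 taxa"):
        nj(matrix_from_array(ids, [[0, 1], [1, 0]]))
    m = matrix_from_array(["a", "b", "c"], [[0, 1, 1], [1, 0, 1], [1, 1, 0]])
    key = frozenset(("a", "b"))
    m.entries[key] = PairDistance(
        id_a="a", id_b="b", model="k2p", n_sites=10,
        n_transitions=0, n_transversions=0, d=None,
    )
    with pytest.raises(ValueError, match="undefined"):
        nj(m)


# -- bootstrap ----------------------------------------------------------------

@pytest.fixture(scope="module")
def two_cluster_records():
    records, _ = simulate(
        SimConfig(n_species=2, n_per_species=3, seq_len=1000,
                  species_tree_height=0.20, intra_height=0.005, seed=8)
    )
    return records


def test_cluster_separating_edge_high_support(two_cluster_records):
    stree = bootstrap_supports(two_cluster_records, B=100, seed=4)
    sep = frozenset(r.id for r in two_cluster_records if r.species == "sp1")
    other = frozenset(r.id for r in two_cluster_records) - sep
    key = sep if (len(sep), sorted(sep)) <= (len(other), sorted(other)) else other
    assert stree.supports[key] >= 99


def test_bootstrap_b1_and_reproducibility(two_cluster_records):
    one = bootstrap_supports(two_cluster_records, B=1, seed=123)
    assert set(one.supports.values()) <= {0, 100}
    a = bootstrap_supports(two_cluster_records, B=20, seed=9)
    b = bootstrap_supports(two_cluster_records, B=20, seed=9)
    assert a.supports == b.supports


def test_bootstrap_supports_in_newick_output(two_cluster_records):
    stree = bootstrap_supports(two_cluster_records, B=10, seed=1)
    nwk = stree.as_newick()
    for val in stree.supports.values():
        assert str(val) in nwk


# -- collapse -----------------------------------------------------------------

def test_collapse_identity_and_star():
    rng = np.random.default_rng(3)
    ids, arr, _ = random_additive(6, rng)
    stree = nj(matrix_from_array(ids, arr))
    same = collapse(stree, 0.0)
    assert leaf_splits(same.tree) == leaf_splits(stree.tree)
    star = collapse(stree, float("inf"))
    assert leaf_splits(star.tree) == set()
    assert sorted(star.leaf_ids) == sorted(ids)


def test_identical_sequences_collapse_to_polytomy():
    base = "ACGT" * 100
    mut = base[:-1] + "C"
    records = [
        make_record("a1", base, species="A"),
        make_record("a2", base, species="A"),
        make_record("a3", base, species="A"),
        make_record("b1", mut.replace("A", "G"), species="B"),
        make_record("b2", mut.replace("A", "G"), species="B"),
    ]
    m = build_matrix(records, min_overlap=10)
    stree = collapse(nj(m))
    # The three identical sequences form a polytomy: no internal split
    # separates a strict subset of {a1,a2,a3}.
    for split in leaf_splits(stree.tree):
        assert not split < {"a1", "a2", "a3"}
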