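"""Best Match / Best Close Match / All Species Barcodes rules."""

import math

import pytest

from barcodekit.distmat import DistanceMatrix, PairDistance, build_matrix
from barcodekit.ident_distance import (
    Threshold,
    all_species_barcodes,
    best_close_match,
    best_match,
    derive_threshold,
    identify_all,
    summarize,
)
from barcodekit.synthetic_data import SimConfig, simulate

from conftest import random_records


def matrix_from_table(ids, table, min_overlap=300):
    """Build a DistanceMatrix directly from a dict {(a, b): d}."""
    entries = {}
    for i, a in enumerate(ids):
        for b in ids[i + 1 :]:
            d = table[(a, b)] if (a, b) in table else table[(b, a)]
            entries[frozenset((a, b))] = PairDistance(
                id_a=a,
                id_b=b,
                model="k2p",
                n_sites=500,
                n_transitions=0,
                n_transversions=0,
                d=d,
            )
    return DistanceMatrix(
        ids=list(ids), model="k2p", min_overlap=min_overlap, entries=entries
    )


@pytest.fixture
def toy():
    """6 sequences, 3 species; a1's nearest is conspecific a2."""
    ids = ["a1", "a2", "b1", "b2", "c1", "c2"]
    labels = {"a1": "A", "a2": "A", "b1": "B", "b2": "B", "c1": "C", "c2": "C"}
    table = {
        ("a1", "a2"): 0.01, ("b1", "b2"): 0.012, ("c1", "c2"): 0.008,
        ("a1", "b1"): 0.11, ("a1", "b2"): 0.12, ("a2", "b1"): 0.10,
        ("a2", "b2"): 0.13, ("a1", "c1"): 0.21, ("a1", "c2"): 0.22,
        ("a2", "c1"): 0.20, ("a2", "c2"): 0.23, ("b1", "c1"): 0.16,
        ("b1", "c2"): 0.17, ("b2", "c1"): 0.15, ("b2", "c2"): 0.18,
    }
    return matrix_from_table(ids, table), labels


def test_threshold_is_bruteforce_minimum(toy):
    matrix, labels = toy
    th = derive_threshold(matrix, labels)
    expected = min(
        p.d for p in matrix.iter_pairs() if labels[p.id_a] != labels[p.id_b]
    )
    assert th.value == expected == 0.10
    assert th.provenance == "smallest_interspecific"


def test_threshold_requires_interspecific_pairs():
    records = random_records(3, 350, seed=2, n_species=1)
    m = build_matrix(records)
    with pytest.raises(ValueError, match="interspecific"):
        derive_threshold(m, {r.id: "one" for r in records})


def test_best_match_nearest_conspecific(toy):
    matrix, labels = toy
    out = best_match("a1", matrix, labels)
    assert out.outcome == "correct"
    assert out.best_ids == ("a2",)
    assert out.best_distance == 0.01


def test_best_match_tie_with_allospecific_is_ambiguous():
    ids = ["a1", "a2", "b1"]
    labels = {"a1": "A", "a2": "A", "b1": "B"}
    table = {("a1", "a2"): 0.05, ("a1", "b1"): 0.05, ("a2", "b1"): 0.2}
    m = matrix_from_table(ids, table)
    out = best_match("a1", m, labels)
    assert out.outcome == "ambiguous"
    assert out.best_ids == ("a2", "b1")


def test_best_match_single_wrong_label_is_misidentified():
    ids = ["a1", "a2", "b1"]
    labels = {"a1": "A", "a2": "A", "b1": "B"}
    table = {("a1", "a2"): 0.3, ("a1", "b1"): 0.05, ("a2", "b1"): 0.4}
    m = matrix_from_table(ids, table)
    assert best_match("a1", m, labels).outcome == "misidentified"


def test_bcm_threshold_boundary_is_strict(toy):
    matrix, labels = toy
    th = derive_threshold(matrix, labels)
    # a2's best distance is 0.01 < 0.10 -> correct.
    assert best_close_match("a2", matrix, labels, th).outcome == "correct"
    # At exactly the threshold the match is rejected.
    at = Threshold(value=0.01, model="k2p")
    assert best_close_match("a2", matrix, labels, at).outcome == "no_match"


def test_bcm_equals_bm_at_infinite_threshold():
    records = random_records(12, 400, seed=9, n_species=3)
    m = build_matrix(records, model="uncorrected", min_overlap=50)
    labels = {r.id: r.species for r in records}
    inf = Threshold(value=math.inf, model="k2p")
    for q in m.ids:
        bm = best_match(q, m, labels)
        bcm = best_close_match(q, m, labels, inf)
        assert bcm.outcome == bm.outcome
        assert bcm.best_ids == bm.best_ids


def test_bcm_never_misidentifies_with_derived_threshold():
    """Every strictly sub-threshold match is intraspecific by construction
    when the threshold is the smallest interspecific distance."""
    for seed in range(4):
        records, _ = simulate(
            SimConfig(n_species=4, n_per_species=3, seq_len=600,
                      species_tree_height=0.15, intra_height=0.02, seed=seed)
        )
        m = build_matrix(records)
        labels = {r.id: r.species for r in records}
        th = derive_threshold(m, labels)
        for q in m.ids:
            assert best_close_match(q, m, labels, th).outcome != "misidentified"


# -- ASB case table (exhaustive over the rule's branches) ---------------------

def asb_fixture(conspecific_ds, allospecific_ds, threshold=0.1):
    """Query q with conspecific references x1.. and allospecific y1..."""
    ids = ["q"] + [f"x{i}" for i in range(len(conspecific_ds))] + [
        f"y{i}" for i in range(len(allospecific_ds))
    ]
    labels = {i: ("S" if i == "q" or i.startswith("x") else "T") for i in ids}
    table = {}
    for i, d in enumerate(conspecific_ds):
        table[("q", f"x{i}")] = d
    for i, d in enumerate(allospecific_ds):
        table[("q", f"y{i}")] = d
    for a in ids[1:]:
        for b in ids[1:]:
            if a < b:
                table[(a, b)] = 0.5
    m = matrix_from_table(ids, table)
    return m, labels, Threshold(value=threshold, model="k2p")


@pytest.mark.parametrize(
    "consp,allo,expected",
    [
        ([0.01, 0.02, 0.03], [0.5], "correct"),  # all 3 conspecifics inside
        ([0.01], [0.5], "ambiguous"),  # only one conspecific barcode
        ([0.01, 0.02], [0.05], "misidentified"),  # an allospecific inside
        ([0.01, 0.02, 0.3], [0.5], "ambiguous"),  # a portion only: x2 outside
        ([0.3, 0.4], [0.5], "no_match"),  # nothing inside the threshold
    ],
)
def test_asb_case_table(consp, allo, expected):
    m, labels, th = asb_fixture(consp, allo)
    assert all_species_barcodes("q", m, labels, th).outcome == expected


def test_category_counts_sum_to_query_count():
    records, _ = simulate(SimConfig(seed=21))
    m = build_matrix(records)
    labels = {r.id: r.species for r in records}
    results = identify_all(m, labels)
    for method, outcomes in results.items():
        s = summarize(outcomes)
        assert sum(s["counts"].values()) == s["n_queries"] == len(outcomes)
        assert sum(s["percent"].values()) == pytest.approx(100.0)
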