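"""Jaccard/hypergeometric conservation statistics and motif discovery."""

from math import comb

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from organnet.community import GeneModule, ModuleCollection
from organnet.conservation import (
    ModuleSimilarityEdge,
    build_similarity_network,
    conservation_groups,
    find_triangles,
    hypergeom_overlap_test,
    jaccard,
    three_way_subgroup,
)
from organnet.errors import DataError


def _module(organ, mid, genes):
    return GeneModule(organ, mid, frozenset(genes))


def _collection(organ, modules, universe=None):
    coll = ModuleCollection(organ, modules, resolution=0.2, seed=0, min_size=1)
    if universe is not None:
        coll.universe = frozenset(universe)
    return coll


# ------------------------------------------------------------------ jaccard
def test_jaccard_examples():
    a = {f"g{i}" for i in range(1, 11)}
    b = {f"g{i}" for i in range(6, 16)}
    assert jaccard(a, a) == 1.0
    assert jaccard(a, {"x", "y"}) == 0.0
    assert jaccard(a, b) == pytest.approx(5 / 15)


def test_jaccard_both_empty_rejected():
    with pytest.raises(DataError):
        jaccard(set(), set())


@settings(max_examples=50, deadline=None, derandomize=True)
@given(
    st.sets(st.integers(0, 30), min_size=1, max_size=15),
    st.sets(st.integers(0, 30), max_size=15),
)
def test_jaccard_symmetric_and_bounded(a, b):
    assert jaccard(a, b) == jaccard(b, a)
    assert 0.0 <= jaccard(a, b) <= 1.0


# ------------------------------------------------- hypergeom_overlap_test
def test_hypergeometric_trivial_tails():
    assert hypergeom_overlap_test(0, 5, 5, 20) == 1.0
    assert hypergeom_overlap_test(7, 7, 7, 7) == 1.0


def test_hypergeometric_enumeration_example():
    # sum_{k=3..5} C(5,k) C(15,5-k) / C(20,5) = 1126/15504
    expected = (comb(5, 3) * comb(15, 2) + comb(5, 4) * comb(15, 1) + comb(5, 5)) / comb(20, 5)
    assert hypergeom_overlap_test(3, 5, 5, 20) == pytest.approx(expected, rel=1e-12)
    assert expected == pytest.approx(1126 / 15504)


def test_hypergeometric_inconsistent_counts_rejected():
    with pytest.raises(DataError):
        hypergeom_overlap_test(6, 5, 5, 20)
    with pytest.raises(DataError):
        hypergeom_overlap_test(1, 25, 5, 20)


# --------------------------------------------------- build_similarity_network
def test_identical_partitions_match_perfectly():
    genes = [f"g{i}" for i in range(40)]
    mods_a = [_module("liver", 0, genes[:20]), _module("liver", 1, genes[20:])]
    mods_b = [_module("kidney", 0, genes[:20]), _module("kidney", 1, genes[20:])]
    edges = build_similarity_network(
        [_collection("liver", mods_a, genes), _collection("kidney", mods_b, genes)]
    )
    assert len(edges) == 2
    assert all(e.jaccard == 1.0 for e in edges)
    matched = {(e.module_a[1], e.module_b[1]) for e in edges}
    assert matched == {(0, 0), (1, 1)}


def test_zero_overlap_pairs_never_edge():
    genes = [f"g{i}" for i in range(40)]
    edges = build_similarity_network(
        [
            _collection("a", [_module("a", 0, genes[:10])], genes),
            _collection("b", [_module("b", 0, genes[10:20])], genes),
        ]
    )
    assert edges == []


def test_single_organ_rejected():
    with pytest.raises(DataError):
        build_similarity_network([_collection("a", [_module("a", 0, {"g"})])])


# -------------------------------------------------------- conservation groups
def _edge(a, b):
    return ModuleSimilarityEdge(a, b, 0.5, 5, 1e-6, 1e-5)


def test_empty_edge_list_gives_no_groups():
    assert conservation_groups([], []) == []


def test_single_edge_two_module_group():
    colls = [
        _collection("a", [_module("a", 0, {"g1", "g2"})]),
        _collection("b", [_module("b", 0, {"g2", "g3"})]),
    ]
    groups = conservation_groups([_edge(("a", 0), ("b", 0))], colls)
    assert len(groups) == 1
    assert groups[0].group_id == "BC1"
    assert groups[0].organs_present == {"a", "b"}
    assert groups[0].union_genes == {"g1", "g2", "g3"}


def test_transitive_component_and_labeling_by_gene_count():
    colls = [
        _collection("a", [_module("a", 0, {"g1"}), _module("a", 1, set("pqrstuv"))]),
        _collection("b", [_module("b", 0, {"g2"}), _module("b", 1, set("pqrxyz"))]),
        _collection("c", [_module("c", 0, {"g3"})]),
    ]
    edges = [
        _edge(("a", 0), ("b", 0)),
        _edge(("b", 0), ("c", 0)),
        _edge(("a", 1), ("b", 1)),
    ]
    groups = conservation_groups(edges, colls)
    assert len(groups) == 2
    assert groups[0].group_id == "BC1"  # bigger union: p..z
    assert groups[0].member_modules == {("a", 1), ("b", 1)}
    assert groups[1].member_modules == {("a", 0), ("b", 0), ("c", 0)}


def test_group_membership_invariant_to_edge_order():
    colls = [
        _collection("a", [_module("a", 0, {"g1"})]),
        _collection("b", [_module("b", 0, {"g2"})]),
        _collection("c", [_module("c", 0, {"g3"})]),
    ]
    edges = [
        _edge(("a", 0), ("b", 0)),
        _edge(("b", 0), ("c", 0)),
        _edge(("a", 0), ("c", 0)),
    ]
    g1 = conservation_groups(edges, colls)
    g2 = conservation_groups(edges[::-1], colls)
    assert [g.member_modules for g in g1] == [g.member_modules for g in g2]


# ------------------------------------------------------------------ triangles
def test_three_cycle_across_three_organs_is_one_triangle():
    colls = [
        _collection("a", [_module("a", 0, {"g"})]),
        _collection("b", [_module("b", 0, {"g"})]),
        _collection("c", [_module("c", 0, {"g"})]),
    ]
    edges = [
        _edge(("a", 0), ("b", 0)),
        _edge(("b", 0), ("c", 0)),
        _edge(("a", 0), ("c", 0)),
    ]
    groups = conservation_groups(edges, colls)
    assert find_triangles(groups[0], edges) == [(("a", 0), ("b", 0), ("c", 0))]


def test_open_path_has_no_triangle():
    colls = [
        _collection("a", [_module("a", 0, {"g"})]),
        _collection("b", [_module("b", 0, {"g"})]),
        _collection("c", [_module("c", 0, {"g"})]),
    ]
    edges = [_edge(("a", 0), ("b", 0)), _edge(("b", 0), ("c", 0))]
    groups = conservation_groups(edges, colls)
    assert find_triangles(groups[0], edges) == []


# ------------------------------------------------------- three_way_subgroup
def test_identical_modules_forced_fold():
    genes = frozenset(f"g{i}" for i in range(20))
    sub = three_way_subgroup(
        _module("a", 0, genes), _module("b", 0, genes), _module("c", 0, genes), N=100
    )
    assert sub.observed_overlap == 20
    assert sub.expected_overlap == pytest.approx(4.0)
    assert sub.fold_enrichment == pytest.approx(5.0)


def test_fold_from_expected_overlap_formula():
    # |A ∩ B| = 10, |C| = 20, core = 6, N = 100 -> expected 2, fold 3
    shared = [f"s{i}" for i in range(10)]
    a = _module("a", 0, shared + [f"a{i}" for i in range(10)])
    b = _module("b", 0, shared + [f"b{i}" for i in range(10)])
    c = _module("c", 0, shared[:6] + [f"c{i}" for i in range(14)])
    sub = three_way_subgroup(a, b, c, N=100)
    assert sub.observed_overlap == 6
    assert sub.expected_overlap == pytest.approx(2.0)
    assert sub.fold_enrichment == pytest.approx(3.0)


def test_disjoint_third_module_not_conserved():
    shared = [f"s{i}" for i in range(10)]
    a = _module("a", 0, shared)
    b = _module("b", 0, shared)
    c = _module("c", 0, [f"c{i}" for i in range(10)])
    sub = three_way_subgroup(a, b, c, N=100)
    assert sub.observed_overlap == 0
    assert sub.p == 1.0


def test_fold_identity_on_random_module_triples(rng):
    """fold_enrichment is exactly observed * N / (n1 * n2) for random modules."""
    universe = np.arange(200)
    for _ in range(200):
        a = _module("a", 0, map(str, rng.choice(universe, rng.integers(5, 60), replace=False)))
        b = _module("b", 0, map(str, rng.choice(universe, rng.integers(5, 60), replace=False)))
        c = _module("c", 0, map(str, rng.choice(universe, rng.integers(5, 60), replace=False)))
        sub = three_way_subgroup(a, b, c, N=200)
        n1 = len(set(a.members) & set(b.members))
        if n1 == 0:
            assert sub.fold_enrichment is None
            continue
        assert sub.fold_enrichment == sub.observed_overlap * 200 / (n1 * c.size)
        assert sub.expected_overlap == n1 * c.size / 200
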