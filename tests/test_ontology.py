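"""OBO parsing, DAG queries, information content and the correlation
matrix with its normalization."""

import math

import numpy as np
import pytest

from gogcn.exceptions import CycleError, OntologyError
from gogcn.ontology import (
    OntologyGraph,
    TermIndex,
    correlation_matrix,
    descendants_within,
    information_content,
    normalize_adjacency,
    parse_obo,
)

from conftest import FIG1_ANCESTORS, random_dag
from oracles import reachable_ancestors, reachable_descendants


class TestParseObo:
    def test_obsolete_terms_are_dropped(self, toy_obo):
        graph = parse_obo(toy_obo)
        assert graph.terms == {"GO:0000001", "GO:0000003"}
        assert graph.edges == {("GO:0000003", "GO:0000001", "is_a")}

    def test_alt_id_mapping(self, toy_obo):
        graph = parse_obo(toy_obo)
        assert graph.alt_ids == {"GO:0000002": "GO:0000001"}
        assert graph.resolve("GO:0000002") == "GO:0000001"

    def test_namespace_codes(self, toy_obo):
        graph = parse_obo(toy_obo)
        assert graph.namespace["GO:0000001"] == "BP"

    def test_cycle_raises_naming_members(self, tmp_path):
        path = tmp_path / "cyclic.obo"
        path.write_text(
            "format-version: 1.2\n\n"
            "[Term]\nid: GO:0000001\nname: a\nnamespace: biological_process\n"
            "is_a: GO:0000002\n\n"
            "[Term]\nid: GO:0000002\nname: b\nnamespace: biological_process\n"
            "is_a: GO:0000001\n"
        )
        with pytest.raises(CycleError) as err:
            parse_obo(path)
        assert set(err.value.cycle) == {"GO:0000001", "GO:0000002"}

    def test_missing_file_is_io_error(self, tmp_path):
        with pytest.raises(OntologyError):
            parse_obo(tmp_path / "nope.obo")

    def test_part_of_opt_in(self, tmp_path):
        path = tmp_path / "rel.obo"
        path.write_text(
            "format-version: 1.2\n\n"
            "[Term]\nid: GO:0000001\nname: whole\nnamespace: cellular_component\n\n"
            "[Term]\nid: GO:0000002\nname: part\nnamespace: cellular_component\n"
            "relationship: part_of GO:0000001\n"
        )
        assert parse_obo(path).edges == set()
        graph = parse_obo(path, relations=("is_a", "part_of"))
        assert graph.edges == {("GO:0000002", "GO:0000001", "part_of")}


class TestDagQueries:
    def test_plasma_membrane_ancestor_closure(self, cc_graph):
        assert cc_graph.ancestors("GO:0005886") == FIG1_ANCESTORS

    def test_root_has_no_ancestors(self, cc_graph):
        assert cc_graph.ancestors("GO:0005575") == set()

    def test_chain_transitivity(self):
        g = OntologyGraph(
            terms={"a", "b", "c"},
            edges={("a", "b", "is_a"), ("b", "c", "is_a")},
            namespace={t: "BP" for t in "abc"},
        )
        assert g.ancestors("a") == {"b", "c"}

    def test_unknown_term_raises(self, cc_graph):
        with pytest.raises(OntologyError):
            cc_graph.ancestors("GO:9999999")

    def test_agrees_with_reachability_oracle_on_random_dags(self):
        rng = np.random.default_rng(11)
        for _ in range(100):
            g = random_dag(rng)
            t = sorted(g.terms)[int(rng.integers(0, len(g.terms)))]
            assert g.ancestors(t) == reachable_ancestors(g.edges, t)
            assert g.descendants(t) == reachable_descendants(g.edges, t)


class TestDescendantsWithin:
    def test_leaf_is_its_own_descendant_set(self, cc_graph):
        idx = TermIndex(sorted(cc_graph.terms))
        assert descendants_within(cc_graph, "GO:0005886", idx) == {"GO:0005886"}

    def test_closure_over_selected_children(self, cc_graph):
        idx = TermIndex(sorted(cc_graph.terms))
        got = descendants_within(cc_graph, "GO:0044464", idx)
        assert got == {"GO:0044464", "GO:0016020", "GO:0071944", "GO:0005886"}

    def test_unselected_descendants_are_excluded(self, cc_graph):
        # brute-force closure intersected with the index gives the oracle
        idx = TermIndex(["GO:0005575", "GO:0005623"])
        full = reachable_descendants(cc_graph.edges, "GO:0005623") | {"GO:0005623"}
        assert descendants_within(cc_graph, "GO:0005623", idx) == full & set(idx.terms)

    def test_unselected_query_term_raises(self, cc_graph):
        idx = TermIndex(["GO:0005575"])
        with pytest.raises(OntologyError):
            descendants_within(cc_graph, "GO:0005886", idx)


def star_graph(n_leaves):
    """One root with n_leaves direct children."""
    root = "GO:0000001"
    leaves = [f"GO:{i + 2:07d}" for i in range(n_leaves)]
    edges = {(leaf, root, "is_a") for leaf in leaves}
    terms = {root, *leaves}
    return (
        OntologyGraph(terms=terms, edges=edges, namespace={t: "BP" for t in terms}),
        root,
        leaves,
    )


class TestInformationContent:
    def test_leaf_value_in_ten_term_set(self):
        # |T|=10, |desc(leaf)|=1 -> 1 - log 2/log 10
        g, root, leaves = star_graph(9)
        idx = TermIndex([root] + leaves)
        ic = information_content(g, idx)
        assert ic[1] == pytest.approx(1 - math.log(2) / math.log(10), abs=1e-9)
        assert ic[1] == pytest.approx(0.69897, abs=1e-5)

    def test_mid_term_with_five_descendants(self):
        # chain root->m, m with 4 leaf children => |desc(m)|=5 among |T|=10
        root, m = "GO:0000001", "GO:0000002"
        kids = [f"GO:{i + 3:07d}" for i in range(4)]
        others = [f"GO:{i + 7:07d}" for i in range(4)]
        edges = {(m, root, "is_a")}
        edges |= {(k, m, "is_a") for k in kids}
        edges |= {(o, root, "is_a") for o in others}
        terms = {root, m, *kids, *others}
        g = OntologyGraph(terms=terms, edges=edges, namespace={t: "BP" for t in terms})
        idx = TermIndex(sorted(terms))
        ic = information_content(g, idx)
        assert ic[idx.index_of(m)] == pytest.approx(0.22185, abs=1e-5)

    def test_log_base_invariance(self):
        g, root, leaves = star_graph(9)
        idx = TermIndex([root] + leaves)
        ic = information_content(g, idx)
        by_log10 = [
            1 - math.log10(1 + len(descendants_within(g, t, idx))) / math.log10(len(idx))
            for t in idx
        ]
        assert np.allclose(ic, by_log10, atol=1e-12)

    def test_covering_root_is_negative_unless_clamped(self):
        g, root, leaves = star_graph(9)
        idx = TermIndex([root] + leaves)
        assert information_content(g, idx)[0] < 0
        assert information_content(g, idx, clamp=True)[0] == 0.0

    def test_monotone_along_hierarchy(self):
        rng = np.random.default_rng(12)
        for _ in range(25):
            g = random_dag(rng)
            idx = TermIndex(sorted(g.terms))
            ic = information_content(g, idx)
            for child, parent, _rel in g.edges:
                assert ic[idx.index_of(child)] >= ic[idx.index_of(parent)] - 1e-12

    def test_too_few_terms_rejected(self):
        g, root, leaves = star_graph(1)
        with pytest.raises(OntologyError):
            information_content(g, TermIndex([root]))


class TestCorrelationMatrix:
    def test_two_children_hand_case(self):
        # n_t=100, n_s=40, both children IC 0.5 -> 0.4 + 0.5
        g, root, leaves = star_graph(2)
        idx = TermIndex([root] + leaves)
        counts = {root: 100, leaves[0]: 40, leaves[1]: 60}
        ic = np.array([0.1, 0.5, 0.5])
        A = correlation_matrix(g, idx, counts, ic)
        assert A[0, 1] == pytest.approx(0.9)
        assert A[0, 2] == pytest.approx(0.6 + 0.5)

    def test_sole_child_gets_ratio_plus_one(self):
        g, root, leaves = star_graph(1)
        idx = TermIndex([root] + leaves)
        A = correlation_matrix(g, idx, {root: 50, leaves[0]: 20}, np.array([0.2, 0.7]))
        assert A[0, 1] == pytest.approx(20 / 50 + 1.0)

    def test_three_child_ic_shares(self):
        # n_t=50, n_s=10, sibling ICs {0.2, 0.3, 0.5}; s is the 0.2 child
        g, root, leaves = star_graph(3)
        idx = TermIndex([root] + leaves)
        counts = {root: 50, leaves[0]: 10, leaves[1]: 20, leaves[2]: 30}
        ic = np.array([0.0, 0.2, 0.3, 0.5])
        with pytest.raises(OntologyError):
            # the parent's own IC may be 0, but a zero-count child must fail
            correlation_matrix(g, idx, {root: 50, leaves[0]: 0}, ic)
        A = correlation_matrix(g, idx, counts, ic)
        assert A[0, 1] == pytest.approx(0.2 + 0.2)

    def test_nonzero_pattern_matches_selected_child_edges(self):
        rng = np.random.default_rng(13)
        for _ in range(20):
            g = random_dag(rng, n_nodes=12)
            selected = sorted(g.terms)[::2]
            idx = TermIndex(selected)
            counts = {t: int(rng.integers(1, 50)) for t in g.terms}
            ic = rng.random(len(idx)) + 0.1
            A = correlation_matrix(g, idx, counts, ic)
            for i, t in enumerate(idx):
                for j, s in enumerate(idx):
                    is_edge = (s, t, "is_a") in g.edges
                    assert (A[i, j] > 0) == is_edge

    def test_zero_parent_count_rejected(self):
        g, root, leaves = star_graph(1)
        idx = TermIndex([root] + leaves)
        with pytest.raises(OntologyError):
            correlation_matrix(g, idx, {root: 0, leaves[0]: 5}, np.array([0.1, 0.5]))


class TestNormalizeAdjacency:
    def test_single_term_self_loop(self):
        assert normalize_adjacency(np.zeros((1, 1))) == pytest.approx(np.ones((1, 1)))

    def test_two_term_hand_case(self):
        A = np.array([[0.0, 0.9], [0.0, 0.0]])
        got = normalize_adjacency(A)
        want = np.array([[1, 0.9], [0.9, 1]]) / 1.9
        assert np.allclose(got, want, atol=1e-4)
        assert got[0, 0] == pytest.approx(0.5263, abs=1e-4)

    def test_symmetric_with_positive_diagonal(self):
        rng = np.random.default_rng(14)
        A = rng.random((6, 6)) * (rng.random((6, 6)) < 0.3)
        got = normalize_adjacency(A)
        assert np.allclose(got, got.T)
        assert (np.diag(got) > 0).all()

    def test_row_variant_rows_sum_to_one(self):
        rng = np.random.default_rng(15)
        A = rng.random((7, 7)) * (rng.random((7, 7)) < 0.4)
        rows = normalize_adjacency(A, variant="row")
        assert np.allclose(rows.sum(axis=1), 1.0, atol=1e-12)

    def test_non_square_rejected(self):
        with pytest.raises(OntologyError):
            normalize_adjacency(np.zeros((2, 3)))
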