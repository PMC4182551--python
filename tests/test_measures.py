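import itertools
import math

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ewrank.measures import (
    build_measure_table,
    go_similarity,
    jukes_cantor_distance,
    jukes_cantor_from_p,
    pearson_correlation,
    read_measure_table,
    triangle_count,
    write_measure_table,
)
from ewrank.network import AnnotationSet
from .conftest import random_graph


def brute_force_edge_triangles(g: nx.Graph, u, v) -> int:
    """Oracle: enumerate all node triples containing the edge."""
    count = 0
    for w in g.nodes:
        if w in (u, v):
            continue
        if g.has_edge(u, w) and g.has_edge(v, w):
            count += 1
    return count


class TestTriangleCount:
    def test_k3_edge_in_one_triangle(self):
        g = nx.complete_graph(3)
        assert triangle_count(g, (0, 1)) == 1

    def test_path_edge_in_no_triangle(self):
        g = nx.path_graph(["A", "B", "C"])
        assert triangle_count(g, ("A", "B")) == 0

    def test_k4_edge(self):
        assert triangle_count(nx.complete_graph(4), (0, 1)) == 2

    def test_absent_edge_errors(self):
        with pytest.raises(ValueError):
            triangle_count(nx.path_graph(3), (0, 2))

    def test_matches_triple_enumeration_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(25):
            g = random_graph(rng, int(rng.integers(5, 51)), 0.15)
            for u, v in g.edges:
                assert triangle_count(g, (u, v)) == brute_force_edge_triangles(g, u, v)

    def test_edge_triangle_sum_is_thrice_graph_triangles(self):
        rng = np.random.default_rng(9)
        for _ in range(5):
            g = random_graph(rng, 30, 0.2)
            total = sum(triangle_count(g, e) for e in g.edges)
            n_triangles = sum(nx.triangles(g).values()) // 3
            assert total == 3 * n_triangles


class TestPearson:
    def expr(self, **rows):
        return pd.DataFrame.from_dict(rows, orient="index")

    def test_identical_profiles(self):
        e = self.expr(a=[1.0, 2.0, 5.0, 3.0], b=[1.0, 2.0, 5.0, 3.0])
        assert pearson_correlation(e, "a", "b") == pytest.approx(1.0)

    def test_anticorrelated_profiles(self):
        e = self.expr(a=[1.0, 2.0, 3.0], b=[3.0, 2.0, 1.0])
        assert pearson_correlation(e, "a", "b") == pytest.approx(-1.0)

    def test_hand_evaluated_value(self):
        e = self.expr(a=[1.0, 2.0, 3.0], b=[1.0, 2.0, 4.0])
        assert pearson_correlation(e, "a", "b") == pytest.approx(9 / math.sqrt(84))

    def test_missing_gene_and_constant_profile(self):
        e = self.expr(a=[1.0, 2.0, 3.0], c=[5.0, 5.0, 5.0])
        assert math.isnan(pearson_correlation(e, "a", "zz"))
        assert math.isnan(pearson_correlation(e, "a", "c"))

    def test_too_few_common_samples(self):
        e = self.expr(a=[1.0, 2.0, np.nan, np.nan], b=[2.0, 1.0, 3.0, 4.0])
        assert math.isnan(pearson_correlation(e, "a", "b"))

    @given(
        st.lists(st.floats(-50, 50), min_size=4, max_size=10, unique=True),
        st.floats(0.1, 5.0),
        st.floats(-10, 10),
    )
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_symmetry_and_positive_affine_invariance(self, xs, slope, shift):
        rng = np.random.default_rng(123)
        ys = list(rng.normal(size=len(xs)))
        e = pd.DataFrame.from_dict(
            {"x": xs, "y": ys, "xt": [slope * v + shift for v in xs]},
            orient="index",
        )
        r_xy = pearson_correlation(e, "x", "y")
        assert r_xy == pytest.approx(pearson_correlation(e, "y", "x"), abs=1e-12)
        assert r_xy == pytest.approx(pearson_correlation(e, "xt", "y"), abs=1e-6)


@pytest.fixture()
def small_annots():
    dag = nx.DiGraph()
    dag.add_node("root")
    for t in "abc":
        dag.add_edge(t, "root", relation="is_a")
    dag.add_edge("a1", "a", relation="is_a")
    dag.add_edge("a2", "a", relation="part_of")
    return AnnotationSet(
        terms={
            "P1": {"a", "b"},
            "P2": {"b", "c"},
            "P3": {"a", "b"},
            "P4": {"a1"},
            "P5": {"a2"},
        },
        ontology=dag,
    )


class TestGoSimilarity:
    def test_identical_sets_are_one_both_methods(self, small_annots):
        for method in ("jaccard", "dag-bma"):
            assert go_similarity(small_annots, "P1", "P3", method) == pytest.approx(1.0)

    def test_disjoint_sets_jaccard_zero(self, small_annots):
        small_annots.terms["P9"] = {"c"}
        assert go_similarity(small_annots, "P4", "P9", "jaccard") == 0.0

    def test_jaccard_partial_overlap(self, small_annots):
        assert go_similarity(small_annots, "P1", "P2") == pytest.approx(1 / 3)

    def test_missing_annotation_is_nan(self, small_annots):
        assert math.isnan(go_similarity(small_annots, "P1", "unannotated"))

    def test_dag_bma_credits_sibling_terms(self, small_annots):
        # a1 and a2 share ancestors {a, root}; jaccard sees nothing
        assert go_similarity(small_annots, "P4", "P5", "jaccard") == 0.0
        sim = go_similarity(small_annots, "P4", "P5", "dag-bma")
        assert 0.0 < sim < 1.0

    def test_dag_bma_hand_value_for_sibling_leaves(self, small_annots):
        # S-values: a1 -> {a1:1, a:.8, root:.64}, a2 -> {a2:1, a:.6, root:.48}
        # shared contribution (.8+.6)+(.64+.48) over (2.44 + 2.08)
        expected = ((0.8 + 0.6) + (0.64 + 0.48)) / (2.44 + 2.08)
        assert go_similarity(small_annots, "P4", "P5", "dag-bma") == pytest.approx(expected)

    def test_symmetry(self, small_annots):
        for method in ("jaccard", "dag-bma"):
            assert go_similarity(small_annots, "P1", "P2", method) == pytest.approx(
                go_similarity(small_annots, "P2", "P1", method)
            )


class TestJukesCantor:
    def test_identical_sequences(self):
        assert jukes_cantor_distance("MKVLA", "MKVLA") == 0.0

    def test_closed_form_at_p_005(self):
        assert jukes_cantor_from_p(0.05) == pytest.approx(
            -0.95 * math.log(1 - 0.05 * 20 / 19)
        )
        assert jukes_cantor_from_p(0.05) == pytest.approx(0.0514, abs=5e-4)

    def test_saturation_is_missing(self):
        assert math.isnan(jukes_cantor_from_p(0.95))

    def test_single_substitution_via_alignment(self):
        d = jukes_cantor_distance("MKVLAMKVLA", "MKVLAMKVIA")
        assert d == pytest.approx(jukes_cantor_from_p(0.1))

    def test_empty_sequence_errors(self):
        with pytest.raises(ValueError):
            jukes_cantor_distance("", "MKV")

    def test_symmetry(self):
        a, b = "MKVLAHGWED", "MKVIAHGWQD"
        assert jukes_cantor_distance(a, b) == pytest.approx(jukes_cantor_distance(b, a))


class TestMeasureTable:
    def test_nte_only(self):
        g = nx.path_graph(["A", "B", "C", "D"])
        t = build_measure_table(g, enabled=("NTE",))
        assert list(t.columns) == ["u", "v", "NTE"]
        assert len(t) == 3 and (t["NTE"] == 0).all()

    def test_enabled_measure_without_input_errors(self):
        with pytest.raises(ValueError, match="PCC"):
            build_measure_table(nx.path_graph(3), enabled=("PCC",))

    def test_empty_network_gives_empty_table(self):
        t = build_measure_table(nx.Graph(), enabled=("NTE",))
        assert t.empty

    def test_full_table_on_fixture_cross_checked(self, bundle, measure_table):
        t = measure_table
        assert len(t) == bundle.net.number_of_edges()
        assert t["NTE"].notna().all()
        # PCC missing exactly when a gene is absent from the matrix
        absent = ~(t["u"].isin(bundle.expr.index) & t["v"].isin(bundle.expr.index))
        assert t.loc[absent, "PCC"].isna().all() if absent.any() else True
        sample = t.sample(20, random_state=0)
        for row in sample.itertuples(index=False):
            assert row.NTE == triangle_count(bundle.net, (row.u, row.v))
            assert row.GE == pytest.approx(
                go_similarity(bundle.annots, row.u, row.v)
            ) or (math.isnan(row.GE) and math.isnan(go_similarity(bundle.annots, row.u, row.v)))
            pcc = pearson_correlation(bundle.expr, row.u, row.v)
            assert (math.isnan(row.PCC) and math.isnan(pcc)) or row.PCC == pytest.approx(pcc)

    def test_round_trip_and_canonical_order(self, tmp_path):
        t = pd.DataFrame(
            {"u": ["B", "C"], "v": ["A", "D"], "GE": [0.5, 0.1],
             "PCC": [0.4, -0.2], "NTE": [3, 0]}
        )
        path = tmp_path / "m.tsv"
        write_measure_table(t, path)
        back = read_measure_table(path)
        assert list(back.iloc[0][["u", "v"]]) == ["A", "B"]
        assert back.iloc[0]["GE"] == 0.5 and back.iloc[0]["NTE"] == 3

    def test_duplicate_edge_row_named_in_error(self, tmp_path):
        path = tmp_path / "m.tsv"
        path.write_text(
            "u\tv\tGE\tPCC\tNTE\nA\tB\t0.5\t0.4\t3\nB\tA\t0.1\t0.2\t1\n"
        )
        with pytest.raises(ValueError, match="A.*B"):
            read_measure_table(path)

    def test_negative_or_fractional_nte_rejected(self, tmp_path):
        path = tmp_path / "m.tsv"
        path.write_text("u\tv\tGE\tPCC\tNTE\nA\tB\t0.5\t0.4\t-1\n")
        with pytest.raises(ValueError, match="NTE"):
            read_measure_table(path)

    def test_pp_column_preserved(self, tmp_path):
        path = tmp_path / "m.tsv"
        path.write_text("u\tv\tGE\tPCC\tNTE\tPP\nA\tB\t0.5\t0.4\t3\t0.07\n")
        back = read_measure_table(path)
        assert back["PP"].iloc[0] == pytest.approx(0.07)

    def test_nte_bounded_by_min_degree(self, bundle, measure_table):
        deg = dict(bundle.net.degree())
        for row in measure_table.itertuples(index=False):
            assert row.NTE <= min(deg[row.u], deg[row.v]) - 1 or row.NTE == 0
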