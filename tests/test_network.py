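"""Semantic networks: oracle equivalence, nesting, queries, coverage."""

import math

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import microlit as ml
from conftest import brute_force_edges


def angle_vector(distance):
    """Unit 2-vector at cosine distance ``distance`` from (1, 0)."""
    a = math.acos(1.0 - distance)
    return np.array([math.cos(a), math.sin(a)])


@pytest.fixture(scope="module")
def toy_coverage():
    """Four mappable reference pairs at distances {0.1, 0.2, 0.6, 1.2}
    plus one pair with an endpoint absent from the vocabulary."""
    vectors = {"m1": np.array([1.0, 0.0]), "m2": np.array([1.0, 0.0]),
               "m3": np.array([1.0, 0.0]), "m4": np.array([1.0, 0.0]),
               "d1": angle_vector(0.1), "d2": angle_vector(0.2),
               "d3": angle_vector(0.6), "d4": angle_vector(1.2)}
    model = ml.EmbeddingModel.from_vectors(vectors)
    ref = ml.ReferenceEdgeSet(pairs=(("m1", "d1"), ("m2", "d2"),
                                     ("m3", "d3"), ("m4", "d4"),
                                     ("ghostbug", "d1")))
    return model, ref


class TestBuildNetwork:
    def test_matches_brute_force_oracle(self, hand_model):
        model, terms = hand_model
        for theta in (0.0, 0.2, 0.35, 0.5, 1.0):
            net = ml.build_network(model, terms, "disease-microbe", theta)
            got = {frozenset(e[:2]) for e in net.edges()}
            assert got == brute_force_edges(
                model, terms["disease"], terms["microbe"], theta)

    def test_theta_zero_has_no_edges_for_generic_vectors(self, hand_model):
        model, terms = hand_model
        net = ml.build_network(model, terms, "disease-microbe", 0.0)
        assert net.n_edges == 0
        assert net.n_nodes == 0  # isolated nodes excluded by default

    def test_edge_at_most_theta_rule(self, toy_coverage):
        model, _ = toy_coverage
        terms = {"disease": ["d1", "d3"], "microbe": ["m1"]}
        net = ml.build_network(model, terms, "disease-microbe", 0.35)
        got = {frozenset(e[:2]) for e in net.edges()}
        assert got == {frozenset(("m1", "d1"))}  # 0.1 in, 0.6 out

    def test_edge_weights_are_cosine_distances(self, hand_model):
        model, terms = hand_model
        net = ml.build_network(model, terms, "disease-microbe", 0.8)
        for a, b, w in net.edges():
            assert w == pytest.approx(ml.cosine_distance(
                model.term_vector(a), model.term_vector(b)), abs=1e-12)

    def test_keep_isolated_retains_all_vocab_terms(self, hand_model):
        model, terms = hand_model
        net = ml.build_network(model, terms, "disease-microbe", 0.0,
                               keep_isolated=True)
        assert net.n_nodes == 50

    def test_unknown_class_pair_is_an_error(self, hand_model):
        model, terms = hand_model
        with pytest.raises(ValueError, match="class pair"):
            ml.build_network(model, terms, "disease-gene", 0.3)

    def test_terms_without_vectors_are_skipped(self, hand_model):
        model, terms = hand_model
        extended = {"disease": terms["disease"] + ["unseen term"],
                    "microbe": terms["microbe"]}
        net = ml.build_network(model, extended, "disease-microbe", 2.0)
        assert "unseen term" not in net.graph


class TestSweep:
    def test_counts_match_build_network_at_every_grid_point(self, hand_model):
        model, terms = hand_model
        grid = (0.0, 0.2, 0.35, 0.5, 1.0)
        sweep = ml.sweep_thresholds(model, terms, "disease-microbe", grid)
        for i, theta in enumerate(grid):
            net = ml.build_network(model, terms, "disease-microbe", theta)
            assert sweep.edge_counts[i] == net.n_edges
            assert sweep.node_counts[i] == net.n_nodes

    def test_counts_non_decreasing(self, hand_model):
        model, terms = hand_model
        sweep = ml.sweep_thresholds(model, terms, "disease-microbe")
        assert list(sweep.edge_counts) == sorted(sweep.edge_counts)
        assert list(sweep.node_counts) == sorted(sweep.node_counts)

    def test_saturation_at_grid_end(self, hand_model):
        model, terms = hand_model
        sweep = ml.sweep_thresholds(model, terms, "disease-microbe",
                                    (0.5, 2.0))
        assert sweep.edge_counts[-1] == 25 * 25
        assert sweep.node_counts[-1] == 50

    def test_unsorted_grid_is_an_error(self, hand_model):
        model, terms = hand_model
        with pytest.raises(ValueError, match="ascending"):
            ml.sweep_thresholds(model, terms, "disease-microbe", (0.5, 0.2))

    @given(theta1=st.floats(0.0, 1.0), theta2=st.floats(0.0, 1.0))
    @settings(max_examples=25)
    def test_nesting_of_edge_and_node_sets(self, hand_model, theta1, theta2):
        """E(theta1) ⊆ E(theta2) and V(theta1) ⊆ V(theta2) for
        theta1 <= theta2."""
        model, terms = hand_model
        lo, hi = sorted((theta1, theta2))
        a = ml.build_network(model, terms, "disease-microbe", lo)
        b = ml.build_network(model, terms, "disease-microbe", hi)
        assert set(a.graph.nodes) <= set(b.graph.nodes)
        assert {frozenset(e[:2]) for e in a.edges()} \
            <= {frozenset(e[:2]) for e in b.edges()}


class TestNeighborhood:
    def test_large_k_gives_full_ranking(self, hand_model):
        model, terms = hand_model
        ranked = ml.neighborhood(model, "disease00", terms["microbe"], k=999)
        assert len(ranked) == 25
        assert [d for _, d in ranked] == sorted(d for _, d in ranked)

    def test_top1_is_argmin_distance(self, hand_model):
        model, terms = hand_model
        fv = model.term_vector("disease00")
        best = min(terms["microbe"],
                   key=lambda m: ml.cosine_distance(
                       fv, model.term_vector(m)))
        assert ml.neighborhood(model, "disease00", terms["microbe"],
                               k=1)[0][0] == best

    def test_theta_filters_ranking(self, toy_coverage):
        model, _ = toy_coverage
        ranked = ml.neighborhood(model, "m1", ["d1", "d2", "d3", "d4"],
                                 k=10, theta=0.35)
        assert [t for t, _ in ranked] == ["d1", "d2"]

    def test_missing_focus_term_names_it(self, hand_model):
        model, terms = hand_model
        with pytest.raises(KeyError, match="nosuchterm"):
            ml.neighborhood(model, "nosuchterm", terms["microbe"])

    def test_planted_partner_ranks_high_on_study_corpus(self, study_run):
        """For focus diseases with a planted microbe partner, that partner
        appears in the top 3 of the microbe ranking."""
        spec, truth, model = study_run
        checked = 0
        hits = 0
        for d, m in truth.planted_edges[:10]:
            if model.term_vector(d) is None or model.term_vector(m) is None:
                continue
            top = [t for t, _ in ml.neighborhood(
                model, d, spec.microbe_terms, k=3)]
            checked += 1
            hits += m in top
        assert checked > 0
        assert hits / checked >= 0.7


class TestHeatmap:
    def test_shape_entries_and_range(self, hand_model):
        model, terms = hand_model
        frame = ml.heatmap_matrix(model, terms["disease"][:4],
                                  terms["microbe"][:6])
        assert frame.shape == (4, 6)
        assert ((frame.values >= 0) & (frame.values <= 2)).all()
        assert frame.loc["disease00", "microbe03"] == pytest.approx(
            ml.cosine_distance(model.term_vector("disease00"),
                               model.term_vector("microbe03")))

    def test_missing_terms_dropped(self, hand_model):
        model, terms = hand_model
        frame = ml.heatmap_matrix(model, ["disease00", "ghost"],
                                  terms["microbe"][:2])
        assert list(frame.index) == ["disease00"]


class TestCoverage:
    def test_exact_counts_on_toy_reference(self, toy_coverage):
        model, ref = toy_coverage
        report = ml.coverage_against_reference(model, ref,
                                               grid=(0.15, 0.5, 1.0, 2.0))
        assert report.n_reference == 5
        assert report.n_mappable == 4
        assert report.n_unmappable == 1
        assert report.n_found_at[0.5] == 2
        assert report.coverage_fraction_at[0.5] == pytest.approx(0.4)
        found = [report.n_found_at[t] for t in report.grid]
        assert found == sorted(found)  # monotone in theta
        assert report.n_found_at[2.0] == report.n_mappable  # saturation

    def test_conservation(self, toy_coverage):
        model, ref = toy_coverage
        report = ml.coverage_against_reference(model, ref)
        assert report.n_reference == report.n_mappable + report.n_unmappable

    def test_synonym_map_rescues_external_names(self, toy_coverage):
        model, _ = toy_coverage
        ref = ml.ReferenceEdgeSet(pairs=(("Microbe One", "d1"),))
        report = ml.coverage_against_reference(
            model, ref, synonym_map={"Microbe One": "m1"})
        assert report.n_mappable == 1

    def test_empty_reference_is_an_error(self, toy_coverage):
        model, _ = toy_coverage
        with pytest.raises(ValueError, match="empty"):
            ml.coverage_against_reference(
                model, ml.ReferenceEdgeSet(pairs=()))


class TestExport:
    @pytest.mark.parametrize("suffix", ["graphml", "tsv"])
    def test_roundtrip_preserves_graph(self, hand_model, tmp_path, suffix):
        model, terms = hand_model
        net = ml.build_network(model, terms, "disease-microbe", 0.8)
        path = tmp_path / f"net.{suffix}"
        ml.export_network(net, path)
        back = ml.load_network(path, theta=0.8, class_pair="disease-microbe")
        assert set(back.graph.nodes) == set(net.graph.nodes)
        assert nx.get_node_attributes(back.graph, "concept_class") \
            == nx.get_node_attributes(net.graph, "concept_class")
        for u, v, w in net.edges():
            assert back.graph[u][v]["cosine_distance"] \
                == pytest.approx(w, abs=1e-9)

    def test_empty_network_exports_cleanly(self, hand_model, tmp_path):
        model, terms = hand_model
        net = ml.build_network(model, terms, "disease-microbe", 0.0)
        path = ml.export_network(net, tmp_path / "empty.tsv")
        assert path.read_text() == ""
        assert ml.load_network(path, 0.0, "disease-microbe").n_edges == 0

    def test_edge_tsv_row_count_equals_edges(self, hand_model, tmp_path):
        model, terms = hand_model
        net = ml.build_network(model, terms, "disease-microbe", 0.8)
        path = ml.export_network(net, tmp_path / "net.tsv")
        rows = [l for l in path.read_text().splitlines() if l.strip()]
        assert len(rows) == net.n_edges

    def test_unsupported_format_is_an_error(self, hand_model, tmp_path):
        model, terms = hand_model
        net = ml.build_network(model, terms, "disease-microbe", 0.1)
        with pytest.raises(ValueError, match="format"):
            ml.export_network(net, tmp_path / "x.bin", format="pickle")
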