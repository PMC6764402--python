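"""Branching, anisotropy, fractal dimension and classification."""

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from synagg.aggregation import detect_clusters
from synagg.morphology import (
    analyze_frame,
    branch_statistics,
    classify_morphology,
    contact_graph,
    fractal_dimension,
    shape_anisotropy,
    unwrap_cluster,
)
from synagg.synthetic import generate_ideal_aggregate


class TestContactGraph:
    def test_linear_stack_gives_path_graph(self):
        frame = generate_ideal_aggregate("linear_stack", 10)
        cs = detect_clusters(frame)
        g = contact_graph(max(cs.clusters, key=len), cs)
        assert nx.is_isomorphic(g, nx.path_graph(10))
        assert not any(g.has_edge(v, v) for v in g)

    def test_branched_tree_hubs_have_degree_three(self):
        frame = generate_ideal_aggregate("branched_tree", 40, seed=3, n_branches=3)
        cs = detect_clusters(frame)
        g = contact_graph(max(cs.clusters, key=len), cs)
        assert nx.is_tree(g)
        hubs = [v for v, d in g.degree() if d >= 3]
        assert len(hubs) == 3

    def test_components_equal_cluster_membership(self):
        frame = generate_ideal_aggregate("branched_tree", 30, seed=1)
        cs = detect_clusters(frame)
        for cluster in cs.clusters:
            g = contact_graph(cluster, cs)
            assert set(g.nodes) == cluster
            if len(cluster) > 1:
                assert nx.is_connected(g)


class TestBranchStatistics:
    @pytest.mark.parametrize(
        "graph,expected",
        [
            (nx.path_graph(10), (0, 2, 0.0)),
            (nx.star_graph(4), (1, 4, 0.2)),  # 4-arm star: hub + 4 leaves
            (nx.balanced_tree(2, 2), (2, 4, 2 / 7)),  # 7-node binary tree
        ],
        ids=["path", "star", "binary_tree"],
    )
    def test_known_graphs(self, graph, expected):
        nb, ne, bf = branch_statistics(graph)
        assert (nb, ne) == expected[:2]
        assert bf == pytest.approx(expected[2])


class TestShapeAnisotropy:
    def test_collinear_beads_are_rod_like(self):
        coords = np.column_stack([np.linspace(0, 30, 40), np.zeros(40), np.zeros(40)])
        k2, _, lam = shape_anisotropy(coords)
        assert k2 == pytest.approx(1.0)
        assert lam[1] == pytest.approx(0.0, abs=1e-12)

    def test_cube_vertices_are_isotropic(self):
        coords = np.array(
            [[i, j, k] for i in (0, 1) for j in (0, 1) for k in (0, 1)], float
        )
        k2, asph, _ = shape_anisotropy(coords)
        assert k2 == pytest.approx(0.0, abs=1e-12)
        assert asph == pytest.approx(0.0, abs=1e-12)

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=25, deadline=None)
    def test_rigid_motion_invariance(self, seed):
        rng = np.random.default_rng(seed)
        coords = rng.normal(size=(30, 3)) * np.array([3.0, 1.0, 0.5])
        k2, _, _ = shape_anisotropy(coords)
        assert 0.0 <= k2 <= 1.0
        # random rotation (QR of a Gaussian matrix) plus translation
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        moved = coords @ q.T + rng.normal(size=3) * 10
        k2_moved, _, _ = shape_anisotropy(moved)
        assert k2_moved == pytest.approx(k2, abs=1e-10)

    def test_too_few_beads_rejected(self):
        with pytest.raises(ValueError):
            shape_anisotropy(np.zeros((2, 3)))


class TestFractalDimension:
    def test_straight_fibril_backbone_is_one_dimensional(self):
        frame = generate_ideal_aggregate("linear_stack", 100)
        cs = detect_clusters(frame)
        coords = unwrap_cluster(max(cs.clusters, key=len), frame, cs)
        centres = coords.reshape(100, -1, 3).mean(axis=1)
        df, fit_range, _ = fractal_dimension(centres)
        assert df is not None
        assert 0.9 <= df <= 1.2
        assert fit_range[0] == 2.0

    def test_uniform_ball_is_three_dimensional(self):
        rng = np.random.default_rng(1)
        n = 4000
        pts = rng.normal(size=(n, 3))
        pts /= np.linalg.norm(pts, axis=1)[:, None]
        pts *= 12.0 * rng.uniform(0, 1, n)[:, None] ** (1 / 3)
        df, _, _ = fractal_dimension(pts)
        assert 2.8 <= df <= 3.2

    def test_uniform_disc_is_two_dimensional(self):
        rng = np.random.default_rng(2)
        n = 4000
        r = 14.0 * np.sqrt(rng.uniform(0, 1, n))
        phi = rng.uniform(0, 2 * np.pi, n)
        pts = np.column_stack([r * np.cos(phi), r * np.sin(phi), np.zeros(n)])
        df, _, _ = fractal_dimension(pts)
        assert 1.8 <= df <= 2.2

    def test_small_aggregates_undefined(self):
        df, rng_, res = fractal_dimension(np.random.default_rng(0).normal(size=(30, 3)))
        assert df is None and rng_ is None and res is None


class TestClassification:
    def test_rule_application_on_report_fields(self):
        assert classify_morphology(40, 0.0, 0.9) == "linear"
        assert classify_morphology(63, 0.1, 0.3, mean_degree=2.0) == "branched"
        assert classify_morphology(40, 0.5, 0.1, mean_degree=3.4) == "globular"
        assert classify_morphology(5, 0.2, 0.2) == "globular"  # too small

    @pytest.mark.parametrize(
        "kind,n,kwargs,expected",
        [
            ("linear_stack", 60, {}, "linear"),
            ("branched_tree", 63, {"n_branches": 5}, "branched"),
            ("globule", 60, {}, "globular"),
        ],
    )
    def test_fixture_labels(self, kind, n, kwargs, expected):
        frame = generate_ideal_aggregate(kind, n, seed=4, **kwargs)
        report = analyze_frame(frame, min_size=10)[0]
        assert report.label == expected


class TestRendering:
    def test_render_writes_image(self, tmp_path):
        from synagg.morphology import render_frame

        frame = generate_ideal_aggregate("branched_tree", 30, seed=1)
        out = tmp_path / "aggregate.png"
        render_frame(frame, out)
        assert out.stat().st_size > 0


class TestUnwrap:
    def test_unwrapped_stack_spans_box_crossing(self):
        frame = generate_ideal_aggregate("linear_stack", 30)
        # push the stack across the periodic boundary
        frame.coordinates[:, 0] += frame.box_length - 10.0
        frame.coordinates = np.mod(frame.coordinates, frame.box_length)
        cs = detect_clusters(frame)
        assert len(max(cs.clusters, key=len)) == 30
        coords = unwrap_cluster(max(cs.clusters, key=len), frame, cs)
        span = coords[:, 0].max() - coords[:, 0].min()
        assert span == pytest.approx(29.0, abs=1e-6)
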