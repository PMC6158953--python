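import math

import numpy as np
import pytest

from _oracles import brute_force_min_cut, exhaustive_min_energy
from cellcut import (
    AppearanceModel,
    BinaryMask,
    BoundaryMap,
    GrayImage,
    LambdaField,
    build_graph,
    build_lambda_field,
    energy,
    estimate_sigma,
    labeling_from_cut,
    max_flow,
    smoothness_weight,
)
from cellcut.graphcut import SegGraph
from cellcut.errors import ContractError

FLOW_TOL = 1e-9


def _graph_from_caps(shape, o_cap, b_cap, nlinks, sigma=10.0):
    """Assemble a SegGraph directly from terminal and neighbor capacities."""
    n = int(np.prod(shape))
    edges = []
    for i in range(n):
        edges.append((n, i, o_cap[i]))      # O t-link
        edges.append((i, n + 1, b_cap[i]))  # B t-link
    edges.extend(nlinks)
    tails = np.repeat([e[0] for e in edges], 2)
    heads = np.repeat([e[1] for e in edges], 2)
    caps = np.repeat([e[2] for e in edges], 2)
    tails[1::2], heads[1::2] = heads[::2].copy(), tails[::2].copy()
    return SegGraph(shape=shape, sigma=sigma, arc_tail=tails.astype(np.int64),
                    arc_head=heads.astype(np.int64), arc_cap=caps.astype(np.float64))


def _grid_nlinks(shape, rng):
    h, w = shape
    idx = np.arange(h * w).reshape(h, w)
    links = []
    for r in range(h):
        for c in range(w):
            if c + 1 < w:
                links.append((int(idx[r, c]), int(idx[r, c + 1]), float(rng.uniform(0, 3))))
            if r + 1 < h:
                links.append((int(idx[r, c]), int(idx[r + 1, c]), float(rng.uniform(0, 3))))
    return links


def _random_model(rng):
    fg = rng.random(256) + 1e-3
    bg = rng.random(256) + 1e-3
    return AppearanceModel(fg_hist=fg / fg.sum(), bg_hist=bg / bg.sum(), smoothing=1e-3)


class TestSmoothnessWeight:
    def test_equal_intensities(self):
        assert smoothness_weight(17, 17, 5.0) == 1.0

    def test_closed_form(self):
        assert smoothness_weight(10, 20, 10.0) == pytest.approx(math.exp(-0.5))

    def test_tail_limit(self):
        assert smoothness_weight(0, 255, 1.0) < 1e-30

    @pytest.mark.parametrize("sigma", [0.0, -1.0])
    def test_bad_sigma(self, sigma):
        with pytest.raises(ContractError):
            smoothness_weight(1, 2, sigma)


class TestBuildGraph:
    def _graph(self, shape, seed=0):
        rng = np.random.default_rng(seed)
        img = GrayImage(rng.integers(0, 256, size=shape))
        return img, build_graph(img, _random_model(rng), LambdaField.static(shape, 20.0), 10.0)

    def test_1x2_counts(self):
        _, g = self._graph((1, 2))
        edges = g.edges
        assert g.n_nodes == 4
        tlinks = [e for e in edges if g.source in e[:2] or g.sink in e[:2]]
        nlinks = [e for e in edges if g.source not in e[:2] and g.sink not in e[:2]]
        assert (len(tlinks), len(nlinks)) == (4, 1)

    def test_3x3_counts(self):
        _, g = self._graph((3, 3))
        edges = g.edges
        tlinks = [e for e in edges if g.source in e[:2] or g.sink in e[:2]]
        nlinks = [e for e in edges if g.source not in e[:2] and g.sink not in e[:2]]
        assert g.n_pixels == 9
        assert (len(tlinks), len(nlinks)) == (18, 12)

    def test_adaptive_boundary_zeroes_sink_link(self):
        rng = np.random.default_rng(1)
        img = GrayImage(rng.integers(0, 256, size=(3, 3)))
        members = np.zeros((3, 3), dtype=bool)
        members[1, 1] = True
        field = build_lambda_field(BoundaryMap(members), 20.0, 20.0)
        g = build_graph(img, _random_model(rng), field, 10.0)
        center = 4  # row-major pixel (1, 1)
        b_caps = [c for u, v, c in g.edges if (u, v) == (center, g.sink)]
        assert b_caps == [0.0]

    def test_shape_mismatch(self):
        rng = np.random.default_rng(2)
        img = GrayImage(rng.integers(0, 256, size=(3, 3)))
        with pytest.raises(ContractError):
            build_graph(img, _random_model(rng), LambdaField.static((2, 2), 20.0), 10.0)

    def test_negative_capacity_rejected(self):
        with pytest.raises(ContractError):
            _graph_from_caps((1, 2), [1.0, -1.0], [1.0, 1.0], [])


class TestMaxFlow:
    def test_toy_network(self):
        # weights 50, 20, 70, 18, 22; the enumeration oracle gives the cut
        # {a-B, O-b, a-b} of capacity 60 with a on the source side
        g = _graph_from_caps((1, 2), o_cap=[50.0, 22.0], b_cap=[20.0, 70.0],
                             nlinks=[(0, 1, 18.0)])
        oracle_val, oracle_set = brute_force_min_cut(2, [50.0, 22.0], [20.0, 70.0],
                                                     [(0, 1, 18.0)])
        assert oracle_val == pytest.approx(60.0)
        assert oracle_set == (1, 0)
        flow, side = max_flow(g)
        assert flow == pytest.approx(60.0, abs=FLOW_TOL)
        assert side[0] and not side[1]  # a with O, b with B

    def test_chain_bottleneck(self):
        g = _graph_from_caps((1, 1), o_cap=[5.0], b_cap=[3.0], nlinks=[])
        flow, _ = max_flow(g)
        assert flow == pytest.approx(3.0, abs=FLOW_TOL)

    def test_all_zero_tlinks(self):
        g = _graph_from_caps((1, 3), [0.0] * 3, [0.0] * 3, [(0, 1, 1.0), (1, 2, 1.0)])
        flow, side = max_flow(g)
        assert flow == 0.0
        assert len(set(side[:3])) == 1  # all pixels on one side

    def test_matches_brute_force_on_random_graphs(self):
        rng = np.random.default_rng(11)
        shapes = [(1, 2), (1, 4), (2, 3), (2, 4), (2, 5), (3, 3)]
        for trial in range(120):
            shape = shapes[trial % len(shapes)]
            n = shape[0] * shape[1]
            o_cap = rng.uniform(0, 5, n).round(3)
            b_cap = rng.uniform(0, 5, n).round(3)
            if trial % 7 == 0:  # exercise zero capacities too
                o_cap[rng.integers(0, n)] = 0.0
            nlinks = _grid_nlinks(shape, rng)
            g = _graph_from_caps(shape, o_cap, b_cap, nlinks)
            flow, side = max_flow(g)
            oracle_val, _ = brute_force_min_cut(n, o_cap, b_cap, nlinks)
            assert flow == pytest.approx(oracle_val, abs=FLOW_TOL)
            # the returned partition must itself achieve the min-cut value
            cut = sum(b_cap[i] if side[i] else o_cap[i] for i in range(n))
            cut += sum(c for i, j, c in nlinks if side[i] != side[j])
            assert cut == pytest.approx(oracle_val, abs=FLOW_TOL)

    def test_flow_conservation_and_capacity_bounds(self):
        from cellcut import _maxflow

        rng = np.random.default_rng(5)
        g = _graph_from_caps((2, 3), rng.uniform(0, 5, 6), rng.uniform(0, 5, 6),
                             _grid_nlinks((2, 3), rng))
        residual = g.arc_cap.copy()
        adj_start, adj_arcs = _maxflow.build_adjacency(g.n_nodes, g.arc_tail, len(g.arc_cap))
        _maxflow._edmonds_karp(g.n_nodes, g.source, g.sink,
                               g.arc_head.astype(np.int64), residual, adj_start, adj_arcs)
        net_arc_flow = g.arc_cap - residual  # positive part = actual flow
        assert (residual >= -FLOW_TOL).all()  # no capacity exceeded
        net = np.zeros(g.n_nodes)
        np.add.at(net, g.arc_tail, np.maximum(net_arc_flow, 0))
        np.add.at(net, g.arc_head, -np.maximum(net_arc_flow, 0))
        for node in range(g.n_pixels):
            assert net[node] == pytest.approx(0.0, abs=1e-6)

    def test_determinism(self):
        rng = np.random.default_rng(9)
        g = _graph_from_caps((2, 4), rng.uniform(0, 5, 8), rng.uniform(0, 5, 8),
                             _grid_nlinks((2, 4), rng))
        flow1, side1 = max_flow(g)
        flow2, side2 = max_flow(g)
        assert flow1 == flow2
        assert (side1 == side2).all()


class TestLabelingFromCut:
    def test_toy_cut_labels(self):
        g = _graph_from_caps((1, 2), [50.0, 22.0], [20.0, 70.0], [(0, 1, 18.0)])
        _, side = max_flow(g)
        mask = labeling_from_cut(side, g)
        assert mask.labels[0, 0] == 1 and mask.labels[0, 1] == 0

    def test_all_source_and_all_sink(self):
        g = _graph_from_caps((1, 3), [0.0] * 3, [0.0] * 3, [])
        all_src = np.ones(g.n_nodes, dtype=bool)
        assert (labeling_from_cut(all_src, g).labels == 1).all()
        all_snk = np.zeros(g.n_nodes, dtype=bool)
        assert (labeling_from_cut(all_snk, g).labels == 0).all()


class TestEnergy:
    def test_constant_labeling_uniform_model(self):
        img = GrayImage(np.full((3, 3), 7))
        model = AppearanceModel(np.full(256, 1 / 256), np.full(256, 1 / 256), 1.0)
        field = LambdaField.static((3, 3), 20.0)
        for fill in (0, 1):
            lab = BinaryMask(np.full((3, 3), fill, dtype=np.uint8))
            assert energy(lab, img, model, field, 10.0) == pytest.approx(
                9 * 20.0 * math.log(256)
            )

    def test_flipping_interior_pixel_adds_four_penalties(self):
        img = GrayImage(np.full((3, 3), 7))  # all weights exactly 1
        model = AppearanceModel(np.full(256, 1 / 256), np.full(256, 1 / 256), 1.0)
        field = LambdaField.static((3, 3), 20.0)
        base = energy(BinaryMask(np.zeros((3, 3), dtype=np.uint8)), img, model, field, 10.0)
        flipped = np.zeros((3, 3), dtype=np.uint8)
        flipped[1, 1] = 1
        assert energy(BinaryMask(flipped), img, model, field, 10.0) == pytest.approx(base + 4.0)

    def test_min_cut_attains_exhaustive_minimum(self):
        rng = np.random.default_rng(21)
        for trial in range(50):
            img = GrayImage(rng.integers(0, 256, size=(3, 3)))
            model = _random_model(rng)
            if trial % 2:
                field = build_lambda_field(BoundaryMap(rng.random((3, 3)) < 0.3), 5.0, 7.0)
            else:
                field = LambdaField.static((3, 3), 5.0)
            sigma = 30.0
            g = build_graph(img, model, field, sigma)
            flow, side = max_flow(g)
            mask = labeling_from_cut(side, g)
            e_cut = energy(mask, img, model, field, sigma)
            e_min = exhaustive_min_energy(img, model, field, sigma, energy, BinaryMask)
            assert e_cut == pytest.approx(e_min, abs=1e-9, rel=1e-9)
            assert flow == pytest.approx(e_min, abs=1e-6, rel=1e-9)

    def test_shape_mismatch(self):
        img = GrayImage(np.full((3, 3), 7))
        model = AppearanceModel(np.full(256, 1 / 256), np.full(256, 1 / 256), 1.0)
        with pytest.raises(ContractError):
            energy(BinaryMask(np.zeros((2, 2), dtype=np.uint8)), img, model,
                   LambdaField.static((3, 3), 20.0), 10.0)


def test_estimate_sigma():
    img = GrayImage(np.array([[0, 10], [0, 10]]))
    # neighbor diffs: rows give +-10 twice, columns 0 twice -> sd of {10,10,0,0}
    assert estimate_sigma(img) == pytest.approx(np.std([10, 10, 0, 0]))
    assert estimate_sigma(GrayImage(np.full((4, 4), 9))) == 1.0


def test_dimacs_dump(tmp_path):
    g = _graph_from_caps((1, 2), [50.0, 22.0], [20.0, 70.0], [(0, 1, 18.0)])
    path = tmp_path / "g.dimacs"
    g.to_dimacs(path)
    text = path.read_text()
    assert text.startswith("p max 4 10")
    assert "n 3 s" in text and "n 4 t" in text
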