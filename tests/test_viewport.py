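"""Viewport transforms, LOD culling, zoom targeting, flights, growth frames."""

import math
import random

import pytest

from phylozoom import (LayoutParams, Viewport, annotate, compute_layout,
                       flight_path, growth_frame, parse_newick, scene_bounds,
                       screen_to_world, visible_elements, world_to_screen,
                       zoom_to_node)

from conftest import brute_force_visible, make_scene, make_yule, random_viewports


class TestTransform:
    VP = Viewport(center=(3.0, -2.0), scale=100.0, screen=(800.0, 600.0))

    def test_center_maps_to_midpoint(self):
        assert world_to_screen(self.VP, (3.0, -2.0)) == (400.0, 300.0)

    def test_linearity_and_y_flip(self):
        sx, sy = world_to_screen(self.VP, (4.0, -2.0))
        assert (sx, sy) == (500.0, 300.0)
        sx, sy = world_to_screen(self.VP, (3.0, -1.0))
        assert (sx, sy) == (400.0, 200.0)  # +y world is up, screen y is down

    def test_roundtrip_inverse(self):
        rng = random.Random(0)
        for _ in range(50):
            p = (rng.uniform(-10, 10), rng.uniform(-10, 10))
            q = screen_to_world(self.VP, world_to_screen(self.VP, p))
            assert q == pytest.approx(p, abs=1e-9)


class TestCulling:
    def test_disjoint_viewport_empty(self):
        tree, scene = make_scene(16)
        vp = Viewport(center=(1e6, 1e6), scale=10.0, screen=(800, 600))
        assert len(visible_elements(scene, vp)) == 0

    def test_home_view_detail_levels(self):
        tree, scene = make_scene(512, seed=6)
        b = scene_bounds(scene)
        vp = zoom_to_node(scene, tree.root.id, (1000.0, 1000.0), fill=0.9)
        draw = visible_elements(scene, vp)
        by_index = {e.index: e.detail for e in draw}
        # the root stem dominates the view -> richest detail
        assert by_index[0] == "shape+label+metadata"
        # deep sub-pixel twigs are absent
        sizes = {i: max(bb[2] - bb[0], bb[3] - bb[1]) * vp.scale
                 for i, bb in enumerate(scene.bboxes)}
        for i, size in sizes.items():
            if size < 1.0:
                assert i not in by_index

    def test_pruned_equals_bruteforce_oracle(self):
        tree, scene = make_scene(256, seed=42, form="natural")
        for vp in random_viewports(scene, 25, seed=7):
            got = [(e.index, e.detail) for e in visible_elements(scene, vp)]
            expected = brute_force_visible(scene, vp)
            assert sorted(got) == sorted(expected)

    def test_draw_order_is_tree_order(self):
        tree, scene = make_scene(64, seed=3)
        vp = zoom_to_node(scene, tree.root.id, (2000.0, 2000.0), fill=0.9)
        idx = [e.index for e in visible_elements(scene, vp)]
        assert idx == sorted(idx)  # preorder indices ascend in tree order

    def test_thresholds_must_increase(self):
        tree, scene = make_scene(8)
        vp = Viewport(center=(0, 0), scale=1.0, screen=(800, 600))
        with pytest.raises(ValueError, match="increasing"):
            visible_elements(scene, vp, {"shape": 10.0, "shape+label": 5.0,
                                         "shape+label+metadata": 150.0})

    def test_invariant_under_scene_similarity_transform(self):
        # scaling the whole scene and the viewport together changes nothing
        t = make_yule(128, seed=21)
        p1 = LayoutParams.preset("spiral")
        p2 = LayoutParams.preset("spiral", root_length=3.0, root_width=0.45)
        s1 = compute_layout(t, p1)
        s2 = compute_layout(t, p2)
        for vp1 in random_viewports(s1, 10, seed=5):
            vp2 = Viewport(center=(vp1.center[0] * 3, vp1.center[1] * 3),
                           scale=vp1.scale / 3, screen=vp1.screen)
            d1 = [(e.index, e.detail) for e in visible_elements(s1, vp1)]
            d2 = [(e.index, e.detail) for e in visible_elements(s2, vp2)]
            assert d1 == d2


class TestZoomToNode:
    def test_home_view_definition(self):
        tree, scene = make_scene(32, seed=2)
        vp = zoom_to_node(scene, tree.root.id, (1000.0, 800.0), fill=1.0)
        b = scene_bounds(scene)
        assert vp.center == pytest.approx(((b[0] + b[2]) / 2, (b[1] + b[3]) / 2))
        assert vp.scale == pytest.approx(min(1000.0 / (b[2] - b[0]),
                                             800.0 / (b[3] - b[1])))

    def test_scale_arithmetic(self):
        tree, scene = make_scene(8)
        idx = 0
        bb = scene.subtree_bboxes[idx]
        fill = 0.9
        vp = zoom_to_node(scene, scene.entries[idx].node_id, (1000.0, 1000.0), fill)
        bw, bh = bb[2] - bb[0], bb[3] - bb[1]
        assert vp.scale == pytest.approx(fill * min(1000.0 / bw, 1000.0 / bh))

    def test_projection_fits_and_fills(self):
        tree, scene = make_scene(200, seed=17, form="natural")
        rng = random.Random(1)
        node_ids = list(scene.node_index)
        for node_id in rng.sample(node_ids, 30):
            vp = zoom_to_node(scene, node_id, (900.0, 700.0), fill=0.85)
            bb = scene.subtree_bboxes[scene.node_index[node_id]]
            pw = (bb[2] - bb[0]) * vp.scale
            ph = (bb[3] - bb[1]) * vp.scale
            assert pw <= 900.0 + 1e-6 and ph <= 700.0 + 1e-6
            assert max(pw, ph) >= 0.85 * min(900.0, 700.0) - 1e-6

    def test_unknown_node(self):
        tree, scene = make_scene(4)
        with pytest.raises(KeyError, match="not in this scene"):
            zoom_to_node(scene, 10**9, (800.0, 600.0))


class TestFlightPath:
    def test_degenerate_two_identical_frames(self):
        tree, scene = make_scene(8)
        end = zoom_to_node(scene, tree.root.id, (800.0, 600.0), fill=0.9)
        fp = flight_path(scene, end, tree.root.id, frames_per_doubling=6,
                         fill=0.9)
        assert len(fp) == 2
        assert fp.frames[0] == fp.frames[1]

    def test_frame_count_ten_doublings(self):
        tree, scene = make_scene(8)
        end = zoom_to_node(scene, tree.root.id, (800.0, 600.0), fill=0.9)
        start = Viewport(center=end.center, scale=end.scale / 1024.0,
                         screen=end.screen)
        fp = flight_path(scene, start, tree.root.id, frames_per_doubling=6,
                         fill=0.9)
        assert len(fp) == 60
        assert fp.frames[0] == start
        assert fp.frames[-1].scale == pytest.approx(end.scale)

    def test_constant_zoom_speed(self):
        tree, scene = make_scene(300, seed=30, form="natural")
        rng = random.Random(2)
        home = zoom_to_node(scene, tree.root.id, (800.0, 600.0), fill=0.95)
        for node_id in rng.sample(list(scene.node_index), 10):
            fp = flight_path(scene, home, node_id, frames_per_doubling=5)
            ratios = [fp.frames[i + 1].scale / fp.frames[i].scale
                      for i in range(len(fp) - 1)]
            for r in ratios[1:]:
                assert r == pytest.approx(ratios[0], rel=1e-9)


class TestGrowthFrame:
    @pytest.fixture
    def dated(self):
        t = annotate(parse_newick("((A:1,B:2):1,(C:3,D:1):2):1;"))
        scene = compute_layout(t, LayoutParams.preset("spiral"))
        return t, scene

    def test_stem_origin_shows_root_only(self, dated):
        t, scene = dated
        origin_age = t.root.date + t.root.length  # 6.0
        sub = growth_frame(scene, t, origin_age - 1e-9)
        assert [g.index for g in sub] == [0]
        assert sub[0].partial

    def test_t_zero_whole_scene(self, dated):
        t, scene = dated
        assert len(growth_frame(scene, t, 0.0)) == len(scene)

    def test_partial_fraction(self, dated):
        t, scene = dated
        # root branch spans ages [5, 6]; at t=5.5 half has grown
        sub = growth_frame(scene, t, 5.5)
        assert len(sub) == 1 and sub[0].fraction == pytest.approx(0.5)

    def test_monotone_growth(self, dated):
        t, scene = dated
        ages = [6.5, 6.0, 5.0, 4.0, 3.0, 2.0, 1.0, 0.5, 0.0]
        counts = [len(growth_frame(scene, t, a)) for a in ages]
        assert counts == sorted(counts)
        assert counts[-1] == len(scene)

    def test_undated_tree_rejected(self):
        t = annotate(parse_newick("(A,B);"))
        scene = compute_layout(t, LayoutParams.preset("spiral"))
        with pytest.raises(ValueError, match="dated"):
            growth_frame(scene, t, 1.0)
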