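"""Path enumeration, DTW template matching, and tracking."""

from functools import lru_cache

import numpy as np
import pytest

from knottrack import rasterize_skeleton, render_image
from knottrack.evaluation import frechet_distance
from knottrack.knot_resolution import (ManualOverride,
                                       TemplateState, TrackConfig,
                                       UnresolvableFrameError, dtw_score,
                                       enumerate_paths, path_to_contour,
                                       resolve_frame, select_key_vertices,
                                       track_series)
from knottrack.segmentation import Skeleton, segment_frame
from knottrack.skeleton_graph import (PixelContour, build_graph,
                                      order_unbranched)
from tests.conftest import figure_eight_pixels, skeleton_from_pixels


def dtw_oracle(a, b):
    """Exhaustive minimum over all monotone warping paths (tiny inputs)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)

    @lru_cache(maxsize=None)
    def rec(i, j):
        cost = float(np.linalg.norm(a[i] - b[j]))
        if i == 0 and j == 0:
            return cost
        best = min((rec(i - 1, j - 1) if i and j else np.inf),
                   (rec(i - 1, j) if i else np.inf),
                   (rec(i, j - 1) if j else np.inf))
        return cost + best

    return rec(len(a) - 1, len(b) - 1)


class TestDtwScore:
    def test_identical_contours_score_zero(self):
        c = PixelContour([(0, 0), (1, 1), (2, 2), (3, 2)])
        assert dtw_score(c, c) == 0.0

    def test_single_point_base_case(self):
        assert dtw_score(np.array([[0.0, 0.0]]),
                         np.array([[3.0, 4.0]])) == pytest.approx(5.0)

    def test_symmetric_for_equal_lengths(self):
        rng = np.random.default_rng(0)
        a = rng.random((6, 2)) * 10
        b = rng.random((6, 2)) * 10
        assert dtw_score(a, b) == pytest.approx(dtw_score(b, a))

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_exhaustive_warping_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n, m = rng.integers(2, 7, size=2)
        a = rng.random((n, 2)) * 8
        b = rng.random((m, 2)) * 8
        assert dtw_score(a, b) == pytest.approx(dtw_oracle(a, b))

    def test_empty_contour_rejected(self):
        with pytest.raises(ValueError):
            dtw_score(np.empty((0, 2)), np.array([[0.0, 0.0]]))


class TestSelectKeyVertices:
    def test_all_on_template_ties_by_label(self, figure_eight):
        g = build_graph(figure_eight, start=(10, 2))
        template = TemplateState(
            PixelContour(figure_eight.pixels), frame_index=0)
        keys = select_key_vertices(g, template)
        assert len(keys) == 3
        assert keys == sorted(keys)

    def test_displaced_vertex_excluded(self, figure_eight):
        g = build_graph(figure_eight, start=(10, 2))
        far = max(g.graph.nodes,
                  key=lambda n: g.pixels_of(n)[:, 0].max())
        # template containing every pixel except those of one vertex,
        # shifted far away from it
        keep = [g.pixels_of(n) for n in g.graph.nodes if n != far]
        template = TemplateState(PixelContour(np.vstack(keep)), 0)
        g.graph.nodes[far]["pixels"] = g.pixels_of(far) + 200
        assert far not in select_key_vertices(g, template)

    def test_small_graph_returns_all(self):
        # two segments and one branch -> all three vertices returned
        pix = [(5, c) for c in range(0, 4)]
        pix += [(5, 4)]
        pix += [(5, c) for c in range(5, 9)]
        pix += [(4, 3), (3, 3), (4, 5), (3, 5)]  # arms making (5,4) a branch
        sk = skeleton_from_pixels(pix)
        g = build_graph(sk, start=(5, 0), junction_merge_len=0)
        template = TemplateState(PixelContour(sk.pixels), 0)
        keys = select_key_vertices(g, template)
        assert set(keys) <= set(g.graph.nodes)
        assert len(keys) == min(3, g.graph.number_of_nodes())


class TestEnumeratePaths:
    def test_linear_chain_single_path(self):
        # tail - T junction - tail (third arm is a dead-end segment)
        pix = [(5, c) for c in range(0, 11)]
        pix += [(4, 5), (3, 5), (2, 5)]
        sk = skeleton_from_pixels(pix)
        g = build_graph(sk, start=(5, 0), junction_merge_len=0)
        paths = enumerate_paths(g)
        # the only full-coverage-free admissible terminal is the far tail;
        # the dead-end arm cannot be left once entered, so enumeration
        # falls back to reach-the-end paths
        assert all(p.vertex_sequence[0] == g.start_vertex for p in paths)
        assert all(p.vertex_sequence[-1] == g.end_vertex for p in paths)

    def test_figure_eight_two_loop_orientations(self, figure_eight):
        g = build_graph(figure_eight, start=(10, 2))
        paths = enumerate_paths(g)
        # full coverage requires passing through the loop; it can be
        # traversed in two orientations
        contours = {tuple(map(tuple, path_to_contour(g, p).points))
                    for p in paths}
        assert len(contours) == 2

    def test_cap_limits_breadth(self, figure_eight):
        g = build_graph(figure_eight, start=(10, 2))
        capped = enumerate_paths(g, cap=1)
        assert len(capped) >= 1
        assert len(capped) <= len(enumerate_paths(g, cap=10))

    def test_max_paths_bound_respected(self, figure_eight):
        g = build_graph(figure_eight, start=(10, 2))
        assert len(enumerate_paths(g, max_paths=1)) == 1

    def test_each_segment_visited_once(self, figure_eight):
        g = build_graph(figure_eight, start=(10, 2))
        segs = set(g.segment_vertices)
        for p in enumerate_paths(g):
            visited = [v for v in p.vertex_sequence if v in segs]
            assert len(visited) == len(set(visited)) == len(segs)


class TestPathToContour:
    def test_single_segment_reduces_to_ordering(self, straight_line_skeleton):
        contour = order_unbranched(straight_line_skeleton, (5, 3))
        np.testing.assert_array_equal(
            contour.points, [(5, c) for c in range(3, 13)])

    def test_figure_eight_contour_covers_skeleton(self, figure_eight):
        tail_in, cross, loop, tail_out = figure_eight_pixels()
        g = build_graph(figure_eight, start=(10, 2))
        paths = enumerate_paths(g)
        contour = path_to_contour(g, paths[0])
        pix_set = {tuple(p) for p in contour.points}
        skel_set = {tuple(p) for p in figure_eight.pixels}
        # no invented pixels, and every non-junction pixel covered
        assert pix_set <= skel_set
        seg_pixels = {tuple(p) for n in g.segment_vertices
                      for p in g.pixels_of(n)}
        assert seg_pixels <= pix_set
        # junction pixels appear, counted once per crossing at most twice
        n_branch = sum(len(g.pixels_of(n)) for n in g.branch_vertices)
        assert len(seg_pixels) < len(contour) <= len(seg_pixels) + 2 * n_branch

    def test_loop_orientations_same_set_different_sequence(self,
                                                           figure_eight):
        g = build_graph(figure_eight, start=(10, 2))
        paths = enumerate_paths(g)
        c1, c2 = (path_to_contour(g, p) for p in paths[:2])
        s1 = {tuple(p) for p in c1.points}
        s2 = {tuple(p) for p in c2.points}
        # same filament pixels up to junction-crossing attribution
        branch = {tuple(p) for n in g.branch_vertices
                  for p in g.pixels_of(n)}
        assert (s1 ^ s2) <= branch
        assert not np.array_equal(c1.points, c2.points)

    def test_junction_jumps_bounded(self, figure_eight):
        g = build_graph(figure_eight, start=(10, 2))
        contour = path_to_contour(g, enumerate_paths(g)[0])
        steps = np.linalg.norm(
            np.diff(contour.points.astype(float), axis=0), axis=1)
        assert steps.max() <= 2.9  # Moore steps, small jumps at junctions


class TestResolveFrame:
    def test_unbranched_ignores_template(self, straight_line_skeleton):
        bogus = TemplateState(PixelContour([(50, 50), (50, 51)]), 0)
        a, _ = resolve_frame(straight_line_skeleton, bogus, (5, 3), 10)
        b, _ = resolve_frame(straight_line_skeleton, None, (5, 3), 10)
        np.testing.assert_array_equal(a.points, b.points)

    def test_branched_without_template_unresolvable(self, figure_eight):
        with pytest.raises(UnresolvableFrameError):
            resolve_frame(figure_eight, None, (10, 2), 10)

    def test_knot_resolved_close_to_truth(self, hook_curves, hook_shape):
        skels = [Skeleton(rasterize_skeleton(c, hook_shape))
                 for c in hook_curves]
        template, _ = resolve_frame(skels[0], None, (150, 40), 10)
        contour, info = resolve_frame(
            skels[1], TemplateState(template, 0),
            (150, 40), 10)
        assert info["branched"]
        fr = frechet_distance(contour.xy, hook_curves[1].points)
        assert fr <= 2.0


class TestTrackSeries:
    def test_all_unbranched_equals_independent_ordering(self, wave_params):
        from knottrack import synthesize_series
        frames = synthesize_series(wave_params)
        skels = [segment_frame(f.image) for f in frames]
        track = track_series(
            skels, TrackConfig(start_xy=wave_params.base_xy))
        assert track.skipped == []
        for skel, contour in zip(skels, track.contours):
            start = tuple(contour.points[0])
            expected = order_unbranched(skel, start)
            np.testing.assert_array_equal(contour.points, expected.points)

    def test_full_image_pipeline_resolves_knot(self, hook_curves, hook_shape):
        rng = np.random.default_rng(1)
        skels = [segment_frame(render_image(rasterize_skeleton(c, hook_shape)))
                 for c in hook_curves]
        track = track_series(skels, TrackConfig(start_xy=(40.0, 150.0)))
        assert track.skipped == []
        assert track.info[1]["branched"]
        fr = frechet_distance(track.contours[1].xy, hook_curves[1].points)
        assert fr <= 2.0

    def test_branched_first_frame_without_override_errors(self, figure_eight):
        with pytest.raises(UnresolvableFrameError):
            track_series([figure_eight], TrackConfig(start_xy=(2.0, 10.0)))

    def test_override_takes_precedence(self, figure_eight):
        g = build_graph(figure_eight, start=(10, 2))
        # force a skip-the-loop path that automatic enumeration (which
        # must cover every segment) would never select
        loop_v = next(s for s in g.segment_vertices
                      if len(g.graph.get_edge_data(
                          s, g.branch_vertices[0]) or {}) == 2)
        seq = [g.start_vertex, g.branch_vertices[0], g.end_vertex]
        override = ManualOverride(0, tuple(seq))
        track = track_series([figure_eight],
                             TrackConfig(start_xy=(2.0, 10.0)),
                             overrides=[override])
        got = {tuple(p) for p in track.contours[0].points}
        loop_pixels = {tuple(p) for p in g.pixels_of(loop_v)}
        assert not (got & loop_pixels)
        start_pixels = {tuple(p) for p in g.pixels_of(g.start_vertex)}
        assert start_pixels <= got

    def test_template_robust_to_small_shift(self, hook_curves, hook_shape):
        skels = [Skeleton(rasterize_skeleton(c, hook_shape))
                 for c in hook_curves]
        template, _ = resolve_frame(skels[0], None, (150, 40), 10)
        base_contour, _ = resolve_frame(
            skels[1], TemplateState(template, 0), (150, 40), 10)
        shifted = TemplateState(
            PixelContour(template.points + np.array([2, 1])), 0)
        shifted_contour, _ = resolve_frame(skels[1], shifted, (150, 40), 10)
        np.testing.assert_array_equal(base_contour.points,
                                      shifted_contour.points)
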