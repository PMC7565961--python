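import numpy as np
import pytest

from cardiomorph import (
    BinaryMask,
    CellSpec,
    ChannelSet,
    CMRecord,
    Contour,
    GrayImage,
    RotatedBox,
    SyntheticScene,
    apply_selection,
    detect_myocytes,
    expand_box,
    filter_boxes,
    filter_contours,
    find_external_contours,
    fit_min_area_box,
    measure_cm,
    rasterize_box,
    render_scene,
    threshold_only_config,
)
from cardiomorph.detect import DegenerateGeometryError, SelectionError


def bmask(arr, scale=1.0):
    return BinaryMask(np.asarray(arr, bool), scale=scale)


def min_area_calipers(points):
    """Rotating-calipers oracle: brute force over convex-hull edge angles."""
    from scipy.spatial import ConvexHull

    pts = np.asarray(points, float)
    hull = pts[ConvexHull(pts).vertices]
    best = np.inf
    for i in range(len(hull)):
        e = hull[(i + 1) % len(hull)] - hull[i]
        t = np.arctan2(e[1], e[0])
        rot = np.array([[np.cos(t), np.sin(t)], [-np.sin(t), np.cos(t)]])
        proj = hull @ rot.T
        span = proj.max(axis=0) - proj.min(axis=0)
        best = min(best, span[0] * span[1])
    return best


class TestContours:
    def test_empty_mask_gives_no_contours(self):
        assert find_external_contours(bmask(np.zeros((10, 10)))) == []

    def test_solid_square_area_follows_corner_cut_convention(self):
        px = np.zeros((14, 14), bool)
        px[2:12, 2:12] = True
        cs = find_external_contours(bmask(px))
        assert len(cs) == 1
        # marching-squares boundary: 10x10 square minus four 45-degree
        # corner cuts of area 1/8 each
        assert cs[0].area_px2 == pytest.approx(99.5)

    def test_interior_hole_suppressed(self):
        px = np.zeros((20, 20), bool)
        px[2:18, 2:18] = True
        px[8:12, 8:12] = False
        cs = find_external_contours(bmask(px))
        assert len(cs) == 1
        assert cs[0].area_px2 > 200  # outer boundary, not the hole

    def test_discovery_order_row_major(self):
        px = np.zeros((30, 30), bool)
        px[20:25, 2:7] = True  # lower-left
        px[2:7, 20:25] = True  # upper-right: discovered first
        cs = find_external_contours(bmask(px))
        assert len(cs) == 2
        assert cs[0].vertices[:, 1].mean() < cs[1].vertices[:, 1].mean()

    def test_diagonal_components_are_eight_connected(self):
        px = np.zeros((10, 10), bool)
        px[2, 2] = px[3, 3] = True
        assert len(find_external_contours(bmask(px))) == 1


class TestFilterContours:
    TRI = [(0, 0), (1, 0), (0, 1)]

    @pytest.mark.parametrize(
        "area,perim,kept",
        [(99, 50, False), (150, 39, False), (150, 50, True), (100, 50, False)],
    )
    def test_strict_plausibility_rules(self, area, perim, kept):
        c = Contour(vertices=self.TRI, area_px2=area, perim_px=perim)
        out = filter_contours([c], scale=1.0)
        assert (len(out) == 1) is kept


class TestMinAreaBox:
    def test_axis_aligned_rectangle(self):
        box = fit_min_area_box(np.array([(0, 0), (10, 0), (10, 4), (0, 4)], float))
        assert box.long_px == pytest.approx(10)
        assert box.short_px == pytest.approx(4)
        assert box.angle_deg == pytest.approx(0, abs=1e-9)

    def test_rotated_rectangle_recovers_angle(self):
        t = np.deg2rad(30)
        rot = np.array([[np.cos(t), -np.sin(t)], [np.sin(t), np.cos(t)]])
        pts = np.array([(0, 0), (10, 0), (10, 4), (0, 4)], float) @ rot.T
        box = fit_min_area_box(pts)
        assert box.long_px == pytest.approx(10, abs=1e-6)
        assert box.short_px == pytest.approx(4, abs=1e-6)
        assert box.angle_deg == pytest.approx(30, abs=1e-6)

    def test_random_clouds_match_calipers_oracle(self, rng):
        for _ in range(50):
            pts = rng.random((20, 2)) * 100
            box = fit_min_area_box(pts)
            assert box.area_px2 == pytest.approx(
                min_area_calipers(pts), rel=1e-6
            )

    def test_never_larger_than_axis_aligned_bbox(self, rng):
        for _ in range(20):
            pts = rng.random((15, 2)) * 50
            box = fit_min_area_box(pts)
            span = pts.max(axis=0) - pts.min(axis=0)
            assert box.area_px2 <= span[0] * span[1] + 1e-9

    def test_collinear_points_rejected(self):
        with pytest.raises(DegenerateGeometryError):
            fit_min_area_box(np.array([(0, 0), (1, 1), (2, 2)], float))


class TestExpandBox:
    def square(self):
        return RotatedBox.from_vertices(
            np.array([(0, 0), (10, 0), (10, 10), (0, 10)], float)
        )

    def test_h_zero_is_identity(self):
        box = self.square()
        out = expand_box(box, 0)
        assert np.allclose(out.vertices, box.vertices)

    def test_canonical_diagonal_projection(self):
        out = expand_box(self.square(), np.sqrt(2))
        expected = np.array([(-1, -1), (11, -1), (11, 11), (-1, 11)], float)
        assert np.allclose(out.vertices, expected, atol=1e-9)

    def test_similarity_preserved(self, rng):
        for _ in range(20):
            box = RotatedBox.from_params(
                center=tuple(rng.random(2) * 100),
                angle_deg=rng.uniform(-90, 90),
                long_px=rng.uniform(10, 50),
                short_px=rng.uniform(2, 10),
            )
            h = rng.uniform(0, 20)
            out = expand_box(box, h)
            assert out.long_px / out.short_px == pytest.approx(
                box.long_px / box.short_px, abs=1e-9
            )
            assert out.diagonal_px == pytest.approx(box.diagonal_px + 2 * h, abs=1e-9)

    def test_negative_padding_rejected(self):
        with pytest.raises(ValueError):
            expand_box(self.square(), -1)

    def test_default_padding_arithmetic(self):
        from cardiomorph import ChannelParams, PipelineConfig

        cfg = PipelineConfig(
            c1=ChannelParams(thr=8),
            c2=ChannelParams(thr=15, ng=3, ng_it=5),
        )
        assert cfg.resolved_h() == 30  # 2 * 3 * 5


class TestMeasure:
    def test_length_averages_fitted_and_padded_boxes(self):
        box = RotatedBox.from_params((0, 0), 0, 100, 20)
        exp = RotatedBox.from_params((0, 0), 0, 120, 24)
        L, W, R, A = measure_cm(box, exp, 0.21)
        assert L == pytest.approx(23.1)
        assert W == pytest.approx(20 * 0.21)
        assert R == pytest.approx(L / W)
        assert A == pytest.approx(L * W)

    def test_h_zero_means_plain_scaled_length(self):
        box = RotatedBox.from_params((0, 0), 0, 100, 20)
        L, _, _, _ = measure_cm(box, expand_box(box, 0), 0.5)
        assert L == pytest.approx(50.0)

    def test_width_independent_of_expansion(self):
        box = RotatedBox.from_params((0, 0), 0, 100, 20)
        _, w1, _, _ = measure_cm(box, expand_box(box, 0), 1.0)
        _, w2, _, _ = measure_cm(box, expand_box(box, 15), 1.0)
        assert w1 == w2 == 20


def _record(L, W):
    box = RotatedBox.from_params((0, 0), 0, 10, 5)
    return CMRecord(
        id=0, box=box, box_expanded=box, L=L, W=W, R=L / W, A=L * W, angle_deg=0
    )


class TestFilterBoxes:
    @pytest.mark.parametrize(
        "L,W,kept",
        [
            (19, 10, False),
            (21, 10, True),
            (100, 55, False),
            (200, 10, False),  # strict upper bound
            (100, 5, False),  # strict lower bound
        ],
    )
    def test_strict_size_bounds(self, L, W, kept):
        assert (len(filter_boxes([_record(L, W)])) == 1) is kept


class TestRasterize:
    def test_axis_aligned_box_pixel_count(self):
        box = RotatedBox.from_params((20, 4), 0, 40, 8)
        rows, cols = rasterize_box(box, (100, 100))
        assert rows.size == 40 * 8
        assert rows.min() == 0 and rows.max() == 7
        assert cols.min() == 0 and cols.max() == 39


class TestDetect:
    def _scene_channels(self, n=10):
        cells = []
        for i in range(n):
            r, c = divmod(i, 4)
            cells.append(
                CellSpec(
                    center=(150 + c * 240, 150 + r * 240),
                    angle_deg=15 * i - 45,
                    L_um=40 + 2 * i,
                    W_um=12 + i,
                )
            )
        scene = SyntheticScene(image_size=(1024, 1024), cells=cells, seed=3)
        return scene, render_scene(scene)

    def test_recovers_all_planted_cells(self):
        scene, (channels, truth) = self._scene_channels()
        recs = detect_myocytes(channels, threshold_only_config())
        assert len(recs) == len(truth)
        by_center = {
            (round(t.box.center[0] / 50), round(t.box.center[1] / 50)): t
            for t in truth
        }
        for r in recs:
            key = (round(r.box.center[0] / 50), round(r.box.center[1] / 50))
            t = by_center[key]
            assert abs(r.L - t.L_um) <= 2 * scene.scale
            assert abs(r.W - t.W_um) <= 2 * scene.scale

    def test_undersized_cells_all_filtered(self):
        cells = [
            CellSpec(center=(50 + 60 * i, 50), angle_deg=0, L_um=8, W_um=8)
            for i in range(3)
        ]
        scene = SyntheticScene(image_size=(200, 200), cells=cells)
        channels, _ = render_scene(scene)
        assert detect_myocytes(channels, threshold_only_config()) == []

    def test_empty_channel_gives_no_records(self):
        channels = ChannelSet(c1=GrayImage(np.zeros((64, 64), np.uint8), 0.21))
        assert detect_myocytes(channels, threshold_only_config()) == []

    def test_detection_is_deterministic(self, small_scene_rendered):
        channels, _ = small_scene_rendered
        cfg = threshold_only_config()
        a = detect_myocytes(channels, cfg)
        b = detect_myocytes(channels, cfg)
        assert len(a) == len(b)
        for ra, rb in zip(a, b):
            assert ra.L == rb.L and ra.W == rb.W and ra.clat == rb.clat
            assert np.array_equal(ra.box.vertices, rb.box.vertices)

    def test_every_record_satisfies_filters(self, small_scene_rendered):
        channels, _ = small_scene_rendered
        for r in detect_myocytes(channels, threshold_only_config()):
            assert 20 < r.L < 200 and 5 < r.W < 50


class TestSelection:
    def make(self, n=5):
        return [_record(50, 10) for _ in range(n)]

    def setup_records(self):
        recs = self.make()
        for i, r in enumerate(recs):
            r.id = i
        return recs

    def test_full_manifest_is_identity(self):
        recs = self.setup_records()
        assert apply_selection(recs, [r.id for r in recs]) == recs

    def test_empty_manifest_empty_result(self):
        assert apply_selection(self.setup_records(), []) == []

    def test_prefix_manifest_keeps_order(self):
        recs = self.setup_records()
        assert apply_selection(recs, [0, 1, 2]) == recs[:3]

    def test_unknown_id_rejected(self):
        with pytest.raises(SelectionError):
            apply_selection(self.setup_records(), [99])
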