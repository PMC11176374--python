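import numpy as np
import pytest
from scipy.spatial import cKDTree
from shapely.geometry import Polygon

import rpemosaic as rm


def make_star(n_points=5, r_outer=10.0, r_inner=3.82, center=(0.0, 0.0)):
    """Vertex list of a regular star polygon (alternating radii)."""
    angles = np.arange(2 * n_points) * np.pi / n_points
    radii = np.where(np.arange(2 * n_points) % 2 == 0, r_outer, r_inner)
    return np.column_stack(
        [center[0] + radii * np.cos(angles), center[1] + radii * np.sin(angles)]
    )


def brute_force_hull_area(points: np.ndarray) -> float:
    """Hull oracle at small n: a point is extreme iff it is inside no
    triangle of three other points; extreme points sorted by angle give the
    hull polygon (all-subsets check, no hull library)."""
    from itertools import combinations

    def cross2(u, v):
        return u[0] * v[1] - u[1] * v[0]

    def in_triangle(p, a, b, c):
        d1 = cross2(b - a, p - a)
        d2 = cross2(c - b, p - b)
        d3 = cross2(a - c, p - c)
        return (d1 >= -1e-12 and d2 >= -1e-12 and d3 >= -1e-12) or (
            d1 <= 1e-12 and d2 <= 1e-12 and d3 <= 1e-12
        )

    n = len(points)
    extreme = []
    for i in range(n):
        others = [j for j in range(n) if j != i]
        inside = any(
            in_triangle(points[i], points[a], points[b], points[c])
            for a, b, c in combinations(others, 3)
        )
        if not inside:
            extreme.append(i)
    hull_pts = points[extreme]
    centroid = hull_pts.mean(axis=0)
    order = np.argsort(np.arctan2(hull_pts[:, 1] - centroid[1], hull_pts[:, 0] - centroid[0]))
    hp = hull_pts[order]
    x, y = hp[:, 0], hp[:, 1]
    return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


class TestSegmentHyporeflective:
    def test_constant_image_gives_no_regions(self):
        assert rm.segment_hyporeflective(np.full((128, 128), 0.6)) == []

    def test_single_dark_disc_recovered(self):
        """Ideal two-level case: one region matching the disc to ~1 px."""
        img = np.full((128, 128), 0.9)
        yy, xx = np.mgrid[0:128, 0:128]
        disc = (xx - 64) ** 2 + (yy - 64) ** 2 <= 20**2
        img[disc] = 0.2
        contours = rm.segment_hyporeflective(img, max_area_px=5000.0)
        assert len(contours) == 1
        poly = Polygon(contours[0])
        true_area = np.pi * 20**2
        assert abs(poly.area - true_area) / true_area < 0.10
        cx, cy = poly.centroid.x, poly.centroid.y
        assert abs(cx - 64) < 1.0 and abs(cy - 64) < 1.0

    def test_ground_truth_blob_iou(self, rendered):
        """>=90% of drawn blobs recovered with IoU >= 0.7 at default params."""
        img, gt = rendered
        qmask = rm.mask_from_quality(rm.quality_map(img), threshold=0.5)
        contours = rm.segment_hyporeflective(img, qmask)
        seg = [Polygon(c * img.pixel_size) for c in contours]
        tree = cKDTree([np.mean(c, axis=0) * img.pixel_size for c in contours])
        ious = []
        for blob in gt.blob_contours:
            gp = Polygon(blob)
            _, j = tree.query(np.mean(blob, axis=0))
            union = gp.union(seg[j]).area
            ious.append(gp.intersection(seg[j]).area / union if union > 0 else 0.0)
        assert np.mean(np.asarray(ious) >= 0.7) >= 0.90

    def test_contours_inside_unmasked_region(self, lowq_rendered):
        img, _, _ = lowq_rendered
        qmask = rm.mask_from_quality(rm.quality_map(img, tile_size=16), threshold=0.5)
        contours = rm.segment_hyporeflective(img, qmask)
        assert contours, "expected blobs in the analyzable region"
        grown = qmask.mask.copy()
        for c in contours:
            cols = np.clip(np.round(c[:, 0]).astype(int), 0, qmask.mask.shape[1] - 1)
            rows = np.clip(np.round(c[:, 1]).astype(int), 0, qmask.mask.shape[0] - 1)
            # contour vertices live on half-pixel boundaries: allow 1 px slack
            window = np.stack([
                grown[rows, cols],
                grown[np.minimum(rows + 1, grown.shape[0] - 1), cols],
                grown[rows, np.minimum(cols + 1, grown.shape[1] - 1)],
                grown[np.maximum(rows - 1, 0), cols],
                grown[rows, np.maximum(cols - 1, 0)],
            ])
            assert window.any(axis=0).all()


class TestAssignRegionsToCells:
    def test_ground_truth_blobs_assigned_to_their_cell(self, rendered):
        _, gt = rendered
        assigned = rm.hypo.assign_regions_to_cells(gt.blob_contours, gt.centers)
        assert np.mean(assigned == np.array(gt.blob_cell_index)) > 0.95

    def test_empty_input(self):
        assert len(rm.hypo.assign_regions_to_cells([], np.zeros((3, 2)))) == 0


class TestShapeDescriptors:
    def test_digitized_disc(self):
        """Rasterized-circle oracle: solidity >= 0.98, circularity in [0.95, 1.05]."""
        img = np.full((96, 96), 0.9)
        yy, xx = np.mgrid[0:96, 0:96]
        img[(xx - 48.3) ** 2 + (yy - 47.6) ** 2 <= 20**2] = 0.1
        contours = rm.segment_hyporeflective(img, max_area_px=5000.0)
        hset = rm.shape_descriptors(contours)
        assert hset.per_region["solidity"].iloc[0] >= 0.98
        assert 0.95 <= hset.per_region["circularity"].iloc[0] <= 1.05

    def test_star_solidity_against_brute_force_hull(self):
        star = make_star()
        hset = rm.shape_descriptors([star])
        star_area = Polygon(star).area
        hull_area = brute_force_hull_area(star)
        expected = star_area / hull_area
        assert hset.per_region["solidity"].iloc[0] == pytest.approx(expected, abs=1e-9)
        assert expected < 0.6
        assert hset.per_region["circularity"].iloc[0] < hset.per_region["solidity"].iloc[0]

    def test_convex_polygon_solidity_is_one(self):
        rng = np.random.default_rng(5)
        pts = rng.normal(size=(30, 2))
        from scipy.spatial import ConvexHull

        hull = ConvexHull(pts)
        poly = pts[hull.vertices]
        hset = rm.shape_descriptors([poly])
        assert hset.per_region["solidity"].iloc[0] == pytest.approx(1.0, abs=1e-6)

    def test_rotation_invariance(self):
        star = make_star()
        theta = 0.7
        rot = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        a = rm.shape_descriptors([star]).per_region
        b = rm.shape_descriptors([star @ rot.T]).per_region
        for col in ("solidity", "circularity", "area_um2", "perimeter_um"):
            assert a[col].iloc[0] == pytest.approx(b[col].iloc[0], abs=1e-3)

    def test_scale_covariance(self):
        star = make_star()
        a = rm.shape_descriptors([star], pixel_size=1.0).per_region
        b = rm.shape_descriptors([star], pixel_size=3.0).per_region
        assert b["area_um2"].iloc[0] == pytest.approx(9 * a["area_um2"].iloc[0])
        assert b["perimeter_um"].iloc[0] == pytest.approx(3 * a["perimeter_um"].iloc[0])
        assert b["solidity"].iloc[0] == pytest.approx(a["solidity"].iloc[0])
        assert b["circularity"].iloc[0] == pytest.approx(a["circularity"].iloc[0])

    def test_degenerate_contours_dropped(self):
        degenerate = np.array([[0.0, 0.0], [1.0, 1.0], [2.0, 2.0]])  # zero area
        hset = rm.shape_descriptors([degenerate, make_star()])
        assert hset.n_dropped_degenerate == 1
        assert len(hset.per_region) == 1

    def test_roughness_degrades_shape_monotonically(self):
        """Rougher blob boundaries: lower mean solidity/circularity, higher
        dispersion of solidity and perimeter (the disease direction)."""
        stats = []
        for roughness in (0.0, 0.15, 0.30):
            sol, circ, sol_sd, per_sd = [], [], [], []
            for seed in range(10):
                rng = np.random.default_rng(seed)
                contours = [rm.generate_blob_contour(2.2, roughness, rng) for _ in range(40)]
                s = rm.shape_descriptors(contours).summary
                sol.append(s["solidity_mean"])
                circ.append(s["circularity_mean"])
                sol_sd.append(s["solidity_sd"])
                per_sd.append(s["perimeter_um_sd"])
            stats.append((np.mean(sol), np.mean(circ), np.mean(sol_sd), np.mean(per_sd)))
        assert stats[0][0] > stats[1][0] > stats[2][0]  # solidity mean falls
        assert stats[0][1] > stats[1][1] > stats[2][1]  # circularity mean falls
        assert stats[0][2] < stats[1][2] < stats[2][2]  # solidity SD rises
        assert stats[0][3] < stats[1][3] < stats[2][3]  # perimeter SD rises
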