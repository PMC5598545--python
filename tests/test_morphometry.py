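"""Skeletons, diameters, distance transforms, spots, sprout counting."""

import numpy as np
import pytest
from scipy import ndimage

import vascniche as v

from conftest import SPACING, cylinder_mask


def brute_force_distance(mask: np.ndarray, spacing) -> np.ndarray:
    """All-pairs nearest-mask-voxel distance; the independent oracle."""
    sp = np.asarray(spacing, dtype=float)
    targets = np.argwhere(mask) * sp
    coords = np.stack(
        np.meshgrid(*[np.arange(n) * s for n, s in zip(mask.shape, sp)],
                    indexing="ij"), axis=-1)
    flat = coords.reshape(-1, 3)
    d = np.sqrt(((flat[:, None, :] - targets[None, :, :]) ** 2).sum(-1)).min(1)
    return d.reshape(mask.shape)


class TestSkeleton:
    def test_thin_line_is_its_own_skeleton(self):
        mask = np.zeros((5, 5, 40), bool)
        mask[2, 2, 5:35] = True
        skel = v.skeletonize_vessels(v.BinaryMask(mask, (1, 1, 1)))
        assert np.array_equal(skel.values, mask)

    def test_cylinder_axis_recovered(self):
        bm = cylinder_mask(radius_vox=4.0)
        skel = v.skeletonize_vessels(bm)
        pts = np.argwhere(skel.values)
        half = (bm.shape[0] - 1) // 2
        dev = np.hypot(pts[:, 0] - half, pts[:, 1] - half)
        assert (dev <= 1.0).mean() >= 0.95

    def test_disjoint_tubes_stay_disjoint(self):
        mask = np.zeros((5, 20, 40), bool)
        mask[2, 4, 5:35] = True
        mask[2, 15, 5:35] = True
        skel = v.skeletonize_vessels(v.BinaryMask(mask, (1, 1, 1)))
        _, n = ndimage.label(skel.values, structure=np.ones((3, 3, 3), bool))
        assert n == 2

    def test_empty_mask_rejected(self):
        with pytest.raises(v.DegenerateInputError):
            v.skeletonize_vessels(v.BinaryMask(np.zeros((4, 4, 4), bool)))


class TestFragments:
    def test_unbranched_tube_single_fragment(self):
        bm = cylinder_mask(radius_vox=3.0)
        frags = v.split_fragments(v.skeletonize_vessels(bm))
        assert len(frags) == 1

    def test_y_junction_three_fragments(self):
        mask = np.zeros((3, 40, 40), bool)
        mask[1, 20, 2:21] = True          # stem
        mask[1, 2:20, 20] = True          # arm up
        mask[1, 21:38, 20] = True         # arm down
        frags = v.split_fragments(
            v.skeletonize_vessels(v.BinaryMask(mask, (1, 1, 1))))
        assert len(frags) == 3

    def test_phantom_tree_fragment_count(self, tree, blurred_stack):
        """Depth-3 tree has 15 segments; skeleton fragments within +-2."""
        _, truth = blurred_stack
        skel = v.skeletonize_vessels(truth.vessel_mask)
        frags = v.split_fragments(skel, prune_um=5.0)
        assert abs(len(frags) - tree.n_segments) <= 2


class TestDiameters:
    def test_cylinder_diameter_within_10pct(self):
        for r in (3.0, 4.0, 5.0):
            bm = cylinder_mask(radius_vox=r)
            frags = v.vessel_mean_diameters(bm)
            est = max(f.mean_diameter_um for f in frags)
            assert est == pytest.approx(2 * r, rel=0.10)

    def test_diameters_scale_with_spacing(self):
        bm1 = cylinder_mask(radius_vox=4.0, spacing=(1.0, 1.0, 1.0))
        bm2 = cylinder_mask(radius_vox=4.0, spacing=(2.0, 2.0, 2.0))
        d1 = v.vessel_mean_diameters(bm1)[0].mean_diameter_um
        d2 = v.vessel_mean_diameters(bm2)[0].mean_diameter_um
        assert d2 == 2.0 * d1

    def test_phantom_segment_diameter_recovery(self):
        """Median relative diameter error <= 10% for radii >= 3 voxels,
        matching fragments to truth segments by centerline position."""
        iso = (1.0, 1.0, 1.0)
        t = v.make_vessel_tree((96, 96, 96), depth=2, root_radius=5.0,
                               taper=0.8, seed=5)
        _, truth = v.render_stack(t, (96, 96, 96), spacing=iso,
                                  leak_fraction=0.0, psf_sigma_um=None,
                                  noise=None, n_cells=0, seed=5)
        frags = v.vessel_mean_diameters(truth.vessel_mask)
        rel_errors = []
        for frag in frags:
            mid = np.asarray(frag.centerline[len(frag.centerline) // 2], float)
            best, best_d = None, np.inf
            for seg in t.segments:
                ab = seg.end - seg.start
                tt = np.clip((mid - seg.start) @ ab / (ab @ ab), 0, 1)
                d = np.linalg.norm(mid - (seg.start + tt * ab))
                if d < best_d:
                    best, best_d = seg, d
            rel_errors.append(abs(frag.mean_diameter_um - best.diameter)
                              / best.diameter)
        assert np.median(rel_errors) <= 0.10

    def test_fragment_outside_mask_rejected(self):
        bm = cylinder_mask(radius_vox=3.0)
        frags = v.split_fragments(v.skeletonize_vessels(bm))
        frags[0].centerline[0] = (0, 0, 0)  # corner voxel is background
        with pytest.raises(v.InconsistencyError):
            v.fragment_diameters(frags, bm)


class TestDistanceMap:
    def test_adjacent_voxel_distance(self):
        mask = np.zeros((3, 3, 3), bool)
        mask[1, 1, 1] = True
        dm = v.distance_map(v.BinaryMask(mask, SPACING))
        assert dm[1, 1, 2] == pytest.approx(0.5)
        assert dm[0, 1, 1] == pytest.approx(2.0)
        assert dm[1, 1, 1] == 0.0

    def test_all_mask_all_zero(self):
        dm = v.distance_map(v.BinaryMask(np.ones((4, 4, 4), bool), SPACING))
        assert np.all(dm == 0)

    def test_matches_brute_force_on_random_masks(self):
        """Exactness of the anisotropic EDT: 20 seeded 16^3 masks."""
        for seed in range(20):
            rng = np.random.default_rng(seed)
            mask = rng.random((16, 16, 16)) < 0.05
            mask[seed % 16, 0, 0] = True  # never empty
            dm = v.distance_map(v.BinaryMask(mask, SPACING))
            bf = brute_force_distance(mask, SPACING)
            assert np.abs(dm - bf).max() < 1e-9

    def test_empty_mask_rejected(self):
        with pytest.raises(v.DegenerateInputError):
            v.distance_map(v.BinaryMask(np.zeros((4, 4, 4), bool)))


class TestVesselHypoxiaDistances:
    def test_overlapping_component_scores_zero(self):
        vm = np.zeros((3, 8, 8), bool); vm[1, 2:4, 2:4] = True
        hm = np.zeros((3, 8, 8), bool); hm[1, 3, 3] = True
        dd = v.vessel_hypoxia_distances(v.BinaryMask(vm, (1, 1, 1)),
                                        v.BinaryMask(hm, (1, 1, 1)))
        assert dd.distances_um.tolist() == [0.0]

    def test_single_pair_known_distance(self):
        vm = np.zeros((3, 8, 21), bool); vm[1, 4, 0] = True
        hm = np.zeros((3, 8, 21), bool); hm[1, 4, 20] = True
        dd = v.vessel_hypoxia_distances(v.BinaryMask(vm, (1, 1, 0.5)),
                                        v.BinaryMask(hm, (1, 1, 0.5)),
                                        bin_width=5.0)
        assert dd.distances_um.tolist() == [10.0]
        assert dd.frequencies.sum() == pytest.approx(1.0)
        assert dd.frequencies[2] == 1.0  # the 10-15 um bin

    def test_aml_like_hypoxia_closer_to_vessels(self, tree):
        """Fast-saturating hypoxia (small lambda) puts hypoxic tissue next
        to vessels: per-vessel distances shrink vs a control-like field."""
        medians = {}
        for label, lam in (("aml", 5.0), ("control", 40.0)):
            ch, truth = v.render_stack(tree, (48, 192, 192), spacing=SPACING,
                                       leak_fraction=0.0, psf_sigma_um=None,
                                       noise=None, n_cells=0,
                                       hypoxia_lambda_um=lam, seed=6)
            hmask = v.segment_mask(ch["hypoxia"], threshold=0.5 * 100.0,
                                   min_component_voxels=1)
            dd = v.vessel_hypoxia_distances(truth.vessel_mask, hmask)
            medians[label] = dd.median_um
        assert medians["aml"] < medians["control"]

    def test_empty_hypoxia_mask_rejected(self):
        vm = v.BinaryMask(np.ones((3, 3, 3), bool))
        hm = v.BinaryMask(np.zeros((3, 3, 3), bool))
        with pytest.raises(v.DegenerateInputError):
            v.vessel_hypoxia_distances(vm, hm)


class TestHypoxiaDensity:
    def test_uniform_volume(self):
        vol = v.ImageVolume(np.full((4, 6, 6), 7.5), SPACING, "hypoxia")
        assert v.hypoxia_density(vol).density == 7.5

    def test_all_zero(self):
        vol = v.ImageVolume(np.zeros((4, 6, 6)), SPACING, "hypoxia")
        assert v.hypoxia_density(vol).density == 0.0

    def test_faster_saturation_higher_density(self, tree):
        dens = {}
        for lam in (10.0, 30.0):
            ch, _ = v.render_stack(tree, (48, 192, 192), spacing=SPACING,
                                   leak_fraction=0.0, psf_sigma_um=None,
                                   noise=None, n_cells=0,
                                   hypoxia_lambda_um=lam, seed=6)
            dens[lam] = v.hypoxia_density(ch["hypoxia"]).density
        assert dens[10.0] > dens[30.0]


class TestSpots:
    def test_empty_volume_no_spots(self):
        vol = v.ImageVolume(np.zeros((8, 16, 16)), SPACING, "cells")
        assert len(v.detect_spots(vol)) == 0

    def test_five_separated_blobs_recovered(self):
        centers = [(8, 20, 20), (8, 60, 20), (8, 20, 60), (8, 60, 60),
                   (16, 40, 40)]
        vals = np.zeros((24, 80, 80))
        for c in centers:
            vals[c] = 1000.0
        vals = ndimage.gaussian_filter(vals, sigma=(1.2, 3.0, 3.0))
        vol = v.ImageVolume(vals, SPACING, "cells")
        pts = v.detect_spots(vol, spot_diameter_um=6.0, threshold=0.2)
        assert len(pts) == 5
        truth = np.asarray(centers) * np.asarray(SPACING)
        for t in truth:
            d = np.abs(pts - t)  # within 1 voxel per axis
            assert np.any(np.all(d <= np.asarray(SPACING) + 1e-9, axis=1))

    def test_close_blobs_may_merge_but_detect(self):
        vals = np.zeros((8, 40, 40))
        vals[4, 20, 18] = vals[4, 20, 22] = 1000.0  # 2 um apart
        vals = ndimage.gaussian_filter(vals, sigma=(1.0, 2.5, 2.5))
        vol = v.ImageVolume(vals, SPACING, "cells")
        pts = v.detect_spots(vol, spot_diameter_um=8.0, threshold=0.2)
        assert len(pts) >= 1


class TestSpotVesselDistances:
    def test_point_on_vessel_zero(self):
        vm = np.zeros((3, 8, 8), bool); vm[1, 4, 4] = True
        dd = v.spot_vessel_distances(np.array([[2.0, 2.0, 2.0]]),
                                     v.BinaryMask(vm, SPACING))
        assert dd.distances_um.tolist() == [0.0]

    def test_known_distance(self):
        vm = np.zeros((3, 8, 21), bool); vm[1, 4, 3] = True
        pt = np.array([[2.0, 2.0, 10.0]])  # 7 um along x from vessel voxel
        dd = v.spot_vessel_distances(pt, v.BinaryMask(vm, (2.0, 0.5, 1.0)))
        assert dd.distances_um.tolist() == [7.0]

    def test_matches_brute_force(self):
        rng = np.random.default_rng(2)
        mask = rng.random((10, 12, 12)) < 0.04
        mask[0, 0, 0] = True
        bm = v.BinaryMask(mask, SPACING)
        sp = np.asarray(SPACING)
        extent = (np.asarray(mask.shape) - 1) * sp
        pts = rng.uniform(0, 1, size=(100, 3)) * extent
        dd = v.spot_vessel_distances(pts, bm)
        targets = np.argwhere(mask) * sp
        half_diag = 0.5 * np.linalg.norm(sp)
        for p, d in zip(pts, dd.distances_um):
            bf = np.sqrt(((targets - p) ** 2).sum(1)).min()
            assert abs(d - bf) <= half_diag + 1e-9

    def test_out_of_bounds_point_rejected(self):
        vm = v.BinaryMask(np.ones((3, 8, 8), bool), SPACING)
        with pytest.raises(v.InvalidParameterError):
            v.spot_vessel_distances(np.array([[100.0, 0.0, 0.0]]), vm)


class TestMVD:
    def test_straight_line_two_sprouts(self):
        img = np.zeros((50, 50), bool)
        img[25, 5:45] = True
        out = v.mvd_sprouts(img, area_mm2=1.0, control_density=2.0)
        assert out["n_sprouts"] == 2
        assert out["fold_over_control"] == 1.0

    def test_closed_loop_no_sprouts(self):
        yy, xx = np.mgrid[0:60, 0:60]
        ring = np.abs(np.hypot(yy - 30, xx - 30) - 18) < 1.2
        out = v.mvd_sprouts(ring, area_mm2=0.5)
        assert out["n_sprouts"] == 0

    def test_planted_sprout_tips_counted(self):
        """Ring with 7 outward spokes -> exactly 7 skeleton endpoints."""
        k = 7
        size = 120
        yy, xx = np.mgrid[0:size, 0:size]
        c = size // 2
        img = np.abs(np.hypot(yy - c, xx - c) - 25) < 1.5
        for i in range(k):
            ang = 2 * np.pi * i / k + 0.1
            for r in np.linspace(26, 45, 60):
                img[int(round(c + r * np.sin(ang))),
                    int(round(c + r * np.cos(ang)))] = True
        out = v.mvd_sprouts(img, area_mm2=1.0, pixel_size_um=(1.0, 1.0))
        assert out["n_sprouts"] == k

    def test_zero_control_density_rejected(self):
        img = np.zeros((20, 20), bool)
        img[10, 2:18] = True
        with pytest.raises(v.UndefinedRatioError):
            v.mvd_sprouts(img, area_mm2=1.0, control_density=0.0)
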