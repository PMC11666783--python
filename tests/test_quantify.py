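import numpy as np
import pandas as pd
import pytest

from conftest import gaussian_blob_image
from meiotrack.errors import AmbiguousAxisError
from meiotrack.quantify import (
    Cylinder,
    ROIConfig,
    Sphere,
    assign_tale_labels,
    classify_telomere_masking,
    classify_telomere_proximity,
    count_mad1_positive,
    gv_nucleus_distances,
    kinetochore_alignment,
    pair_sisters,
    per_cell_normalized,
    roi_intensity,
    separation_times,
    sister_ikd_normalized,
)
from meiotrack.simulate import SceneConfig, place_telomeres, simulate_congression

VOXEL = (0.32, 0.1, 0.1)


class TestTaleLabels:
    @pytest.mark.parametrize("dist,labelled", [(1.9, True), (2.0, True), (2.1, False)])
    def test_distance_boundary(self, dist, labelled):
        kt = [(5.0, 5.0, 5.0)]
        tale = [(5.0, 5.0, 5.0 + dist)]
        assert assign_tale_labels(kt, tale)[0] == labelled

    def test_empty_kinetochores_error(self):
        with pytest.raises(ValueError):
            assign_tale_labels(np.empty((0, 3)), [(0, 0, 0)])

    def test_no_tale_all_unlabelled(self):
        out = assign_tale_labels([(0, 0, 0), (1, 1, 1)], np.empty((0, 3)))
        assert not out.any()

    def test_shift_applied(self):
        from meiotrack.geometry import RigidShift
        kt = [(5.0, 5.0, 5.0)]
        tale = [(5.0, 5.0, 10.0)]  # 5 um away unshifted
        shift = RigidShift(translation_um=(0, 0, -4.0))
        assert assign_tale_labels(kt, tale, shift=shift)[0]


class TestAlignment:
    def _prolate(self, axis, n=400, seed=0):
        rng = np.random.default_rng(seed)
        pts = rng.normal(0, 1, (n, 3)) * np.array([0.1, 0.1, 1.0])
        axis = np.asarray(axis, dtype=float)
        axis /= np.linalg.norm(axis)
        # rotate z onto the requested axis
        z = np.array([0.0, 0, 1.0])
        v = np.cross(z, axis)
        if np.linalg.norm(v) < 1e-12:
            rot = np.eye(3)
        else:
            c = np.dot(z, axis)
            vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
            rot = np.eye(3) + vx + vx @ vx / (1 + c)
        return pts @ rot.T

    def test_parallel_blob(self):
        pts = self._prolate((0, 0, 1))
        assert kinetochore_alignment(pts, (0, 0, 1)) == pytest.approx(1.0, abs=0.05)

    def test_perpendicular_blob(self):
        pts = self._prolate((0, 1, 0))
        assert kinetochore_alignment(pts, (0, 0, 1)) == pytest.approx(0.0, abs=0.05)

    def test_45_degree_blob_matches_moment_oracle(self):
        pts = self._prolate((0, 1, 1))
        val = kinetochore_alignment(pts, (0, 0, 1))
        assert val == pytest.approx(np.sqrt(0.5), abs=0.05)
        # oracle: leading eigenvector of the covariance computed in the test
        cov = np.cov((pts - pts.mean(0)).T)
        w, v = np.linalg.eigh(cov)
        assert val == pytest.approx(abs(v[:, 2] @ np.array([0, 0, 1.0])), abs=1e-6)

    def test_degenerate_region_flagged(self):
        # a symmetric cube has three equal second moments: no main axis
        pts = np.array([(z, y, x) for z in range(3) for y in range(3) for x in range(3)], float)
        with pytest.raises(AmbiguousAxisError):
            kinetochore_alignment(pts, (0, 0, 1))

    def test_too_few_voxels(self):
        with pytest.raises(ValueError):
            kinetochore_alignment(np.zeros((3, 3)), (0, 0, 1))


class TestIKD:
    def test_equal_distances_normalise_to_one(self):
        pairs = [((0, 0, 0), (0, 0, 1.0)), ((2, 0, 0), (2, 0, 1.0))]
        out = sister_ikd_normalized(pairs)
        assert np.allclose(out.ikd_norm, 1.0)

    def test_mean_one_normalisation(self):
        pairs = [((0, 0, 0), (0, 0, 0.8)), ((2, 0, 0), (2, 0, 1.2))]
        out = sister_ikd_normalized(pairs)
        assert np.allclose(sorted(out.ikd_norm), [0.8, 1.2])

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            sister_ikd_normalized(np.empty((0, 2, 3)))

    def test_pair_sisters_mutual_nearest(self):
        pts = np.array([[0, 0, 0], [0, 0, 1.0], [0, 5, 0], [0, 5, 1.1], [0, 10, 0]])
        pairs = pair_sisters(pts, max_dist_um=2.0)
        assert {frozenset(p) for p in pairs.tolist()} == {frozenset((0, 1)), frozenset((2, 3))}


class TestROIIntensity:
    def test_constant_image_background_subtracted(self):
        img = np.full((20, 40, 40), 7.0)
        v = roi_intensity(img, VOXEL, Sphere((3.0, 2.0, 2.0), 0.8), background=2.0)
        assert v == pytest.approx(5.0)

    def test_sphere_inside_constant_blob(self):
        img = np.full((20, 40, 40), 100.0)
        v = roi_intensity(img, VOXEL, Sphere((3.0, 2.0, 2.0), 0.5), background=10.0)
        assert v == pytest.approx(90.0)

    def test_cylinder_linear_in_intensity_and_motion_invariant(self):
        img = np.full((20, 60, 60), 4.0)
        roi1 = Cylinder((3.0, 2.0, 1.0), (3.0, 2.0, 2.0), 0.5)
        roi2 = Cylinder((3.0, 3.5, 2.5), (3.0, 3.5, 3.5), 0.5)
        v1 = roi_intensity(img, VOXEL, roi1)
        v2 = roi_intensity(img, VOXEL, roi2)
        assert v1 == pytest.approx(v2)
        assert roi_intensity(3 * img, VOXEL, roi1) == pytest.approx(3 * v1)

    def test_empty_roi_errors(self):
        img = np.zeros((10, 10, 10))
        with pytest.raises(ValueError):
            roi_intensity(img, VOXEL, Sphere((0.5, 0.5, 0.5), 0.01))

    def test_per_cell_normalisation(self):
        out = per_cell_normalized([2.0, 4.0])
        assert np.allclose(out, [2 / 3, 4 / 3])

    def test_cohesin_class_ratio_recovered(self):
        # generator round-trip: acro/meta cohesin ratio 0.8 from rendered ROIs
        from meiotrack.simulate import render_scene, simulate_mii_egg

        ratios = []
        for s in range(6):
            cfg = SceneConfig(stage="metaphase_II", seed=200 + s)
            gt = simulate_mii_egg(cfg)
            scene = render_scene(gt)
            ch = scene.channels["cohesin"]
            bg = float(np.median(ch))
            ids, pairs = gt.kt_pairs(0)
            vals = []
            for pq in pairs:
                vals.append(roi_intensity(ch, cfg.voxel_size_um,
                                          Cylinder(pq[0], pq[1], 0.5), background=bg))
            norm = per_cell_normalized(vals)
            cls = gt.chromosomes.centromere_class.to_numpy()
            ratios.append(norm[cls == "acro"].mean() / norm[cls == "meta"].mean())
        assert np.mean(ratios) == pytest.approx(0.8, abs=0.05)


class TestMad1:
    def test_no_spots_zero(self):
        img = np.zeros((24, 60, 60))
        count, frac = count_mad1_positive(img, VOXEL, [(3.0, 3.0, 3.0)])
        assert (count, frac) == (0, 0.0)

    def test_seeded_positives_recovered(self):
        rng = np.random.default_rng(1)
        kts = rng.uniform(4, 10, (10, 3))
        positive = kts[:4]
        img = gaussian_blob_image((48, 144, 144), VOXEL, positive, (1.0, 0.5, 0.5))
        img += rng.normal(0, 0.002, img.shape)
        count, frac = count_mad1_positive(img, VOXEL, kts)
        assert count == 4 and frac == pytest.approx(0.4)

    def test_generator_fraction_recovered(self):
        # ground-truth Mad1 positivity across scenes converges to 29%
        pos = tot = 0
        for s in range(140):
            cfg = SceneConfig(stage="metaphase_I", seed=s, n_frames=1)
            gt = simulate_congression(cfg)
            pos += gt.chromosomes.mad1_kt1.sum() + gt.chromosomes.mad1_kt2.sum()
            tot += 2 * len(gt.chromosomes)
        p = pos / tot
        se = np.sqrt(0.29 * 0.71 / tot)
        assert abs(p - 0.29) < max(2 * se, 0.02)


class TestTelomereClassification:
    def test_proximity(self):
        pair = [(5, 5, 5), (5, 5, 6.0)]
        assert classify_telomere_proximity(pair, [(5, 5, 5.3)]) == "proximal"
        assert classify_telomere_proximity(pair, [(5, 5, 9.0)]) == "non_proximal"

    def test_masking_rule(self):
        kt = (5.0, 5.0, 5.0)
        axis = (0, 0, 1.0)
        # pair faces the negative pole: poleward displacement means smaller x
        assert classify_telomere_masking(kt, (5, 5, 4.7), axis, -1) == "masked"
        assert classify_telomere_masking(kt, (5, 5, 5.3), axis, -1) == "exposed"
        assert classify_telomere_masking(kt, kt, axis, -1) == "exposed"  # tie

    def test_acro_vs_meta_proximity_from_generator(self):
        cfg = SceneConfig(stage="metaphase_I", seed=0, n_frames=1)
        gt = place_telomeres(cfg, simulate_congression(cfg))
        pts = gt.points[gt.points.frame == 0].set_index(["chromosome_id", "kind"])
        for _, row in gt.chromosomes.iterrows():
            cid = row.chromosome_id
            pair = pts.loc[[(cid, "kt1"), (cid, "kt2")]][["z_um", "y_um", "x_um"]].to_numpy(float)
            telos = pts.loc[[(cid, "telo1"), (cid, "telo2")]][["z_um", "y_um", "x_um"]].to_numpy(float)
            status = classify_telomere_proximity(pair, telos)
            assert status == ("proximal" if row.centromere_class == "acro" else "non_proximal")

    def test_masking_classifier_recovers_generator_state(self):
        hits = tot = 0
        for s in range(60):
            cfg = SceneConfig(stage="metaphase_I", seed=s, n_frames=1)
            gt = place_telomeres(cfg, simulate_congression(cfg))
            pts = gt.points[gt.points.frame == 0].set_index(["chromosome_id", "kind"])
            acro = gt.chromosomes[gt.chromosomes.centromere_class == "acro"]
            for _, row in acro.iterrows():
                cid = row.chromosome_id
                k1 = pts.loc[(cid, "kt1")][["z_um", "y_um", "x_um"]].to_numpy(float)
                k2 = pts.loc[(cid, "kt2")][["z_um", "y_um", "x_um"]].to_numpy(float)
                t1 = pts.loc[(cid, "telo1")][["z_um", "y_um", "x_um"]].to_numpy(float)
                axis = (k2 - k1) / np.linalg.norm(k2 - k1)
                out = classify_telomere_masking(k1, t1, axis, -1)
                hits += out == row.masking
                tot += 1
        assert hits / tot > 0.99


class TestSeparationTimes:
    def test_relative_to_first(self):
        rel, first = separation_times([34, 30, 41], classes=["meta", "acro", "meta"])
        assert np.array_equal(rel, [4, 0, 11])
        assert first == "acro"

    def test_single_event(self):
        rel, _ = separation_times([12.0])
        assert np.array_equal(rel, [0.0])

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            separation_times([])


class TestGVNucleus:
    def _nucleus(self):
        shape = (32, 64, 64)
        vs = (0.2, 0.2, 0.2)
        coords = [(np.arange(n) + 0.5) * s for n, s in zip(shape, vs)]
        zz, yy, xx = np.meshgrid(*coords, indexing="ij", sparse=True)
        center = np.array([3.2, 6.4, 6.4])
        r = np.sqrt((zz - center[0]) ** 2 + (yy - center[1]) ** 2 + (xx - center[2]) ** 2)
        img = np.where(r <= 2.5, 0.1, 1.0)  # dim nucleus in bright cytoplasm
        return img, vs, center

    def test_spot_at_centre(self):
        img, vs, c = self._nucleus()
        d, _ = gv_nucleus_distances([c], img, vs)
        assert d[0] < 0.2

    def test_spot_on_surface(self):
        img, vs, c = self._nucleus()
        d, _ = gv_nucleus_distances([c + (0, 0, 2.5)], img, vs)
        assert d[0] == pytest.approx(2.5, abs=0.2)

    def test_acro_more_central_than_meta(self):
        img, vs, c = self._nucleus()
        rng = np.random.default_rng(0)
        acro = c + rng.normal(0, 0.3, (20, 3))
        meta = c + rng.normal(0, 0.3, (20, 3)) + (0, 0, 1.5)
        da, _ = gv_nucleus_distances(acro, img, vs)
        dm, _ = gv_nucleus_distances(meta, img, vs)
        assert da.mean() < dm.mean()
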