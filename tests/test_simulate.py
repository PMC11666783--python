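import numpy as np
import pandas as pd
import pytest

from meiotrack.errors import MeiotrackError
from meiotrack.simulate import (
    SceneConfig,
    make_karyotype,
    place_telomeres,
    render_scene,
    simulate_anaphase,
    simulate_congression,
    simulate_mii_egg,
    simulate_trimaway,
)


class TestKaryotype:
    def test_porcine_composition(self):
        k = make_karyotype("porcine", "acro")
        df = k.as_frame()
        assert len(df) == 19
        assert (df.centromere_class == "acro").sum() == 6
        assert (df.centromere_class == "meta").sum() == 13
        assert df.tale_labelled.sum() == 6
        assert set(df.loc[df.tale_labelled, "centromere_class"]) == {"acro"}

    def test_meta_mode_labels_6_of_13(self):
        df = make_karyotype("porcine", "meta").as_frame()
        labelled = df[df.tale_labelled]
        assert len(labelled) == 6
        assert set(labelled.centromere_class) == {"meta"}

    def test_none_mode(self):
        df = make_karyotype("porcine", "none").as_frame()
        assert len(df) == 19 and df.tale_labelled.sum() == 0

    def test_human(self):
        df = make_karyotype("human", "none").as_frame()
        assert len(df) == 23
        assert (df.centromere_class == "acro").sum() == 5

    def test_unknown_inputs(self):
        with pytest.raises(ValueError):
            make_karyotype("bovine", "acro")
        with pytest.raises(ValueError):
            make_karyotype("porcine", "sideways")

    def test_deterministic(self):
        assert make_karyotype("porcine", "both") == make_karyotype("porcine", "both")


class TestCongression:
    def test_zero_offset_zero_noise_converges_to_plate(self):
        cfg = SceneConfig(stage="metaphase_I", seed=0, n_frames=5,
                          plate_offset_um=0.0, ou_sigma_um=1e-12)
        gt = simulate_congression(cfg)
        plate_x = gt.frames.plate_x.iloc[0]
        last = gt.points[(gt.points.frame == 4) & gt.points.kind.isin(["kt1", "kt2"])]
        mids = last.groupby("chromosome_id")["x_um"].mean()
        assert np.allclose(mids, plate_x, atol=1e-6)

    def test_acro_meta_plate_distance_gap(self):
        # Monte-Carlo mean of the configured stationary process
        gaps = []
        for s in range(50):
            cfg = SceneConfig(stage="metaphase_I", seed=s, n_frames=2)
            gt = simulate_congression(cfg)
            plate_x = gt.frames.plate_x.iloc[0]
            last = gt.points[(gt.points.frame == 1) & gt.points.kind.isin(["kt1", "kt2"])]
            mids = last.groupby("chromosome_id")["x_um"].mean()
            d = (mids - plate_x).abs()
            cls = gt.chromosomes.set_index("chromosome_id").centromere_class
            gaps.append(d[cls == "acro"].mean() - d[cls == "meta"].mean())
        assert np.mean(gaps) == pytest.approx(1.0, abs=0.2)

    def test_seeded_determinism(self):
        cfg = SceneConfig(stage="metaphase_I", seed=9, n_frames=3)
        a = simulate_congression(cfg)
        b = simulate_congression(SceneConfig(stage="metaphase_I", seed=9, n_frames=3))
        pd.testing.assert_frame_equal(a.points, b.points)

    def test_invalid_relaxation_time(self):
        with pytest.raises(ValueError):
            simulate_congression(SceneConfig(stage="metaphase_I", ou_tau_min=-1))


class TestAnaphase:
    def test_zero_probabilities_all_correct(self):
        cfg = SceneConfig(stage="anaphase_I", seed=0,
                          misseg_prob={"acro": 0, "meta": 0},
                          lagging_mild_prob={"acro": 0, "meta": 0},
                          lagging_severe_prob={"acro": 0, "meta": 0})
        gt = simulate_anaphase(cfg)
        assert set(gt.chromosomes.fate) == {"correct"}
        assert set(gt.chromosomes.lagging) == {"none"}

    def test_class_missegregation_rates(self):
        # binomial sampling check at ~5000 chromosomes per class
        tables = [simulate_anaphase(SceneConfig(stage="anaphase_I", seed=s)).chromosomes
                  for s in range(840)]
        df = pd.concat(tables, ignore_index=True)
        for cls, p in (("acro", 0.08), ("meta", 0.01)):
            sub = df[df.centromere_class == cls]
            rate = (sub.fate != "correct").mean()
            se = np.sqrt(p * (1 - p) / len(sub))
            assert abs(rate - p) < max(2 * se, 0.01 if cls == "acro" else 0.004)

    def test_severe_laggard_in_central_zone_at_20min(self):
        for s in range(200):
            cfg = SceneConfig(stage="anaphase_I", seed=s)
            gt = simulate_anaphase(cfg)
            sev = gt.chromosomes[gt.chromosomes.lagging == "severe"]
            if len(sev) == 0:
                continue
            f20 = gt.onset_frame + 5  # 20 min at 4-min frames
            masses = gt.frames.set_index("frame").loc[f20]
            mid = (masses.mass_neg_x + masses.mass_pos_x) / 2
            width = masses.mass_pos_x - masses.mass_neg_x
            cid = sev.chromosome_id.iloc[0]
            pos = gt.points[(gt.points.frame == f20) & (gt.points.chromosome_id == cid)
                            & (gt.points.kind == "kt2")].x_um.iloc[0]
            assert abs(pos - mid) < 0.25 * width
            return
        pytest.fail("no severe laggard generated in 200 scenes")

    def test_invalid_probability(self):
        with pytest.raises(ValueError):
            simulate_anaphase(SceneConfig(stage="anaphase_I", misseg_prob={"acro": 1.2, "meta": 0}))


class TestMIIEgg:
    def test_euploid_has_38_kinetochores(self):
        gt = simulate_mii_egg(SceneConfig(stage="metaphase_II", seed=0))
        kts = gt.points[gt.points.kind.isin(["kt1", "kt2"])]
        assert len(kts) == 38

    def test_zero_variance_ikd_exact(self):
        cfg = SceneConfig(stage="metaphase_II", seed=0)
        cfg.ikd_um = {k: (m, 0.0) for k, (m, _) in cfg.ikd_um.items()}
        gt = simulate_mii_egg(cfg)
        ids, pairs = gt.kt_pairs(0)
        d = np.linalg.norm(pairs[:, 0] - pairs[:, 1], axis=1)
        lab = gt.chromosomes.label.to_numpy()
        assert np.allclose(d[lab == "acro_labelled"], 1.09, atol=1e-9)

    def test_acro_ikd_law_of_large_numbers(self):
        vals = []
        for s in range(1700):  # > 10,000 acro pairs
            gt = simulate_mii_egg(SceneConfig(stage="metaphase_II", seed=s))
            vals.append(gt.chromosomes.loc[gt.chromosomes.label == "acro_labelled", "ikd_true_um"])
        v = pd.concat(vals)
        assert len(v) >= 10000
        assert v.mean() == pytest.approx(1.09, abs=0.01)

    def test_aneuploid_fates(self):
        fates = [(cid, 1) for cid in range(1, 20)]
        fates[0] = (1, 2)  # both homologues into the egg
        gt = simulate_mii_egg(SceneConfig(stage="metaphase_II", seed=0), fates=fates)
        assert len(gt.points[gt.points.kind.isin(["kt1", "kt2"])]) == 40


class TestTrimAway:
    def test_equal_cohesin_first_class_proportional(self):
        firsts = []
        for s in range(400):
            cfg = SceneConfig(stage="trim_away", seed=s, cohesin_ratio_acro=1.0,
                              cohesin_jitter_sd=0.0)
            gt = simulate_trimaway(cfg)
            i = gt.chromosomes.separation_time_min.idxmin()
            firsts.append(gt.chromosomes.loc[i, "centromere_class"] == "acro")
        # exchangeable chromosomes: acro first with probability 6/19
        p = 6 / 19
        se = np.sqrt(p * (1 - p) / 400)
        assert abs(np.mean(firsts) - p) < 3 * se

    def test_low_cohesin_class_separates_first(self):
        firsts = []
        for s in range(400):
            cfg = SceneConfig(stage="trim_away", seed=s, cohesin_ratio_acro=0.5)
            gt = simulate_trimaway(cfg)
            i = gt.chromosomes.separation_time_min.idxmin()
            firsts.append(gt.chromosomes.loc[i, "centromere_class"] == "acro")
        assert np.mean(firsts) > 0.8

    def test_invalid_scale(self):
        with pytest.raises(ValueError):
            simulate_trimaway(SceneConfig(stage="trim_away", separation_scale_min=0))


class TestTelomeres:
    def _scene(self, seed=0, **kw):
        cfg = SceneConfig(stage="metaphase_I", seed=seed, n_frames=1, **kw)
        return cfg, place_telomeres(cfg, simulate_congression(cfg))

    def test_all_masked_when_fraction_one(self):
        cfg, gt = self._scene(masked_fraction={"porcine": 1.0, "human": 1.0})
        acro = gt.chromosomes[gt.chromosomes.centromere_class == "acro"]
        assert set(acro.masking) == {"masked"}
        # masked telomeres sit poleward (outward along the pair axis) of the kinetochore
        pts = gt.points[gt.points.frame == 0].set_index(["chromosome_id", "kind"])
        for cid in acro.chromosome_id:
            k1 = pts.loc[(cid, "kt1"), ["z_um", "y_um", "x_um"]].to_numpy(float)
            k2 = pts.loc[(cid, "kt2"), ["z_um", "y_um", "x_um"]].to_numpy(float)
            t1 = pts.loc[(cid, "telo1"), ["z_um", "y_um", "x_um"]].to_numpy(float)
            axis = (k2 - k1) / np.linalg.norm(k2 - k1)
            assert np.dot(t1 - k1, -axis) > 0  # beyond kt1, away from the centre

    def test_masked_fraction_binomial(self):
        masked = total = 0
        for s in range(1700):
            _, gt = self._scene(seed=s)
            acro = gt.chromosomes[gt.chromosomes.centromere_class == "acro"]
            masked += (acro.masking == "masked").sum()
            total += len(acro)
        assert total >= 10000
        assert masked / total == pytest.approx(0.20, abs=0.01)

    def test_metacentric_telomeres_not_proximal(self):
        _, gt = self._scene()
        pts = gt.points[gt.points.frame == 0]
        meta_ids = gt.chromosomes.loc[gt.chromosomes.centromere_class == "meta", "chromosome_id"]
        for cid in meta_ids:
            sub = pts[pts.chromosome_id == cid].set_index("kind")
            kt = sub.loc[["kt1", "kt2"], ["z_um", "y_um", "x_um"]].to_numpy(float)
            tl = sub.loc[["telo1", "telo2"], ["z_um", "y_um", "x_um"]].to_numpy(float)
            d = np.linalg.norm(kt[:, None] - tl[None, :], axis=2)
            assert d.min() > 1.0


class TestRendering:
    def test_single_kinetochore_peak_at_truth(self):
        cfg = SceneConfig(stage="metaphase_II", seed=0, noise=False)
        gt = simulate_mii_egg(cfg)
        scene = render_scene(gt)
        img = scene.channels["kinetochore"]
        pk = np.unravel_index(np.argmax(img), img.shape)
        pos = (np.array(pk) + 0.5) * np.array(cfg.voxel_size_um)
        kts = gt.points[gt.points.kind.isin(["kt1", "kt2"])][["z_um", "y_um", "x_um"]].to_numpy()
        assert np.linalg.norm(kts - pos, axis=1).min() < np.max(cfg.voxel_size_um)

    def test_bit_exact_reproducibility(self):
        cfg = SceneConfig(stage="metaphase_II", seed=42)
        a = render_scene(simulate_mii_egg(cfg))
        b = render_scene(simulate_mii_egg(SceneConfig(stage="metaphase_II", seed=42)))
        for name in a.channels:
            assert np.array_equal(a.channels[name], b.channels[name])

    def test_chromatin_volume_in_range(self):
        from skimage.filters import threshold_otsu

        cfg = SceneConfig(stage="metaphase_I", seed=1, n_frames=1, noise=False)
        scene = render_scene(simulate_congression(cfg))
        dna = scene.channels["dna"]
        vol = (dna > threshold_otsu(dna)).sum() * np.prod(cfg.voxel_size_um)
        assert 150 <= vol <= 800

    def test_truth_and_render_consistent(self):
        # noise off: rendered blob centroids within 0.5 voxel of the sidecar
        from meiotrack.tracking import detect_spots

        cfg = SceneConfig(stage="metaphase_II", seed=3, noise=False)
        gt = simulate_mii_egg(cfg)
        scene = render_scene(gt)
        det = detect_spots(scene.channels["kinetochore"], cfg.voxel_size_um, 0.5, 1.6)
        kts = gt.points[gt.points.kind.isin(["kt1", "kt2"])][["z_um", "y_um", "x_um"]].to_numpy()
        assert len(det) == 38
        for p in det[["z_um", "y_um", "x_um"]].to_numpy():
            err = np.abs(kts - p) / np.array(cfg.voxel_size_um)
            assert err[np.linalg.norm(kts - p, axis=1).argmin()].max() < 0.5

    def test_out_of_bounds_objects_error(self):
        cfg = SceneConfig(stage="metaphase_II", seed=0, shape=(10, 20, 20))
        gt = simulate_mii_egg(SceneConfig(stage="metaphase_II", seed=0))
        with pytest.raises(MeiotrackError, match="chromosomes"):
            render_scene(gt, cfg)
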