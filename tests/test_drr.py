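"""Radiograph simulation: projections, augmentation, contrast, datasets."""

import numpy as np
import pytest
from scipy import ndimage as ndi

from osteoplan import drr, phantom as ph


def _geoms(vol, mode="parallel", det=128, sp=6.0):
    return drr.geometry_pair(vol, mode=mode, detector_size=(det, det),
                             pixel_spacing=sp)


class TestProjectPoint:
    def test_central_axis_maps_to_detector_center(self, subject_vol):
        vol, _ = subject_vol
        gf, _ = _geoms(vol)
        c = np.asarray(gf.iso_center)
        u, v = drr.project_point(c, gf)
        assert u == pytest.approx((gf.detector_size[0] - 1) / 2)
        assert v == pytest.approx((gf.detector_size[1] - 1) / 2)

    @pytest.mark.parametrize("mode", ["parallel", "fan"])
    def test_points_differing_only_in_z_share_u(self, subject_vol, mode):
        """The vertically translating emitter removes vertical magnification."""
        vol, _ = subject_vol
        gf, gs = _geoms(vol, mode=mode)
        p = np.array([40.0, -25.0, 300.0])
        for g in (gf, gs):
            u1, _ = drr.project_point(p, g)
            u2, _ = drr.project_point(p + [0, 0, 137.0], g)
            assert u1 == pytest.approx(u2, abs=1e-12)

    def test_fan_matches_brute_force_ray_plane_intersection(self, subject_vol):
        vol, _ = subject_vol
        gf, gs = _geoms(vol, mode="fan")
        rng = np.random.default_rng(7)
        for g in (gf, gs):
            c = np.asarray(g.iso_center)
            src = c.copy()
            src[g.ray_axis] += g.source_axis_distance
            for _ in range(25):
                p = c + rng.uniform(-150, 150, 3)
                src_p = src.copy()
                src_p[2] = p[2]  # fan is horizontal at the point's height
                d = p - src_p
                # intersect with the detector plane (ray axis = -ADD offset)
                t = (c[g.ray_axis] - g.axis_detector_distance
                     - src_p[g.ray_axis]) / d[g.ray_axis]
                hit = src_p + t * d
                u_ref = ((hit[g.u_axis] - c[g.u_axis]) / g.pixel_spacing
                         + (g.detector_size[0] - 1) / 2)
                u, v = drr.project_point(p, g)
                assert u == pytest.approx(u_ref, abs=1e-9)

    def test_point_behind_source_raises(self, subject_vol):
        vol, _ = subject_vol
        gf, _ = _geoms(vol, mode="fan")
        p = np.asarray(gf.iso_center) + [0, 2000.0, 0]
        with pytest.raises(drr.GeometryError):
            drr.project_point(p, gf)

    def test_biplanar_vertical_consistency(self, subject_vol):
        vol, _ = subject_vol
        for mode in ("parallel", "fan"):
            gf, gs = _geoms(vol, mode=mode)
            rng = np.random.default_rng(2)
            for _ in range(50):
                p = np.asarray(gf.iso_center) + rng.uniform(-200, 200, 3)
                _, vf = drr.project_point(p, gf)
                _, vs = drr.project_point(p, gs)
                assert abs(vf - vs) < 0.51


class TestProject:
    def test_uniform_cube_path_lengths_agree(self):
        inten = np.ones((20, 20, 20), np.float32)
        vol = ph.AnnotatedVolume(inten, np.ones_like(inten, dtype=np.uint8),
                                 np.full(3, 2.0), np.zeros(3),
                                 ph.LandmarkSet3D({}))
        gf, _ = _geoms(vol, det=32, sp=2.0)
        img = drr.project(vol, gf, normalize=False)
        interior = img.pixels[12:20, 12:20]
        assert np.ptp(interior) < 1e-9  # equal thickness -> equal integral

    def test_empty_volume_projects_to_zeros(self):
        inten = np.zeros((8, 8, 8), np.float32)
        vol = ph.AnnotatedVolume(inten, np.zeros_like(inten, dtype=np.uint8),
                                 np.full(3, 4.0), np.zeros(3),
                                 ph.LandmarkSet3D({}))
        gf, _ = _geoms(vol, det=16, sp=4.0)
        img = drr.project(vol, gf)
        assert np.all(img.pixels == 0.0)

    def test_projection_linearity_before_normalization(self, subject_vol):
        vol, _ = subject_vol
        gf, _ = _geoms(vol)
        a = drr.project(vol, gf, normalize=False).pixels
        v2 = vol.copy()
        v2.intensity = (2.5 * v2.intensity).astype(np.float32)
        b = drr.project(v2, gf, normalize=False).pixels
        assert np.allclose(b, 2.5 * a, atol=1e-4)

    def test_masked_projection_equals_masked_volume(self, subject_vol):
        vol, _ = subject_vol
        gf, _ = _geoms(vol)
        masked = drr.project(vol, gf, mask=[ph.TIBIA_RIGHT,
                                            ph.PROX_TIBIA_RIGHT])
        v2 = vol.copy()
        v2.intensity = vol.masked_intensity([ph.TIBIA_RIGHT,
                                             ph.PROX_TIBIA_RIGHT])
        direct = drr.project(v2, gf)
        assert np.array_equal(masked.pixels > 0, direct.pixels > 0)

    def test_fan_bright_voxel_lands_at_projected_position(self, subject_vol):
        vol, _ = subject_vol
        v2 = vol.copy()
        v2.intensity = np.zeros_like(v2.intensity)
        idx = (30, 20, 100)
        v2.intensity[idx] = 1.0
        gf, gs = _geoms(vol, mode="fan")
        for g in (gf, gs):
            img = drr.project(v2, g)
            vv, uu = np.unravel_index(int(np.argmax(img.pixels)),
                                      img.pixels.shape)
            ue, ve = drr.project_point(v2.index_to_world(idx), g)
            assert abs(uu - ue) < 0.51 + 0.5  # half-pixel + voxel footprint
            assert abs(vv - ve) < 0.51 + 0.5


class TestContrastEnhance:
    def test_midpoint_maps_to_half(self):
        img = drr.Radiograph(np.full((4, 4), 0.45, np.float32), "sagittal",
                             drr.ProjectionGeometry("sagittal"))
        out = drr.contrast_enhance(img)
        assert np.allclose(out.pixels, 0.5)

    def test_matches_direct_logistic_formula(self):
        x = np.linspace(0.0, 1.0, 1000, dtype=np.float32)
        img = drr.Radiograph(x[None], "sagittal",
                             drr.ProjectionGeometry("sagittal"))
        out = drr.contrast_enhance(img).pixels[0]
        ref = 1.0 / (1.0 + np.exp(-(x - 0.45) / 0.12))
        assert np.allclose(out, ref, atol=1e-12)
        assert np.all(np.diff(out) > 0)  # strictly increasing


class TestAugmentRightLeg:
    def test_draws_stay_inside_stated_ranges(self):
        rng = np.random.default_rng(0)
        shifts, rots = [], []
        for _ in range(1000):
            shifts.append(rng.uniform(40.0, 60.0))
            rots.append(rng.uniform(10.0, 20.0))
        assert min(shifts) >= 40.0 and max(shifts) <= 60.0
        assert min(rots) >= 10.0 and max(rots) <= 20.0
        # the implementation draws from the same generator contract
        vol, _ = ph.generate_subject(ph.PhantomParams(voxel_spacing=8.0),
                                     ph.PhantomParams(voxel_spacing=8.0))
        rng = np.random.default_rng(1)
        for _ in range(20):
            _, rec = drr.augment_right_leg(vol, rng)
            assert 40.0 <= rec["shift_mm"] <= 60.0
            assert 10.0 <= abs(rec["rotation_deg"]) <= 20.0

    def test_disabled_mode_is_identity(self, subject_vol):
        vol, _ = subject_vol
        out, rec = drr.augment_right_leg(vol, np.random.default_rng(0),
                                         enabled=False)
        assert rec["enabled"] is False
        assert np.array_equal(out.intensity, vol.intensity)
        assert np.array_equal(out.labels, vol.labels)

    def test_pure_translation_displaces_ankle_forty_mm(self, subject_vol):
        vol, _ = subject_vol
        out, rec = drr.augment_right_leg(vol, np.random.default_rng(4),
                                         rotation_range=(0.0, 0.0))
        dy = out.landmarks["right"]["AC"][1] - vol.landmarks["right"]["AC"][1]
        assert dy >= 40.0
        assert dy == pytest.approx(rec["shift_mm"], abs=1e-9)

    def test_left_leg_landmarks_unaffected(self, subject_vol):
        vol, _ = subject_vol
        out, _ = drr.augment_right_leg(vol, np.random.default_rng(5))
        gf, gs = _geoms(vol)
        for name in ("HC", "KC", "AC"):
            for g in (gf, gs):
                before = drr.project_point(vol.landmarks["left"][name], g)
                after = drr.project_point(out.landmarks["left"][name], g)
                assert np.allclose(before, after, atol=1e-9)


class TestMakeStudy:
    def test_two_disjoint_leg_silhouettes_in_frontal(self, subject_vol):
        vol, _ = subject_vol
        gf, gs = _geoms(vol)
        study = drr.make_study(vol, gf, gs)
        _, n = ndi.label(study.I_fron.pixels > 0.1)
        assert n == 2

    def test_separated_support_within_full_sagittal(self, subject_vol):
        vol, _ = subject_vol
        gf, gs = _geoms(vol)
        raw_r = drr.project(vol, gs, mask=ph.RIGHT_LABELS)
        full = drr.project(vol, gs)
        assert np.all(full.pixels[raw_r.pixels > 1e-6] > 0)

    def test_projected_knee_inside_tibia_silhouette(self, subject_vol):
        vol, _ = subject_vol
        gf, gs = _geoms(vol)
        study = drr.make_study(vol, gf, gs)
        tib = drr.project(vol, gf, mask=[ph.TIBIA_RIGHT, ph.PROX_TIBIA_RIGHT])
        u, v = study.landmarks2d["frontal"]["right/KC"]
        assert tib.pixels[int(round(v)), int(round(u))] > 0

    def test_landmark_counts_per_view(self, subject_vol):
        vol, _ = subject_vol
        gf, gs = _geoms(vol)
        study = drr.make_study(vol, gf, gs)
        assert len(study.landmarks2d["frontal"]) == 6
        assert len(study.landmarks2d["sagittal_left"]) == 3
        assert len(study.landmarks2d["sagittal_right"]) == 3
        assert not study.single_leg


class TestHeatmaps:
    def test_peak_value_and_argmax_at_rounded_landmark(self):
        hm = drr.make_heatmaps({"KC": (17.3, 40.8)}, sigma=5.0, shape=(64, 64))
        ch = hm.channel("KC")
        v, u = np.unravel_index(int(np.argmax(ch)), ch.shape)
        assert (u, v) == (17, 41)
        assert ch[v, u] == pytest.approx(1.0)

    def test_gaussian_falloff_at_one_sigma(self):
        hm = drr.make_heatmaps({"p": (30.0, 30.0)}, sigma=5.0, shape=(64, 64))
        ch = hm.channel("p")
        assert ch[30, 35] == pytest.approx(np.exp(-0.5), abs=1e-9)
        assert ch.min() >= 0.0 and ch.max() <= 1.0

    def test_argmax_matches_exhaustive_search(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            u0, v0 = rng.uniform(5, 58, 2)
            hm = drr.make_heatmaps({"x": (u0, v0)}, 4.0, (64, 64))
            ch = hm.channel("x")
            best = max(((ch[v, u], (u, v)) for v in range(64)
                        for u in range(64)))
            assert best[1] == (int(round(u0)), int(round(v0)))

    def test_nonpositive_sigma_rejected(self):
        with pytest.raises(ValueError):
            drr.make_heatmaps({"x": (1.0, 1.0)}, 0.0, (8, 8))


class TestDatasetAssembly:
    def test_split_arithmetic_ten_patients(self):
        split = drr.split_patients([f"p{i}" for i in range(10)], seed=0)
        assert len(split.test) == 1
        assert len(split.val) == 2
        assert len(split.train) == 7
        all_ids = split.train + split.val + split.test
        assert sorted(all_ids) == sorted(f"p{i}" for i in range(10))

    def test_too_few_patients_raises(self):
        with pytest.raises(ValueError):
            drr.split_patients(["a", "b"])

    def test_build_dataset_counts_and_patient_level_split(self):
        cohort = ph.generate_cohort(
            10, ph.PhantomParams(voxel_spacing=12.0), seed=2)
        studies, split = drr.build_dataset(cohort, n_aug=2, seed=2,
                                           detector_size=(48, 48),
                                           pixel_spacing=18.0)
        assert len(studies) == 20
        assert len(split.test) == 1
        # each patient id appears in exactly one partition
        for s in studies:
            parts = [s.patient_id in split.train, s.patient_id in split.val,
                     s.patient_id in split.test]
            assert sum(parts) == 1
        # all augmented copies of one patient share a partition by id
        by_pat = {}
        for s in studies:
            by_pat.setdefault(s.patient_id, []).append(split.partition_of(
                s.patient_id))
        assert all(len(set(v)) == 1 for v in by_pat.values())

    def test_recon_targets_attached_and_nonempty(self, small_studies):
        _, _, studies, _ = small_studies
        for s in studies[:4]:
            for side in ("left", "right"):
                tgt = s.extras["recon"][side]["target"]
                assert tgt.shape == (32, 32, 32)
                assert 0 < tgt.sum() < tgt.size
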