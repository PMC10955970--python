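import numpy as np
import pytest

from holopol.features import (
    ROI,
    fps_features,
    fringe_contrast,
    glszm_features,
    ngtdm_features,
    quantize,
    segment_particles,
    transparency,
    extract_all,
)
from holopol.io_core import FeatureSettings, OpticalConfig
from holopol.polarimetry import compute_polarization_maps, compute_stokes
from holopol.simulator import modulate_field, propagate, record_frame, simulate_particle_frame
from tests.oracles import brute_glszm, brute_ngtdm
from tests.test_simulator import uniform_scene


def qroi_from(levels, mask=None, n_levels=None):
    from holopol.features import QuantizedROI

    levels = np.asarray(levels, dtype=np.int32)
    if mask is None:
        mask = levels > 0
    n_levels = n_levels or int(levels.max())
    return QuantizedROI(levels=levels * mask, mask=np.asarray(mask, bool),
                        n_levels=n_levels, edges=np.array([]))


class TestQuantize:
    def test_constant_roi_maps_to_level_one(self):
        grid = np.full((5, 5), 0.7)
        q = quantize(grid, np.ones((5, 5), bool), 8)
        assert (q.levels == 1).all()

    def test_two_level_split_at_midpoint(self):
        grid = np.array([[0.0, 0.49], [0.5, 1.0]])
        q = quantize(grid, np.ones((2, 2), bool), 2)
        np.testing.assert_array_equal(q.levels, [[1, 1], [2, 2]])

    def test_level_histogram_conserves_mask_area(self):
        rng = np.random.default_rng(0)
        grid = rng.random((12, 12))
        mask = rng.random((12, 12)) > 0.4
        q = quantize(grid, mask, 5)
        assert np.bincount(q.levels.ravel())[1:].sum() == mask.sum()
        assert q.levels[~mask].max(initial=0) == 0

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            quantize(np.ones((3, 3)), np.zeros((3, 3), bool), 4)


class TestNgtdm:
    def test_constant_roi_has_no_contrast(self):
        q = qroi_from(np.ones((6, 6)), n_levels=4)
        out = ngtdm_features(q)
        assert out["ngtdm_contrast"] == 0.0
        assert out["ngtdm_complexity"] == 0.0
        assert out["ngtdm_coarseness"] == 1e6  # flat ROI hits the cap

    def test_checkerboard_matches_brute_force_oracle(self):
        levels = np.indices((4, 4)).sum(axis=0) % 2 + 1
        q = qroi_from(levels, np.ones((4, 4), bool), n_levels=2)
        ours = ngtdm_features(q)
        oracle = brute_ngtdm(q.levels, q.mask, 2)
        for short, name in zip(
            ("coarseness", "contrast", "busyness", "complexity", "strength"),
            ("ngtdm_coarseness", "ngtdm_contrast", "ngtdm_busyness",
             "ngtdm_complexity", "ngtdm_strength"),
        ):
            assert ours[name] == pytest.approx(oracle[short], rel=1e-12)

    def test_contrast_invariant_under_level_relabeling(self):
        levels = np.indices((4, 4)).sum(axis=0) % 2 + 1
        mask = np.ones((4, 4), bool)
        swapped = 3 - levels
        a = ngtdm_features(qroi_from(levels, mask, 2))
        b = ngtdm_features(qroi_from(swapped, mask, 2))
        assert a["ngtdm_contrast"] == pytest.approx(b["ngtdm_contrast"], rel=1e-12)

    def test_random_rois_match_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(25):
            h, w = rng.integers(3, 11, 2)
            ng = int(rng.integers(2, 5))
            levels = rng.integers(1, ng + 1, (h, w)).astype(np.int32)
            mask = rng.random((h, w)) > 0.25
            if not mask.any():
                continue
            ours = ngtdm_features(qroi_from(levels, mask, ng))
            oracle = brute_ngtdm(levels * mask, mask, ng)
            for short, name in zip(oracle, ours):
                if np.isnan(oracle[short]):
                    assert np.isnan(ours[name])
                else:
                    assert ours[name] == pytest.approx(oracle[short], rel=1e-12, abs=1e-12)


class TestGlszm:
    def test_single_zone_algebra(self):
        n = 5
        out = glszm_features(qroi_from(np.ones((n, n)), np.ones((n, n), bool), 2))
        assert out["glszm_zsn"] == pytest.approx(1.0)
        assert out["glszm_sze"] == pytest.approx(1.0 / n**4)
        assert out["glszm_zse"] == pytest.approx(0.0, abs=1e-12)

    def test_stripes_make_column_zones(self):
        # alternating single-pixel-wide vertical stripes: every zone is
        # one full column under both 4- and 8-connectivity
        n = 6
        levels = np.tile(np.arange(n) % 2 + 1, (n, 1))
        out = glszm_features(qroi_from(levels, np.ones((n, n), bool), 2))
        assert out["glszm_lze"] == pytest.approx(n**2)  # all zones size n
        assert out["glszm_zsn"] == pytest.approx(n)  # n zones of one size

    def test_random_rois_match_flood_fill_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(25):
            h, w = rng.integers(3, 11, 2)
            ng = int(rng.integers(2, 5))
            levels = rng.integers(1, ng + 1, (h, w)).astype(np.int32)
            mask = rng.random((h, w)) > 0.25
            if not mask.any():
                continue
            ours = glszm_features(qroi_from(levels, mask, ng))
            oracle = brute_glszm(levels * mask, mask, ng)
            for short, name in zip(oracle, ours):
                assert ours[name] == pytest.approx(oracle[short], rel=1e-12, abs=1e-12)


class TestFps:
    def test_profiles_are_normalized(self):
        rng = np.random.default_rng(1)
        grid = rng.random((20, 24))
        mask = np.ones((20, 24), bool)
        out = fps_features(grid, mask, 8, 8)
        assert sum(out[f"fps_radial_{i+1}"] for i in range(8)) == pytest.approx(1.0)
        assert sum(out[f"fps_angular_{i+1}"] for i in range(8)) == pytest.approx(1.0)

    def test_isotropic_blob_has_flat_angular_profile(self):
        # a tight blob spreads its spectrum over many lattice rings; the
        # large grid keeps the per-sector pixel discretization mild
        n = 256
        Y, X = np.mgrid[:n, :n]
        blob = np.exp(-(((Y - n / 2) ** 2 + (X - n / 2) ** 2) / (2 * 1.5**2)))
        out = fps_features(blob, np.ones((n, n), bool), 8, 8)
        vals = [out[f"fps_angular_{i+1}"] for i in range(8)]
        assert max(vals) / min(vals) <= 1.2

    def test_horizontal_grating_concentrates_power(self):
        n = 64
        X = np.arange(n)[None, :].repeat(n, axis=0)
        grating = 1.0 + np.cos(2 * np.pi * X / 8.0)
        out = fps_features(grating, np.ones((n, n), bool), 8, 8)
        # grating varies along x: spectral peaks on the fx axis, angle 0
        assert out["fps_angular_1"] >= 0.9

    def test_degenerate_roi_rejected(self):
        mask = np.zeros((4, 4), bool)
        mask[0, 0] = True
        with pytest.raises(ValueError, match="degenerate"):
            fps_features(np.ones((4, 4)), mask)


def _disc_roi(n=64, r=10, annulus=8):
    Y, X = np.ogrid[:n, :n]
    d2 = (Y - n // 2) ** 2 + (X - n // 2) ** 2
    mask = d2 <= r**2
    ring = (d2 > r**2) & (d2 <= (r + annulus) ** 2)
    return ROI(0, mask, (0, 0, n, n), ring)


class TestHolographicFeatures:
    def test_constant_annulus_has_zero_contrast(self):
        roi = _disc_roi()
        assert fringe_contrast(np.ones((64, 64)), roi) == 0.0

    def test_full_modulation_fringe_contrast_near_one(self):
        roi = _disc_roi()
        X = np.arange(64)[None, :].repeat(64, axis=0)
        grid = 1.0 + np.cos(2 * np.pi * X / 6.0)
        assert fringe_contrast(grid, roi) == pytest.approx(1.0, abs=0.02)

    def test_contrast_grows_with_propagation_distance(self):
        optics0 = OpticalConfig(shape=(128, 128), bit_depth=None, z=0.0)
        scene = uniform_scene(optics0, background=True)
        Y, X = np.ogrid[:128, :128]
        disc = (Y - 64) ** 2 + (X - 64) ** 2 <= 12**2
        scene.maps["label"] = disc.astype(float)
        scene.maps["transmittance"] = np.where(disc, 0.0, 1.0)
        field = modulate_field(scene)
        roi = _disc_roi(128, 12, 10)
        contrasts = []
        for z in (0.0, 5e-3):
            frame = record_frame(propagate(field, z, optics0), optics0)
            S0 = compute_stokes(frame).S0
            contrasts.append(fringe_contrast(S0, roi))
        assert contrasts[1] > contrasts[0]

    @pytest.mark.parametrize("t, expected", [(0.0, 0.0), (1.0, 1.0), (0.5, 0.25)])
    def test_transparency_is_intensity_ratio(self, t, expected):
        # at focus transparency is t^2: amplitude transmittance squared
        optics = OpticalConfig(shape=(64, 64), bit_depth=None, z=0.0)
        scene = uniform_scene(optics, background=True)
        roi = _disc_roi(64, 10, 8)
        scene.maps["label"] = roi.mask.astype(float)
        scene.maps["transmittance"] = np.where(roi.mask, t, 1.0)
        # phase-only particle for the t=1 case
        frame = record_frame(modulate_field(scene), optics)
        S0 = compute_stokes(frame).S0
        assert transparency(S0, roi) == pytest.approx(expected, abs=1e-9)


class TestSegmentation:
    def test_uniform_grid_yields_no_rois(self):
        assert len(segment_particles(np.full((64, 64), 0.5))) == 0

    def test_single_disc_recovered_with_high_iou(self, profiles):
        optics = OpticalConfig(shape=(128, 128), bit_depth=None, z=0.0)
        frame, scene = simulate_particle_frame(profiles["PC"], optics, 2, noise=False)
        S0 = compute_stokes(frame).S0
        rois = segment_particles(S0)
        assert len(rois) == 1
        gt = scene.maps["label"] > 0
        mask = rois.rois[0].mask
        iou = (mask & gt).sum() / (mask | gt).sum()
        assert iou >= 0.8

    def test_two_separated_discs_give_two_rois(self):
        optics = OpticalConfig(shape=(128, 128), bit_depth=None, z=0.0)
        scene = uniform_scene(optics, background=True)
        Y, X = np.ogrid[:128, :128]
        d1 = (Y - 40) ** 2 + (X - 40) ** 2 <= 10**2
        d2 = (Y - 90) ** 2 + (X - 90) ** 2 <= 10**2
        scene.maps["label"] = (d1 | d2).astype(float)
        scene.maps["transmittance"] = np.where(d1 | d2, 0.3, 1.0)
        frame = record_frame(modulate_field(scene), optics)
        assert len(segment_particles(compute_stokes(frame).S0)) == 2


@pytest.fixture(scope="module")
def one_frame(profiles):
    optics = OpticalConfig(shape=(128, 128), bit_depth=None)
    frame, _ = simulate_particle_frame(profiles["PVC"], optics, 9, noise=False)
    return frame


class TestExtractAll:
    def _table(self, frame, settings=None):
        settings = settings or FeatureSettings()
        stokes = compute_stokes(frame)
        maps = compute_polarization_maps(frame)
        rois = segment_particles(stokes.S0, settings)
        return extract_all(frame, stokes, maps, rois, settings, label="PVC")

    def test_every_group_represented_and_deterministic(self, one_frame):
        t1 = self._table(one_frame)
        t2 = self._table(one_frame)
        assert len(t1.df) == 1
        assert set(t1.groups.values()) == {"C1", "C2", "C3", "C4", "C5", "C6", "C7", "C8"}
        assert t1.df.equals(t2.df)

    def test_features_invariant_to_global_intensity_scale(self, one_frame):
        from holopol.polarimetry import PolarizationFrame

        t1 = self._table(one_frame)
        scaled = PolarizationFrame(
            {ch: 0.5 * one_frame[ch] for ch in one_frame.channels},
            channels=one_frame.channels,
        )
        t2 = self._table(scaled)
        for col in t1.feature_columns:
            assert t1.df[col].iloc[0] == pytest.approx(t2.df[col].iloc[0], rel=1e-6, abs=1e-9)

    def test_translation_invariance_at_focus(self, profiles):
        optics = OpticalConfig(shape=(128, 128), bit_depth=None, z=0.0)
        t = []
        for dr, dc in ((0, 0), (7, -5)):
            frame, _ = simulate_particle_frame(
                profiles["PP"], optics, 13, noise=False, center=(64 + dr, 64 + dc)
            )
            t.append(self._table(frame))
        for col in t[0].feature_columns:
            assert t[0].df[col].iloc[0] == pytest.approx(
                t[1].df[col].iloc[0], rel=1e-6, abs=1e-8
            )

    def test_class_profiles_separate_in_mean_retardance(self, profiles):
        # PC vs plant root: retardance gap larger than the summed spreads
        optics = OpticalConfig(shape=(96, 96), bit_depth=None, z=0.0)
        vals = {}
        for cls in ("PC", "PlantRoot"):
            out = []
            for seed in range(10):
                frame, _ = simulate_particle_frame(profiles[cls], optics, 100 + seed, noise=False)
                tab = self._table(frame)
                out.append(tab.df["ret_mean"].iloc[0])
            vals[cls] = np.array(out)
        gap = abs(vals["PC"].mean() - vals["PlantRoot"].mean())
        assert gap > vals["PC"].std() + vals["PlantRoot"].std()
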