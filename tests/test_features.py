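"""Handcrafted texture features: degenerate conventions, exact oracles,
parameter recovery, and invariances."""

import numpy as np
import pytest

from fewtex.features import (
    FEATURE_NAMES,
    GMRF_OFFSETS,
    FeatureVector33,
    extract_features,
    gabor_features,
    glcm_accumulate,
    glcm_statistics,
    gmrf_fit,
    grey_histogram_features,
    quantize_levels,
    synthesize_gmrf,
    tamura_features,
)
from fewtex.phantom import LabeledImage


def full_mask(shape):
    return np.ones(shape, dtype=bool)


class TestQuantize:
    def test_constant_patch_all_zeros(self):
        q = quantize_levels(np.full((8, 8), 0.3), full_mask((8, 8)), levels=32)
        assert (q == 0).all()

    def test_two_valued_patch_two_levels(self):
        p = np.where(np.arange(64).reshape(8, 8) % 2 == 0, 0.2, 0.8)
        q = quantize_levels(p, full_mask((8, 8)), levels=2)
        assert set(np.unique(q)) == {0, 1}
        assert ((q == 1) == (p == 0.8)).all()

    def test_floor_formula_oracle(self, rng):
        p = rng.uniform(0.1, 0.9, size=(16, 16))
        levels = 32
        q = quantize_levels(p, full_mask(p.shape), levels)
        lo, hi = p.min(), p.max()
        expect = np.minimum(np.floor((p - lo) / (hi - lo) * levels), levels - 1)
        np.testing.assert_array_equal(q, expect.astype(int))

    def test_rejects_bad_inputs(self):
        with pytest.raises(ValueError, match="levels"):
            quantize_levels(np.zeros((4, 4)), full_mask((4, 4)), levels=1)
        with pytest.raises(ValueError, match="foreground"):
            quantize_levels(np.zeros((4, 4)), np.zeros((4, 4), bool))


class TestGreyHistogram:
    def test_constant_patch_convention(self):
        gh = grey_histogram_features(np.full((8, 8), 0.4), full_mask((8, 8)))
        np.testing.assert_allclose(gh, [0.4, 0.0, 0.0, 0.0, 1.0, 0.0], atol=1e-12)

    def test_two_valued_entropy_energy(self):
        p = np.where(np.arange(64).reshape(8, 8) % 2 == 0, 0.2, 0.8)
        gh = grey_histogram_features(p, full_mask((8, 8)))
        assert gh[5] == pytest.approx(1.0)  # entropy, bits
        assert gh[4] == pytest.approx(0.5)  # energy

    def test_hand_summed_oracle(self, rng):
        vals = rng.uniform(0, 1, size=(4, 4))
        gh = grey_histogram_features(vals, full_mask((4, 4)))
        v = vals.ravel()
        mean = sum(v) / 16
        var = sum((x - mean) ** 2 for x in v) / 16
        sd = var**0.5
        skew = sum(((x - mean) / sd) ** 3 for x in v) / 16
        kurt = sum(((x - mean) / sd) ** 4 for x in v) / 16 - 3
        counts = np.zeros(256)
        for x in v:
            counts[min(int(x * 256), 255)] += 1
        p = counts / 16
        energy = sum(pi**2 for pi in p)
        entropy = -sum(pi * np.log2(pi) for pi in p if pi > 0)
        np.testing.assert_allclose(gh, [mean, var, skew, kurt, energy, entropy], atol=1e-12)


class TestGlcm:
    def test_constant_patch_single_entry(self):
        q = np.zeros((3, 3), dtype=int)
        cm, degenerate = glcm_accumulate(q, full_mask((3, 3)), 1, 0, levels=4)
        assert not degenerate
        assert cm[0, 0] == pytest.approx(1.0)
        assert cm.sum() == pytest.approx(1.0)

    def test_vertical_stripes_mass_split(self):
        # columns alternate levels 1,2 -> horizontal neighbors always differ
        q = np.tile([1, 2, 1, 2], (4, 1))
        cm, _ = glcm_accumulate(q, full_mask(q.shape), 1, 0, levels=4)
        assert cm[1, 2] == pytest.approx(0.5)
        assert cm[2, 1] == pytest.approx(0.5)
        assert cm.sum() == pytest.approx(1.0)

    def test_sums_to_one_and_symmetric(self, rng):
        q = rng.integers(0, 8, size=(12, 12))
        mask = rng.uniform(size=(12, 12)) > 0.3
        for angle in (0, 45, 90, 135):
            cm, degenerate = glcm_accumulate(q, mask, 1, angle, levels=8)
            if not degenerate:
                assert cm.sum() == pytest.approx(1.0)
                np.testing.assert_allclose(cm, cm.T, atol=1e-15)

    def test_pair_enumeration_oracle(self, rng):
        """Counts match an exhaustive loop over all in-mask pixel pairs."""
        offsets = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}
        q = rng.integers(0, 4, size=(9, 9))
        mask = rng.uniform(size=(9, 9)) > 0.25
        for angle, (dr, dc) in offsets.items():
            expect = np.zeros((4, 4))
            for r in range(9):
                for c in range(9):
                    r2, c2 = r + dr, c + dc
                    if 0 <= r2 < 9 and 0 <= c2 < 9 and mask[r, c] and mask[r2, c2]:
                        expect[q[r, c], q[r2, c2]] += 1
            expect = expect + expect.T
            cm, degenerate = glcm_accumulate(q, mask, 1, angle, levels=4)
            if expect.sum() == 0:
                assert degenerate
            else:
                np.testing.assert_allclose(cm, expect / expect.sum(), atol=1e-15)

    def test_skimage_cross_check_full_mask(self, rng):
        """On a full mask the matrix equals skimage's symmetric normed GLCM."""
        graycomatrix = pytest.importorskip("skimage.feature").graycomatrix
        q = rng.integers(0, 8, size=(16, 16)).astype(np.uint8)
        cm, _ = glcm_accumulate(q, full_mask((16, 16)), 1, 0, levels=8)
        ref = graycomatrix(q, [1], [0], levels=8, symmetric=True, normed=True)[:, :, 0, 0]
        np.testing.assert_allclose(cm, ref, atol=1e-12)

    def test_statistics_constant_patch(self):
        q = np.zeros((5, 5), dtype=int)
        mats = [glcm_accumulate(q, full_mask((5, 5)), 1, a, levels=4) for a in (0, 45, 90, 135)]
        stats = glcm_statistics(mats)
        # contrast, correlation, energy, homogeneity, entropy, dissimilarity
        np.testing.assert_allclose(stats, [0.0, 1.0, 1.0, 1.0, 0.0, 0.0], atol=1e-12)

    def test_checkerboard_contrast(self):
        q = np.indices((8, 8)).sum(axis=0) % 2
        cm, _ = glcm_accumulate(q, full_mask((8, 8)), 1, 0, levels=2)
        stats = glcm_statistics([(cm, False)])
        assert stats[0] == pytest.approx(1.0)  # contrast: every pair differs by 1

    def test_energy_entropy_ranges(self, rng):
        q = rng.integers(0, 8, size=(20, 20))
        mats = [glcm_accumulate(q, full_mask((20, 20)), 1, a, levels=8) for a in (0, 45, 90, 135)]
        stats = glcm_statistics(mats)
        assert 0 < stats[2] <= 1.0
        assert stats[4] >= 0.0

    def test_all_degenerate_warns(self):
        zero = (np.zeros((4, 4)), True)
        with pytest.warns(UserWarning, match="degenerate"):
            stats = glcm_statistics([zero, zero])
        np.testing.assert_allclose(stats, [0.0, 1.0, 1.0, 1.0, 0.0, 0.0])


class TestGabor:
    def test_constant_patch_zero_response(self):
        g = gabor_features(np.full((32, 32), 0.6), full_mask((32, 32)))
        assert (g < 1e-6).all()

    def test_grating_at_filter_wavelength(self):
        """A grating varying along x at the filter wavelength excites the
        0-degree filter more than the 120-degree filter; the direct-
        convolution oracle agrees on the ranking."""
        yy, xx = np.mgrid[0:32, 0:32]
        patch = 0.5 + 0.4 * np.sin(2 * np.pi * xx / 8.0)
        g = gabor_features(patch, full_mask((32, 32)))
        assert g[0] > g[2]

        # independent oracle: explicit gaussian-windowed complex sinusoid
        def oracle(theta):
            k = 15
            ky, kx = np.mgrid[-k // 2 + 1:k // 2 + 1, -k // 2 + 1:k // 2 + 1]
            rot = kx * np.cos(theta) + ky * np.sin(theta)
            kern = np.exp(-(kx**2 + ky**2) / (2 * 4.0**2)) * np.exp(2j * np.pi * rot / 8.0)
            kern -= kern.mean()
            resp = np.zeros((32, 32))
            for r in range(32):
                for c in range(32):
                    acc = 0.0 + 0.0j
                    for dr in range(-7, 8):
                        for dc in range(-7, 8):
                            rr = min(max(r + dr, 0), 31)
                            cc = min(max(c + dc, 0), 31)
                            acc += patch[rr, cc] * kern[7 + dr, 7 + dc]
                    resp[r, c] = abs(acc)
            return resp.mean()

        assert oracle(0.0) > oracle(np.deg2rad(120.0))

    def test_rotated_grating_permutes_maximum(self):
        yy, xx = np.mgrid[0:48, 0:48]
        m = full_mask((48, 48))
        for angle_deg, expect_argmax in ((0.0, 0), (60.0, 1), (120.0, 2)):
            th = np.deg2rad(angle_deg)
            patch = 0.5 + 0.4 * np.sin(2 * np.pi * (xx * np.cos(th) + yy * np.sin(th)) / 8.0)
            g = gabor_features(patch, m)
            assert int(np.argmax(g)) == expect_argmax

    def test_rejects_small_patch(self):
        with pytest.raises(ValueError, match="16x16"):
            gabor_features(np.zeros((8, 8)), full_mask((8, 8)))


class TestGmrf:
    def test_white_noise_parameters_near_zero(self):
        ests = np.array([
            gmrf_fit(np.random.default_rng(s).standard_normal((64, 64)), full_mask((64, 64)))
            for s in range(10)
        ])
        assert np.abs(ests.mean(axis=0)).max() < 0.05

    def test_single_parameter_recovery(self):
        ests = np.array([
            gmrf_fit(synthesize_gmrf((64, 64), {(0, 1): 0.2}, seed=s), full_mask((64, 64)))
            for s in range(10)
        ])
        mean = ests.mean(axis=0)
        assert abs(mean[GMRF_OFFSETS.index((0, 1))] - 0.2) < 0.05
        others = np.delete(mean, GMRF_OFFSETS.index((0, 1)))
        assert np.abs(others).max() < 0.05

    def test_constant_patch_zeros(self):
        theta = gmrf_fit(np.full((32, 32), 0.7), full_mask((32, 32)))
        np.testing.assert_array_equal(theta, np.zeros(12))

    def test_too_few_sites_warns_zeros(self):
        mask = np.zeros((16, 16), bool)
        mask[2:13, 2:13] = np.eye(11, dtype=bool)  # thin diagonal: no full neighborhood
        mask[0:9, 0:9] |= False
        mask[2:11, 2] = True  # ensure bbox >= 9x9 and >= 32 fg pixels
        mask[2, 2:11] = True
        mask[12, 3:12] = True
        with pytest.warns(UserWarning, match="usable"):
            theta = gmrf_fit(np.random.default_rng(0).uniform(size=(16, 16)), mask)
        np.testing.assert_array_equal(theta, np.zeros(12))

    def test_small_bbox_rejected(self):
        with pytest.raises(ValueError, match="9x9"):
            gmrf_fit(np.zeros((8, 8)), full_mask((8, 8)))


class TestTamura:
    def test_constant_patch_conventions(self):
        t = tamura_features(np.full((40, 40), 0.5), full_mask((40, 40)))
        coarseness, contrast, directionality, _, _, roughness = t
        assert coarseness == pytest.approx(1.0)  # tie rule: smallest size wins
        assert contrast == pytest.approx(0.0)
        assert directionality == pytest.approx(0.0)  # no gradients above threshold
        assert roughness == pytest.approx(coarseness + contrast)

    def test_grating_more_directional_than_noise(self):
        yy, xx = np.mgrid[0:64, 0:64]
        grating = 0.5 + 0.4 * np.sin(2 * np.pi * yy / 8.0)
        noise = np.random.default_rng(3).uniform(size=(64, 64))
        m = full_mask((64, 64))
        d_grating = tamura_features(grating, m)[2]
        d_noise = tamura_features(noise, m)[2]
        assert d_grating > d_noise
        assert d_grating > 0.5  # near the sharp-histogram maximum of 1

    def test_roughness_identity_on_random_patches(self, rng):
        for _ in range(5):
            p = rng.uniform(size=(48, 48))
            t = tamura_features(p, full_mask((48, 48)))
            assert t[5] == pytest.approx(t[0] + t[1], abs=1e-12)

    def test_small_bbox_rejected(self):
        with pytest.raises(ValueError, match="32x32"):
            tamura_features(np.zeros((16, 16)), full_mask((16, 16)))


class TestExtractFeatures:
    def test_exactly_33_finite_ordered(self, cohort):
        fv = extract_features(cohort["images"][0])
        assert len(fv) == 33
        assert np.isfinite(fv.values).all()
        assert fv.names == FEATURE_NAMES
        assert [n.split("_")[0] for n in fv.names].count("gh") == 6
        assert [n.split("_")[0] for n in fv.names].count("glcm") == 6
        assert [n.split("_")[0] for n in fv.names].count("gabor") == 3
        assert [n.split("_")[0] for n in fv.names].count("gmrf") == 12
        assert [n.split("_")[0] for n in fv.names].count("tamura") == 6

    def test_deterministic(self, cohort):
        img = cohort["images"][5]
        np.testing.assert_array_equal(extract_features(img).values, extract_features(img).values)

    def test_intensity_shift_invariance(self, rng):
        pixels = rng.uniform(0.1, 0.7, size=(64, 64))
        mask = np.zeros((64, 64), bool)
        mask[10:55, 8:60] = True
        img0 = LabeledImage(pixels, mask, 0, "a")
        img1 = LabeledImage(pixels + 0.2, mask, 0, "b")
        f0, f1 = extract_features(img0).values, extract_features(img1).values
        names = list(FEATURE_NAMES)
        assert f1[names.index("gh_mean")] - f0[names.index("gh_mean")] == pytest.approx(0.2, abs=1e-9)
        for name in names:
            if name.startswith(("glcm", "gmrf")) or name == "tamura_directionality":
                assert f1[names.index(name)] == pytest.approx(f0[names.index(name)], abs=1e-9), name

    def test_mask_shrink_changes_values_not_shape(self, cohort):
        img = cohort["images"][2]
        rows = np.nonzero(img.mask.any(axis=1))[0]
        shrunk = img.mask.copy()
        shrunk[rows[: len(rows) // 3], :] = False
        img2 = LabeledImage(img.pixels, shrunk, img.label, img.sample_id)
        f1, f2 = extract_features(img), extract_features(img2)
        assert len(f1) == len(f2) == 33
        assert not np.array_equal(f1.values, f2.values)

    def test_vector_validation(self):
        with pytest.raises(ValueError, match="33"):
            FeatureVector33(np.zeros(10))
        with pytest.raises(ValueError, match="finite"):
            FeatureVector33(np.full(33, np.nan))
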