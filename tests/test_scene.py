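"""Synthetic scene generator: spectra, cover fields, rendering, truth patches."""
import numpy as np
import pytest

from coverwise.geo import GeoTransform
from coverwise.scene import (ConfigurationError, CoverScene, SimulationError,
                             SpectralLibrary, extract_truth_patches,
                             make_endmember, make_spectral_library,
                             make_wavelength_grid, render_cube,
                             simulate_cover_field, truth_mask)


def spectral_angle(a, b):
    return np.arccos(np.clip(a @ b / (np.linalg.norm(a) * np.linalg.norm(b)),
                             -1, 1))


class TestEndmembers:
    def test_vegetation_shape_and_bounds(self, wl_small):
        for seed in range(5):
            r = make_endmember(wl_small, "background", jitter_seed=seed)
            assert np.all((r >= 0) & (r <= 1))
            i550 = np.argmin(np.abs(wl_small - 550))
            i680 = np.argmin(np.abs(wl_small - 680))
            assert r[i550] > r[i680]

    def test_deterministic_given_seed(self, wl_small):
        a = make_endmember(wl_small, "target", jitter_seed=42)
        b = make_endmember(wl_small, "target", jitter_seed=42)
        np.testing.assert_array_equal(a, b)

    def test_distinct_backgrounds(self, wl_small):
        spectra = [make_endmember(wl_small, "background", jitter_seed=s)
                   for s in range(10)]
        for i in range(10):
            for j in range(i + 1, 10):
                assert spectral_angle(spectra[i], spectra[j]) > 0

    def test_invalid_inputs(self, wl_small):
        with pytest.raises(ConfigurationError):
            make_endmember(np.array([500.0, 400.0, 600.0]))
        with pytest.raises(ConfigurationError):
            make_endmember(wl_small, kind="water")


class TestSpectralLibrary:
    def test_one_target_and_separability_scale(self, library_small):
        assert library_small.labels.count("target") == 1
        mean_bg = library_small.background_spectra.mean(axis=0)
        dev = np.max(np.abs(library_small.target_spectrum - mean_bg))
        # equality can only be broken by clipping at the reflectance bounds
        assert dev == pytest.approx(0.03, rel=1e-6)

    def test_invariant_validation(self, wl_small):
        with pytest.raises(ConfigurationError):
            SpectralLibrary(wavelengths=wl_small,
                            spectra=np.full((2, wl_small.size), 1.5),
                            labels=["target", "b"])


class TestCoverField:
    def test_prevalence_on_default_sized_scene(self):
        scene = simulate_cover_field(500, 500, correlation_length_m=20.0,
                                     prevalence_target=0.04, seed=12)
        assert 0.032 <= scene.prevalence <= 0.048

    def test_zero_prevalence_gives_empty_field(self):
        scene = simulate_cover_field(64, 64, 5.0, prevalence_target=0.0, seed=0)
        assert np.all(scene.cover == 0)

    def test_deterministic(self):
        a = simulate_cover_field(80, 80, 5.0, 0.04, seed=9)
        b = simulate_cover_field(80, 80, 5.0, 0.04, seed=9)
        np.testing.assert_array_equal(a.cover, b.cover)
        np.testing.assert_array_equal(a.background_weights,
                                      b.background_weights)

    def test_all_strata_populated(self, scene_small):
        c = scene_small.cover
        for lo, hi in ((0.15, 0.45), (0.45, 0.75), (0.75, 1.01)):
            assert np.any((c >= lo) & (c < hi))

    def test_background_weights_convex(self, scene_small):
        w = scene_small.background_weights
        assert np.all(w >= 0)
        np.testing.assert_allclose(w.sum(axis=2), 1.0, atol=1e-9)

    def test_too_small_scene_raises(self):
        with pytest.raises(SimulationError):
            simulate_cover_field(4, 4, 2.0, prevalence_target=0.04, seed=0)

    def test_prevalence_above_cap_rejected(self):
        with pytest.raises(ConfigurationError):
            simulate_cover_field(64, 64, 5.0, prevalence_target=0.2, seed=0)


def _two_member_library(wl):
    target = make_endmember(wl, "target", jitter_seed=1)
    bg = make_endmember(wl, "background", jitter_seed=2)
    return SpectralLibrary(wavelengths=wl, spectra=np.vstack([target, bg]),
                           labels=["target", "bg"])


class TestRenderCube:
    def test_pure_pixels_reproduce_endmembers(self, wl_small):
        lib = _two_member_library(wl_small)
        cover = np.array([[1.0, 0.0], [0.5, 0.25]])
        scene = CoverScene(cover, np.ones((2, 2, 1)))
        cube = render_cube(scene, lib, noise_sd=0.0)
        np.testing.assert_allclose(cube.data[:, 0, 0], lib.target_spectrum)
        np.testing.assert_allclose(cube.data[:, 0, 1], lib.spectra[1])
        np.testing.assert_allclose(
            cube.data[:, 1, 0], (lib.spectra[0] + lib.spectra[1]) / 2)

    def test_noise_sd_recovered(self, wl_small):
        lib = _two_member_library(wl_small)
        scene = CoverScene(np.full((120, 120), 0.5),
                           np.ones((120, 120, 1)))
        noiseless = render_cube(scene, lib, noise_sd=0.0)
        noisy = render_cube(scene, lib, noise_sd=0.01, seed=3)
        resid = noisy.data - noiseless.data
        # interior reflectance: clipping at [0, 1] never triggers
        band_sd = resid.reshape(resid.shape[0], -1).std(axis=1)
        assert np.all(np.abs(band_sd - 0.01) < 0.002)

    def test_noiseless_cube_in_endmember_hull(self, scene_small, library_small):
        cube = render_cube(scene_small, library_small, noise_sd=0.0)
        lo = library_small.spectra.min(axis=0)
        hi = library_small.spectra.max(axis=0)
        assert np.all(cube.data >= lo[:, None, None] - 1e-12)
        assert np.all(cube.data <= hi[:, None, None] + 1e-12)

    def test_deterministic_and_negative_noise_rejected(self, scene_small,
                                                       library_small):
        a = render_cube(scene_small, library_small, noise_sd=0.01, seed=4)
        b = render_cube(scene_small, library_small, noise_sd=0.01, seed=4)
        np.testing.assert_array_equal(a.data, b.data)
        with pytest.raises(ConfigurationError):
            render_cube(scene_small, library_small, noise_sd=-0.1)


def _flood_fill_mask(binary, min_px):
    """Independent 4-connected component filter (BFS oracle)."""
    rows, cols = binary.shape
    seen = np.zeros_like(binary, dtype=bool)
    keep = np.zeros_like(binary, dtype=bool)
    for r0 in range(rows):
        for c0 in range(cols):
            if not binary[r0, c0] or seen[r0, c0]:
                continue
            comp, queue = [], [(r0, c0)]
            seen[r0, c0] = True
            while queue:
                r, c = queue.pop()
                comp.append((r, c))
                for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                    rr, cc = r + dr, c + dc
                    if (0 <= rr < rows and 0 <= cc < cols
                            and binary[rr, cc] and not seen[rr, cc]):
                        seen[rr, cc] = True
                        queue.append((rr, cc))
            if len(comp) >= min_px:
                for r, c in comp:
                    keep[r, c] = True
    return keep


def _scene_from_cover(cover):
    return CoverScene(cover, np.ones(cover.shape + (1,)))


class TestTruthPatches:
    def test_empty_for_zero_cover(self):
        scene = _scene_from_cover(np.zeros((10, 10)))
        assert extract_truth_patches(scene) == []

    def test_single_block_area(self):
        cover = np.zeros((10, 10))
        cover[2:5, 3:7] = 1.0                      # 3 x 4 = 12 m2
        patches = extract_truth_patches(_scene_from_cover(cover))
        assert len(patches) == 1
        assert patches[0].area == pytest.approx(12.0)

    def test_subthreshold_block_discarded(self):
        cover = np.zeros((10, 10))
        cover[2:5, 3:6] = 1.0                      # 9 m2 < 10 m2
        assert extract_truth_patches(_scene_from_cover(cover)) == []

    def test_mask_matches_flood_fill_oracle(self, rng):
        cover = (rng.random((40, 40)) > 0.6) * rng.random((40, 40))
        scene = _scene_from_cover(cover)
        got = truth_mask(scene)
        expected = _flood_fill_mask(cover >= 0.2, min_px=10)
        np.testing.assert_array_equal(got, expected)

    def test_patch_area_equals_mask_area(self, scene_small):
        patches = extract_truth_patches(scene_small)
        total = sum(p.area for p in patches)
        assert total == pytest.approx(truth_mask(scene_small).sum())
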