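"""Tests for the Raman hyperspectral pipeline."""

import numpy as np
import pytest
from scipy import stats as sps
from sklearn.metrics import adjusted_rand_score

from eosiquant import synthetic
from eosiquant.raman import (
    MarkerCollisionError,
    SpectralCube,
    anova_groups,
    band_integrate,
    baseline_correct,
    class_mean_spectra,
    fit_unsaturation_calibration,
    integration_map,
    kmeans_segment,
    pca_cytoplasm,
    remove_cosmic_rays,
    unsaturation_ratio,
)


@pytest.fixture(scope="module")
def axis():
    return synthetic.default_wavenumber_axis()


@pytest.fixture(scope="module")
def fatty_refs():
    return synthetic.reference_fatty_acid_spectra([1, 2, 3])


class TestCosmicRays:
    def test_smooth_spectrum_unchanged(self, axis):
        spec = np.exp(-((axis - 1500.0) ** 2) / (2 * 200.0**2))
        cube = SpectralCube(spectra=spec[None, :], wavenumber_axis=axis, spatial_shape=(1, 1))
        out, replaced = remove_cosmic_rays(cube)
        assert replaced == []
        assert np.array_equal(out.spectra, cube.spectra)

    def test_injected_spike_removed_neighbours_untouched(self, axis):
        rng = np.random.default_rng(0)
        noise_sd = 0.001
        spec = 0.05 * np.exp(-((axis - 1440.0) ** 2) / (2 * 10.0**2)) + rng.normal(0, noise_sd, axis.size)
        clean = spec.copy()
        spec[600] += 50 * noise_sd
        cube = SpectralCube(spectra=spec[None, :], wavenumber_axis=axis, spatial_shape=(1, 1))
        out, replaced = remove_cosmic_rays(cube)
        assert (0, 600) in replaced
        untouched = np.delete(np.arange(axis.size), [r[1] for r in replaced])
        assert np.array_equal(out.spectra[0, untouched], spec[untouched])
        assert abs(out.spectra[0, 600] - clean[600]) < 5 * noise_sd

    def test_spike_tally_matches_generator(self, raman_cube_with_truth):
        cube, truth = raman_cube_with_truth
        _, replaced = remove_cosmic_rays(cube)
        assert set(replaced) == set(truth["spikes"])

    def test_idempotence(self, raman_cube_with_truth):
        cube, _ = raman_cube_with_truth
        once, _ = remove_cosmic_rays(cube)
        twice, second = remove_cosmic_rays(once)
        assert second == []
        assert np.array_equal(once.spectra, twice.spectra)

    def test_even_filter_size_rejected(self, raman_cube_with_truth):
        with pytest.raises(ValueError):
            remove_cosmic_rays(raman_cube_with_truth[0], filter_size=4)


class TestBaseline:
    def test_pure_cubic_removed(self, axis):
        u = (axis - axis[0]) / (axis[-1] - axis[0])
        spec = 1.0 + 2.0 * u - 0.5 * u**2 + 0.3 * u**3
        corrected = baseline_correct(spec, axis)
        assert np.abs(corrected).max() < 1e-6

    def test_band_area_preserved(self, axis):
        u = (axis - axis[0]) / (axis[-1] - axis[0])
        band = 0.08 * np.exp(-((axis - 1440.0) ** 2) / (2 * 10.0**2))
        spec = (0.01 + 0.02 * u + 0.01 * u**3) + band
        corrected = baseline_correct(spec, axis)
        area_before = band_integrate(band, axis, (1390, 1490))
        area_after = band_integrate(corrected, axis, (1390, 1490))
        assert area_after == pytest.approx(area_before, rel=0.05)

    def test_flat_zero_maps_to_zero(self, axis):
        corrected = baseline_correct(np.zeros_like(axis), axis)
        assert np.abs(corrected).max() < 1e-12

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            baseline_correct(np.array([1.0, 2.0]), np.array([0.0, 1.0]))


class TestBandIntegrate:
    def test_zero_spectrum(self, axis):
        assert band_integrate(np.zeros_like(axis), axis, (1000, 1100)) == 0.0

    def test_triangle_area(self, axis):
        # unit-height triangle, base 20 cm⁻¹ centred at 1500 -> area 10
        spec = np.clip(1.0 - np.abs(axis - 1500.0) / 10.0, 0.0, None)
        area = band_integrate(spec, axis, (1480, 1520))
        assert area == pytest.approx(10.0, rel=0.02)

    def test_additivity_over_adjacent_windows(self, axis):
        rng = np.random.default_rng(1)
        spec = rng.random(axis.size) * 0.01
        whole = band_integrate(spec, axis, (1000, 1200))
        # additivity holds for the plain trapezoid (no local-baseline chord)
        def trapz_only(window):
            lo, hi = window
            inside = (axis > lo) & (axis < hi)
            xs = np.concatenate(([lo], axis[inside], [hi]))
            ys = np.concatenate(([np.interp(lo, axis, spec)], spec[inside], [np.interp(hi, axis, spec)]))
            return np.trapezoid(ys, xs)

        assert trapz_only((1000, 1200)) == pytest.approx(
            trapz_only((1000, 1100)) + trapz_only((1100, 1200)), rel=1e-9
        )
        assert np.isfinite(whole)

    def test_window_outside_axis_rejected(self, axis):
        with pytest.raises(ValueError):
            band_integrate(np.zeros_like(axis), axis, (100, 200))


class TestIntegrationMap:
    def test_zero_cube(self, axis):
        cube = SpectralCube(spectra=np.zeros((6, axis.size)), wavenumber_axis=axis, spatial_shape=(2, 3))
        img = integration_map(cube, (2830, 2900))
        assert img.pixels.shape == (2, 3)
        assert np.allclose(img.pixels, 0.0)

    def test_matches_per_pixel_oracle(self, raman_cube_with_truth):
        cube, _ = raman_cube_with_truth
        img = integration_map(cube, (2830, 2900))
        flat = img.pixels.ravel()
        for i in (0, 57, 123, 399):
            assert flat[i] == pytest.approx(
                band_integrate(cube.spectra[i], cube.wavenumber_axis, (2830, 2900))
            )

    def test_lipid_pixel_bright_in_lipid_window_only(self, raman_cube_with_truth):
        cube, truth = raman_cube_with_truth
        lipid_map = integration_map(cube, (2830, 2900)).pixels
        lb_mask = truth["class_map"] == "lb"
        assert lipid_map[lb_mask].mean() > 10 * abs(lipid_map[truth["class_map"] == "background"].mean())


class TestKmeansSegment:
    def test_separable_cube_recovered_exactly(self, raman_cube_with_truth):
        cube, truth = raman_cube_with_truth
        despiked, _ = remove_cosmic_rays(cube)
        seg = kmeans_segment(despiked, k=4, seed=11)
        ari = adjusted_rand_score(
            truth["class_map"].ravel().astype(str), np.asarray(seg.class_labels).astype(str)
        )
        assert ari >= 0.95
        assert set(seg.class_labels) == {"background", "cytoplasm", "lb", "nucleus"}

    def test_pixel_permutation_equivariance(self, raman_cube_with_truth):
        cube, _ = raman_cube_with_truth
        despiked, _ = remove_cosmic_rays(cube)
        seg = kmeans_segment(despiked, k=4, seed=11)
        rng = np.random.default_rng(3)
        perm = rng.permutation(despiked.n_pixels)
        permuted = SpectralCube(
            spectra=despiked.spectra[perm],
            wavenumber_axis=despiked.wavenumber_axis,
            spatial_shape=despiked.spatial_shape,
        )
        seg_p = kmeans_segment(permuted, k=4, seed=11)
        assert list(np.asarray(seg_p.class_labels)) == list(np.asarray(seg.class_labels)[perm])

    def test_two_class_cube_exact(self, axis):
        comps = synthetic.default_spectral_components(axis)
        layout = np.empty((6, 6), dtype=object)
        layout[:] = "background"
        layout[2:5, 2:5] = "lb"
        mixing = {"background": {}, "lb": {"lipid": 1.0}}
        cube, truth = synthetic.make_raman_cube(layout, mixing, noise_sd=0.0002, seed=2, components=comps)
        seg = kmeans_segment(cube, k=2, seed=1)
        labels = np.asarray(seg.class_labels).reshape(6, 6)
        assert np.all((labels == "lb") == (truth["class_map"] == "lb"))

    def test_k_below_two_rejected(self, raman_cube_with_truth):
        with pytest.raises(ValueError):
            kmeans_segment(raman_cube_with_truth[0], k=1, seed=0)

    def test_marker_collision_detected(self, axis):
        # two clusters, one of which wins both lipid and dna markers
        spec_hot = (
            synthetic.default_spectral_components(axis).components["lipid"]
            + synthetic.default_spectral_components(axis).components["dna"]
        )
        spectra = np.vstack([np.zeros_like(axis)] * 4 + [spec_hot] * 4)
        cube = SpectralCube(spectra=spectra, wavenumber_axis=axis, spatial_shape=(2, 4))
        with pytest.raises(MarkerCollisionError):
            kmeans_segment(cube, k=2, seed=0)


class TestClassMeans:
    def test_single_member_class_sd_zero(self, axis):
        cube = SpectralCube(
            spectra=np.ones((1, axis.size)),
            wavenumber_axis=axis,
            spatial_shape=(1, 1),
            class_labels=np.array(["lb"], dtype=object),
        )
        means = class_mean_spectra(cube)
        assert np.allclose(means["lb"][1], 0.0)

    def test_two_member_mean(self, axis):
        a, b = np.zeros(axis.size), np.ones(axis.size)
        cube = SpectralCube(
            spectra=np.vstack([a, b]),
            wavenumber_axis=axis,
            spatial_shape=(1, 2),
            class_labels=np.array(["x", "x"], dtype=object),
        )
        assert np.allclose(class_mean_spectra(cube)["x"][0], 0.5)

    def test_matches_loop_oracle(self, raman_cube_with_truth):
        cube, truth = raman_cube_with_truth
        labelled = SpectralCube(
            spectra=cube.spectra,
            wavenumber_axis=cube.wavenumber_axis,
            spatial_shape=cube.spatial_shape,
            class_labels=truth["class_map"].ravel(),
        )
        means = class_mean_spectra(labelled)
        flat = truth["class_map"].ravel()
        for cls in ("lb", "cytoplasm"):
            rows = [cube.spectra[i] for i in range(cube.n_pixels) if flat[i] == cls]
            assert np.allclose(means[cls][0], np.mean(rows, axis=0))


class TestUnsaturation:
    def test_equal_area_bands_give_one(self, axis):
        # bands well inside their windows (sigma 5 vs half-widths 20/25)
        spec = np.exp(-((axis - 1660.0) ** 2) / (2 * 5.0**2)) + np.exp(
            -((axis - 1440.0) ** 2) / (2 * 5.0**2)
        )
        assert unsaturation_ratio(spec, axis) == pytest.approx(1.0, rel=5e-3)

    def test_scaling_invariance(self, fatty_refs):
        ax = fatty_refs.wavenumber_axis
        spec = fatty_refs.components["linoleic (18:2)"]
        assert unsaturation_ratio(3.7 * spec, ax) == pytest.approx(
            unsaturation_ratio(spec, ax), rel=1e-12
        )

    def test_zero_denominator_fails(self, axis):
        with pytest.raises(ZeroDivisionError):
            unsaturation_ratio(np.zeros_like(axis), axis)


class TestCalibration:
    @pytest.fixture
    def calibration(self, fatty_refs):
        by_count = {
            1: fatty_refs.components["oleic (18:1)"],
            2: fatty_refs.components["linoleic (18:2)"],
            3: fatty_refs.components["alpha-linolenic (18:3)"],
        }
        return fit_unsaturation_calibration(by_count, fatty_refs.wavenumber_axis), by_count

    def test_two_point_line_through_origin(self, fatty_refs):
        ax = fatty_refs.wavenumber_axis
        by_count = {
            1: fatty_refs.components["oleic (18:1)"],
            2: fatty_refs.components["linoleic (18:2)"],
        }
        cal = fit_unsaturation_calibration(by_count, ax)
        r1 = unsaturation_ratio(by_count[1], ax)
        assert cal.slope == pytest.approx(r1, rel=1e-9)
        assert cal.intercept == pytest.approx(0.0, abs=1e-12)

    def test_round_trip_on_references(self, calibration, fatty_refs):
        cal, by_count = calibration
        ax = fatty_refs.wavenumber_axis
        for count, spec in by_count.items():
            assert cal.estimate_double_bonds(unsaturation_ratio(spec, ax)) == pytest.approx(
                count, abs=1e-9
            )

    def test_equal_mixture_estimates_mid_count(self, calibration, fatty_refs):
        cal, by_count = calibration
        ax = fatty_refs.wavenumber_axis
        mixture = 0.5 * by_count[1] + 0.5 * by_count[2]
        assert cal.estimate_double_bonds(unsaturation_ratio(mixture, ax)) == pytest.approx(
            1.5, abs=1e-9
        )

    def test_degenerate_references_fail(self, fatty_refs):
        with pytest.raises(ValueError):
            fit_unsaturation_calibration(
                {1: fatty_refs.components["oleic (18:1)"]}, fatty_refs.wavenumber_axis
            )


class TestAnova:
    def test_identical_groups_f_zero(self):
        g = {"control": [1.0, 1.2, 0.9], "a": [1.0, 1.2, 0.9], "b": [1.0, 1.2, 0.9]}
        res = anova_groups(g, control="control")
        assert res["F"] == pytest.approx(0.0, abs=1e-12)
        assert res["p"] == pytest.approx(1.0)

    def test_two_groups_f_equals_t_squared(self):
        rng = np.random.default_rng(2)
        a = rng.normal(0, 1, 10).tolist()
        b = rng.normal(0.8, 1, 12).tolist()
        res = anova_groups({"control": a, "treated": b}, control="control")
        t, _ = sps.ttest_ind(a, b)
        assert res["F"] == pytest.approx(t**2, rel=1e-9)

    def test_shifting_a_group_increases_f(self):
        rng = np.random.default_rng(3)
        base = {"control": rng.normal(1, 0.1, 8), "x": rng.normal(1, 0.1, 8)}
        f0 = anova_groups(base, control="control")["F"]
        shifted = {"control": base["control"], "x": base["x"] + 0.5}
        f1 = anova_groups(shifted, control="control")["F"]
        assert f1 > f0

    def test_insufficient_n_rejected(self):
        with pytest.raises(ValueError):
            anova_groups({"control": [1.0], "x": [1.0, 2.0]}, control="control")


class TestPca:
    def test_identical_spectra_zero_variance(self, axis):
        spectra = np.tile(np.sin(axis / 200.0), (5, 1))
        res = pca_cytoplasm(spectra, axis)
        assert np.allclose(res.explained_variance, 0.0, atol=1e-12)
        assert np.allclose(res.scores, 0.0, atol=1e-6)

    def test_rank_one_variation_dominates_pc1(self, axis):
        rng = np.random.default_rng(4)
        base = np.exp(-((axis - 1200.0) ** 2) / (2 * 100.0**2))
        direction = np.exp(-((axis - 1600.0) ** 2) / (2 * 30.0**2))
        coeffs = rng.normal(0, 1.0, 20)
        spectra = base[None, :] + coeffs[:, None] * direction[None, :]
        spectra += rng.normal(0, 0.001, spectra.shape)
        res = pca_cytoplasm(spectra, axis)
        assert res.explained_variance_ratio[0] >= 0.95

    def test_reconstruction_and_variance_bookkeeping(self, axis):
        rng = np.random.default_rng(5)
        spectra = rng.random((8, axis.size))
        res = pca_cytoplasm(spectra, axis, n_components=7)
        centered = spectra[:, (axis >= 600) & (axis <= 1800)] - res.mean
        recon = res.scores @ res.loadings
        assert np.allclose(recon, centered, atol=1e-8)
        assert np.allclose(res.scores.mean(axis=0), 0.0, atol=1e-9)
        total_var = centered.var(axis=0, ddof=1).sum()
        assert np.sum(res.explained_variance) == pytest.approx(total_var, rel=1e-9)

    def test_sign_convention(self, axis):
        rng = np.random.default_rng(6)
        spectra = rng.random((6, axis.size))
        res = pca_cytoplasm(spectra, axis)
        for row in res.loadings:
            assert row[np.argmax(np.abs(row))] > 0

    def test_too_few_spectra_rejected(self, axis):
        with pytest.raises(ValueError):
            pca_cytoplasm(np.random.default_rng(0).random((2, axis.size)), axis)
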