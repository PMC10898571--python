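"""Normalization, difference spectra, PLS calibration and regression LOD."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import drsopt as d
from drsopt.calibration import (
    NormalizationError,
    collagen_band_area,
    difference_spectrum,
    fit_pls,
    fit_regression_lod,
    load_calibration,
    normalize_to_polystyrene,
    predict_thickness,
    save_calibration,
)
from drsopt.synth import PAPER_THICKNESSES_UM


@pytest.fixture(scope="module")
def composite_pair(noise_free_spec):
    wm = d.WeightModel()
    fbr = d.make_composite_spectrum(wm.weights_at(100.0), noise_free_spec)
    ic = d.make_composite_spectrum(wm.weights_at(0.0), noise_free_spec)
    return fbr, ic


class TestNormalization:
    def test_window_spans_unit_interval(self, composite_pair):
        fbr, _ = composite_pair
        norm = normalize_to_polystyrene(fbr)
        w = norm.counts[norm.band_slice((990.0, 1020.0))]
        assert w.min() == pytest.approx(0.0, abs=1e-12)
        assert w.max() == pytest.approx(1.0, abs=1e-12)

    @given(st.floats(0.1, 50.0), st.floats(-100.0, 100.0))
    def test_affine_invariance(self, c, offset):
        spec = d.make_reference_spectrum(
            "polystyrene", d.GeneratorSpec(poisson_noise=False))
        base = normalize_to_polystyrene(spec)
        scaled = normalize_to_polystyrene(spec.copy_with(c * spec.counts + offset))
        assert np.allclose(base.counts, scaled.counts, atol=1e-9)

    def test_matches_independent_minmax(self, noise_free_spec):
        spec = d.make_composite_spectrum(
            d.WeightModel().weights_at(80.0),
            d.GeneratorSpec(poisson_noise=True, seed=7))
        norm = normalize_to_polystyrene(spec)
        w = (spec.wavenumbers >= 990) & (spec.wavenumbers <= 1020)
        lo, hi = spec.counts[w].min(), spec.counts[w].max()
        assert np.allclose(norm.counts, (spec.counts - lo) / (hi - lo),
                           atol=1e-12)

    def test_flat_window_rejected(self):
        wn = 800.0 + 2.0 * np.arange(200)
        with pytest.raises(NormalizationError):
            normalize_to_polystyrene(d.Spectrum(wn, np.ones(200)))


class TestDifferenceSpectrum:
    def test_identical_inputs_cancel(self, composite_pair):
        fbr, _ = composite_pair
        diff = difference_spectrum(fbr, fbr)
        assert np.all(diff.counts == 0.0)

    def test_recovers_added_collagen(self, noise_free_spec, composite_pair):
        _, ic = composite_pair
        coll = d.make_reference_spectrum("collagen", noise_free_spec)
        alpha = 0.37
        fbr = ic.copy_with(ic.counts + alpha * coll.counts)
        diff = difference_spectrum(fbr, ic)
        assert np.allclose(diff.counts, alpha * coll.counts, rtol=1e-10)

    def test_polystyrene_features_cancel(self, composite_pair):
        fbr, ic = composite_pair
        diff = difference_spectrum(normalize_to_polystyrene(fbr),
                                   normalize_to_polystyrene(ic))
        m = (diff.wavenumbers >= 995) & (diff.wavenumbers <= 1015)
        residual = np.abs(diff.counts[m]).sum()
        assert residual < 0.05 * collagen_band_area(diff)

    def test_axis_mismatch_rejected(self, composite_pair):
        fbr, _ = composite_pair
        other = d.Spectrum(fbr.wavenumbers + 1.0, fbr.counts)
        with pytest.raises(ValueError):
            difference_spectrum(fbr, other)


class TestBandArea:
    def test_zero_difference_zero_area(self, composite_pair):
        fbr, _ = composite_pair
        assert collagen_band_area(difference_spectrum(fbr, fbr)) == 0.0

    def test_linear_in_collagen_amount(self, noise_free_spec, composite_pair):
        _, ic = composite_pair
        coll = d.make_reference_spectrum("collagen", noise_free_spec)
        areas = []
        for alpha in (0.1, 0.2, 0.4):
            diff = difference_spectrum(ic.copy_with(ic.counts + alpha * coll.counts), ic)
            areas.append(collagen_band_area(diff))
        assert areas[1] == pytest.approx(2 * areas[0], rel=1e-9)
        assert areas[2] == pytest.approx(4 * areas[0], rel=1e-9)


class TestPLS:
    def test_exact_linear_structure_is_solved_by_one_component(
            self, noise_free_spec):
        coll = d.make_reference_spectrum("collagen", noise_free_spec)
        pairs = [(coll.copy_with(coll.counts * (t / 100.0)), t)
                 for t in PAPER_THICKNESSES_UM for _ in range(2)]
        res = fit_pls(pairs)
        assert res.n_components == 1
        assert res.loo_rmse_um < 1e-6

    def test_paper_training_design(self, snr4_count_scale, make_pairs):
        # 8 thicknesses × 2 replicates = 16 difference spectra
        series = d.make_thickness_series(
            d.GeneratorSpec(seed=11, count_scale=snr4_count_scale))
        pairs = make_pairs(series)
        assert len(pairs) == 16
        res = fit_pls(pairs)
        assert res.loo_rmse_um > 0
        assert "PLS thickness calibration" in res.summary()

    def test_degenerate_response_rejected(self, noise_free_spec):
        coll = d.make_reference_spectrum("collagen", noise_free_spec)
        pairs = [(coll, 50.0)] * 6
        with pytest.raises(ValueError):
            fit_pls(pairs)

    def test_training_set_rmse_not_worse_than_loo(self, snr4_count_scale,
                                                  make_pairs):
        series = d.make_thickness_series(
            d.GeneratorSpec(seed=12, count_scale=snr4_count_scale))
        pairs = make_pairs(series)
        res = fit_pls(pairs)
        _, rmse = predict_thickness(res, [s for s, _ in pairs],
                                    [t for _, t in pairs])
        assert rmse <= res.loo_rmse_um

    def test_independent_test_rmse_tracks_loo(self, snr4_count_scale,
                                              make_pairs):
        loo, test = [], []
        for seed in range(8):
            tr = d.make_thickness_series(
                d.GeneratorSpec(seed=700 + seed, count_scale=snr4_count_scale))
            te = d.make_thickness_series(
                d.GeneratorSpec(seed=800 + seed, count_scale=snr4_count_scale))
            res = fit_pls(make_pairs(tr))
            loo.append(res.loo_rmse_um)
            te_pairs = make_pairs(te)
            _, rmse = predict_thickness(res, [s for s, _ in te_pairs],
                                        [t for _, t in te_pairs])
            test.append(rmse)
        ratio = np.mean(test) / np.mean(loo)
        assert 0.5 < ratio < 1.5

    def test_parameter_recovery_bias_is_negligible(self, make_pairs):
        # shrinkage bias stays within max(2 SE, 3 µm) at every thickness
        biases = {t: [] for t in PAPER_THICKNESSES_UM}
        for seed in range(20):
            series = d.make_thickness_series(d.GeneratorSpec(seed=900 + seed))
            res = fit_pls(make_pairs(series))
            for rec, pred in zip(series.records, res.loo_predictions_um):
                biases[rec.thickness_um].append(pred - rec.thickness_um)
        for t, b in biases.items():
            b = np.asarray(b)
            se = b.std(ddof=1) / np.sqrt(len(b))
            assert abs(b.mean()) <= max(2 * se, 3.0), f"bias at {t} um"

    def test_rmse_improves_with_photon_count(self, snr4_count_scale,
                                             make_pairs):
        # 4× the counts should halve the thickness RMSE (shot-noise limit)
        def mean_rmse(scale, base_seed):
            out = []
            for seed in range(8):
                series = d.make_thickness_series(
                    d.GeneratorSpec(seed=base_seed + seed, count_scale=scale))
                out.append(fit_pls(make_pairs(series)).loo_rmse_um)
            return np.mean(out)

        low = mean_rmse(snr4_count_scale, 1000)
        high = mean_rmse(4 * snr4_count_scale, 1100)
        assert 1.5 < low / high < 2.7

    def test_pls_not_worse_than_band_regression(self, snr4_count_scale,
                                                make_pairs):
        pls, band = [], []
        for seed in range(8):
            series = d.make_thickness_series(
                d.GeneratorSpec(seed=1200 + seed, count_scale=snr4_count_scale))
            pairs = make_pairs(series)
            pls.append(fit_pls(pairs).loo_rmse_um)
            areas = [(collagen_band_area(s), t) for s, t in pairs]
            reg = fit_regression_lod(areas)
            band.append(reg.residual_rmse / abs(reg.slope))
        assert np.mean(pls) <= 1.1 * np.mean(band)

    def test_archive_round_trip(self, snr4_count_scale, make_pairs, tmp_path):
        series = d.make_thickness_series(
            d.GeneratorSpec(seed=5, count_scale=snr4_count_scale))
        pairs = make_pairs(series)
        res = fit_pls(pairs)
        save_calibration(res, tmp_path / "cal.json")
        loaded = load_calibration(tmp_path / "cal.json")
        spectra = [s for s, _ in pairs]
        assert np.allclose(loaded.predict(spectra), res.predict(spectra),
                           rtol=1e-10)


class TestRegressionLOD:
    def test_perfect_line(self):
        pairs = [(0.5 * t + 2.0, t) for t in (10.0, 50.0, 90.0, 130.0)]
        reg = fit_regression_lod(pairs)
        assert reg.r_squared == pytest.approx(1.0)
        assert reg.t_lod_um == pytest.approx(0.0, abs=1e-9)

    def test_formula(self):
        # slope 1 area-unit/µm with residual RMSE 10 → 16.45 µm
        rng = np.random.default_rng(0)
        reg = d.RegressionLOD(slope=1.0, intercept=0.0, r_squared=0.9,
                              residual_rmse=10.0, criterion=1.645)
        assert reg.t_lod_um == pytest.approx(16.45)
        assert reg.t_lod_unit_um == pytest.approx(10.0)

    def test_matches_closed_form_ols(self, rng):
        thick = np.array([15.0, 37.0, 62.0, 83.0] * 3)
        area = 0.02 * thick + rng.normal(0, 0.15, thick.size)
        reg = fit_regression_lod(list(zip(area, thick)))
        # normal-equation oracle
        X = np.column_stack([np.ones_like(thick), thick])
        beta = np.linalg.solve(X.T @ X, X.T @ area)
        resid = area - X @ beta
        ss_tot = np.sum((area - area.mean()) ** 2)
        assert reg.intercept == pytest.approx(beta[0], rel=1e-10)
        assert reg.slope == pytest.approx(beta[1], rel=1e-10)
        assert reg.r_squared == pytest.approx(1 - resid @ resid / ss_tot,
                                              rel=1e-10)
        assert reg.residual_rmse == pytest.approx(
            np.sqrt(np.mean(resid**2)), rel=1e-10)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            fit_regression_lod([(1.0, 10.0), (2.0, 20.0)])
        with pytest.raises(ValueError):
            fit_regression_lod([(1.0, 10.0), (2.0, 10.0), (3.0, 10.0)])


class TestPipelineInvariance:
    @given(st.floats(0.2, 20.0))
    def test_gain_invariance_end_to_end(self, gain):
        # per-spectrum gain is removed by normalization before differencing
        spec = d.GeneratorSpec(poisson_noise=False)
        wm = d.WeightModel()
        fbr = d.make_composite_spectrum(wm.weights_at(120.0), spec)
        ic = d.make_composite_spectrum(wm.weights_at(0.0), spec)
        base = collagen_band_area(difference_spectrum(
            normalize_to_polystyrene(fbr), normalize_to_polystyrene(ic)))
        scaled = collagen_band_area(difference_spectrum(
            normalize_to_polystyrene(fbr.copy_with(gain * fbr.counts)),
            normalize_to_polystyrene(ic.copy_with(ic.counts / gain))))
        assert scaled == pytest.approx(base, rel=1e-9)
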