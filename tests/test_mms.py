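"""Similarity-spectrum processing, band deconvolution and melt analysis."""

import numpy as np
import pandas as pd
import pytest

from stabscreen import fixtures
from stabscreen.mms import (
    Band,
    BandModel,
    HOSComposition,
    SimilaritySpectrum,
    deconvolve_bands,
    default_band_model,
    fit_ec50,
    melt_analysis,
    normalize_spectrum,
    run_thermal_ramp,
    similarity_spectrum,
)
from stabscreen.synthdata import generate_ir_series

WN = np.arange(1588.0, 1712.0 + 1e-9, 1.0)


def _gauss(center, width, amp=1.0):
    return amp * np.exp(-0.5 * ((WN - center) / width) ** 2)


class TestNormalize:
    def test_factor_one_is_identity(self, rng):
        y = rng.normal(size=50)
        assert np.array_equal(normalize_spectrum(y, 1.0), y)

    def test_invertible(self, rng):
        y = rng.normal(size=50)
        back = normalize_spectrum(y, 0.63) * 0.63
        assert np.allclose(back, y, atol=1e-12)

    def test_fractions_invariant_to_factor(self):
        series = generate_ir_series(fixtures.ir_params("apo", noise_sd=0.0), 0)
        model = default_band_model()
        row = series.absorbance[0]
        f1 = deconvolve_bands(
            similarity_spectrum(WN, normalize_spectrum(row, 0.63)), model,
            refine=False).fractions
        f2 = deconvolve_bands(
            similarity_spectrum(WN, normalize_spectrum(row, 0.5)), model,
            refine=False).fractions
        for cls in f1:
            assert f1[cls] == pytest.approx(f2[cls], abs=1e-9)


class TestSimilaritySpectrum:
    def test_gaussian_peaks_at_band_center(self):
        sim = similarity_spectrum(WN, _gauss(1650.0, 8.0))
        assert WN[np.argmax(sim.values)] == pytest.approx(1650.0, abs=1.0)

    def test_flat_spectrum_is_all_zero(self):
        sim = similarity_spectrum(WN, np.full_like(WN, 0.7))
        assert np.allclose(sim.values, 0.0, atol=1e-12)

    def test_two_equal_bands_equal_heights(self):
        sim = similarity_spectrum(WN, _gauss(1620.0, 6.0) + _gauss(1680.0, 6.0))
        left = sim.values[WN < 1650].max()
        right = sim.values[WN >= 1650].max()
        assert left == pytest.approx(right, rel=0.02)

    def test_even_window_rejected(self):
        with pytest.raises(ValueError, match="odd"):
            similarity_spectrum(WN, _gauss(1650, 6.0), sg_window=18)

    def test_values_non_negative(self):
        sim = similarity_spectrum(WN, _gauss(1650.0, 6.0) - _gauss(1610.0, 5.0, 0.3))
        assert np.all(sim.values >= 0.0)


class TestDeconvolveBands:
    def test_self_recovery_from_model_bands(self):
        """A spectrum built directly from the model's own Gaussians is
        decomposed back into the generating fractions within 1e-3."""
        model = default_band_model()
        amps = {b.label: a for b, a in zip(
            model.bands, (0.1, 0.0, 0.7, 0.5, 0.45, 0.8, 1.0, 0.4, 0.3, 0.0))}
        spec = sum(_gauss(b.center, b.width, amps[b.label]) for b in model.bands)
        sim = SimilaritySpectrum(WN, spec)  # no derivative: Gaussian route
        comp = deconvolve_bands(sim, model, refine=False)
        areas = {b.label: amps[b.label] * b.width * np.sqrt(2 * np.pi)
                 for b in model.bands if b.structure_class != "side_chain"}
        total = sum(areas.values())
        expected = {}
        for b in model.bands:
            if b.structure_class == "side_chain":
                continue
            expected[b.structure_class] = expected.get(b.structure_class, 0.0) \
                + areas[b.label] / total
        for cls, frac in comp.fractions.items():
            assert frac == pytest.approx(expected[cls], abs=1e-3)

    def test_single_band_fraction_is_one(self):
        model = BandModel([Band("b", "native_beta", 1633.0)])
        sim = SimilaritySpectrum(WN, _gauss(1633.0, 6.0))
        comp = deconvolve_bands(sim, model)
        assert comp.fractions == {"native_beta": pytest.approx(1.0)}

    def test_three_to_one_area_ratio(self):
        model = BandModel([Band("b1", "native_beta", 1620.0),
                           Band("h1", "alpha_helix", 1680.0)])
        sim = SimilaritySpectrum(WN, _gauss(1620.0, 6.0, 3.0) + _gauss(1680.0, 6.0, 1.0))
        comp = deconvolve_bands(sim, model, refine=False)
        assert comp.fractions["native_beta"] == pytest.approx(0.75, abs=0.01)
        assert comp.fractions["alpha_helix"] == pytest.approx(0.25, abs=0.01)

    def test_scale_invariance(self):
        series = generate_ir_series(fixtures.ir_params("apo", noise_sd=0.0), 0)
        sim = similarity_spectrum(WN, series.absorbance[0])
        sim_scaled = similarity_spectrum(WN, 5.0 * series.absorbance[0])
        model = default_band_model()
        f1 = deconvolve_bands(sim, model, refine=False).fractions
        f2 = deconvolve_bands(sim_scaled, model, refine=False).fractions
        for cls in f1:
            assert f1[cls] == pytest.approx(f2[cls], abs=1e-9)

    def test_duplicate_bands_warn(self):
        model = BandModel([Band("a", "turn", 1667.0), Band("b", "turn", 1667.0)])
        sim = SimilaritySpectrum(WN, _gauss(1667.0, 6.0))
        with pytest.warns(UserWarning, match="duplicate"):
            deconvolve_bands(sim, model, refine=False)

    def test_fractions_sum_to_one_along_ramp(self):
        series = generate_ir_series(fixtures.ir_params("apo"), 3)
        comps, _, _ = run_thermal_ramp(series)
        for comp in comps:
            total = sum(comp.fractions.values())
            assert total == pytest.approx(1.0, abs=1e-6)
            assert all(0.0 <= v <= 1.0 for v in comp.fractions.values())


def _comp_from_fractions(fracs: dict) -> HOSComposition:
    table = pd.DataFrame(columns=["label", "structure_class", "center", "width",
                                  "amplitude", "area"])
    return HOSComposition(fracs, table)


class TestMeltAnalysis:
    def test_exact_logistic_midpoint(self):
        temps = np.arange(25.0, 76.0, 1.0)
        y = 0.1 + 0.4 / (1.0 + np.exp((55.0 - temps) / 2.0))
        comps = [_comp_from_fractions({"native_beta": v, "alpha_helix": 1 - v})
                 for v in y]
        res = melt_analysis(temps, comps, signal="fraction")
        assert res.per_class["native_beta"].tm == pytest.approx(55.0, abs=0.01)

    def test_flat_class_flagged(self):
        temps = np.arange(25.0, 76.0, 1.0)
        comps = [_comp_from_fractions({"turn": 0.5, "unordered": 0.5}) for _ in temps]
        res = melt_analysis(temps, comps, signal="fraction")
        assert np.isnan(res.per_class["turn"].tm)
        assert "flat" in res.per_class["turn"].flags

    def test_sigmoid_and_derivative_methods_agree_noiseless(self):
        series = generate_ir_series(fixtures.ir_params("apo", noise_sd=0.0), 0)
        _, sig, _ = run_thermal_ramp(series, method="sigmoid")
        _, der, _ = run_thermal_ramp(series, method="derivative")
        step = float(np.median(np.diff(series.temperatures)))
        assert abs(sig.per_class["native_beta"].tm
                   - der.per_class["native_beta"].tm) <= step

    def test_too_few_temperatures_rejected(self):
        temps = np.arange(25.0, 31.0, 1.0)
        comps = [_comp_from_fractions({"turn": 1.0}) for _ in temps]
        with pytest.raises(ValueError, match="8 temperatures"):
            melt_analysis(temps, comps, signal="fraction")

    def test_per_class_recovery_within_1C(self):
        """Default-noise apo ramp: every melting class's Tm lands within
        1 degC of its generating midpoint."""
        params = fixtures.ir_params("apo")
        series = generate_ir_series(params, 8)
        _, analysis, _ = run_thermal_ramp(series)
        truth = {}
        for b in params.band_truth:
            truth.setdefault(b.structure_class, b.melt_tm)
        for cls, tm_true in truth.items():
            assert analysis.per_class[cls].tm == pytest.approx(tm_true, abs=1.0), cls


class TestFitEC50:
    CONCS = (0.0, 100.0, 250.0, 500.0, 1000.0, 2000.0)

    def test_noiseless_exact_recovery(self):
        pts = [(c, 53.4 + 6.0 * c / (c + 400.0)) for c in self.CONCS]
        fit = fit_ec50(pts)
        assert fit.tm0 == pytest.approx(53.4, abs=1e-6)
        assert fit.delta_tm_max == pytest.approx(6.0, abs=1e-6)
        assert fit.ec50 == pytest.approx(400.0, rel=1e-6)

    def test_constant_tm_flagged_unidentifiable(self):
        fit = fit_ec50([(c, 53.4) for c in self.CONCS])
        assert fit.delta_tm_max == pytest.approx(0.0, abs=1e-9)
        assert "no_stabilization" in fit.flags
        assert np.isnan(fit.ec50)

    def test_matches_grid_search_oracle(self):
        pts = [(c, 53.4 + 6.0 * c / (c + 400.0)) for c in self.CONCS]
        fit = fit_ec50(pts)
        conc = np.array([p[0] for p in pts])
        tm = np.array([p[1] for p in pts])
        d_grid = np.linspace(4.0, 8.0, 200)
        e_grid = np.linspace(100.0, 800.0, 200)
        model = 53.4 + d_grid[:, None, None] * conc / (conc + e_grid[None, :, None])
        sse = ((model - tm) ** 2).sum(axis=2)
        i, j = np.unravel_index(np.argmin(sse), sse.shape)
        assert abs(fit.delta_tm_max - d_grid[i]) <= np.diff(d_grid)[0] + 1e-12
        assert abs(fit.ec50 - e_grid[j]) <= np.diff(e_grid)[0] + 1e-12

    def test_zero_point_required(self):
        with pytest.raises(ValueError, match="apo"):
            fit_ec50([(100.0, 54.0), (200.0, 55.0), (400.0, 56.0), (800.0, 57.0)])
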