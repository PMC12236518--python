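"""STD amplification factors, buildup/Langmuir fits and K_d combination."""

import numpy as np
import pytest

from stabscreen import fixtures
from stabscreen.stdnmr import (
    EpitopeRegion,
    LangmuirFit,
    combine_kd,
    compute_std_af,
    fit_buildup,
    fit_langmuir,
    integrate_region,
    run_std_pipeline,
)
from stabscreen.synthdata import generate_std_dataset

DESIGN_TIMES = (0.5, 0.75, 1.0, 1.5, 2.0, 2.5, 3.5, 5.0)


class TestComputeStdAf:
    @pytest.mark.parametrize(
        "i_diff, i_ref, L, P, expected",
        [
            (0.0, 100.0, 500.0, 20.0, 0.0),
            (7.0, 7.0, 30.0, 30.0, 1.0),
            (1.0, 100.0, 1000.0, 20.0, 0.5),  # epsilon=50, ratio=0.01
        ],
    )
    def test_arithmetic(self, i_diff, i_ref, L, P, expected):
        assert compute_std_af(i_diff, i_ref, L, P) == pytest.approx(expected)

    def test_nonpositive_reference_rejected(self):
        with pytest.raises(ValueError):
            compute_std_af(1.0, 0.0, 100.0, 20.0)


class TestIntegrateRegion:
    REGION = EpitopeRegion("amide", 8.39, 8.42)

    def test_zero_spectrum(self):
        ppm = np.linspace(8.0, 9.0, 2001)
        assert integrate_region(ppm, np.zeros_like(ppm), self.REGION) == 0.0

    def test_unit_rectangle(self):
        ppm = np.round(np.arange(8.0, 9.0, 0.001), 4)
        intensity = ((ppm >= 8.39) & (ppm <= 8.42)).astype(float)
        area = integrate_region(ppm, intensity, self.REGION)
        assert area == pytest.approx(0.03, rel=1e-9)

    def test_lorentzian_matches_closed_form(self):
        """Trapezoidal integral of a Lorentzian versus its arctangent
        antiderivative, within 1%."""
        ppm = np.arange(7.0, 8.5, 0.0005)
        x0, gamma, amp = 7.80, 0.02, 5.0
        region = EpitopeRegion("e2", 7.78, 7.83)
        y = amp * gamma**2 / ((ppm - x0) ** 2 + gamma**2)
        expected = amp * gamma * (np.arctan((region.ppm_hi - x0) / gamma)
                                  - np.arctan((region.ppm_lo - x0) / gamma))
        assert integrate_region(ppm, y, region) == pytest.approx(expected, rel=0.01)

    def test_region_outside_spectrum_rejected(self):
        ppm = np.linspace(6.0, 7.0, 100)
        with pytest.raises(ValueError, match="spectral width"):
            integrate_region(ppm, np.ones_like(ppm), self.REGION)

    def test_descending_ppm_supported(self):
        ppm = np.arange(9.0, 8.0, -0.001)
        y = np.ones_like(ppm)
        assert integrate_region(ppm, y, self.REGION) == pytest.approx(0.03, rel=1e-6)


class TestFitBuildup:
    def test_noiseless_recovery(self):
        pts = [(t, 1.0 * (1 - np.exp(-0.8 * t))) for t in DESIGN_TIMES]
        fit = fit_buildup(pts)
        assert fit.af_max == pytest.approx(1.0, abs=1e-6)
        assert fit.k_sat == pytest.approx(0.8, abs=1e-6)
        assert fit.af0 == pytest.approx(0.8, abs=1e-6)

    def test_all_zero_signal(self):
        fit = fit_buildup([(t, 0.0) for t in DESIGN_TIMES])
        assert fit.af_max == 0.0
        assert fit.af0 == 0.0

    def test_matches_grid_search_oracle(self):
        """200x200 brute-force SSE grid over (af_max, k_sat) finds the same
        minimum as the optimizer, within one grid step."""
        true = (1.3, 0.6)
        pts = [(t, true[0] * (1 - np.exp(-true[1] * t))) for t in DESIGN_TIMES]
        fit = fit_buildup(pts)
        t = np.array([p[0] for p in pts])
        af = np.array([p[1] for p in pts])
        a_grid = np.linspace(0.5, 2.0, 200)
        k_grid = np.linspace(0.1, 2.0, 200)
        model = a_grid[:, None, None] * (1 - np.exp(-k_grid[None, :, None] * t))
        sse = ((model - af) ** 2).sum(axis=2)
        i, j = np.unravel_index(np.argmin(sse), sse.shape)
        assert abs(fit.af_max - a_grid[i]) <= np.diff(a_grid)[0] + 1e-12
        assert abs(fit.k_sat - k_grid[j]) <= np.diff(k_grid)[0] + 1e-12

    def test_too_few_times_rejected(self):
        with pytest.raises(ValueError):
            fit_buildup([(0.5, 0.1), (1.0, 0.2)])

    def test_decreasing_data_rejected(self):
        with pytest.raises(ValueError, match="decreases"):
            fit_buildup([(0.5, 1.0), (1.0, 0.6), (2.0, 0.2)])


def _af0(alpha, kd, conc):
    return alpha * conc / (conc + kd)


class TestFitLangmuir:
    CONCS = (200.0, 400.0, 600.0, 800.0, 1000.0)

    def test_noiseless_recovery_171(self):
        pts = [(c, _af0(3.0, 171.0, c), None) for c in self.CONCS]
        fit = fit_langmuir(pts)
        assert fit.kd == pytest.approx(171.0, rel=1e-4)
        assert fit.alpha_std == pytest.approx(3.0, rel=1e-4)

    def test_half_saturation_identity(self):
        pts = [(c, _af0(2.4, 350.0, c), None) for c in self.CONCS]
        fit = fit_langmuir(pts)
        at_kd = fit.alpha_std * fit.kd / (fit.kd + fit.kd)
        assert at_kd == pytest.approx(fit.alpha_std / 2)

    def test_plateau_is_flagged_saturated(self):
        pts = [(c, 1.7, None) for c in self.CONCS]
        fit = fit_langmuir(pts)
        assert "saturated" in fit.flags

    def test_narrow_span_warns(self):
        pts = [(c, _af0(1.0, 100.0, c), None) for c in (500.0, 600.0, 700.0)]
        with pytest.warns(UserWarning, match="2-fold"):
            fit_langmuir(pts)

    def test_matches_grid_search_oracle(self):
        pts = [(c, _af0(3.0, 171.0, c), None) for c in self.CONCS]
        fit = fit_langmuir(pts)
        conc = np.array([p[0] for p in pts])
        af0 = np.array([p[1] for p in pts])
        a_grid = np.linspace(2.0, 4.0, 200)
        kd_grid = np.linspace(50.0, 400.0, 200)
        model = a_grid[:, None, None] * conc / (conc + kd_grid[None, :, None])
        sse = ((model - af0) ** 2).sum(axis=2)
        i, j = np.unravel_index(np.argmin(sse), sse.shape)
        assert abs(fit.alpha_std - a_grid[i]) <= np.diff(a_grid)[0] + 1e-12
        assert abs(fit.kd - kd_grid[j]) <= np.diff(kd_grid)[0] + 1e-12


class TestCombineKd:
    def test_equal_estimates_pass_through(self):
        fits = [LangmuirFit(1.0, 376.0, 20.0, 0.0, e) for e in "abc"]
        est = combine_kd(fits)
        assert est.kd_combined == pytest.approx(376.0)

    def test_single_fit_unchanged(self):
        est = combine_kd([LangmuirFit(1.0, 210.0, 15.0, 0.0, "a")])
        assert est.kd_combined == pytest.approx(210.0)
        assert est.kd_combined_se == pytest.approx(15.0)

    def test_inverse_variance_weighting(self):
        fits = [LangmuirFit(1.0, 100.0, 10.0, 0.0, "a"),
                LangmuirFit(1.0, 300.0, 30.0, 0.0, "b")]
        est = combine_kd(fits)
        assert est.kd_combined == pytest.approx(120.0)

    def test_combined_within_span(self):
        fits = [LangmuirFit(1.0, kd, se, 0.0, e)
                for kd, se, e in ((150.0, 12.0, "a"), (200.0, 25.0, "b"), (180.0, 9.0, "c"))]
        est = combine_kd(fits)
        assert 150.0 <= est.kd_combined <= 200.0

    def test_all_nonfinite_se_falls_back_unweighted(self):
        fits = [LangmuirFit(1.0, 100.0, np.nan, 0.0, "a"),
                LangmuirFit(1.0, 300.0, np.nan, 0.0, "b")]
        with pytest.warns(UserWarning, match="unweighted"):
            est = combine_kd(fits)
        assert est.kd_combined == pytest.approx(200.0)


class TestPipeline:
    def test_zero_noise_recovers_fixture_kd(self):
        truth = fixtures.binding_truth("KG-96")
        est = run_std_pipeline(generate_std_dataset(truth, 0.0, 0))
        assert est.kd_combined == pytest.approx(171.0, rel=1e-3)

    def test_design_produces_15_buildups_and_3_langmuirs(self):
        truth = fixtures.binding_truth("KG-96")
        ds = generate_std_dataset(truth, 0.0, 0)
        assert len(ds.records) == 3 * 5 * 8
        est = run_std_pipeline(ds)
        assert len(est.buildup_fits) == 15
        assert len(est.per_epitope) == 3

    def test_scale_equivariance(self):
        """Scaling all difference integrals scales alpha_STD but leaves
        K_d untouched."""
        truth = fixtures.binding_truth("KG-96")
        ds = generate_std_dataset(truth, 0.0, 0)
        est = run_std_pipeline(ds)
        scaled = ds.records.copy()
        scaled["i_diff"] *= 3.7
        est2 = run_std_pipeline(type(ds)(scaled, ds.protein_conc))
        assert est2.kd_combined == pytest.approx(est.kd_combined, rel=1e-6)
        for a, b in zip(est.per_epitope, est2.per_epitope):
            assert b.alpha_std == pytest.approx(3.7 * a.alpha_std, rel=1e-6)

    def test_noisy_recovery_and_coverage(self):
        """Over 50 seeded 3%-CV simulations the median relative K_d error
        stays below 10% and the reported SE covers truth in >= 80%."""
        truth = fixtures.binding_truth("KG-96")
        errs, covered = [], []
        for seed in range(50):
            est = run_std_pipeline(generate_std_dataset(truth, 0.03, seed))
            errs.append(abs(est.kd_combined - truth.kd_true) / truth.kd_true)
            covered.append(abs(est.kd_combined - truth.kd_true)
                           <= 1.96 * est.kd_combined_se)
        assert float(np.median(errs)) < 0.10
        assert np.mean(covered) >= 0.80
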