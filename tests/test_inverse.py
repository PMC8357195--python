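import numpy as np
import pytest

from drslut.inverse import (
    FitError,
    chi2_percent,
    fit,
    percent_error_curve,
    predict_reflectance,
    validate_luts,
)
from drslut.optics import ScatteringModel, TissueAbsorberModel, load_extinction_table
from drslut.phantoms import (
    forward_reflectance,
    hb_stock_mua,
    synthesize_tissue_spectrum,
)
from drslut.spectral import WAVELENGTH_GRID_NM, Spectrum

WL = WAVELENGTH_GRID_NM


def refl(values, sds=2.0):
    return Spectrum(WL, np.asarray(values, float), "reflectance", sds)


@pytest.fixture(scope="module")
def lut2(study):
    return study["luts"][2.0]


@pytest.fixture(scope="module")
def stock():
    return hb_stock_mua(WL)


class TestPrediction:
    def test_zero_absorber_depends_only_on_scattering(self, lut2, stock):
        base = {"musp0": 8.0, "b": 1.0, "c": 0.0}
        a = predict_reflectance(base, "phantom", lut2, WL, stock_mua=stock)
        b = predict_reflectance({**base, "musp0": 8.0}, "phantom", lut2, WL,
                                stock_mua=stock)
        assert np.array_equal(a.values, b.values)
        higher = predict_reflectance({**base, "musp0": 10.0}, "phantom", lut2,
                                     WL, stock_mua=stock)
        assert not np.array_equal(a.values, higher.values)

    def test_tissue_nests_phantom_at_zero_absorber(self, lut2, stock, ext_table):
        phantom = predict_reflectance(
            {"musp0": 8.0, "b": 1.0, "c": 0.0}, "phantom", lut2, WL,
            stock_mua=stock,
        )
        tissue = predict_reflectance(
            {"musp0": 8.0, "b": 1.0, "thc": 0.0, "sto2": 0.5, "rvess": 5.0},
            "tissue", lut2, WL, ext=ext_table,
        )
        assert np.allclose(phantom.values, tissue.values, rtol=1e-12)

    def test_prediction_at_truth_matches_noiseless_spectrum(self, lut2, stock):
        c = 3.6 / stock.max()
        musp = 8.5 * (WL / 630.0) ** -0.9
        mua = c * stock
        measured = forward_reflectance(musp, mua, 2.0)
        pred = predict_reflectance(
            {"musp0": 8.5, "b": 0.9, "c": c}, "phantom", lut2, WL,
            stock_mua=stock,
        )
        inside = (musp > 4.2) & (musp < 11.8)
        rel = np.abs(pred.values - measured)[inside] / measured[inside]
        assert np.median(rel) < 0.02


class TestChiSquare:
    def test_perfect_fit_is_zero(self):
        m = refl(np.linspace(0.1, 0.2, WL.size))
        assert chi2_percent(m, m) == 0.0

    def test_uniform_ten_percent_miss_is_one_percent(self):
        m = refl(np.linspace(0.1, 0.2, WL.size))
        f = refl(m.values * 1.1)
        assert chi2_percent(f, m) == pytest.approx(1.0, rel=1e-9)

    def test_uniform_thirty_percent_miss_fails_gate(self):
        m = refl(np.linspace(0.1, 0.2, WL.size))
        f = refl(m.values * 1.3)
        chi2 = chi2_percent(f, m)
        assert chi2 == pytest.approx(9.0, rel=1e-9)
        assert chi2 > 5.0

    def test_zero_measured_rejected(self):
        z = refl(np.zeros(WL.size))
        with pytest.raises(FitError):
            chi2_percent(z, z)


class TestPercentError:
    def test_exact_curve_is_zero(self):
        e = np.linspace(1, 2, 100)
        assert percent_error_curve(e, e) == 0.0

    def test_constant_relative_offset(self):
        e = np.linspace(1, 2, 100)
        assert percent_error_curve(e, 1.05 * e) == pytest.approx(5.0)

    def test_alternating_errors_do_not_cancel(self):
        e = np.ones(100)
        f = e * np.where(np.arange(100) % 2 == 0, 1.1, 0.9)
        assert percent_error_curve(e, f) == pytest.approx(10.0)

    def test_empty_mask_rejected(self):
        with pytest.raises(FitError):
            percent_error_curve(np.zeros(10), np.ones(10), min_expected=0.05)


class TestPhantomFit:
    def test_noiseless_parameter_recovery(self, lut2, stock):
        scaled_stock = stock * (7.0 / stock.max())  # peak 7 so C=0.5 stays in domain
        truth = {"musp0": 8.5, "b": 1.0, "c": 0.5}
        musp = truth["musp0"] * (WL / 630.0) ** (-truth["b"])
        measured = refl(forward_reflectance(musp, truth["c"] * scaled_stock, 2.0))
        result = fit(measured, "phantom", lut2, stock_mua=scaled_stock)
        assert result.params["musp0"] == pytest.approx(8.5, rel=0.02)
        assert result.params["b"] == pytest.approx(1.0, abs=0.08)
        assert result.params["c"] == pytest.approx(0.5, rel=0.02)
        assert result.accepted

    def test_init_insensitivity(self, lut2, stock):
        c = 3.6 / stock.max()
        musp = 7.5 * (WL / 630.0) ** -0.9
        measured = refl(forward_reflectance(musp, c * stock, 2.0))
        midpoint = fit(measured, "phantom", lut2, stock_mua=stock,
                       init={"musp0": 8.5, "b": 2.0, "c": 0.5})
        rng = np.random.default_rng(1)
        random_init = {"musp0": rng.uniform(2, 15), "b": rng.uniform(0, 4),
                       "c": rng.uniform(0, 1)}
        other = fit(measured, "phantom", lut2, stock_mua=stock, init=random_init)
        for k in ("musp0", "b", "c"):
            assert midpoint.params[k] == pytest.approx(other.params[k], rel=1e-3)

    def test_nonfinite_spectrum_rejected(self, lut2, stock):
        bad = np.linspace(0.1, 0.2, WL.size)
        bad[5] = np.nan
        with pytest.raises(FitError):
            fit(Spectrum(WL, np.nan_to_num(bad), "sample", 2.0), "phantom",
                lut2, stock_mua=stock)


class TestTissueFit:
    def test_noiseless_recovery(self, lut2, ext_table):
        scat = ScatteringModel(8.0, 1.2)
        absorber = TissueAbsorberModel(5.0, 0.5, 5.0)
        s = synthesize_tissue_spectrum(scat, absorber, 2.0, snr_db=None,
                                       ext=ext_table)
        result = fit(s, "tissue", lut2, ext=ext_table)
        assert result.params["thc"] == pytest.approx(5.0, rel=0.05)
        assert result.params["sto2"] == pytest.approx(0.5, abs=0.05)
        assert result.params["musp0"] == pytest.approx(8.0, rel=0.03)

    def test_recovery_error_shrinks_with_snr(self, lut2, ext_table):
        # mean scattering-scale recovery error is non-increasing from
        # 10 dB to 30 dB noise floors (fixed seeds)
        rng = np.random.default_rng(0)
        cases = [
            (ScatteringModel(rng.uniform(6, 10), rng.uniform(0.8, 1.4)),
             TissueAbsorberModel(rng.uniform(2, 7), rng.uniform(0.3, 0.8),
                                 rng.uniform(3, 10)))
            for _ in range(5)
        ]
        errs = []
        for snr in (10.0, 15.0, 30.0):
            e = []
            for k, (scat, absorber) in enumerate(cases):
                s = synthesize_tissue_spectrum(scat, absorber, 2.0, seed=k,
                                               snr_db=snr, ext=ext_table)
                res = fit(s, "tissue", lut2, ext=ext_table)
                e.append(abs(res.params["musp0"] - scat.musp0) / scat.musp0)
            errs.append(np.mean(e))
        assert errs[2] <= errs[0] + 0.01
        assert errs[1] <= errs[0] + 0.02


class TestValidation:
    def test_report_shape(self, validation_report):
        assert len(validation_report) == 4
        assert {"musp_percent_error", "mua_percent_error", "n_discarded"} <= set(
            validation_report.columns
        )
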