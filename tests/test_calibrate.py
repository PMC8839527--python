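"""Coefficient re-derivation: component fits, composition, full pipeline."""

import numpy as np
import pandas as pd
import pytest

import balticrrs as b
from balticrrs.bands import BANDS


class TestPowerLawFit:
    def test_noiseless_recovery(self):
        x = np.logspace(-1, 2, 20)
        fit = b.fit_power_law(x, 0.056 * x**0.827)
        assert fit.coefficient == pytest.approx(0.056, abs=1e-10)
        assert fit.exponent == pytest.approx(0.827, abs=1e-10)
        assert fit.r_squared_log == pytest.approx(1.0)

    def test_two_point_exact_line(self):
        fit = b.fit_power_law([1.0, 10.0], [2.0, 20.0])
        assert fit.coefficient == pytest.approx(2.0)
        assert fit.exponent == pytest.approx(1.0)

    def test_noisy_exponent_within_ols_error(self):
        rng = np.random.default_rng(42)
        x = np.logspace(-1, 2, 500)
        y = 0.056 * x**0.827 * 10 ** (0.14 * rng.standard_normal(500))
        fit = b.fit_power_law(x, y)
        # analytic slope SE = 0.14 / sqrt(n * var(log10 x)) ~ 0.0072; +-0.03 is >4 SE
        assert fit.exponent == pytest.approx(0.827, abs=0.03)

    def test_nonpositive_pairs_dropped_and_counted(self):
        est = b.PowerLawRegressor().fit([1.0, 2.0, -1.0, 0.0], [2.0, 4.0, 1.0, 1.0])
        assert est.n_used_ == 2 and est.n_dropped_ == 2

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            b.fit_power_law([1.0], [2.0])


class TestRatioExponentialFit:
    def test_recovers_published_pigment_correction(self):
        c = np.linspace(0.0, 1.5, 30)
        fit = b.fit_ratio_exponential(1.692 * np.exp(-0.824 * c), c)
        assert fit.prefactor == pytest.approx(1.692, abs=1e-10)
        assert fit.rate == pytest.approx(-0.824, abs=1e-10)

    def test_constant_ratio(self):
        fit = b.fit_ratio_exponential([1.0, 1.0, 1.0], [0.0, 0.5, 1.0])
        assert fit.prefactor == pytest.approx(1.0)
        assert fit.rate == pytest.approx(0.0, abs=1e-12)

    def test_unit_prefactor_correction(self):
        c = np.linspace(0.0, 1.0, 20)
        fit = b.fit_ratio_exponential(np.exp(-0.903 * c), c)
        assert fit.prefactor == pytest.approx(1.0, abs=1e-10)
        assert fit.rate == pytest.approx(-0.903, abs=1e-10)


class TestComposition:
    def test_published_488_composition(self):
        composed = b.compose_two_parameter(
            b.PowerLawFit(0.037, 0.820, 10, 1.0),
            b.RatioExponentialFit(1.692, -0.824, 10, 1.0))
        assert composed[0] == pytest.approx(0.02187, abs=5e-5)
        assert composed[0] == pytest.approx(0.022, rel=0.01)
        assert composed == (pytest.approx(0.037 / 1.692), 0.820, 0.824)

    def test_identity_correction(self):
        assert b.compose_two_parameter(
            b.PowerLawFit(0.31, 0.9, 5, 1.0),
            b.RatioExponentialFit(1.0, 0.0, 5, 1.0)) == (0.31, 0.9, 0.0)

    def test_exponent_never_altered(self):
        composed = b.compose_two_parameter(
            b.PowerLawFit(0.008, 0.891, 9, 1.0),
            b.RatioExponentialFit(1.0, -0.827, 9, 1.0))
        assert composed == (pytest.approx(0.008), 0.891, pytest.approx(0.827))


class TestCdomLogPoly:
    def test_noiseless_recovery(self):
        a400 = np.linspace(0.3, 5.0, 40)
        u = np.log10(a400)
        y = 10.0 ** (-0.624 * u**2 + 1.077 * u - 0.485)
        fit = b.fit_cdom_logpoly(a400, y)
        assert fit.m == pytest.approx(0.624, abs=1e-10)
        assert fit.n == pytest.approx(1.077, abs=1e-10)
        assert fit.p == pytest.approx(0.485, abs=1e-10)

    def test_identity_spectrum(self):
        a400 = np.array([0.3, 0.7, 1.5, 3.0])
        fit = b.fit_cdom_logpoly(a400, a400)
        assert fit.m == pytest.approx(0.0, abs=1e-10)
        assert fit.n == pytest.approx(1.0, abs=1e-10)
        assert fit.p == pytest.approx(0.0, abs=1e-10)

    def test_noisy_recovery_within_ols_bound(self):
        rng = np.random.default_rng(5)
        a400 = np.exp(rng.uniform(np.log(0.3), np.log(5.0), 300))
        u = np.log10(a400)
        y = 10.0 ** (-0.624 * u**2 + 1.077 * u - 0.485 + 0.05 * rng.standard_normal(300))
        fit = b.fit_cdom_logpoly(a400, y)
        assert fit.m == pytest.approx(0.624, rel=0.10)
        assert fit.n == pytest.approx(1.077, rel=0.10)
        assert fit.p == pytest.approx(0.485, rel=0.10)

    def test_collinear_design_rejected(self):
        with pytest.raises(ValueError):
            b.fit_cdom_logpoly([1.0, 1.0, 1.0, 1.0], [0.7, 0.7, 0.7, 0.7])


class TestFOverQ:
    def test_exact_recovery_from_noiseless_stations(self, noiseless_table, baltic):
        for band in BANDS:
            got = b.fit_f_over_q(noiseless_table, band)
            assert got == pytest.approx(baltic.band(band).f_over_q, abs=1e-12)

    def test_single_station_is_its_own_ratio(self, noiseless_table):
        one = noiseless_table.iloc[[0]]
        expected = float((one["lu_488"] / one["ed_488"]).iloc[0]
                         * (one["aph_488"] + one["ad_488"] + one["acdom_488"] + 0.0147
                            + one["bbp_488"] + 0.0012).iloc[0]
                         / (one["bbp_488"] + 0.0012).iloc[0])
        assert b.fit_f_over_q(one, 488) == pytest.approx(expected)

    def test_median_robust_under_radiance_noise(self):
        params = b.PopulationParams(n_stations=200, seed=9,
                                    iop_noise_sigma_log10=0.0,
                                    lu_noise_sigma_log10=0.05)
        table = b.generate_dataset(params)
        assert b.fit_f_over_q(table, 488) == pytest.approx(0.10, rel=0.05)


class TestCalibrateAll:
    def test_noiseless_joint_closure(self, noiseless_table, baltic):
        result = b.calibrate_all(noiseless_table, fit_method="joint")
        for band in BANDS:
            for fam in ("aph", "ad", "bbp", "acdom"):
                got = np.array(getattr(result.coefficients.band(band), fam))
                want = np.array(getattr(baltic.band(band), fam))
                assert np.allclose(got, want, atol=1e-8), (fam, band)
            assert result.f_over_q[band] == pytest.approx(baltic.band(band).f_over_q,
                                                          abs=1e-12)

    def test_noisy_two_step_recovery(self, baltic):
        # n sized so a +-15% band is >3.5 sigma for every constant: the
        # aph coefficient inherits mean(SumC/Chl) times the rate error,
        # whose sd is sigma_ln / (sqrt(n) * sd(covariate)) ~ 4% at n=800
        params = b.PopulationParams(n_stations=800, seed=31)
        table = b.generate_dataset(params)
        result = b.calibrate_all(table, fit_method="two_step")
        for band in BANDS:
            for fam in ("aph", "ad", "bbp"):
                got = getattr(result.coefficients.band(band), fam)
                want = getattr(baltic.band(band), fam)
                assert got[0] == pytest.approx(want[0], rel=0.15), (fam, band, "coefficient")
                assert got[1] == pytest.approx(want[1], rel=0.15), (fam, band, "exponent")

    def test_missing_column_is_schema_error(self, noiseless_table):
        broken = noiseless_table.drop(columns=["sum_c_mg_m3"])
        with pytest.raises(KeyError, match="sum_c_mg_m3"):
            b.calibrate_all(broken)

    def test_no_radiometry_falls_back_to_base_f_over_q(self, noiseless_table, baltic):
        trimmed = noiseless_table.drop(
            columns=[c for c in noiseless_table.columns if c.startswith(("lu_", "ed_", "eu_"))])
        with pytest.warns(UserWarning, match="radiometry"):
            result = b.calibrate_all(trimmed)
        assert result.f_over_q == {band: baltic.band(band).f_over_q for band in BANDS}

    def test_two_parameter_fit_never_scatters_worse_in_sample(self, noisy_table):
        # nested log-space OLS: adding the composition covariate cannot
        # increase the in-sample log-residual scatter
        families = {"aph": ("chl_a_mg_m3", "sum_c_mg_m3"),
                    "ad": ("spm_g_m3", "spm_inorg_g_m3"),
                    "bbp": ("spm_g_m3", "spm_inorg_g_m3")}
        for fam, (driver_col, num_col) in families.items():
            driver = noisy_table[driver_col].to_numpy()
            covariate = noisy_table[num_col].to_numpy() / driver
            for band in BANDS:
                meas = noisy_table[f"{fam}_{band}"].to_numpy()
                one_p = b.PowerLawRegressor().fit(driver, meas)
                resid_1p = np.log10(meas) - np.log10(one_p.predict(driver))
                design = np.column_stack([np.ones_like(driver), np.log10(driver), covariate])
                beta, _, _, _ = np.linalg.lstsq(design, np.log10(meas), rcond=None)
                resid_2p = np.log10(meas) - design @ beta
                assert resid_2p.std() <= resid_1p.std() + 1e-12


def test_train_test_split_is_seeded_partition(noiseless_table):
    train, test = b.train_test_split_stations(noiseless_table, 0.25, seed=4)
    train2, test2 = b.train_test_split_stations(noiseless_table, 0.25, seed=4)
    assert len(train) + len(test) == len(noiseless_table)
    pd.testing.assert_frame_equal(test, test2)
    assert not set(train.index) & set(test.index)
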