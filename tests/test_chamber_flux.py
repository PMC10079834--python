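"""Flux fitting: ideal-gas conversion, OLS and saturating-exponential fits,
model selection, and minimum detectable flux."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from chamberflux.errors import InsufficientDataError, InvalidConfigError
from chamberflux.fluxfit import (
    FitConfig,
    calibrate_precision_for_mdf,
    fit_exponential,
    fit_linear,
    minimum_detectable_flux,
    select_model,
    slope_to_molar_flux,
)
from chamberflux.units import R_GAS, MOLAR_MASS, SECONDS_PER_DAY

from conftest import make_deployment


class TestLinearFit:
    def test_constant_trace_gives_zero_flux(self):
        dep = make_deployment(slope_ppm_s=0.0)
        est = fit_linear(dep)
        assert est.flux_molar == pytest.approx(0.0, abs=1e-15)
        assert est.flux_mass == pytest.approx(0.0, abs=1e-15)

    def test_ideal_gas_conversion_matches_hand_computation(self):
        # 0.001 ppb/s N2O trace: hand oracle F = b * P*V/(R*T*A)
        dep = make_deployment(
            slope_ppm_s=1e-6, temp_k=298.15, press_kpa=101.325, area=0.2, volume=0.05
        )
        est = fit_linear(dep)
        slope_molmol = 1e-6 * 1e-6  # ppm/s -> mol mol-1 s-1
        expected_mol = slope_molmol * 101325.0 * 0.05 / (R_GAS * 298.15 * 0.2)
        assert est.flux_molar == pytest.approx(expected_mol * 1e9, rel=1e-9)
        # mass/molar coherence
        expected_mass = est.flux_molar * MOLAR_MASS["n2o"] * SECONDS_PER_DAY * 1e-6
        assert est.flux_mass == pytest.approx(expected_mass, rel=1e-12)

    def test_noise_free_recovery_is_exact(self):
        dep = make_deployment(slope_ppm_s=3.7e-4)
        est = fit_linear(dep)
        assert est.slope_ppm_s == pytest.approx(3.7e-4, rel=1e-9)
        assert est.r_squared == pytest.approx(1.0, abs=1e-12)

    @given(
        slope=st.floats(-1e-2, 1e-2),
        intercept=st.floats(0.1, 500),
        n=st.integers(20, 200),
        seed=st.integers(0, 1000),
    )
    def test_ols_matches_closed_form(self, slope, intercept, n, seed):
        """The fitted slope equals sum((t-tbar)(C-Cbar))/sum((t-tbar)^2)."""
        dep = make_deployment(
            slope_ppm_s=slope, intercept_ppm=intercept, n=n, noise_sd=0.01, seed=seed
        )
        cfg = FitConfig(deadband_s=0.0, min_samples=10)
        est = fit_linear(dep, cfg)
        t, c = dep.time_s, dep.mole_fraction_ppm
        brute = float(((t - t.mean()) * (c - c.mean())).sum() / ((t - t.mean()) ** 2).sum())
        assert est.slope_ppm_s == pytest.approx(brute, rel=1e-9, abs=1e-15)

    def test_value_reflection_negates_flux(self):
        dep = make_deployment(slope_ppm_s=5e-4, noise_sd=0.002, seed=3)
        mirrored = make_deployment(
            trace=2 * dep.mole_fraction_ppm[0] - dep.mole_fraction_ppm
        )
        f1 = fit_linear(dep)
        f2 = fit_linear(mirrored)
        assert f2.flux_molar == pytest.approx(-f1.flux_molar, rel=1e-9)

    def test_too_few_samples_raises(self):
        dep = make_deployment(n=12)
        with pytest.raises(InsufficientDataError):
            fit_linear(dep, FitConfig(deadband_s=5.0, min_samples=10))

    def test_noisy_slope_within_four_se_of_truth(self):
        """Monte-Carlo: the OLS slope falls within 4 SE of the configured
        slope in at least 99% of seeds."""
        slope = 2e-4
        hits = 0
        n_seeds = 200
        for seed in range(n_seeds):
            dep = make_deployment(slope_ppm_s=slope, n=120, noise_sd=0.01, seed=seed)
            est = fit_linear(dep, FitConfig(deadband_s=0.0))
            hits += abs(est.slope_ppm_s - slope) <= 4 * est.slope_se_ppm_s
        assert hits / n_seeds >= 0.99


class TestExponentialFit:
    def test_exact_exponential_recovered(self):
        # C(t) = phi + (C0-phi) exp(-kappa t); initial slope kappa*(phi-C0)
        kappa, delta = 0.002, 0.050  # ppm units; 50 ppb amplitude
        t = np.arange(600, dtype=float)
        trace = (0.33 + delta) - delta * np.exp(-kappa * t)
        dep = make_deployment(trace=trace, n=600)
        est = fit_exponential(dep, FitConfig(deadband_s=0.0))
        assert est.slope_ppm_s == pytest.approx(kappa * delta, rel=1e-6)

    def test_linear_limit_matches_linear_slope(self):
        dep = make_deployment(slope_ppm_s=4e-4, n=600)
        cfg = FitConfig(deadband_s=0.0)
        lin = fit_linear(dep, cfg)
        exp = fit_exponential(dep, cfg)
        assert exp.slope_ppm_s == pytest.approx(lin.slope_ppm_s, rel=0.01)

    def test_decreasing_trace_gives_negative_flux(self):
        t = np.arange(600, dtype=float)
        trace = 1.9 - 0.02 * (1 - np.exp(-0.003 * t))
        dep = make_deployment(trace=trace, gas="ch4")
        est = fit_exponential(dep, FitConfig(deadband_s=0.0))
        assert est.flux_molar < 0


class TestModelSelection:
    def _est(self, ratio, model="linear"):
        dep = make_deployment(slope_ppm_s=1e-4)
        est = fit_linear(dep)
        est.uncertainty_ratio = ratio
        est.model = model
        return est

    def test_smaller_ratio_wins(self):
        assert select_model(self._est(0.1), self._est(0.5, "exponential")).model == "linear"
        assert select_model(self._est(0.5), self._est(0.1, "exponential")).model == "exponential"

    def test_both_high_uncertainty_rejected(self):
        cfg = FitConfig(max_uncertainty_ratio=1.0)
        assert select_model(self._est(2.0), self._est(2.0, "exponential"), cfg) is None

    def test_tie_goes_to_linear(self):
        assert select_model(self._est(0.3), self._est(0.3, "exponential")).model == "linear"


class TestMinimumDetectableFlux:
    GEOM = dict(collar_area_m2=0.049, volume_m3=0.01935)

    def test_longer_closure_lowers_mdf(self):
        cfg = FitConfig()
        m1 = minimum_detectable_flux(cfg, "n2o", closure_s=600, **self.GEOM)
        m2 = minimum_detectable_flux(cfg, "n2o", closure_s=1200, **self.GEOM)
        # doubling closure time at fixed 1 Hz doubles n too: factor 2*sqrt(2)
        assert m2 == pytest.approx(m1 / (2 * math.sqrt(2)), rel=1e-9)

    def test_gas_mdfs_scale_with_precision_ratio(self):
        cfg = FitConfig()
        m_n2o = minimum_detectable_flux(cfg, "n2o", closure_s=600, **self.GEOM)
        m_ch4 = minimum_detectable_flux(cfg, "ch4", closure_s=600, **self.GEOM)
        ratio = cfg.analyzer_precision_ppm["ch4"] / cfg.analyzer_precision_ppm["n2o"]
        assert m_ch4 == pytest.approx(m_n2o * ratio, rel=1e-12)

    def test_zero_precision_gives_zero_mdf(self):
        cfg = FitConfig(analyzer_precision_ppm={"n2o": 0.0})
        assert minimum_detectable_flux(cfg, "n2o", closure_s=600, **self.GEOM) == 0.0

    def test_default_precisions_reproduce_reference_mdfs(self):
        """The default analyzer precisions and the default geometry yield
        the conservative reference detection limits for each gas."""
        cfg = FitConfig()
        for gas, ref in cfg.mdf_reference_nmol.items():
            mdf = minimum_detectable_flux(
                cfg, gas, closure_s=600, temp_k=298.15, press_kpa=101.325, **self.GEOM
            )
            assert mdf == pytest.approx(ref, rel=1e-4)

    def test_calibration_round_trip(self):
        sigma = calibrate_precision_for_mdf(0.002)
        cfg = FitConfig(analyzer_precision_ppm={"x": sigma})
        assert minimum_detectable_flux(cfg, "x", closure_s=600, **self.GEOM) == pytest.approx(
            0.002, rel=1e-9
        )

    def test_zero_closure_invalid(self):
        with pytest.raises(InvalidConfigError):
            minimum_detectable_flux(FitConfig(), "n2o", closure_s=0, **self.GEOM)


def test_slope_to_molar_flux_is_linear():
    dep = make_deployment()
    assert slope_to_molar_flux(2.0, dep) == pytest.approx(2 * slope_to_molar_flux(1.0, dep))
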