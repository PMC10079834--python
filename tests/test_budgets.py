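"""Budget arithmetic: GWP conversion, site-year assignment, annualization,
harvest accounting, composites, pairwise regression."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from chamberflux import budgets as b
from chamberflux.errors import InsufficientDataError, UndefinedStatisticError
from chamberflux.site_data import (
    HARVEST_C_G_M2_Y,
    HARVEST_CO2_G_M2_Y,
    load_annual_inputs,
)


class TestGWP:
    @pytest.mark.parametrize(
        "flux,gas,expected",
        [
            (624.4, "n2o", 186.1),
            (263.6, "n2o", 78.6),
            (-53.5, "ch4", -1.5),
            (-78.2, "ch4", -2.2),
            (0.0, "n2o", 0.0),
        ],
    )
    def test_published_gwp_cells(self, flux, gas, expected):
        assert b.to_co2e(flux, gas) == pytest.approx(expected, abs=0.05)

    @given(a=st.floats(-1e4, 1e4), c=st.floats(-1e4, 1e4))
    def test_linearity(self, a, c):
        assert b.to_co2e(a + c, "n2o") == pytest.approx(
            b.to_co2e(a, "n2o") + b.to_co2e(c, "n2o"), rel=1e-9, abs=1e-9
        )

    def test_unknown_gas_rejected(self):
        with pytest.raises(ValueError):
            b.to_co2e(1.0, "h2o")


class TestTotalCO2e:
    def test_published_rows_close(self):
        total1, _ = b.total_co2e(-1757, 181.9, -1.2)
        total3, _ = b.total_co2e(-2942, 231.6, -1.7)
        assert total1 == pytest.approx(-1576.3, abs=0.05)
        assert total3 == pytest.approx(-2712.1, abs=0.05)

    def test_mean_nee_of_published_years(self):
        df = load_annual_inputs()
        years = df[df["site_year"] != "all"]
        assert years["nee"].mean() == pytest.approx(-2330.0, abs=0.5)

    def test_zero_budget(self):
        total, offset = b.total_co2e(0.0, 0.0, 0.0)
        assert total == 0.0 and np.isnan(offset)

    def test_closure_is_exact(self):
        nee, n2o, ch4 = -1931.77, 212.345, -1.987
        total, _ = b.total_co2e(nee, n2o, ch4)
        assert total - (nee + n2o + ch4) == 0.0

    def test_offset_diagnostics_cover_candidate_denominators(self):
        diag = b.offset_diagnostics(-2330.0, 186.1, -1.5)
        assert len(diag) == 3
        chosen = diag.loc[diag["denominator"] == "abs(nee + ch4_gwp)", "offset_pct"].item()
        assert chosen == pytest.approx(100 * 186.1 / 2331.5, rel=1e-9)


class TestNitrogenConversion:
    def test_published_value(self):
        assert b.n2o_mass_to_n_per_ha(624.4) == pytest.approx(4.0, abs=0.05)

    def test_exact_fraction(self):
        assert b.n2o_mass_to_n_per_ha(44.0) == pytest.approx(0.28, rel=1e-9)

    @given(x=st.floats(-1e6, 1e6))
    def test_round_trip(self, x):
        assert b.n_per_ha_to_n2o_mass(b.n2o_mass_to_n_per_ha(x)) == pytest.approx(
            x, rel=1e-12, abs=1e-12
        )


class TestSiteYear:
    @pytest.mark.parametrize(
        "ts,label",
        [
            ("2018-01-26", "2017-2018"),
            ("2018-01-27", "2018-2019"),
            ("2018-01-27 00:00:00", "2018-2019"),
            ("2020-02-29", "2020-2021"),
            ("2017-12-31", "2017-2018"),
        ],
    )
    def test_boundaries(self, ts, label):
        assert b.assign_site_year(ts) == label

    def test_vectorized(self):
        labels = b.assign_site_year(["2018-01-26", "2018-01-27"])
        assert list(labels) == ["2017-2018", "2018-2019"]


class TestComposites:
    def _fluxes(self, values, timestamps, gas="n2o"):
        return pd.DataFrame(
            {"timestamp": pd.to_datetime(timestamps), "gas": gas, "flux_mass": values}
        )

    def test_identical_values_have_zero_se(self):
        ts = pd.date_range("2018-06-01", periods=80, freq="15min")
        daily = b.daily_composite(self._fluxes(np.full(80, 2.5), ts))
        assert daily["se"].iloc[0] == pytest.approx(0.0)

    def test_mean_and_se_arithmetic(self):
        ts = pd.date_range("2018-06-01", periods=3, freq="h")
        daily = b.daily_composite(self._fluxes([1.0, 2.0, 3.0], ts))
        assert daily["mean"].iloc[0] == pytest.approx(2.0)
        assert daily["se"].iloc[0] == pytest.approx(1 / np.sqrt(3))

    def test_empty_days_absent(self):
        ts = ["2018-06-01 10:00", "2018-06-03 10:00", "2018-06-03 11:00"]
        daily = b.daily_composite(self._fluxes([1, 2, 3], ts))
        assert len(daily) == 2  # June 2 absent, not zero

    def test_diel_composite_peak_hour(self):
        ts = pd.date_range("2018-06-01", periods=24 * 30, freq="h")
        vals = 5 + 3 * np.sin(2 * np.pi * (ts.hour - 10) / 24)  # peak at hour 16
        comp = b.diel_seasonal_composite(self._fluxes(vals, ts))
        summer = comp[comp["season"] == "summer"]
        assert summer.loc[summer["mean"].idxmax(), "hour"] == 16

    def test_constant_flux_flat_profile(self):
        ts = pd.date_range("2018-06-01", periods=24 * 5, freq="h")
        comp = b.diel_seasonal_composite(self._fluxes(np.full(24 * 5, 1.0), ts))
        assert comp["mean"].nunique() == 1


class TestAnnualize:
    def test_constant_daily_flux(self):
        days = pd.date_range("2018-01-27", "2019-01-26", freq="D")
        daily = pd.DataFrame(
            {"gas": "n2o", "date": days, "mean": 1.711, "se": 0.0, "n": 80}
        )
        out = b.annualize(daily)
        assert out["annual_flux"].iloc[0] == pytest.approx(1.711 * 365, rel=1e-12)  # 624.5
        assert bool(out["complete"].iloc[0])

    def test_zero_flux(self):
        days = pd.date_range("2018-01-27", periods=365, freq="D")
        daily = pd.DataFrame({"gas": "n2o", "date": days, "mean": 0.0, "se": 0.0, "n": 1})
        assert b.annualize(daily)["annual_flux"].iloc[0] == 0.0

    def test_incomplete_year_flagged_not_dropped(self):
        days = pd.date_range("2018-01-27", periods=100, freq="D")
        daily = pd.DataFrame({"gas": "n2o", "date": days, "mean": 1.0, "se": 0.0, "n": 1})
        out = b.annualize(daily, completeness_threshold=0.5)
        assert len(out) == 1 and not bool(out["complete"].iloc[0])


class TestHarvest:
    def test_published_percentage(self):
        acc = b.harvest_accounting(-2330.0, 186.1, harvest_co2=HARVEST_CO2_G_M2_Y)
        assert round(acc.pct_of_nee) == 89
        assert acc.residual_sink == pytest.approx(258.0, abs=0.5)
        # the residual sink is ~70% offset by N2O
        assert acc.n2o_offset_pct_of_residual == pytest.approx(72.1, abs=0.5)

    def test_carbon_input_converted_stoichiometrically(self):
        acc = b.harvest_accounting(-2330.0, 186.1, harvest_c=HARVEST_C_G_M2_Y)
        assert acc.harvest_co2 == pytest.approx(595 * 44 / 12, rel=1e-9)  # 2181.7

    def test_zero_harvest(self):
        acc = b.harvest_accounting(-2330.0, 186.1, harvest_co2=0.0)
        assert acc.residual_sink == 2330.0

    def test_over_harvest_flagged(self):
        acc = b.harvest_accounting(-100.0, 10.0, harvest_co2=150.0)
        assert acc.negative_residual

    def test_requires_exactly_one_input(self):
        with pytest.raises(ValueError):
            b.harvest_accounting(-100.0, 1.0)
        with pytest.raises(ValueError):
            b.harvest_accounting(-100.0, 1.0, harvest_co2=1.0, harvest_c=1.0)


class TestPairwiseRegression:
    def test_exact_line(self):
        x = np.arange(10.0)
        res = b.pairwise_regression(x, 2 * x)
        assert res["slope"] == pytest.approx(2.0)
        assert res["r_squared"] == pytest.approx(1.0)

    def test_independent_noise_has_low_r2(self):
        rng = np.random.default_rng(8)
        res = b.pairwise_regression(rng.standard_normal(1000), rng.standard_normal(1000))
        assert res["r_squared"] < 0.01

    def test_too_few_pairs(self):
        with pytest.raises(InsufficientDataError):
            b.pairwise_regression([1, 2], [3, 4])

    def test_degenerate_x(self):
        with pytest.raises(UndefinedStatisticError):
            b.pairwise_regression(np.ones(10), np.arange(10.0))


def test_budget_table_closure_from_published_inputs():
    """total_co2e - (nee + n2o_gwp + ch4_gwp) == 0 exactly, per row."""
    df = load_annual_inputs()
    years = df[df["site_year"] != "all"]
    annual = pd.concat(
        [
            pd.DataFrame(
                {
                    "gas": gas,
                    "site_year": years["site_year"],
                    "annual_flux": years[f"{gas}_flux"].to_numpy(),
                    "annual_se": years[f"{gas}_se"].to_numpy(),
                }
            )
            for gas in ("n2o", "ch4")
        ],
        ignore_index=True,
    )
    table = b.annual_budget_table(annual, years[["site_year", "nee"]])
    resid = table["total_co2e"] - (table["nee"] + table["n2o_gwp"] + table["ch4_gwp"])
    assert (resid == 0).all()
    row1 = table[table["site_year"] == "2017-2018"].iloc[0]
    assert row1["total_co2e"] == pytest.approx(-1576.3, abs=0.05)
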