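"""Aggregation to daily/seasonal/annual scales and CO2-equivalent budgets.

Fluxes are aggregated as daily means (+/- standard error over measurements
within the day), annualized as mean daily flux x 365 within each site year
(the annual accounting window runs January 27 through January 26), and
converted to 100-year CO2 equivalents with IPCC AR5 global warming
potentials (CH4 = 28, N2O = 298).  The total ecosystem CO2e budget adds
the chamber-derived N2O and CH4 terms to eddy-covariance net ecosystem
exchange (NEE; negative = net uptake), and the harvest accounting removes
exported crop carbon from the apparent NEE sink.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InsufficientDataError, UndefinedStatisticError

N_FRACTION_N2O = 28.0 / 44.0  # mass fraction of N in N2O (2 x 14 / 44)
C_TO_CO2 = 44.0 / 12.0


@dataclass
class GWPConfig:
    """100-year global warming potentials (mass CO2e per mass gas)."""

    gwp_ch4: float = 28.0
    gwp_n2o: float = 298.0
    horizon: str = "AR5 100-year"

    def __post_init__(self) -> None:
        if self.gwp_ch4 <= 0 or self.gwp_n2o <= 0:
            raise ValueError("GWP values must be positive")

    def for_gas(self, gas: str) -> float:
        if gas == "ch4":
            return self.gwp_ch4
        if gas == "n2o":
            return self.gwp_n2o
        raise ValueError(f"no GWP defined for gas {gas!r}")


def assign_site_year(timestamps, start_month: int = 1, start_day: int = 27):
    """Label each timestamp with its site year ("2017-2018", ...).

    The window opens at 00:00 on the start date (inclusive) and closes just
    before the next year's start date.
    """
    scalar = np.ndim(timestamps) == 0 and not isinstance(timestamps, (list, tuple))
    ts = pd.DatetimeIndex(pd.to_datetime([timestamps] if scalar else timestamps))
    month, day, year = ts.month, ts.day, ts.year
    after_start = (month > start_month) | ((month == start_month) & (day >= start_day))
    start_year = np.where(after_start, year, year - 1)
    labels = pd.Index([f"{y}-{y + 1}" for y in start_year])
    return labels[0] if scalar else labels


def daily_composite(fluxes: pd.DataFrame, value_col: str = "flux_mass") -> pd.DataFrame:
    """Daily mean +/- standard error per gas.

    Days without measurements are simply absent from the output (gaps are
    never zero-filled here).
    """
    df = fluxes.copy()
    df["date"] = pd.to_datetime(df["timestamp"]).dt.normalize()
    g = df.groupby(["gas", "date"])[value_col]
    out = g.agg(mean="mean", sd=lambda x: x.std(ddof=1), n="count").reset_index()
    out["se"] = out["sd"] / np.sqrt(out["n"])
    return out.drop(columns="sd")


def annualize(
    daily: pd.DataFrame,
    days_per_year: float = 365.0,
    completeness_threshold: float = 0.5,
) -> pd.DataFrame:
    """Annual flux +/- se per gas and site year from daily means.

    annual = mean(daily means) x days_per_year; the se is the se of the
    daily-mean series scaled the same way.  Site years with fewer than
    ``completeness_threshold`` x 365 days of data are flagged, not dropped.
    """
    df = daily.copy()
    df["site_year"] = assign_site_year(df["date"])
    rows = []
    for (gas, sy), grp in df.groupby(["gas", "site_year"]):
        vals = grp["mean"].to_numpy(dtype=float)
        if vals.size == 0:
            continue
        mean_daily = vals.mean()
        se_daily = vals.std(ddof=1) / np.sqrt(vals.size) if vals.size > 1 else np.nan
        rows.append(
            {
                "gas": gas,
                "site_year": sy,
                "annual_flux": mean_daily * days_per_year,
                "annual_se": se_daily * days_per_year,
                "n_days": int(vals.size),
                "complete": vals.size >= completeness_threshold * 365.0,
            }
        )
    return pd.DataFrame(rows)


def to_co2e(mass_flux_mg_m2_y, gas: str, cfg: Optional[GWPConfig] = None):
    """mg gas m-2 y-1 -> g CO2e m-2 y-1 (mass flux x GWP / 1000)."""
    cfg = cfg or GWPConfig()
    return np.multiply(mass_flux_mg_m2_y, cfg.for_gas(gas)) / 1000.0


def n2o_mass_to_n_per_ha(mass_flux_mg_m2_y):
    """mg N2O m-2 y-1 -> kg N-N2O ha-1 y-1 (x 0.01 area scaling x 28/44)."""
    return np.multiply(mass_flux_mg_m2_y, 0.01) * N_FRACTION_N2O


def n_per_ha_to_n2o_mass(n_kg_ha_y):
    """Inverse of :func:`n2o_mass_to_n_per_ha`."""
    return np.divide(n_kg_ha_y, 0.01 * N_FRACTION_N2O)


def total_co2e(nee, n2o_gwp, ch4_gwp):
    """Total ecosystem CO2e flux and the N2O offset of the carbon sink.

    total = NEE + N2O-GWP + CH4-GWP (all g CO2e m-2 y-1).  The offset is
    the N2O term as a percentage of the magnitude of the carbon-based sink
    (NEE + CH4 GWP); NaN when that denominator is zero.
    """
    total = nee + n2o_gwp + ch4_gwp
    denom = abs(nee + ch4_gwp)
    offset_pct = 100.0 * n2o_gwp / denom if denom != 0 else float("nan")
    return total, offset_pct


def offset_diagnostics(nee, n2o_gwp, ch4_gwp) -> pd.DataFrame:
    """N2O offset under every defensible denominator, for transparency."""
    candidates = {
        "abs(nee + ch4_gwp)": abs(nee + ch4_gwp),
        "abs(nee)": abs(nee),
        "abs(total_co2e)": abs(nee + n2o_gwp + ch4_gwp),
    }
    rows = [
        {"denominator": k, "value": v, "offset_pct": 100.0 * n2o_gwp / v if v else np.nan}
        for k, v in candidates.items()
    ]
    return pd.DataFrame(rows)


@dataclass
class HarvestAccounting:
    harvest_co2: float  # g CO2 m-2 y-1 removed as crop biomass
    pct_of_nee: float
    residual_sink: float  # g CO2 m-2 y-1 left in the ecosystem
    n2o_offset_pct_of_residual: float
    negative_residual: bool


def harvest_accounting(
    nee: float,
    n2o_gwp: float,
    harvest_co2: Optional[float] = None,
    harvest_c: Optional[float] = None,
) -> HarvestAccounting:
    """Remove harvested crop carbon from the NEE sink.

    Exactly one of ``harvest_co2`` (g CO2 m-2 y-1) or ``harvest_c``
    (g C m-2 y-1, converted stoichiometrically by 44/12) must be given;
    the two are never silently interconverted.
    """
    if (harvest_co2 is None) == (harvest_c is None):
        raise ValueError("give exactly one of harvest_co2 or harvest_c")
    if harvest_co2 is None:
        harvest_co2 = harvest_c * C_TO_CO2
    if nee == 0:
        raise UndefinedStatisticError("harvest accounting needs a nonzero NEE")
    sink = abs(nee)
    residual = sink - harvest_co2
    return HarvestAccounting(
        harvest_co2=harvest_co2,
        pct_of_nee=100.0 * harvest_co2 / sink,
        residual_sink=residual,
        n2o_offset_pct_of_residual=100.0 * n2o_gwp / residual if residual != 0 else float("nan"),
        negative_residual=residual < 0,
    )


def annual_budget_table(
    annual_fluxes: pd.DataFrame,
    nee_table: pd.DataFrame,
    cfg: Optional[GWPConfig] = None,
) -> pd.DataFrame:
    """Combine per-site-year chamber fluxes with NEE into the budget table.

    ``annual_fluxes`` comes from :func:`annualize` (long by gas/site_year,
    with N2O and CH4 in mg m-2 y-1 and CO2 in g m-2 y-1 after the caller's
    unit choice); ``nee_table`` has columns site_year, nee (g CO2 m-2 y-1)
    and optionally reco/gpp.  Output columns mirror the standard annual
    greenhouse-gas reporting layout.
    """
    cfg = cfg or GWPConfig()
    wide = annual_fluxes.pivot(index="site_year", columns="gas", values="annual_flux")
    se = annual_fluxes.pivot(index="site_year", columns="gas", values="annual_se")
    nee = nee_table.set_index("site_year")
    rows = []
    for sy in wide.index:
        n2o = float(wide.loc[sy].get("n2o", np.nan))
        ch4 = float(wide.loc[sy].get("ch4", np.nan))
        co2 = float(wide.loc[sy].get("co2", np.nan))
        n2o_gwp = to_co2e(n2o, "n2o", cfg)
        ch4_gwp = to_co2e(ch4, "ch4", cfg)
        nee_val = float(nee.loc[sy, "nee"]) if sy in nee.index else np.nan
        if np.isfinite(nee_val):
            total, offset = total_co2e(nee_val, n2o_gwp, ch4_gwp)
        else:
            total, offset = np.nan, np.nan
        rows.append(
            {
                "site_year": sy,
                "n2o_flux": n2o,
                "n2o_se": float(se.loc[sy].get("n2o", np.nan)) if sy in se.index else np.nan,
                "n2o_gwp": n2o_gwp,
                "ch4_flux": ch4,
                "ch4_se": float(se.loc[sy].get("ch4", np.nan)) if sy in se.index else np.nan,
                "ch4_gwp": ch4_gwp,
                "chamber_co2": co2,
                "nee": nee_val,
                "total_co2e": total,
                "n2o_offset_pct": offset,
                "n2o_kg_n_ha": n2o_mass_to_n_per_ha(n2o),
            }
        )
    return pd.DataFrame(rows)


_MET_SEASONS = {
    12: "winter", 1: "winter", 2: "winter",
    3: "spring", 4: "spring", 5: "spring",
    6: "summer", 7: "summer", 8: "summer",
    9: "fall", 10: "fall", 11: "fall",
}


def diel_seasonal_composite(
    fluxes: pd.DataFrame,
    value_col: str = "flux_mass",
    utc_offset_hours: float = 0.0,
) -> pd.DataFrame:
    """Hourly mean +/- se per meteorological season (DJF/MAM/JJA/SON) per gas.

    ``utc_offset_hours`` shifts stored UTC timestamps to site-local time
    before binning by hour of day.
    """
    df = fluxes.copy()
    local = pd.to_datetime(df["timestamp"]) + pd.to_timedelta(utc_offset_hours, unit="h")
    df["season"] = local.dt.month.map(_MET_SEASONS)
    df["hour"] = local.dt.hour
    g = df.groupby(["gas", "season", "hour"])[value_col]
    out = g.agg(mean="mean", sd=lambda x: x.std(ddof=1), n="count").reset_index()
    out["se"] = out["sd"] / np.sqrt(out["n"])
    return out.drop(columns="sd")


def pairwise_regression(x, y):
    """OLS of day-aligned pairs: slope, intercept, r2, p.

    NaN pairs are dropped; fewer than 3 remaining pairs or zero variance in
    x is an error.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if x.size < 3:
        raise InsufficientDataError("need at least 3 aligned pairs")
    if np.ptp(x) == 0:
        raise UndefinedStatisticError("x has no variance; slope undefined")
    res = stats.linregress(x, y)
    return {
        "slope": res.slope,
        "intercept": res.intercept,
        "r_squared": res.rvalue**2,
        "p_value": res.pvalue,
        "n": int(x.size),
    }
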