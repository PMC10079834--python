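"""Synthetic chamber campaigns with known ground truth.

The generator emulates the measurement structure of a multi-year automated
chamber study over irrigated alfalfa: chambers sampled sequentially
(10-min closures separated by 1.5-min flushes), three gases per closure
(CO2, CH4, N2O) analyzed by one cavity ring-down instrument, 15-min
depth-resolved soil sensors (moisture, O2, temperature at 10/30/50 cm),
daily vegetation reflectance (NDVI, NIR, NIRv = NDVI x NIR), and annual
eddy-covariance NEE per site year (January 27 - January 26).

The statistical structure, not the biogeochemistry, is modelled:

* N2O background is lognormal around a seasonal (summer-peaking) median --
  strictly positive and right-skewed like observed fluxes -- plus rare hot
  moments: sharp pulses triggered 0-2 days after irrigation/rain events,
  with lognormally distributed peak magnitudes and fast exponential decay.
* CH4 is a small persistent sink (negative mean) with weak seasonality.
* CO2 respiration follows soil temperature through a Q10 response.
* Soil moisture jumps at water events and dries exponentially; O2 moves
  opposite to moisture; temperature is annual + diel sinusoids damped with
  depth.  NIRv regrows along saturating curves reset at each harvest.

Every deployment trace is built by inverting the ideal-gas chamber model,
so noise-free campaigns round-trip exactly through flux fitting, and the
per-timestamp true fluxes and hot-moment indicator are returned as ground
truth together with true annual budgets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .budgets import assign_site_year
from .errors import InvalidConfigError
from .fluxfit import (
    DEFAULT_BASE_VOLUME_M3,
    DEFAULT_COLLAR_AREA_M2,
    DEFAULT_COLLAR_HEIGHT_M,
    Deployment,
    slope_to_molar_flux,
)
from .units import GASES, mass_to_molar_flux, SECONDS_PER_DAY

AMBIENT_PPM = {"n2o": 0.33, "ch4": 1.9, "co2": 420.0}

#: analyzer 1-sigma concentration noise per gas (ppm), matching the
#: precisions that give the conservative reference detection limits
DEFAULT_NOISE_PPM = {"n2o": 0.0012877, "co2": 0.0386305, "ch4": 0.0012877}


@dataclass
class CampaignConfig:
    """Geometry and schedule of a synthetic campaign."""

    seed: int = 0
    n_chambers: int = 9
    closure_minutes: float = 10.0
    flush_minutes: float = 1.5
    start_date: str = "2017-01-27"
    end_date: str = "2021-01-27"
    site_year_start: Tuple[int, int] = (1, 27)  # (month, day)
    sample_hz: float = 1.0
    collar_area_m2: float = DEFAULT_COLLAR_AREA_M2
    base_volume_m3: float = DEFAULT_BASE_VOLUME_M3
    collar_height_series_m: Optional[Sequence[float]] = None  # weekly heights
    idle_minutes_per_cycle: float = 0.0
    cavity_temp_k: float = 313.15
    cavity_press_kpa: float = 20.0

    def __post_init__(self) -> None:
        if self.n_chambers < 1:
            raise InvalidConfigError("n_chambers must be >= 1")
        if self.closure_minutes <= 0 or self.flush_minutes < 0:
            raise InvalidConfigError("closure must be positive, flush non-negative")
        start = pd.Timestamp(self.start_date)
        end = pd.Timestamp(self.end_date)
        if end <= start:
            raise InvalidConfigError("end_date must be after start_date")
        if (end - start) < pd.Timedelta(days=1):
            raise InvalidConfigError("date range must span at least one day")
        if self.sample_hz <= 0:
            raise InvalidConfigError("sample_hz must be positive")

    def collar_height_at(self, when: pd.Timestamp) -> float:
        """Collar height, interpolated between weekly measurements."""
        if not self.collar_height_series_m:
            return DEFAULT_COLLAR_HEIGHT_M
        heights = np.asarray(self.collar_height_series_m, dtype=float)
        weeks = (when - pd.Timestamp(self.start_date)).total_seconds() / (7 * SECONDS_PER_DAY)
        return float(np.interp(weeks, np.arange(heights.size), heights))

    def volume_at(self, when: pd.Timestamp) -> float:
        return self.base_volume_m3 + self.collar_height_at(when) * self.collar_area_m2


@dataclass
class HotMomentProcess:
    """Event-pulse process for N2O hot moments.

    In campaign mode pulses are triggered by irrigation/rain dates with a
    uniform 0-2 day lag; :func:`inject_hot_moments` instead flags each
    timestamp independently with probability ``rate``.  Peak magnitudes are
    lognormal; each pulse decays exponentially with e-folding
    ``decay_days``.  Ground truth marks samples where the pulse component
    is at >= ``truth_fraction`` of its peak.
    """

    magnitude_median: float = 350.0  # mg N2O m-2 d-1
    magnitude_sigma: float = 0.3  # lognormal sigma (log scale)
    decay_days: float = 0.02
    lag_days_max: float = 2.0
    rate: float = 0.005
    truth_fraction: float = 0.5

    def __post_init__(self) -> None:
        if self.magnitude_median <= 0 or self.decay_days <= 0:
            raise InvalidConfigError("pulse magnitude and decay time must be positive")
        if not 0.0 <= self.rate <= 1.0:
            raise InvalidConfigError("rate must lie in [0, 1]")


@dataclass
class TrueFluxModel:
    """Parameters of the true flux and driver processes."""

    # N2O background (mg m-2 d-1): lognormal around a seasonal median
    n2o_median: float = 1.3
    n2o_seasonal_amp: float = 0.5  # log-scale seasonal amplitude
    n2o_lognormal_sigma: float = 0.35
    hot: HotMomentProcess = field(default_factory=HotMomentProcess)
    # CH4: persistent sink (mg m-2 d-1)
    ch4_sink_level: float = -0.147
    ch4_seasonal_amp: float = 0.05
    ch4_noise_sd: float = 0.03
    # CO2 respiration (mg m-2 d-1 at the reference temperature)
    co2_ref_flux: float = 13500.0
    co2_ref_temp_c: float = 15.0
    co2_q10: float = 2.0
    co2_noise_frac: float = 0.08
    # event calendars (ISO date strings); derived from the config if None
    irrigation_dates: Optional[List[str]] = None
    rain_dates: Optional[List[str]] = None
    harvest_dates: Optional[List[str]] = None
    # concentration noise per gas (ppm, 1-sigma); {} disables trace noise
    noise_sd_ppm: Dict[str, float] = field(default_factory=lambda: dict(DEFAULT_NOISE_PPM))

    def flux_noise_free(self) -> "TrueFluxModel":
        """Copy with all stochastic terms switched off (deterministic truth
        and exact traces); hot moments are disabled too."""
        import copy

        m = copy.deepcopy(self)
        m.n2o_lognormal_sigma = 0.0
        m.ch4_noise_sd = 0.0
        m.co2_noise_frac = 0.0
        m.noise_sd_ppm = {}
        m.hot = HotMomentProcess(rate=0.0)
        m.irrigation_dates = []
        m.rain_dates = []
        return m


@dataclass
class GroundTruth:
    """Per-timestamp true fluxes and true annual budgets."""

    series: pd.DataFrame  # timestamp, gas, true_flux, hot_indicator, hot_component
    annual: pd.DataFrame  # site_year, gas, annual_flux (mg m-2 y-1)


def default_event_dates(start: pd.Timestamp, end: pd.Timestamp):
    """Deterministic irrigation / rain / harvest calendars.

    Irrigation every 15 days May-September; rain events through the wet
    season (October-March); up to seven harvests per year April-October.
    """
    irrigation, rain, harvest = [], [], []
    for year in range(start.year - 1, end.year + 1):
        for doy in range(125, 270, 15):
            irrigation.append(pd.Timestamp(year, 1, 1) + pd.Timedelta(days=doy - 1))
        for doy in list(range(280, 360, 16)) + list(range(8, 80, 16)):
            rain.append(pd.Timestamp(year, 1, 1) + pd.Timedelta(days=doy - 1))
        for doy in range(100, 290, 30):
            harvest.append(pd.Timestamp(year, 1, 1) + pd.Timedelta(days=doy - 1))
    window = lambda dates: [d for d in dates if start <= d <= end]
    return window(irrigation), window(rain), window(harvest)


def _resolve_events(config: CampaignConfig, model: TrueFluxModel):
    start, end = pd.Timestamp(config.start_date), pd.Timestamp(config.end_date)
    irr, rain, harv = default_event_dates(start, end)
    irrigation = (
        [pd.Timestamp(d) for d in model.irrigation_dates]
        if model.irrigation_dates is not None
        else irr
    )
    rain_ev = [pd.Timestamp(d) for d in model.rain_dates] if model.rain_dates is not None else rain
    harvest = (
        [pd.Timestamp(d) for d in model.harvest_dates]
        if model.harvest_dates is not None
        else harv
    )
    return irrigation, rain_ev, harvest


def _day_fraction(ts: pd.DatetimeIndex) -> np.ndarray:
    return (ts - ts.normalize()).total_seconds().to_numpy() / SECONDS_PER_DAY


def _doy(ts: pd.DatetimeIndex) -> np.ndarray:
    return ts.dayofyear.to_numpy(dtype=float)


def _seasonal(ts: pd.DatetimeIndex, peak_doy: float = 211.0) -> np.ndarray:
    """Unit sinusoid peaking at ``peak_doy`` (late July by default)."""
    return np.sin(2.0 * np.pi * (_doy(ts) - (peak_doy - 91.25)) / 365.25)


def soil_temperature(ts: pd.DatetimeIndex, depth_cm: float) -> np.ndarray:
    annual = 8.0 * np.exp(-depth_cm / 40.0) * _seasonal(ts)
    diel = 3.0 * np.exp(-depth_cm / 12.0) * np.sin(
        2.0 * np.pi * (_day_fraction(ts) - 10.0 / 24.0)
    )
    return 15.0 + annual + diel


def _event_pulse(ts: pd.DatetimeIndex, events: Sequence[pd.Timestamp], decay_days: float) -> np.ndarray:
    """Sum of unit pulses decaying exponentially after each event."""
    t_days = (ts - ts[0]).total_seconds().to_numpy() / SECONDS_PER_DAY
    out = np.zeros(len(ts))
    for ev in events:
        dt = t_days - (ev - ts[0]).total_seconds() / SECONDS_PER_DAY
        active = dt >= 0
        out[active] += np.exp(-dt[active] / decay_days)
    return out


def true_background_fluxes(
    timestamps: pd.DatetimeIndex, model: TrueFluxModel, rng: np.random.Generator
) -> Dict[str, np.ndarray]:
    """Background (non-hot-moment) true fluxes, mg gas m-2 d-1."""
    ts = timestamps
    n = len(ts)
    n2o = model.n2o_median * np.exp(
        model.n2o_seasonal_amp * _seasonal(ts)
        + (model.n2o_lognormal_sigma * rng.standard_normal(n) if model.n2o_lognormal_sigma else 0.0)
    )
    ch4 = (
        model.ch4_sink_level
        - model.ch4_seasonal_amp * _seasonal(ts, peak_doy=230.0)
        + (model.ch4_noise_sd * rng.standard_normal(n) if model.ch4_noise_sd else 0.0)
    )
    temp = soil_temperature(ts, depth_cm=10.0)
    co2 = model.co2_ref_flux * model.co2_q10 ** ((temp - model.co2_ref_temp_c) / 10.0)
    if model.co2_noise_frac:
        co2 = co2 * np.exp(model.co2_noise_frac * rng.standard_normal(n))
    return {"n2o": n2o, "ch4": ch4, "co2": co2}


def hot_moment_component(
    timestamps: pd.DatetimeIndex,
    process: HotMomentProcess,
    event_dates: Sequence[pd.Timestamp],
    rng: np.random.Generator,
) -> Tuple[np.ndarray, np.ndarray]:
    """Event-triggered pulse component and its ground-truth indicator.

    Each event fires one pulse at a uniform 0-``lag_days_max`` day lag,
    snapped to the next sampled timestamp so the peak is observed.  The
    indicator marks samples where the pulse is at >= ``truth_fraction`` of
    its peak magnitude.
    """
    n = len(timestamps)
    component = np.zeros(n)
    indicator = np.zeros(n, dtype=bool)
    if n == 0 or not event_dates:
        return component, indicator
    t_days = (timestamps - timestamps[0]).total_seconds().to_numpy() / SECONDS_PER_DAY
    for ev in sorted(event_dates):
        lag = rng.uniform(0.0, process.lag_days_max)
        onset = (ev - timestamps[0]).total_seconds() / SECONDS_PER_DAY + lag
        idx = int(np.searchsorted(t_days, onset))
        if idx >= n:
            continue
        magnitude = process.magnitude_median * np.exp(
            process.magnitude_sigma * rng.standard_normal()
        )
        dt = t_days[idx:] - t_days[idx]
        pulse = magnitude * np.exp(-dt / process.decay_days)
        component[idx:] += pulse
        indicator[idx:] |= pulse >= process.truth_fraction * magnitude
    return component, indicator


def inject_hot_moments(
    background, process: HotMomentProcess, seed: int
) -> Tuple[np.ndarray, np.ndarray]:
    """Add point pulses at randomly flagged timestamps.

    Each timestamp is flagged independently with probability
    ``process.rate``; flagged values get a lognormal pulse added.  Returns
    (series, indicator).
    """
    bg = np.asarray(background, dtype=float)
    if bg.size == 0:
        raise InvalidConfigError("background series is empty")
    rng = np.random.default_rng(seed)
    indicator = rng.random(bg.size) < process.rate
    series = bg.copy()
    n_hot = int(indicator.sum())
    if n_hot:
        series[indicator] += process.magnitude_median * np.exp(
            process.magnitude_sigma * rng.standard_normal(n_hot)
        )
    return series, indicator


def deployment_schedule(config: CampaignConfig) -> pd.DataFrame:
    """Closure start times and chamber assignments for the campaign.

    Chambers cycle sequentially (flush then closure each); an optional idle
    period after every full cycle thins the schedule for reduced-scale
    campaigns.  A deployment is scheduled iff its closure ends within the
    campaign window.
    """
    start = pd.Timestamp(config.start_date)
    end = pd.Timestamp(config.end_date)
    slot = pd.Timedelta(minutes=config.flush_minutes + config.closure_minutes)
    closure = pd.Timedelta(minutes=config.closure_minutes)
    flush = pd.Timedelta(minutes=config.flush_minutes)
    idle = pd.Timedelta(minutes=config.idle_minutes_per_cycle)
    rows = []
    t = start
    i = 0
    while True:
        chamber = i % config.n_chambers
        closure_start = t + flush
        if closure_start + closure > end:
            break
        rows.append(
            {
                "deployment_id": f"D{i:07d}",
                "chamber_id": f"CH{chamber + 1}",
                "start_time": closure_start,
            }
        )
        t = t + slot
        i += 1
        if chamber == config.n_chambers - 1:
            t = t + idle
    return pd.DataFrame(rows)


def synthesize_deployment(
    flux_by_gas: Dict[str, float],
    config: CampaignConfig,
    deployment_id: str,
    chamber_id: str,
    start_time: pd.Timestamp,
    rng: Optional[np.random.Generator] = None,
    noise_sd_ppm: Optional[Dict[str, float]] = None,
    saturation_kappa: float = 0.0,
) -> List[Deployment]:
    """Concentration traces implied by true fluxes (mg gas m-2 d-1).

    Linear accumulation by default; with ``saturation_kappa`` > 0 the trace
    follows the saturating form C0 + a*(1-exp(-kappa*t))/kappa with the
    same initial slope a.  Gaussian i.i.d. analyzer noise is added per gas
    when a noise level is configured.
    """
    noise_sd_ppm = noise_sd_ppm or {}
    n = int(round(config.closure_minutes * 60.0 * config.sample_hz))
    t = np.arange(n, dtype=float) / config.sample_hz
    volume = config.volume_at(start_time)
    deployments = []
    for gas, flux_mass in flux_by_gas.items():
        probe = Deployment(
            deployment_id=deployment_id,
            chamber_id=chamber_id,
            gas=gas,
            time_s=t[:2],
            mole_fraction_ppm=np.zeros(2),
            cavity_temp_k=config.cavity_temp_k,
            cavity_press_kpa=config.cavity_press_kpa,
            collar_area_m2=config.collar_area_m2,
            volume_m3=volume,
            start_time=start_time,
        )
        flux_nmol = mass_to_molar_flux(flux_mass, gas)
        # invert the ideal-gas slope conversion used by the fitter
        slope_ppm_s = flux_nmol / slope_to_molar_flux(1.0, probe)
        if saturation_kappa > 0:
            conc = AMBIENT_PPM[gas] + slope_ppm_s * -np.expm1(-saturation_kappa * t) / saturation_kappa
        else:
            conc = AMBIENT_PPM[gas] + slope_ppm_s * t
        sd = noise_sd_ppm.get(gas, 0.0)
        if sd and rng is not None:
            conc = conc + sd * rng.standard_normal(n)
        deployments.append(
            Deployment(
                deployment_id=deployment_id,
                chamber_id=chamber_id,
                gas=gas,
                time_s=t,
                mole_fraction_ppm=conc,
                cavity_temp_k=np.full(n, config.cavity_temp_k),
                cavity_press_kpa=np.full(n, config.cavity_press_kpa),
                collar_area_m2=config.collar_area_m2,
                volume_m3=volume,
                start_time=start_time,
            )
        )
    return deployments


def sensor_series(
    config: CampaignConfig, model: TrueFluxModel, rng: np.random.Generator
) -> pd.DataFrame:
    """15-min soil moisture / O2 / temperature at 10, 30 and 50 cm."""
    ts = pd.date_range(config.start_date, config.end_date, freq="15min", inclusive="left")
    irrigation, rain, _ = _resolve_events(config, model)
    events = sorted(irrigation + rain)
    rows = []
    pulse = _event_pulse(ts, events, decay_days=5.0) if events else np.zeros(len(ts))
    for depth in (10.0, 30.0, 50.0):
        damp = np.exp(-depth / 40.0)
        moisture = 0.25 + 0.15 * damp * pulse + 0.005 * rng.standard_normal(len(ts))
        moisture = np.clip(moisture, 0.02, 0.60)
        o2 = np.clip(20.0 - 40.0 * (moisture - 0.25) + 0.3 * rng.standard_normal(len(ts)), 0.0, 21.0)
        temp = soil_temperature(ts, depth) + 0.1 * rng.standard_normal(len(ts))
        for var, vals in (("moisture", moisture), ("o2", o2), ("temperature", temp)):
            rows.append(
                pd.DataFrame(
                    {"timestamp": ts, "depth_cm": depth, "variable": var, "value": vals}
                )
            )
    return pd.concat(rows, ignore_index=True)


def vegetation_series(
    config: CampaignConfig, model: TrueFluxModel, rng: np.random.Generator
) -> pd.DataFrame:
    """Daily NDVI / NIR / NIRv with regrowth curves reset at harvests."""
    dates = pd.date_range(config.start_date, config.end_date, freq="D", inclusive="left")
    _, _, harvests = _resolve_events(config, model)
    harvest_arr = pd.DatetimeIndex(sorted(harvests)) if harvests else pd.DatetimeIndex([])
    days_since = np.full(len(dates), 60.0)
    if len(harvest_arr):
        pos = harvest_arr.searchsorted(dates, side="right")
        has_prev = pos > 0
        prev = harvest_arr[np.maximum(pos - 1, 0)]
        delta = (dates - prev).days.to_numpy(dtype=float)
        days_since = np.where(has_prev, delta, 60.0)
    ndvi = 0.35 + 0.45 * (1.0 - np.exp(-days_since / 12.0))
    ndvi = np.clip(ndvi + 0.01 * rng.standard_normal(len(dates)), 0.0, 1.0)
    nir = np.clip(0.30 + 0.10 * ndvi + 0.005 * rng.standard_normal(len(dates)), 0.0, 1.0)
    nirv = ndvi * nir
    return pd.DataFrame({"date": dates, "ndvi": ndvi, "nir": nir, "nirv": nirv})


def nee_table(config: CampaignConfig, model: TrueFluxModel) -> pd.DataFrame:
    """Annual NEE / R_eco / GPP per site year (g CO2 m-2 y-1).

    Constant plausible magnitudes for an irrigated perennial forage system:
    a strong CO2 sink whose NEE = R_eco - GPP.
    """
    sm, sd = config.site_year_start
    dates = pd.date_range(config.start_date, config.end_date, freq="D", inclusive="left")
    labels = assign_site_year(dates, start_month=sm, start_day=sd).unique()
    nee, reco = -2330.0, 6451.0
    return pd.DataFrame(
        {
            "site_year": labels,
            "nee": nee,
            "reco": reco,
            "gpp": reco - nee,
        }
    )


def _true_annual(truth_series: pd.DataFrame, site_year_start: Tuple[int, int]) -> pd.DataFrame:
    sm, sd = site_year_start
    df = truth_series.copy()
    df["date"] = pd.to_datetime(df["timestamp"]).dt.normalize()
    daily = df.groupby(["gas", "date"])["true_flux"].mean().reset_index()
    daily["site_year"] = assign_site_year(daily["date"], start_month=sm, start_day=sd)
    annual = (
        daily.groupby(["gas", "site_year"])["true_flux"]
        .mean()
        .mul(365.0)
        .rename("annual_flux")
        .reset_index()
    )
    return annual


def generate_campaign(
    config: CampaignConfig, model: Optional[TrueFluxModel] = None
):
    """Build a full synthetic campaign.

    Returns (deployments, sensors, vegetation, nee, truth): a list of
    per-gas :class:`Deployment` traces, the sensor and vegetation frames,
    the annual NEE table, and the :class:`GroundTruth`.  Deterministic for
    a fixed ``config.seed``.
    """
    model = model or TrueFluxModel()
    rng = np.random.default_rng(config.seed)
    schedule = deployment_schedule(config)
    ts = pd.DatetimeIndex(schedule["start_time"])
    background = true_background_fluxes(ts, model, rng)
    irrigation, rain, _ = _resolve_events(config, model)
    hot_component, hot_indicator = hot_moment_component(
        ts, model.hot, sorted(irrigation + rain), rng
    )
    true_flux = dict(background)
    true_flux["n2o"] = true_flux["n2o"] + hot_component

    deployments: List[Deployment] = []
    for i, row in enumerate(schedule.itertuples(index=False)):
        flux_by_gas = {gas: float(true_flux[gas][i]) for gas in GASES}
        deployments.extend(
            synthesize_deployment(
                flux_by_gas,
                config,
                deployment_id=row.deployment_id,
                chamber_id=row.chamber_id,
                start_time=row.start_time,
                rng=rng,
                noise_sd_ppm=model.noise_sd_ppm,
            )
        )

    truth_rows = []
    for gas in GASES:
        truth_rows.append(
            pd.DataFrame(
                {
                    "timestamp": ts,
                    "gas": gas,
                    "true_flux": true_flux[gas],
                    "hot_indicator": hot_indicator if gas == "n2o" else False,
                    "hot_component": hot_component if gas == "n2o" else 0.0,
                }
            )
        )
    truth_series = pd.concat(truth_rows, ignore_index=True)
    truth = GroundTruth(
        series=truth_series,
        annual=_true_annual(truth_series, config.site_year_start),
    )
    sensors = sensor_series(config, model, np.random.default_rng(config.seed + 1))
    vegetation = vegetation_series(config, model, np.random.default_rng(config.seed + 2))
    nee = nee_table(config, model)
    return deployments, sensors, vegetation, nee, truth
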