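"""Per-deployment chamber flux estimation.

A closed opaque chamber of volume V (m3) over soil area A (m2) accumulates
gas released at flux F (mol m-2 s-1).  In the well-mixed, non-saturating
regime the cavity mole fraction grows linearly,

    C(t) = C0 + F * A / (V * rho) * t,

with rho the molar density of air from the ideal-gas law at the cavity
temperature and pressure.  Inverting, a fitted mole-fraction slope b
(mol mol-1 s-1) gives

    F = b * P * V / (R * T * A).

Two models are fitted to every concentration trace: an ordinary
least-squares line, and the Hutchinson-Mosier saturating exponential

    C(t) = C0 + a * (1 - exp(-kappa * t)) / kappa,

whose initial slope a is the flux-relevant quantity and which tends to the
line C0 + a*t as kappa -> 0.  Model selection keeps whichever fit has the
smaller uncertainty ratio |SE/estimate| of its slope; if both ratios exceed
a configurable ceiling the deployment is rejected (consumed by qaqc).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .errors import InsufficientDataError, InvalidConfigError, InvalidGeometryError
from .units import (
    MOLAR_MASS,
    R_GAS,
    SECONDS_PER_DAY,
    mole_fraction_to_ppm,
    molar_to_mass_flux,
)

LINEAR = "linear"
EXPONENTIAL = "exponential"

# Default chamber geometry: ~25 cm automated chamber over a 15 cm collar.
DEFAULT_COLLAR_AREA_M2 = 0.049
DEFAULT_BASE_VOLUME_M3 = 0.012
DEFAULT_COLLAR_HEIGHT_M = 0.15
DEFAULT_VOLUME_M3 = DEFAULT_BASE_VOLUME_M3 + DEFAULT_COLLAR_HEIGHT_M * DEFAULT_COLLAR_AREA_M2


@dataclass
class Deployment:
    """One chamber closure's concentration trace for one gas.

    Timestamps are seconds relative to chamber closure and must be strictly
    increasing.  Mole fractions are stored in ppm regardless of the unit
    they were recorded in (``unit`` keeps the original label).
    """

    deployment_id: str
    chamber_id: str
    gas: str
    time_s: np.ndarray
    mole_fraction_ppm: np.ndarray
    cavity_temp_k: np.ndarray
    cavity_press_kpa: np.ndarray
    collar_area_m2: float
    volume_m3: float
    start_time: pd.Timestamp
    unit: str = "ppm"

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.mole_fraction_ppm = np.asarray(self.mole_fraction_ppm, dtype=float)
        self.cavity_temp_k = np.atleast_1d(np.asarray(self.cavity_temp_k, dtype=float))
        self.cavity_press_kpa = np.atleast_1d(
            np.asarray(self.cavity_press_kpa, dtype=float)
        )
        if self.volume_m3 <= 0 or self.collar_area_m2 <= 0:
            raise InvalidGeometryError(
                f"deployment {self.deployment_id}: volume and area must be positive"
            )
        if self.time_s.size >= 2 and not np.all(np.diff(self.time_s) > 0):
            raise ValueError(
                f"deployment {self.deployment_id}: timestamps must be strictly increasing"
            )
        if not self.unit:
            raise ValueError("mole-fraction unit label required")

    @property
    def duration_s(self) -> float:
        return float(self.time_s[-1] - self.time_s[0]) if self.time_s.size else 0.0

    @property
    def mean_temp_k(self) -> float:
        return float(np.nanmean(self.cavity_temp_k))

    @property
    def mean_press_kpa(self) -> float:
        return float(np.nanmean(self.cavity_press_kpa))


@dataclass
class FitConfig:
    """Fitting and detection-limit settings.

    ``analyzer_precision_ppm`` is the 1-sigma mole-fraction noise per gas;
    the defaults are the precisions at which the default chamber geometry
    and a 10-min, 1 Hz closure yield the conservative reference detection
    limits in ``mdf_reference_nmol`` (0.002 nmol N2O, 0.06 nmol CO2,
    0.002 nmol CH4 m-2 s-1), so the two sets of defaults are mutually
    consistent; see :func:`calibrate_precision_for_mdf`.
    """

    deadband_s: float = 30.0
    max_uncertainty_ratio: float = 1.0
    analyzer_precision_ppm: dict = field(
        default_factory=lambda: {"n2o": 0.0012877, "co2": 0.0386305, "ch4": 0.0012877}
    )
    mdf_reference_nmol: dict = field(
        default_factory=lambda: {"n2o": 0.002, "co2": 0.06, "ch4": 0.002}
    )
    min_samples: int = 10

    def __post_init__(self) -> None:
        if self.deadband_s < 0:
            raise InvalidConfigError("deadband must be >= 0")
        if self.max_uncertainty_ratio <= 0:
            raise InvalidConfigError("max_uncertainty_ratio must be > 0")


@dataclass
class FluxEstimate:
    """One gas flux estimate for one deployment."""

    deployment_id: str
    chamber_id: str
    gas: str
    start_time: pd.Timestamp
    flux_molar: float  # nmol m-2 s-1
    flux_mass: float  # mg gas m-2 d-1
    slope_ppm_s: float
    slope_se_ppm_s: float
    r_squared: float
    model: str
    uncertainty_ratio: float
    below_mdf: bool = False
    converged: bool = True

    def __post_init__(self) -> None:
        # unit-coherence invariant: molar and mass fluxes must agree
        if math.isfinite(self.flux_molar):
            expected = molar_to_mass_flux(self.flux_molar, self.gas)
            if abs(expected - self.flux_mass) > 1e-9 * max(1.0, abs(expected)):
                raise ValueError("flux_mass inconsistent with flux_molar")


def _post_deadband(dep: Deployment, cfg: FitConfig):
    mask = dep.time_s >= dep.time_s[0] + cfg.deadband_s if dep.time_s.size else slice(0)
    t = dep.time_s[mask]
    c = dep.mole_fraction_ppm[mask]
    if t.size < cfg.min_samples:
        raise InsufficientDataError(
            f"deployment {dep.deployment_id}/{dep.gas}: "
            f"{t.size} post-deadband samples (< {cfg.min_samples})"
        )
    return t, c


def slope_to_molar_flux(slope_ppm_s: float, dep: Deployment) -> float:
    """ppm s-1 -> nmol m-2 s-1 via the ideal-gas conversion at the
    deployment's mean cavity temperature and pressure."""
    p_pa = dep.mean_press_kpa * 1000.0
    mol_per_molfrac = p_pa * dep.volume_m3 / (R_GAS * dep.mean_temp_k * dep.collar_area_m2)
    return slope_ppm_s * 1e-6 * mol_per_molfrac * 1e9


def _make_estimate(dep, slope, slope_se, r2, model, converged=True) -> FluxEstimate:
    flux_molar = slope_to_molar_flux(slope, dep)
    ratio = abs(slope_se / slope) if slope != 0 else (0.0 if slope_se == 0 else np.inf)
    return FluxEstimate(
        deployment_id=dep.deployment_id,
        chamber_id=dep.chamber_id,
        gas=dep.gas,
        start_time=dep.start_time,
        flux_molar=flux_molar,
        flux_mass=molar_to_mass_flux(flux_molar, dep.gas),
        slope_ppm_s=slope,
        slope_se_ppm_s=slope_se,
        r_squared=r2,
        model=model,
        uncertainty_ratio=ratio,
        converged=converged,
    )


def fit_linear(dep: Deployment, cfg: Optional[FitConfig] = None) -> FluxEstimate:
    """Ordinary least-squares flux estimate for one deployment."""
    cfg = cfg or FitConfig()
    t, c = _post_deadband(dep, cfg)
    tb = t - t.mean()
    cb = c - c.mean()
    sxx = float(tb @ tb)
    slope = float(tb @ cb) / sxx
    resid = cb - slope * tb
    n = t.size
    sse = float(resid @ resid)
    slope_se = math.sqrt(sse / (n - 2) / sxx) if n > 2 else np.inf
    sst = float(cb @ cb)
    r2 = 1.0 - sse / sst if sst > 0 else 1.0
    return _make_estimate(dep, slope, slope_se, r2, LINEAR)


def _hm_model(t, c0, a, kappa):
    # C0 + a*(1-exp(-k t))/k, numerically stable as k -> 0
    kt = kappa * t
    with np.errstate(over="ignore"):
        return c0 + a * np.where(kt > 1e-8, -np.expm1(-kt) / np.maximum(kappa, 1e-300), t * (1 - kt / 2))


def _hm_jac(t, c0, a, kappa):
    kt = kappa * t
    small = kt <= 1e-8
    with np.errstate(over="ignore"):
        e = np.exp(-kt)
        d_c0 = np.ones_like(t)
        d_a = np.where(small, t * (1 - kt / 2), -np.expm1(-kt) / np.maximum(kappa, 1e-300))
        d_k = np.where(
            small,
            -a * t * t / 2,
            a * (t * e * kappa + np.expm1(-kt)) / np.maximum(kappa**2, 1e-300),
        )
    return np.column_stack([d_c0, d_a, d_k])


def fit_exponential(dep: Deployment, cfg: Optional[FitConfig] = None) -> FluxEstimate:
    """Hutchinson-Mosier saturating-exponential flux estimate.

    The model is parametrized by its initial slope ``a`` so the standard
    error of the flux comes straight out of the fit covariance and the
    linear model is nested at kappa -> 0.  Non-convergence yields an
    estimate flagged ``converged=False`` with infinite uncertainty ratio.
    """
    cfg = cfg or FitConfig()
    t, c = _post_deadband(dep, cfg)
    t0 = t - t[0]
    lin = np.polyfit(t0, c, 1)
    p0 = (float(lin[1]), float(lin[0]), 1e-4)
    try:
        popt, pcov = curve_fit(
            _hm_model,
            t0,
            c,
            p0=p0,
            jac=_hm_jac,
            bounds=([-np.inf, -np.inf, 0.0], [np.inf, np.inf, 1.0]),
            maxfev=200,
        )
        a = float(popt[1])
        a_se = float(np.sqrt(pcov[1, 1])) if np.all(np.isfinite(pcov)) else np.inf
        resid = c - _hm_model(t0, *popt)
        sse = float(resid @ resid)
        cb = c - c.mean()
        sst = float(cb @ cb)
        r2 = 1.0 - sse / sst if sst > 0 else 1.0
        return _make_estimate(dep, a, a_se, r2, EXPONENTIAL)
    except RuntimeError:
        est = _make_estimate(dep, p0[1], np.inf, 0.0, EXPONENTIAL, converged=False)
        est.uncertainty_ratio = np.inf
        return est


def select_model(
    lin: FluxEstimate, exp: FluxEstimate, cfg: Optional[FitConfig] = None
) -> Optional[FluxEstimate]:
    """Keep the fit with the smaller uncertainty ratio.

    Returns ``None`` (a rejection, not an error) when both models carry an
    uncertainty ratio above ``cfg.max_uncertainty_ratio``; qaqc accounts
    for these rejections.  Ties go to the linear (simpler) model.
    """
    cfg = cfg or FitConfig()
    if (
        lin.uncertainty_ratio > cfg.max_uncertainty_ratio
        and exp.uncertainty_ratio > cfg.max_uncertainty_ratio
    ):
        return None
    if not exp.converged:
        return lin
    return lin if lin.uncertainty_ratio <= exp.uncertainty_ratio else exp


def minimum_detectable_flux(
    cfg: FitConfig,
    gas: str,
    collar_area_m2: float,
    volume_m3: float,
    closure_s: float,
    temp_k: float = 298.15,
    press_kpa: float = 101.325,
    sample_hz: float = 1.0,
) -> float:
    """Analyzer-noise detection limit, nmol m-2 s-1.

    MDF = (sigma / t_closure) * sqrt(2/n) * P*V / (R*T*A), with sigma the
    1-sigma analyzer precision and n the number of samples in the closure.
    Decreases with longer closures and denser sampling.
    """
    if closure_s <= 0 or sample_hz <= 0:
        raise InvalidConfigError("closure time and sampling rate must be positive")
    if collar_area_m2 <= 0 or volume_m3 <= 0:
        raise InvalidGeometryError("area and volume must be positive")
    sigma_ppm = cfg.analyzer_precision_ppm[gas]
    n = max(closure_s * sample_hz, 1.0)
    slope_sigma = sigma_ppm / closure_s * math.sqrt(2.0 / n)
    p_pa = press_kpa * 1000.0
    return slope_sigma * 1e-6 * p_pa * volume_m3 / (R_GAS * temp_k * collar_area_m2) * 1e9


def calibrate_precision_for_mdf(
    target_mdf_nmol: float,
    collar_area_m2: float = DEFAULT_COLLAR_AREA_M2,
    volume_m3: float = DEFAULT_VOLUME_M3,
    closure_s: float = 600.0,
    temp_k: float = 298.15,
    press_kpa: float = 101.325,
    sample_hz: float = 1.0,
) -> float:
    """Analyzer precision (ppm, 1-sigma) at which the given geometry and
    closure produce ``target_mdf_nmol`` as the minimum detectable flux."""
    probe = FitConfig(analyzer_precision_ppm={"probe": 1.0})
    unit_mdf = minimum_detectable_flux(
        probe, "probe", collar_area_m2, volume_m3, closure_s, temp_k, press_kpa, sample_hz
    )
    return target_mdf_nmol / unit_mdf


def flag_below_mdf(est: FluxEstimate, cfg: FitConfig) -> FluxEstimate:
    """Mark (never drop) estimates whose magnitude is under the per-gas
    reference MDF."""
    ref = cfg.mdf_reference_nmol.get(est.gas)
    if ref is not None and abs(est.flux_molar) < ref:
        return replace(est, below_mdf=True)
    return est


def estimate_fluxes(
    deployments, cfg: Optional[FitConfig] = None, fit_both: bool = True
):
    """Fit every deployment; return (DataFrame of kept fluxes, n_rejected).

    Each row of the frame is one kept per-gas flux estimate; deployments
    where both models exceeded the uncertainty ceiling are counted in
    ``n_rejected`` and their ids returned for the QC report.
    """
    cfg = cfg or FitConfig()
    rows = []
    rejected_ids = []
    for dep in deployments:
        lin = fit_linear(dep, cfg)
        if fit_both:
            exp = fit_exponential(dep, cfg)
            best = select_model(lin, exp, cfg)
        else:
            best = lin if lin.uncertainty_ratio <= cfg.max_uncertainty_ratio else None
        if best is None:
            rejected_ids.append((dep.deployment_id, dep.gas))
            continue
        best = flag_below_mdf(best, cfg)
        rows.append(
            {
                "deployment_id": best.deployment_id,
                "chamber_id": best.chamber_id,
                "timestamp": best.start_time,
                "gas": best.gas,
                "flux_mass": best.flux_mass,
                "flux_molar": best.flux_molar,
                "model": best.model,
                "uncertainty_ratio": best.uncertainty_ratio,
                "r_squared": best.r_squared,
                "below_mdf": best.below_mdf,
                "qc_flags": "",
            }
        )
    df = pd.DataFrame(
        rows,
        columns=[
            "deployment_id",
            "chamber_id",
            "timestamp",
            "gas",
            "flux_mass",
            "flux_molar",
            "model",
            "uncertainty_ratio",
            "r_squared",
            "below_mdf",
            "qc_flags",
        ],
    )
    return df, rejected_ids
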