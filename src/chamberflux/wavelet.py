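"""Morlet continuous wavelet transform and wavelet coherence.

The transform follows the standard FFT formulation for the Morlet mother
wavelet with angular frequency omega0 = 6, on dyadic scales s_j = s0 *
2^(j*dj) from s0 = 2*dt up to n*dt/3, with sub-octave resolution dj (default
1/12).  The Fourier period of scale s is

    period = 4*pi*s / (omega0 + sqrt(2 + omega0^2))  ~ 1.033 s,

and the cone of influence is the e-folding distance sqrt(2)*s from each
edge.

Wavelet coherence between series x and y is the locally smoothed squared
cross-spectrum,

    R^2 = |S(Wxy / s)|^2 / ( S(|Wx|^2 / s) * S(|Wy|^2 / s) ),

with Wxy = Wx * conj(Wy) and S a boxcar smoother acting over time (window
equal to the scale, in samples) then over scale (0.6 octave).  Smoothing is
what makes coherence informative: unsmoothed coherence is identically 1.
Because S has positive weights, the Cauchy-Schwarz inequality bounds R^2 in
[0, 1].  The cross-spectrum phase gives lead/lag between the series.

Pointwise significance is Monte Carlo: surrogate pairs (white noise,
shuffled data, or fitted AR1) are run through the same coherence pipeline
and the p-value at each (time, scale) is the fraction of surrogates whose
coherence there reaches the observed value.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np
from scipy.ndimage import uniform_filter1d

from .errors import InsufficientDataError, InvalidConfigError

WHITE_NOISE = "white_noise"
SHUFFLE = "shuffle"
AR1 = "ar1"


@dataclass
class WaveletConfig:
    omega0: float = 6.0
    dt: float = 1.0  # sampling interval, days
    dj: float = 1.0 / 12.0  # sub-octave resolution
    scale_smoothing_octaves: float = 0.6
    n_sims: int = 1000
    surrogate: str = WHITE_NOISE
    alpha: float = 0.05
    seed: int = 0
    max_missing_fraction: float = 0.5

    def __post_init__(self) -> None:
        if self.n_sims < 1:
            raise InvalidConfigError("n_sims must be >= 1")
        if self.dj <= 0 or self.dt <= 0:
            raise InvalidConfigError("dt and dj must be positive")
        if self.surrogate not in (WHITE_NOISE, SHUFFLE, AR1):
            raise InvalidConfigError(f"unknown surrogate kind {self.surrogate!r}")

    @property
    def fourier_factor(self) -> float:
        return 4.0 * np.pi / (self.omega0 + np.sqrt(2.0 + self.omega0**2))

    def scales(self, n: int) -> np.ndarray:
        """Dyadic scale grid from 2*dt to <= n*dt/3."""
        s0 = 2.0 * self.dt
        smax = n * self.dt / 3.0
        if smax < s0:
            raise InsufficientDataError("series too short for the smallest scale")
        jmax = int(np.floor(np.log2(smax / s0) / self.dj))
        return s0 * 2.0 ** (self.dj * np.arange(jmax + 1))


@dataclass
class CoherenceResult:
    time: np.ndarray  # sample times (units of dt)
    period: np.ndarray  # Fourier periods per scale row
    scales: np.ndarray
    coherence: np.ndarray  # (n_scales, n_times), in [0, 1]
    phase: np.ndarray  # radians in (-pi, pi]
    cross_power: np.ndarray
    power_x: np.ndarray
    power_y: np.ndarray
    coi_period: np.ndarray  # largest in-cone period per time
    p_value: Optional[np.ndarray] = None
    significant: Optional[np.ndarray] = None
    alpha: float = 0.05

    @property
    def in_coi(self) -> np.ndarray:
        """Boolean (n_scales, n_times) mask of points inside the cone."""
        return self.period[:, None] <= self.coi_period[None, :]


def preprocess(series, cfg: Optional[WaveletConfig] = None) -> Tuple[np.ndarray, np.ndarray, bool]:
    """Center on the observed mean and set missing values to zero.

    Returns (filled series, gap mask, warning flag).  Because the series is
    centered first, a zero-filled gap sits exactly at the mean, which keeps
    the wavelet variance estimator unbiased by gaps.
    """
    cfg = cfg or WaveletConfig()
    x = np.asarray(series, dtype=float)
    missing = ~np.isfinite(x)
    n_obs = int((~missing).sum())
    if n_obs == 0:
        raise InsufficientDataError("series has no finite values")
    out = x - x[~missing].mean()
    out[missing] = 0.0
    warn = missing.mean() > cfg.max_missing_fraction
    return out, missing, warn


def cwt_morlet(series, cfg: Optional[WaveletConfig] = None):
    """Morlet CWT of a (gap-free) series.

    Returns (W, scales, periods, coi_period): W is complex with shape
    (n_scales, n).  The series is zero-padded to the next power of two so
    the FFT convolution does not wrap; the cone of influence marks where
    the padding (and edges generally) contaminate coefficients.
    """
    cfg = cfg or WaveletConfig()
    x = np.asarray(series, dtype=float)
    n = x.size
    scales = cfg.scales(n)
    npad = int(2 ** np.ceil(np.log2(n))) if n > 1 else 2
    fx = np.fft.fft(x, npad)
    omega = 2.0 * np.pi * np.fft.fftfreq(npad, d=cfg.dt)
    # Morlet daughter in Fourier space, unit-energy normalization
    norm = (np.pi**-0.25) * np.sqrt(2.0 * np.pi * scales[:, None] / cfg.dt)
    heaviside = omega[None, :] > 0
    arg = (scales[:, None] * omega[None, :] - cfg.omega0) ** 2 / 2.0
    daughter = np.where(heaviside, norm * np.exp(-np.where(heaviside, arg, 0.0)), 0.0)
    W = np.fft.ifft(fx[None, :] * np.conj(daughter), axis=1)[:, :n]
    periods = cfg.fourier_factor * scales
    dist = np.minimum(np.arange(n), np.arange(n)[::-1]) * cfg.dt
    coi_period = cfg.fourier_factor * dist / np.sqrt(2.0)
    return W, scales, periods, coi_period


def _smooth(field2d: np.ndarray, scales: np.ndarray, cfg: WaveletConfig) -> np.ndarray:
    """Boxcar smoothing over time (window = scale, per row) then scale."""
    out = np.empty_like(field2d)
    for i, s in enumerate(scales):
        w = max(1, int(round(s / cfg.dt)))
        out[i] = uniform_filter1d(field2d[i], size=w, mode="nearest")
    nrows = max(1, int(round(cfg.scale_smoothing_octaves / cfg.dj)))
    if nrows > 1:
        out = uniform_filter1d(out, size=nrows, axis=0, mode="nearest")
    return out


def _coherence_fields(wx, wy, scales, cfg):
    sinv = 1.0 / scales[:, None]
    cross = wx * np.conj(wy) * sinv
    s_cross = _smooth(cross.real, scales, cfg) + 1j * _smooth(cross.imag, scales, cfg)
    s_px = _smooth((np.abs(wx) ** 2) * sinv, scales, cfg)
    s_py = _smooth((np.abs(wy) ** 2) * sinv, scales, cfg)
    denom = s_px * s_py
    with np.errstate(divide="ignore", invalid="ignore"):
        coh = np.abs(s_cross) ** 2 / denom
    coh = np.where(denom > 0, coh, 0.0)
    return np.clip(coh, 0.0, 1.0), s_cross, s_px, s_py


def coherence(x, y, cfg: Optional[WaveletConfig] = None) -> CoherenceResult:
    """Wavelet coherence, phase and powers of two equal-length series."""
    cfg = cfg or WaveletConfig()
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("series must have the same length")
    wx, scales, periods, coi = cwt_morlet(x, cfg)
    wy, _, _, _ = cwt_morlet(y, cfg)
    coh, s_cross, s_px, s_py = _coherence_fields(wx, wy, scales, cfg)
    return CoherenceResult(
        time=np.arange(x.size) * cfg.dt,
        period=periods,
        scales=scales,
        coherence=coh,
        phase=np.angle(s_cross),
        cross_power=np.abs(s_cross),
        power_x=s_px,
        power_y=s_py,
        coi_period=coi,
        alpha=cfg.alpha,
    )


def _fit_ar1(x: np.ndarray) -> Tuple[float, float]:
    x = x - x.mean()
    denom = float(x[:-1] @ x[:-1])
    rho = float(x[1:] @ x[:-1]) / denom if denom > 0 else 0.0
    rho = min(max(rho, -0.999), 0.999)
    sigma = np.sqrt(max(x.var() * (1 - rho**2), 1e-300))
    return rho, sigma


def _surrogate(x: np.ndarray, kind: str, rng: np.random.Generator) -> np.ndarray:
    if kind == WHITE_NOISE:
        return rng.standard_normal(x.size) * x.std()
    if kind == SHUFFLE:
        return rng.permutation(x)
    rho, sigma = _fit_ar1(x)
    eps = rng.standard_normal(x.size) * sigma
    out = np.empty_like(eps)
    out[0] = eps[0] / np.sqrt(1 - rho**2)
    for i in range(1, x.size):
        out[i] = rho * out[i - 1] + eps[i]
    return out


def significance(x, y, cfg: Optional[WaveletConfig] = None) -> CoherenceResult:
    """Coherence with Monte-Carlo pointwise p-values and an alpha mask.

    The mask is restricted to the cone of influence.  Deterministic for a
    fixed ``cfg.seed``.
    """
    cfg = cfg or WaveletConfig()
    result = coherence(x, y, cfg)
    rng = np.random.default_rng(cfg.seed)
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    exceed = np.zeros_like(result.coherence)
    for _ in range(cfg.n_sims):
        sx = _surrogate(x, cfg.surrogate, rng)
        sy = _surrogate(y, cfg.surrogate, rng)
        sim = coherence(sx, sy, cfg)
        exceed += sim.coherence >= result.coherence
    result.p_value = exceed / cfg.n_sims
    result.significant = (result.p_value < cfg.alpha) & result.in_coi
    return result


def lead_lag_summary(result: CoherenceResult, period_band: Tuple[float, float]) -> dict:
    """Circular-mean phase and implied lag over significant in-cone points
    within a period band.  Positive phase: x leads y.  Returns NaNs when
    the band holds no significant points.
    """
    lo, hi = period_band
    band = (result.period >= lo) & (result.period <= hi)
    if not band.any():
        raise ValueError("period band outside the computed period grid")
    mask = result.in_coi[band]
    if result.significant is not None:
        mask = mask & result.significant[band]
    phases = result.phase[band][mask]
    periods = np.broadcast_to(result.period[band, None], result.phase[band].shape)[mask]
    if phases.size == 0:
        return {"mean_phase": float("nan"), "mean_lag": float("nan"), "n_points": 0}
    mean_phase = float(np.angle(np.exp(1j * phases).mean()))
    mean_period = float(periods.mean())
    return {
        "mean_phase": mean_phase,
        "mean_lag": mean_phase / (2.0 * np.pi) * mean_period,
        "n_points": int(phases.size),
    }
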