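# Methods

This note records the models implemented, the defaults and why, what the
synthetic generator does and does not emulate, and the numerical choices a
maintainer would otherwise have to reverse-engineer.

## Chamber flux estimation

A closure accumulates gas in a headspace of volume *V* (m³) over soil area
*A* (m²). In the non-saturating regime the mole fraction is linear in time
and the flux follows from the OLS slope *b* via the ideal-gas law,
*F = b·P·V/(R·T·A)* with *R* = 8.314462618 J mol⁻¹ K⁻¹ and *T*, *P* the
deployment means of the analyzer cavity readings (the only temperature and
pressure available per sample in this data model; no water-vapor dilution
correction is applied — the emulated instrument reports dry mole
fractions). Mass fluxes are reported as mg gas m⁻² d⁻¹
(= nmol m⁻² s⁻¹ × molar mass × 86400 × 10⁻⁶, asserted for every estimate).

The saturating alternative is the Hutchinson–Mosier exponential. We
parametrize it by its **initial slope** *a*:

    C(t) = C0 + a·(1 − e^{−κt})/κ,   κ ∈ [0, 1] s⁻¹,

which (i) tends smoothly to the straight line *C0 + a·t* as κ → 0, so the
fit stays well-conditioned on nearly linear traces, and (ii) makes the
flux-relevant quantity a fitted parameter, so its standard error comes
directly from the covariance matrix rather than a delta-method propagation.
Fits use analytic Jacobians with a series expansion below κt = 10⁻⁸.
Non-convergence yields a flagged estimate with infinite uncertainty ratio
(the deployment then falls back to the linear model if that one is valid).

Model selection keeps the fit with the smaller uncertainty ratio
|SE/estimate|; ties go to the simpler (linear) model; when both ratios
exceed `max_uncertainty_ratio` (default 1.0 — i.e. the standard error
exceeds the estimate itself) the closure is rejected and accounted for in
the QC report. The first 30 s of each closure are discarded by default
(deadband) to avoid closure turbulence; both thresholds are configurable
because field practice varies.

**Minimum detectable flux.** MDF = (σ/t_closure)·√(2/n)·P·V/(R·T·A), with
σ the 1-σ analyzer precision and n the samples per closure. The default
per-gas precisions (1.29 ppb N₂O, 38.6 ppb CO₂ — in ppm units 0.0013 and
0.0386 — and 1.29 ppb CH₄) are chosen so the default geometry (0.049 m²
collar, 19.35 L total volume, 10-min closure at 1 Hz) yields the
conservative reference limits 0.002 / 0.06 / 0.002 nmol m⁻² s⁻¹ for
N₂O / CO₂ / CH₄. Estimates under the limit are flagged `below_mdf`, never
dropped, and the flagged fraction is reported.

## QA/QC

Record-level filters, in fixed order, attribution to the first failure:

1. deployment period outside 9–11 min (chamber malfunction),
2. any negative mole fraction (instrument malfunction),
3. cavity temperature outside 30–50 °C or pressure outside 15–25 kPa
   (defaults bracket a reduced-pressure ring-down cavity set point; the
   plausible range is configurable because "erroneous" has no universal
   bounds).

All gases of a closure are dropped together (one analyzer, one verdict).
Both-model-uncertainty rejections from fitting appear as a separate row in
the same report so the overall removed fraction can be read either
including or excluding them. Filtering is idempotent and conserves
records: kept + removed = input, and the kept set is independent of input
order.

## Hot moments

A measurement is a hot moment when x > mean + k·sd with k = 4, both
moments computed in a **single pass including prospective outliers** —
iterative re-screening would flag more points and is deliberately not
done. Detection runs per site year and in aggregate; the upper tail only
by default (emission events), with a two-sided option for uptake studies.
Contribution is 100·Σ(hot)/Σ(all) on the summed-flux basis, equivalent to
time weighting under approximately even sampling; per-measurement and
annualized means are both reported. The exact per-measurement
decomposition mean_all·n = hot_mean·n_hot + mean_without·(n − n_hot) is a
tested invariant.

## Budgets

* Site year: Jan 27 00:00 (inclusive) to the next Jan 27 (exclusive).
* Daily composite: mean ± SE over measurements per calendar day; days
  without data are absent, never zero.
* Annualization: mean of daily means × 365 (365.25 configurable); site
  years below a 50% completeness threshold are flagged, not dropped. The
  integration scheme is a package choice; alternatives (day-weighted
  trapezoid) differ negligibly at near-continuous coverage.
* CO₂ equivalents: AR5 100-year GWPs (N₂O 298, CH₄ 28, mass basis);
  g CO₂e = mg gas × GWP / 1000. Linearity is asserted.
* Total CO₂e = NEE + N₂O-GWP + CH₄-GWP, exact closure on unrounded
  values. The N₂O offset of the carbon sink uses denominator
  |NEE + CH₄-GWP| (the C-based sink); because other denominators are
  defensible, a diagnostics table reports |NEE| and |total CO₂e| variants
  too.
* N mass: kg N-N₂O ha⁻¹ y⁻¹ = mg N₂O m⁻² y⁻¹ × 0.01 × 28/44; the inverse
  round-trips to 1e-12 relative.
* Harvest accounting accepts harvested C (g C m⁻² y⁻¹, converted by
  44/12) **or** harvested CO₂ directly, never silently interconverting —
  published yield figures are sometimes inconsistent between the two
  bases, so the caller must choose one.
* Diel composites use meteorological seasons (DJF/MAM/JJA/SON) and a
  configurable UTC offset for site-local hour.

## Wavelet coherence

Torrence–Compo-style Morlet CWT (ω₀ = 6) computed by FFT with zero-padding
to the next power of two; dyadic scales from 2·dt to n·dt/3 at 12
sub-octaves; Fourier period = 4πs/(ω₀+√(2+ω₀²)) ≈ 1.033 s; cone of
influence at the √2·s e-folding distance from each edge.

Coherence R² = |S(W_xy/s)|²/(S(|W_x|²/s)·S(|W_y|²/s)). Smoothing S is a
boxcar over time of width equal to the scale (in samples) followed by a
boxcar over 0.6 octave in scale. Any positive-weight smoother gives
R² ∈ [0,1] by Cauchy–Schwarz (unsmoothed coherence is identically 1, so
smoothing is mandatory); values are clipped to [0,1] against float error.
Phase = arg S(W_xy/s), positive when x leads y; band lead/lag summaries
use the circular mean of phase over significant in-cone points and convert
via lag = phase/(2π)·period per point.

Gaps are handled by mean-centering on the observed values and then setting
missing entries to zero (a zero then sits exactly at the mean, keeping the
wavelet variance estimator unbiased by gaps); a flag is raised above 50%
missing.

Significance is pointwise Monte Carlo: surrogate pairs — white noise
matched in variance (default), shuffled data, or fitted AR1 — run through
the identical pipeline; p = fraction of surrogates whose coherence at that
(time, scale) reaches the observed value; the α = 0.05 mask is restricted
to the cone of influence and is deterministic given the seed. The
white-noise default matches common practice; AR1 is offered because flux
series are autocorrelated, making white-noise p-values anti-conservative
at long periods. Production analyses use 1000 simulations; desk-scale
runs (tests, the numbered scripts, the acceptance script) use 200, which
resolves α = 0.05 to ±0.015 at 1σ.

## Synthetic campaign generator

The generator emulates the *measurement structure* of a four-site-year
automated chamber study, not its biogeochemistry (no denitrification
kinetics, no O₂ diffusion — it is a statistical emulator):

* **Schedule.** Chambers cycle back-to-back: 1.5-min flush then 10-min
  closure each. Nine chambers give ~125 closures/day; the desk-scale
  configuration used throughout the scripts and tests is one chamber with
  a 132.5-min idle per cycle (~10 closures/day) over four site years at
  0.2 Hz sampling — chosen to keep a full pipeline run in minutes on one
  CPU while preserving every structural feature. Collar heights may be
  supplied as a weekly series and are interpolated, entering the chamber
  volume.
* **N₂O background**: lognormal around a summer-peaking seasonal median
  (median 1.3 mg m⁻² d⁻¹, log-scale seasonal amplitude 0.5, σ = 0.35) —
  strictly positive and right-skewed like observed flux distributions.
* **Hot moments**: each irrigation/rain event (deterministic calendars:
  irrigation every 15 d May–Sep, rain every ~16 d Oct–Mar) triggers one
  pulse at a uniform 0–2 day lag, snapped to the next sampled timestamp so
  the peak is observed. Peak magnitudes are lognormal with median
  350 mg N₂O m⁻² d⁻¹ (the scale of observed event means), decaying with a
  0.02-day e-folding — sharp sub-hour pulses, consistent with emissions
  peaking within hours of irrigation onset. Ground truth marks samples
  where the pulse is at ≥ 50% of its peak. At the default event calendar
  this yields ~0.5% of measurements as hot moments carrying roughly half
  of the total N₂O emission.
* **CH₄**: persistent sink, mean −0.147 mg m⁻² d⁻¹ with weak seasonality
  and Gaussian noise.
* **CO₂**: Q10 = 2 response of respiration to the 10-cm soil temperature
  around a 15 °C reference of 13.5 g CO₂ m⁻² d⁻¹, with multiplicative
  noise.
* **Sensors**: moisture = baseline 0.25 m³ m⁻³ + event pulses drying with
  a 5-day e-folding, damped with depth; O₂ an affine decreasing function
  of moisture; temperature annual + diel sinusoids damped with depth; all
  at 15-min cadence, depths 10/30/50 cm.
* **NIRv** = NDVI × NIR, with NDVI regrowing along a saturating curve
  reset at each harvest (monthly April–October).
* **NEE table**: constant plausible sink (−2330 g CO₂ m⁻² y⁻¹ with
  R_eco 6451 and GPP = R_eco − NEE) per site year.
* **Traces** invert the exact ideal-gas conversion the fitter uses, at
  cavity conditions 313.15 K / 20 kPa, ambient starts 0.33 ppm N₂O,
  1.9 ppm CH₄, 420 ppm CO₂, with i.i.d. Gaussian analyzer noise at the
  default per-gas precisions. Noise-free campaigns therefore round-trip
  exactly: fitted fluxes equal configured truth to machine precision, and
  annualized budgets match the ground-truth budgets to ≪ 0.1%.

What passing tests on this generator show: that the estimators and
accounting are correct against known truth under the stated statistical
structure. What they do not show: robustness to real-instrument pathologies
(drift, spikes, water-vapor interference), spatial chamber heterogeneity,
autocorrelated background noise, or hot-moment shapes other than sharp
exponential pulses.

## Degenerate inputs and tie-breaks

* Constant trace → zero slope; its uncertainty ratio is infinite (no
  signal), so such closures survive only through the below-MDF flag path.
* Hot-moment groups need ≥ 2 finite values (sample sd undefined
  otherwise → explicit error); zero total flux → contribution NaN.
* Zero-variance x in pairwise regression → explicit undefined-slope error.
* Equal uncertainty ratios → linear model.
* All-zero series in the CWT → zero power, coherence 0/0 handled as 0.

## Known limitations

* Annualization SE treats daily means as independent; autocorrelation
  makes the reported annual SE optimistic.
* The pointwise Monte-Carlo significance mask carries the usual
  multiple-testing caveat across the time–period plane; area-wise
  corrections are out of scope.
* The white-noise surrogate understates long-period significance
  thresholds for autocorrelated series (use the AR1 surrogate).
* NEE enters as given annual values ± SE; no eddy-covariance processing
  or NEE uncertainty propagation is attempted.
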