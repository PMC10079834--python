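# CSV formats

All artifacts are UTF-8 CSV with a header row and ISO-8601 timestamps
(stored in UTC; site-local time is derived only for diel composites via a
configured offset). Extra columns are accepted and preserved; missing
required columns raise a schema error naming them.

## deployments (long form, one row per sample per gas)

| column | unit / form |
|---|---|
| deployment_id | string, one per closure |
| chamber_id | string |
| timestamp | ISO-8601 |
| gas | n2o / ch4 / co2 |
| mole_fraction | in `unit` |
| unit | ppm or ppb |
| cavity_temp_k | K |
| cavity_press_kpa | kPa |
| collar_area_m2 | m² |
| volume_m3 | m³ (base + collar height × area) |

## fluxes (one row per kept estimate)

deployment_id, chamber_id, timestamp, gas, flux_mass (mg gas m⁻² d⁻¹),
flux_molar (nmol m⁻² s⁻¹), model (linear/exponential), uncertainty_ratio,
r_squared, below_mdf, qc_flags.

## sensors

timestamp, depth_cm (10/30/50), variable (moisture m³ m⁻³ / o2 % /
temperature °C), value.

## vegetation

date, ndvi, nir, nirv (= ndvi × nir).

## nee (annual, g CO₂ m⁻² y⁻¹; negative = net uptake)

site_year (e.g. 2017-2018), nee, reco, gpp.

## ground truth

timestamp, gas, true_flux (mg m⁻² d⁻¹), hot_indicator (bool, N₂O only),
hot_component (mg m⁻² d⁻¹).

## qc report

rule, n_removed, n_input, fraction_of_input; the TOTAL row aggregates.
Rules: duration_out_of_range, negative_concentration, cavity_out_of_range,
both_models_high_uncertainty.

## coherence (long form)

time, period (days), coherence [0,1], phase (radians, positive = x leads),
p_value, significant (bool, α mask within the cone of influence).
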