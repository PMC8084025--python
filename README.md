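# hydricniche

Thermal–hydric mechanistic niche analysis for terrestrial-breeding
amphibians.

Terrestrial-breeding frogs such as the critically endangered
white-bellied frog (*Geocrinia alba*) of southwestern Australia complete
their entire life cycle in narrow riparian soil microhabitats, so their
persistence hinges on two physiological limits: how hot the soil can get
before development fails, and how dry it can get before the frog can no
longer absorb water through its skin. `hydricniche` packages the full
analysis chain used to quantify both limits and compare them against
field microclimates and regional climate trends. It is written for
ecophysiologists and conservation scientists who have incubation
records, water-balance trials, soil sensor series and weather-station
data, and want reproducible threshold estimates.

## What it computes

**Thermal limits from development rates** (`hydricniche.devrate`).
Development rate *r(T)* (% development day⁻¹) is a five-parameter
unimodal curve: with *v* = (*T* − *b*₃)/(*b*₃ − *b*₂),

    r(T) = b1 · 10^(−v²)                        for T ≤ b3
    r(T) = b1 · 10^(−v²) · max(0, 1 − (b4+b5)v²)  for T > b3

so the peak rate *b*₁ is reached exactly at the thermal optimum
*T*_opt = *b*₃ and the rate falls to zero at
*b*₃ + (*b*₃ − *b*₂)/√(*b*₄+*b*₅), the extrapolated critical thermal
maximum *CT*_max. Durations under arbitrary (constant or fluctuating)
regimes are predicted by rate summation — accumulating *r(T_t)*·Δt/24 h
until 100% development — and the curve is fitted to observed
stage-19→39 durations by bounded nonlinear least squares with any
parameter subset held fixed (*b*₅ = 0.4 by convention). Warming
tolerance (WT = *CT*_max − *T*_hab-max) and thermal safety margin
(TSM = *T*_opt − *T*_hab) follow.

**Hydric limits from water-balance trials** (`hydricniche.waterbal`).
Net cutaneous flux (mg cm⁻² h⁻¹, surface area 9.9·mass^0.56) is reduced
per substrate water-potential treatment, and the absorption threshold
*AT* — the ψ at which net flux is zero — is located by linear
interpolation between the bracketing treatment means (or a global
isotonic fit).

**Soil hydration context** (`hydricniche.soilhydro`): van Genuchten
retention curves convert volumetric water content to water potential
(packaged sand and clay curves are anchored at 10.5% and 27.6% VWC
↔ −50 kPa). **Microclimate exposure** (`hydricniche.microclim`): 30-min
soil sensor series are summarised into days per July–June year breaching
*AT*, *T*_opt and *CT*_max, with Spearman correlation of exceedance
against population size. **Climate trends** (`hydricniche.trends`):
Mann–Kendall tests, Sen's slopes with rank-based CIs, 1961–1990 baseline
anomalies and percentile ranks. **Field water loss**
(`hydricniche.fieldloss`): agar-model deployments standardised to a 9-h
daytime loss and summarised by habitat/cover group. Every input can
also be simulated with known truth (`hydricniche.synth`).

## Worked example

```python
>>> import hydricniche as hn
>>> thr = hn.estimate_ctmax(hn.GEOCRINIA_ALBA)
>>> round(thr.t_opt, 2), round(thr.ct_max, 2)
(23.33, 29.59)
```

The published *G. alba* curve peaks at 23.33 °C and its predicted rate
reaches zero at 29.59 °C — the extrapolated *CT*_max. The same applies
end to end on synthetic data:

```sh
$ hydricniche run --out run1 --seed 1
{
  "t_opt_C": 23.26545285251808,
  "ct_max_C": 29.545452852519063,
  "at_kPa": -48.5290759609241,
  "mean_at_exceedance_days": 37.5,
  "spearman_rs": -0.9940297973880049,
  "spearman_p": 5.296153515644835e-07,
  "sen_slope_per_decade": -105.78833550651325
}
```

Here the development-rate curve refitted from 28 simulated split-clutch
durations recovers a thermal optimum of 23.27 °C (truth 23.33 °C), the
flux estimator places the absorption threshold at −48.5 kPa (truth
−50 kPa), the sensor summaries show soils drier than the threshold on
an average of 37.5 days per year with drier sites holding smaller
populations (r_s = −0.99), and the rainfall series' Sen slope of
−106 mm decade⁻¹ recovers the generating −109 mm decade⁻¹ trend. The
report bundle (fitted parameters, thresholds, per-site summaries, trend
table, manifest) is written to `run1/`.

Each stage is also exposed as a subcommand (`fit-devrate`, `ctmax`,
`absorption-threshold`, `soil-convert`, `exceedance`, `trend`,
`fieldloss`, `synth`); see `hydricniche --help`.

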