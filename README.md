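# antshift

Climate-warming vulnerability analysis for ant communities sampled
along altitudinal gradients.

Ground-foraging ants are keystone insects of temperate forests, and
their distributions track air temperature closely. When a region warms
decade by decade, three community-level questions follow: which species
run out of cool habitat entirely (extinction risk), how does each
species' suitable area grow or shrink, and how does the altitudinal
pattern of species richness — temperate assemblages peak at low
altitude, tropical ones at mid-altitude — shift as a result?
`antshift` implements that full analysis as a reusable, tested
pipeline, exercised end-to-end on synthetic landscapes that emulate a
335-site altitude-stratified survey of ~29 common species.

## The models

**Thermal niches (weighted averaging).** For species *j* with
abundance *y<sub>ij</sub>* at sites with air temperature
*x<sub>i</sub>*, the optimum and tolerance are

> WA<sub>j</sub> = Σ<sub>i</sub> x<sub>i</sub> y<sub>ij</sub> / Σ<sub>i</sub> y<sub>ij</sub>,  TOL<sub>j</sub> = √( Σ<sub>i</sub> (x<sub>i</sub> − WA<sub>j</sub>)² y<sub>ij</sub> / Σ<sub>i</sub> y<sub>ij</sub> )

with site-bootstrap standard errors (1000 cycles) and whole-model
diagnostics from weighted-averaging calibration with inverse
deshrinking.

**Extinction risk.** A species is at risk in a decade if
WA + TOL is smaller than the decade's lowest available air
temperature — the 1st percentile of temperatures in 100-m buffers
around the sites, minimised over sites. Risk rates are reported per
decade, per altitude band, and as a logistic regression of risk on
optimal altitude.

**Occurrence models.** Presence/absence is fitted with an additive
logistic model, g(μ) = α + Σ f<sub>i</sub>(x<sub>i</sub>): one
penalised smooth per predictor (nine temperature variables:
annual/January/July × max/mean/min) plus a linear autocovariate that
absorbs the spatial autocorrelation detected by Moran's I. Validation
is a stratified 70/30 split: AUC, and sensitivity/specificity at the
training Youden threshold; AUC ≥ 0.7 counts as acceptable.

**Projection.** Fitted models are evaluated on warmed predictor
surfaces (+0.5 / +1.2 / +2.4 / +3.5 °C for the 2020s–2080s),
thresholded into presence maps, and summarised as per-species
suitable-area trends (decreased / increased / stable), per-decade
richness surfaces, the altitude of peak richness, its upward rate in
m yr⁻¹, and the shape of the richness–altitude curve
(monotonic-decrease / bell-shaped / monotonic-increase / flat).

See `docs/methods.md` for assumptions, defaults and limitations.

## Worked example

```python
from antshift import PipelineConfig, run_pipeline

config = PipelineConfig(seed=7)          # default synthetic survey design
summary = run_pipeline(config, "demo_run")
print(f"WA calibration r2: {summary['warm_r2']:.2f}")
print(f"mean cross-validated AUC: {summary['mean_auc']:.2f}")
print("risk rate by decade (%):",
      {d: round(v, 1) for d, v in summary['risk_rate_pct'].items()})
print("richness peak altitude (m):", summary['peak_altitude_m'])
print(f"upward movement: {summary['upward_rate_m_per_yr']:.1f} m/yr")
```

prints

```
WA calibration r2: 0.96
mean cross-validated AUC: 0.89
risk rate by decade (%): {'2000s': 0.0, '2020s': 0.0, '2040s': 0.0, '2060s': 0.0, '2080s': 3.4}
richness peak altitude (m): {'2000s': 425.0, '2020s': 525.0, '2040s': 625.0, '2060s': 775.0, '2080s': 975.0}
upward movement: 6.9 m/yr
```

Reading: community composition tracks temperature almost perfectly on
these synthetic data (r² = 0.96), the occurrence models discriminate
well (AUC 0.89), no species loses its last cool refuge before the
2080s (3.4 % = 1 of 29 species at risk then), and the richness peak
climbs 550 m over 80 years. `demo_run/` also receives the full CSV
tables (niche estimates, risk per species × decade, per-band rates,
SDM metrics, trends, richness summaries), per-decade richness grids as
ESRI ASCII, and the resolved `config.yaml` that reproduces the run
bit-for-bit.

The same stages are available from the shell:

```bash
antshift --seed 7 --outdir demo_run run      # full pipeline
antshift --seed 7 --outdir demo_run synth    # just the generator
antshift validate demo_run/sites.csv demo_run/abundance.csv demo_run/temperature_2000s.asc
```

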