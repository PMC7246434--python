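# pocus-impact

Environmental and health impact accounting for **point-of-care ultrasound
(POCUS)** in primary care.

When a general practitioner performs an ultrasound scan at the primary-care
centre (PCC), the patient usually no longer needs to drive to the referral
radiology service. This package turns an event-level scan register into the
savings that follow from those avoided round trips:

* **Avoidance classification** — a scan avoided a face-to-face radiology
  consultation when no same-type radiology visit followed it within a
  90-day window; centres are stratified as *rural* (assigned population
  < 10,000 **and** density < 150 inhabitants/km²) or *urban*.
* **Travel savings** — avoided distance (km), time (min), fuel
  (6.9 L/100 km, small family car) and fuel cost per stratum, with
  per-journey means and 95% confidence intervals.
* **Emission reductions** — for each pollutant, `E = M × N × EF`, where
  `M` is the round-trip distance (km), `N` the number of vehicles (one
  per avoided journey) and `EF` a fleet-average COPERT/EMEP-EEA emission
  factor (g per vehicle-km); 13 pollutants from NOx to SO₂ (CO₂ is outside
  the reporting inventory and deliberately excluded).
* **Health impact assessment** — attributable mortality of a PM₁₀ excess
  over a counterfactual concentration, using a log-linearly rescaled
  relative risk `RR' = RR^(ΔC/10)` and the attributable fraction
  `AD = deaths × (RR' − 1)/RR'`.
* **Descriptive statistics** — scan rates per 10⁴ assigned inhabitants and
  rural-vs-urban Mann–Whitney rank-sum comparisons, with an
  exact-enumeration mode for small groups.

Because such registers are administrative and rarely shareable, the package
ships a **synthetic-data generator**: a study profile captures the aggregate
structure of a real deployment (scan count matrix per professional and type,
referral counts, centre geography), and `generate_register` realises it as a
reproducible event-level register. The bundled `osona` profile encodes a
2019 deployment in Osona county (Catalonia): 1556 scans by 8 GPs across
2 urban and 3 rural centres, 36 referrals, and centre round-trip
distances/times calibrated to the deployment's published stratum summaries
(see `docs/methods.md` for what is measurement and what is calibration).

## Worked example

```bash
$ pocus-impact run-all --seed 1 --out runs/osona
avoided 97.7% of consultations; 27123.0 km, 1871.5 L, 2658.1 EUR saved
```

Of the 1556 scans, 36 led to a face-to-face radiology consult anyway, so
97.7% of consultations were avoided — 1520 round trips, 27,123 km and
1871.5 L of fuel (≈ €2658) in one year. The output directory contains the
register and centre CSVs, one CSV per results table (scan counts, rates,
avoidance, travel, emissions), the HIA result and a run manifest; the same
seed reproduces the bundle byte for byte.

```bash
$ pocus-impact hia --out runs/hia.json
attributable deaths/year: 3.85 (2.57-5.13), rounded 4
```

For the bundled scenario (1426 deaths/year in a population of 153,000,
observed PM₁₀ 24.52 µg/m³, counterfactual 20 µg/m³, RR 1.006 per 10 µg/m³),
lowering PM₁₀ to the counterfactual level would avoid about 4 deaths per
year (interval 3–5 from the RR confidence bounds).

The same computations are available as library calls:

```python
from pocus_impact import (
    default_osona_profile, generate_register,
    avoided_fraction, aggregate_travel, aggregate_emissions,
)

register, centres = generate_register(default_osona_profile(), seed=1)
print(avoided_fraction(register).loc["total", "avoided_pct"])   # 97.7
travel = aggregate_travel(register, centres)
emissions = aggregate_emissions(register, centres)
```

`aggregate_emissions` reports, per journey, means such as 61.4 g CO,
14.8 g NOx, 2.7 g SO₂ and 0.7 g PM₁₀ for the bundled profile.

## Layout

| module | contents |
| --- | --- |
| `pocus_impact.synth` | study profiles, synthetic register generator, CSV I/O |
| `pocus_impact.classify` | rurality rule, avoided-consultation rule |
| `pocus_impact.travel` | fuel/cost/segment-time conversions, stratified travel table |
| `pocus_impact.emissions` | emission-factor table, `E = M × N × EF`, maintenance overhead |
| `pocus_impact.hia` | relative-risk scaling, attributable deaths, PM₁₀ mass |
| `pocus_impact.stats` | stratum summaries, per-10k rates, rank-sum test |
| `pocus_impact.cli` | `pocus-impact` command-line pipeline |
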