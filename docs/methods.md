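# Methods

This note documents the models implemented in `pocus_impact`, the
assumptions behind the bundled `osona` study profile, and the numerical
and design choices a maintainer should know about.

## The avoided-journey model

The unit of analysis is a point-of-care ultrasound scan performed at a
primary-care centre (PCC). A scan is classified as having **avoided** a
face-to-face radiology consultation when no radiology visit *of the same
scan type* occurred in the window `0 < (visit − scan) ≤ window_days` after
it. The window defaults to 90 days ("three months"), with the boundary
inclusive: a same-type visit exactly 90 days later blocks avoidance, a
same-day visit does not. "Same type" is exact equality on the closed
six-type taxonomy (abdomen, joints, soft tissue, thyroid, vesico-renal,
vascular); there is no type hierarchy. The window is configurable because
the calendar-month reading of "three months" is equally defensible.

Each avoided consultation saves one **round trip** PCC → radiology
service → PCC. Round-trip distance and time are properties of the centre
(fixed road routes), not of the patient, so every avoided journey from a
centre carries the same distance. Consequences worth noting:

* Stratum confidence intervals reflect *between-centre* spread only. In a
  real deployment patients travel from home, not from the centre, so real
  per-journey variance is larger; the generator deliberately does not
  model this.
* Travel, fuel, cost and emission totals are exactly linear in the centre
  distances (the test suite uses this as an oracle).

Fuel use is `distance × consumption / 100` with consumption in litres per
100 km (default 6.9 L/100 km — a small family car, under three passengers,
no luggage, smooth driving). Cost is litres × price. The default price,
1.4203 €/L, is *derived*, not quoted: it is the ratio of the deployment's
published annual cost to its published annual fuel volume, standing in for
an unpublished average over Gasoline SP95/SP98, Diesel A/A+ and Biodiesel.
Segment travel times use road-class average speeds of 30 (urban),
60 (secondary) and 120 km/h (main roads), all configurable.

## Emissions

Emitted mass follows `E = M × N × EF` with `N = 1` single-occupancy private
car per avoided journey (configurable). The packaged factor table
(`data/emission_factors.yaml`) holds fleet-average factors in g per
vehicle-km for 13 pollutants, averaged over road types for the Catalan
passenger-car fleet (COPERT 4 v10.0 / EMEP-EEA inventory style). The table
is validated on load: factors positive, PM₂.₅ ≤ PM₁₀, and NO + NO₂ = NOx
within 1e-6. CO₂ is excluded by design — it is not in the mandatory
reporting inventory the other factors come from, and mixing inventories
would make the totals incomparable.

Scanner maintenance generates its own car journeys (about ten per year for
devices spread across PCCs versus two for a single specialised-service
scanner). `maintenance_overhead`/`maintenance_net_overhead` report this
separately so net savings can be stated as patient savings minus the extra
maintenance travel; it is not folded into the main tables.

## Health impact assessment

The HIA is a standard comparative risk assessment (WHO/AirQ form). A
relative risk per 10 µg/m³ PM₁₀ is rescaled log-linearly to the excess of
the observed concentration over a counterfactual, `RR' = RR^(ΔC/10)`, and
applied through the attributable fraction:

    AD = deaths × (RR' − 1) / RR'

computed at the central RR and both confidence bounds. The bundled
scenario (1426 deaths/year, population 153,000, PM₁₀ 24.52 → 20 µg/m³,
RR 1.006 (1.004–1.008)) gives 3.85 (2.57–5.13), i.e. about 4 (3–5)
avoidable deaths per year. For RR this close to 1 the small-effect linear
form `deaths × (RR−1) × ΔC/10` agrees within 1% and rounds to the same
integer; the log-linear form is kept because it remains correct for larger
ΔC.

The PM₁₀ mass of the avoided journeys themselves is reported in grams
only. Converting a yearly emitted mass into an ambient concentration
change requires an atmospheric dispersion model, which is outside the
scope of this package; no such conversion is attempted.

## Statistics

Stratum summaries report mean, sample SD (n−1), total, and a 95% CI as
`mean ± 1.96·sd/√n` (normal approximation; swappable, and degenerate — NaN
bounds — for n = 1). Rural-vs-urban comparisons use the two-sided
Mann–Whitney U test: tie-corrected, continuity-corrected normal
approximation in general, and exact enumeration of all
`C(n₁+n₂, n₁)` midrank assignments when both groups have ≤ 8 observations.
The exact two-sided p uses the doubled-tail convention
`min(1, 2·min(P(U ≤ u), P(U ≥ u)))`; with ties the permutation
distribution of U is not symmetric across achievable values, and the
doubled-tail form is the one scipy's exact permutation method implements,
which the test suite uses as an independent oracle.

A caution on the two modes: the normal approximation tracks the exact
p-value closely for moderate groups (observed deviation ≈ 0.005 at 8 vs 8)
but *not* for very small or unbalanced ones — a 1-vs-7 split cannot have
an exact two-sided p below 0.25, while the normal approximation reports
≈ 0.12–0.18 there. Worst-case disagreement over all splits of an 8-value
pool is 0.11–0.26 depending on ties, and ≥ 0.03 even for balanced 4-vs-4
splits. No continuity/mid-p convention removes this; it is intrinsic
discreteness. The automatic dispatch therefore prefers exact enumeration
precisely where the approximation is weakest.

## The bundled study profile: measurement vs calibration

The `osona` profile encodes the aggregates of a real 2019 deployment. The
following are taken directly from that deployment's published tables:

* the 8-professional × 6-type scan count matrix (1556 scans; 511 urban,
  1045 rural);
* per-type referral counts (19, 1, 5, 4, 7, 0; 36 total);
* stratum totals and means of round-trip distance and time
  (rural 20,297.8 km / 24,620 min; urban 6825.2 km / 7956 min).

Everything else is **calibration**, chosen once and documented here:

* **Centre composition.** Professionals P1–P3 belong to the two urban
  centres (U1 = {P1, P2}, U2 = {P3}) and P4–P8 to the three rural ones
  (R1 = {P4, P5}, R2 = {P6, P7}, R3 = {P8}). Only the urban/rural grouping
  is published.
* **Referral allocation.** The published per-type referral counts are
  split per (centre, type), with stratum margins of 28 rural and 8 urban
  referrals — the unique stratum split that reproduces all four published
  stratum means (20.0/13.6 km, 24.2/15.8 min per journey) at one-decimal
  precision together with the published totals. Fixing the allocation at
  centre level (rather than drawing it per seed across centres) is what
  makes every downstream total seed-invariant: distances are centre
  constants, so only *which* events within a (centre, type) cell carry the
  referral is random, and that choice affects nothing downstream.
* **Centre distances and times.** Per stratum, all centres but one get
  round plausible values (U1: 11.8 km/14 min; R1: 24 km/28 min; R2:
  16 km/20 min) and the last (U2, R3) is solved from the published stratum
  totals. This is the single free allocation in the fixture.
* **Scan dates** are uniform over the study year and referral follow-ups
  uniform in (0, 90] days after the scan. Dates matter only through the
  window rule, so these distributions are inconsequential.
* **Assigned populations** are not published. Rural populations (4800,
  7600, 9500; densities 45, 62, 110 /km²) are chosen to satisfy the
  rurality criterion so the classifier reproduces the published grouping;
  urban populations (22,000; 25,055) are chosen so the urban mean scan
  rate is 108.6 per 10⁴ inhabitants as published.

One published figure is knowingly **not** reproduced: the rural mean scan
rate of 229.7 per 10⁴ inhabitants. With rural populations below 10,000 per
centre (the rurality criterion) and 1045 rural scans, each rural centre's
rate exceeds its scan count, so the mean over the three rural centres must
exceed 1045/3 ≈ 348 — no population assignment can reach 229.7. The
published rural rates imply assigned populations of roughly 12,600–35,000,
contradicting the rurality definition they accompany; the profile sides
with the rurality criterion, which the rest of the analysis depends on.
Similarly, the published per-pollutant emission *totals* imply a slightly
different distance base (≈ 26,944 km) than the published travel total
(27,123 km), with the PM₁₀/PM₂.₅ totals apparently transposed; this
package computes totals consistently from the travel distance base, and
its per-journey means match the published ones.

## What passing tests do and do not show

The generator reproduces aggregate structure, not patient-level realism:
no seasonality, no demand modelling, no patient covariates, no home-to-
centre travel, and centre-constant distances (hence understated journey
variance). Tests passing on this fixture demonstrate that the pipeline's
accounting is internally consistent and reproduces the deployment's
published aggregates from its published inputs — not that the model's
assumptions (single-occupancy car travel, fleet-average emission factors,
90-day window) hold in any particular health system.

Problem sizes are those of the deployment itself (1556 scans, 1520 avoided
journeys); the whole pipeline runs in well under a second, and the test
suite's heaviest item (100-seed generator fidelity sweep) in a few
seconds.
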