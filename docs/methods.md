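# Methods

This note records the models, conventions and design choices behind
`chamberflux`, and what the synthetic-data tests do and do not
demonstrate about real field data.

## The measurement model

A sealed, transparent chamber encloses one coral colony (or, for
controls, only seawater).  Water samples drawn at the start and end of a
cycle of duration `I_t` give concentration drifts that are attributed to
the colony after blank correction:

* **ΔTA = TA_start − TA_end** (μmol kg⁻¹).  The alkalinity-anomaly
  method rests on the stoichiometry of CaCO₃ precipitation, which
  removes two equivalents of alkalinity per mole of mineral; hence the
  factor 0.5 and the sign convention that makes net calcification
  positive.  Dissolution yields a negative G and is reported as such.
* **ΔO₂ = O₂_end − O₂_start** (μmol L⁻¹).  Light-phase flux is net
  photosynthesis; dark-phase flux is negated so respiration is a
  positive rate.  A colony that *produces* O₂ in the dark after blank
  correction is physically anomalous; the value is kept and flagged,
  never silently dropped or clipped.

Alkalinity is measured per kilogram of seawater and oxygen per litre.
The density `ρ` that reconciles the two unit systems enters exactly once,
in the calcification kernel (`ΔTA·ρ·0.5·V` converts μmol kg⁻¹ to μmol);
the oxygen equation uses `V` alone.  Keeping this asymmetry in one place
is deliberate: unit errors in this literature most often come from
applying ρ inconsistently.

**Blank correction.**  Treatment drifts are corrected by subtracting the
*mean* drift of same-phase, same-cycle (and, by default, same-site)
control chambers, in concentration units, *before* any volume or
surface-area scaling — controls carry no colony surface area and need
not share the treatment's volume.  A missing control is an error, not a
zero correction, because an uncorrected microbial signal is
indistinguishable from colony metabolism.

**Daily integration** is the stepwise sum `Σ rate(t)·Δt` over measured
windows.  Start/end sampling cannot resolve within-window dynamics, so
nothing fancier (trapezoids, splines) is defensible.  When the measured
windows cover less than the declared photoperiod the integral is
reported with its coverage; constant-mean-rate extrapolation exists but
only behind an explicit flag, because diel rate curves are not flat.

**Volume accounting.**  The chamber volume is reconstructed per cycle as
extracted aliquot + residual volume; a per-chamber configured volume is
the fallback, and the absence of both is an error.  Field protocol
(100 ml extracted, ~950–1000 ml residual) implies V ≈ 1.05–1.10 L, the
simulator's default.

## Seawater physics

* Density: EOS-80 one-atmosphere polynomial (Millero & Poisson 1981),
  evaluated at the interval's mean salinity and temperature.  Checked in
  the tests against the published check values (σ(35, 25) = 23.343,
  σ(35, 5) = 27.675 kg m⁻³).  A configured constant density is available
  for users reproducing analyses that fixed ρ.
* O₂ solubility: Garcia & Gordon (1992) refit of the Benson & Krause
  data, evaluated in μmol kg⁻¹ and converted to μmol L⁻¹ with the same
  density, so saturation percentages are directly comparable with
  optode readings.
* Pressure dependence is ignored (deployments are within a few metres of
  the surface), and salinity values are treated as practical salinity as
  logged, without refractometer-scale conversion.

## Chamber-volume safety analysis

The water-volume-to-biomass ratio trades signal against harm: small
volumes reach supersaturation (light) or anoxia (dark) within a flushing
interval; large volumes dilute drifts below analytic detectability.

* Oxygen state: light-phase samples are unsafe above 200% of the
  equilibrium solubility (the supersaturation levels reported for
  zooxanthellate tissue in shallow water); dark-phase samples are unsafe
  below an anoxia floor of 5 μmol L⁻¹, or below 30% of saturation under
  the hypoxia criterion.  Only the 200% anchor has a literature basis;
  the other two are package defaults, config-exposed and stamped into
  outputs.  The bundled bench-trial table labels its light-phase column
  with the same "O2Sat" shorthand as its dark column even though light
  incubations supersaturate rather than hypoxiate; the classifier
  interprets the light criterion as supersaturation.
* Detectable metabolic change: a drift counts as detectable when it
  exceeds `k = 3` times the analytic precision (TA 2 μmol kg⁻¹, O₂
  0.05 μmol L⁻¹), and the combined criterion requires *both* analytes
  to clear the bar.  The boundary is strict (`>`), so a drift exactly at
  3σ is not detectable.
* Consensus over replicate colonies: all-false → "−", all-true → "+",
  otherwise "±".
* Acceptance: a volume passes iff at the decision hour (default 3 h, the
  flushing interval) the oxygen code is "−" and the detectability code
  is "+" in both the light and dark series.  Acceptance is non-monotone
  in volume by construction.

Two paths feed this analysis: an encode-the-table path that consumes a
verbatim consensus-code table (the bundled bench trial), and a
classification path that derives codes from simulated or logged
trajectories.  The bundled bench-trial preset of the simulator uses
deliberately amplified rates: with the trial's 12 cm² nubbins,
literature-scale areal rates cannot exhaust a 250 ml chamber within an
hour as the bench observed, so the preset is documented as qualitative —
it reproduces the shape of the decision table (small volumes unsafe
quickly, very large volumes undetectable), not its exact codes.

**Extraction error.**  Water left in the chamber biases the
reconstructed volume, and hence every rate, linearly: the relative error
is (unaccounted ml / reference volume).  Against the 250 ml bench fill
this is 0.4% per ml; the bundled trial summary (mean 2.0 ml, max 5.0 ml
over 30 trials) gives a 0.8% mean and 2.0% worst-case rate error.

## Statistics

* **Chamber equivalence**: two-sided paired t (same colonies in both
  chamber types) or independent t (different colonies), with the mean
  difference and its standard error as the effect size.  Degenerate
  zero-variance paired differences are handled explicitly (t = 0, p = 1
  for identical vectors).
* **Species × habitat comparison**: a random-intercept linear mixed
  model with sampling day as the grouping factor, fitted by REML
  (statsmodels MixedLM).  Consecutive-day measurements share weather,
  tide and light; treating day as a random intercept absorbs that shared
  variation.  The treatment-coding reference level of each factor is
  explicit in the specification, because rotated-intercept refits change
  labels but must not change fitted values (tested).  Cell-means coding
  (`0 + C(cell)`) is available for direct estimation of species × site
  means.
* **Degenerate fits**: with a single day the model is refused outright
  (the day variance is inestimable) rather than silently reduced.  When
  the optimizer collapses on noiseless or boundary data, the fit falls
  back to its ordinary-least-squares limit with zero variance
  components — the correct limit of the model, not an approximation.
* **Confidence intervals**: the default interval for fixed effects uses
  a t reference with (number of days − 1) degrees of freedom.  With only
  ~5 grouping levels the day variance is poorly estimated and Wald z
  intervals undercover; the groups-df t interval is the standard
  small-sample correction.  A `normal` option retains the Wald form.
* **Model simplification**: nested fixed-effect structures are compared
  by likelihood ratio after refitting both models under ML — REML
  likelihoods are not comparable across fixed-effect structures.
  Residual checks (Shapiro–Wilk, Levene by factor, residual-vs-fitted
  correlation) are emitted as advisory tables, never as gates.

## The simulator and what passing tests show

The forward model inverts the rate equations under a
constant-rate-within-window assumption, adds optional linear microbial
drift (identical in treatments and controls, which is what blank
correction assumes and removes), floors oxygen at zero with an anoxia
flag, and adds i.i.d. Gaussian analytic noise per measured sample at the
instrument precisions.  A seed is mandatory for any stochastic run and
identical seeds give byte-identical output.

Default study conditions mirror the field campaign the package targets:
3 h light and dark cycles, three controls per site, chamber volume
1.05 L, colony area 12 cm², 2 sites × 3 species × 5 colonies × 5 days,
bundled published cell means as generating truth, day-intercept sd
0.25 mmol m⁻² h⁻¹ (consistent with the published between-day standard
errors), and analytic noise as above.  The northern site's mean salinity
is not published; 33.0 is used, reflecting the reported freshwater
influence there.

What the passing synthetic tests demonstrate: the reduction inverts the
forward model exactly at zero noise (to 1e−9 over randomized regimes);
blank correction removes exactly-shared drifts; recovery variance grows
with analytic noise; and under the campaign design the mixed model's
95% intervals cover the generating cell means at their nominal rate.
What they do not demonstrate: robustness to boundary-layer effects,
within-window nonlinearity (e.g. light fluctuation), chamber leakage,
carbonate-system feedback on calcification, or non-Gaussian instrument
error — none of which the forward model emulates.  Field conclusions
still rest on the deployment checks (leak tests, temperature
co-variability, volume sensitivity) that the safety-analysis module
encodes.

## Problem sizes used by the routine checks

The test suite runs the simulate→reduce inversion over 100 random
configurations, the parameter-recovery study over 200 replicate
campaigns at the full 2 × 3 × 5 × 5 design, and t-test calibration over
2000 null draws — sizes chosen so the whole suite completes in a few
minutes on one core while keeping Monte-Carlo error well inside the
asserted margins.

## Known limitations

* TA is consumed as a measured input; Gran-titration curve processing
  and carbonate-system speciation (pCO₂, Ω) are out of scope.
* Surface area is an input; no geometric reconstruction is provided.
* The mixed model covers a single random intercept (day); crossed or
  nested random effects (e.g. colony within site) are not exposed.
* The simulator's volume-trial preset is qualitative (see above), and
  published regression coefficients from rotated-intercept refits are
  not reproducible without the raw per-colony data, which were never
  deposited; the package therefore treats such coefficients as
  non-targets and exposes the reference level instead.
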