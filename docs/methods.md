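# Methods

This note records the statistical models, conventions and design choices the
package implements, in the spirit of a methods section a maintainer can
audit.

## Assay model

The assay quantifies a panel of plasma metabolites with two complementary LC
methods (HILIC for polar compounds, reversed phase for apolar ones) on a
triple quadrupole acquiring two SRM transitions per analyte — a quantifier
and a qualifier — in scheduled mode with fast polarity switching. Samples
are prepared dilute-and-shoot: 200 µL plasma + 800 µL cold isopropanol
(1:5), supernatant further diluted 1 + 19 (1:100 overall); both dilutions
are injected so that each analyte lands inside its calibration range at one
of them. A full-scale registry has 235 analytes and 467 transitions
(two per analyte, three single-transition compounds); six analytes split
their two transitions across polarities because no two reliable transitions
existed in one polarity. The shipped fixture registry covers ~20
representative analytes; the full table is user-suppliable as CSV.

### Gradient programs and solvent arithmetic

Run duration is the final segment time of a gradient program: 23.0 min (RP)
and 16.5 min (HILIC), 39.5 min per sample over both methods. Solvent
mixture polarity indices are volume-fraction-weighted means of component
indices, printed rounded to one decimal with ties away from zero. The
component table uses isopropanol 4.3, acetonitrile 6.2, methanol 6.6,
acetone 5.4 and water 9.0; the last two are the values that reproduce every
printed binary-mixture index (6.8, 6.1, 5.3, 5.2, 4.9) under linear mixing
and rounding — note that naively inverting a single rounded mixture value
gives water ≈ 9.2, which contradicts the other printed mixtures, so the
jointly consistent solution is used.

## Scheduled-SRM dwell model

A transition is active at time *t* iff |t − rt| ≤ window/2 (closed
interval; default window 30 s, 60 s for retention-shifting phospholipids;
grid step 1 s). With *n* = n⁺ + n⁻ active transitions, target cycle 1000 ms,
pause 5 ms per transition and settling 15 ms per polarity switch (charged
twice per cycle when both polarities are present, once entering each), the
equal-split allocation is

    dwell = (1000 − overhead − 5 n) / n,  floored at 3 ms.

Where the floor binds, the realized cycle is overhead + n·(3 + 5) ms > 1000
and the grid point is flagged infeasible rather than raising. Equal split
is an explicit modeling choice: vendor schedulers do not disclose their
allocation; the rule is isolated in one function so a proportional scheme
can be slotted in. Points per chromatographic peak are
width × 1000 / cycle.

## Calibration

Curves are fitted by weighted least squares (statsmodels WLS) with weights
1/x on the nominal concentration; the zero standard is excluded (its weight
is undefined; it serves only as a blank). The weighted r² is reported. When
the model is not forced, linear is kept if its weighted r² ≥ 0.995,
otherwise quadratic — and that same dichotomy later selects the recovery
estimator. Quadratic inversion uses the numerically stable root formula and
takes the root on the monotone (pre-vertex) branch within [0, 1.05·ULOQ];
curvature below 1e−14 of the slope is treated as linear to avoid
catastrophic cancellation.

S/N is apex height above local baseline divided by the standard deviation of
the baseline noise, both supplied per measurement (the field does not share
a single S/N convention; this one is isolated in the LOD/LLOQ routine). On
the 14-level validation grid (0, 0.1, 0.3, 1, 3, 10, 30, 100, 300, 1000,
3000, 10000, 25000, 50000 µg/L):

* LOD = lowest level with S/N ≥ 3; LLOQ = lowest with S/N ≥ 10.
* Carryover fallback: when the area fails to grow by ≥ 2× between the first
  detectable level and the next (the grid is ~3×-spaced, so a healthy
  response roughly triples), the LOD is undetermined and the LLOQ is the
  lowest level with both an area jump ≥ 2× and S/N ≥ 10. The factor is
  configurable; the stall check deliberately applies only at the bottom of
  the range, because near the 2×-spaced top levels (25000 → 50000) a linear
  response legitimately yields a ratio of exactly 2.
* ULOQ: descending search from the top level; a candidate is accepted when
  the fit restricted to [LLOQ, L] has r² > 0.995 and back-calculation at L
  is within 95–105% of nominal. No qualifying level → undetermined.

The reference ion ratio is the mean qualifier/quantifier area ratio at three
levels spread across the linear range.

## Validation statistics

Carryover % = 100 × blank area / standard area, the blank injected directly
after the 1 mg/L standard (or the highest level when LLOQ > 1 mg/L); flag
bins [0,1), [1,5), [5,∞), closed on the left. Carryover is scale-invariant.

Apparent recovery from standard addition (6 levels at 0.5–3× the native
concentration — or 12.5–75× LLOQ for analytes undetected in plasma — in
triplicate):

* slope ratio, `R_A = 100 · slope(spiked)/slope(neat)`, for analytes whose
  calibration model is linear;
* level-wise Eq-style estimator, `R_A = 100 · (c_sp − c_NS)/c_A` averaged
  over the 18 observations, with c_sp back-calculated through the neat curve,
  for quadratic responders (and the single-level design used for poorly
  soluble compounds, where only the top spike is feasible).

The estimator choice keys on the analyte's response type, not on the r² of
the noisy 6-point spiked series: with 5% measurement noise the spiked
series' r² routinely falls below 0.995 even for perfectly linear analytes,
and gating on it would divert them to the noisier level-wise route. The
low-level slope-ratio function still enforces a configurable r² bound on
both series as a guard for direct use. Negative per-level recoveries are
kept (not truncated) so the repeatability RSD — sample SD over mean of the
18 recoveries — reflects the raw spread. Acceptance: 70 ≤ R_A ≤ 130 →
accept; outside → correct (quantification divides by R_A/100); outside AND
RSD > 25% → reject (the analyte cannot be reliably corrected; the 25% bound
mirrors the repeatability convention and is configurable).

## Quantification

Drift is modeled as a multiplicative factor over the injection index and
corrected either from repeated pooled-QC injections (piecewise-linear
interpolation of the QC response relative to the first QC) or from the
bracketing calibrations. In bracket mode the fitted slope of a drifting
bracket does not represent the drift at the bracket's midpoint: under 1/x
weights the slope is dominated by the top standards, so each anchor is
placed at the effective index Σ kᵢ·injᵢ·responseᵢ / slope, with k the slope
row of the WLS influence matrix — this makes the correction exact for drift
linear in index. Calibration curves are then fitted on both brackets (two
injections per level), which halves the variance of the concentration scale
relative to a single bracket.

Per sample and analyte, the measurement at each dilution is back-calculated
and censored against [LLOQ, ULOQ]; the most dilute in-range measurement is
selected (dilution minimizes matrix effects), except for low-abundance
classes (carboxylic acids, eicosanoids, ethanolamides, nucleotides, sugars)
which can be pinned to the 1:5 route. Above-ULOQ at the highest dilution →
censored ">ULOQ" with an advisory to dilute further (the glucose situation);
below-LLOQ at the lowest → "<LLOQ". The plasma concentration is the
measurement times the dilution factor; if the matching dilution's R_A is
outside 70–130% the correction c × 100/R_A is applied and flagged.
Duplicate randomized injections are averaged after censoring resolution;
when the duplicates disagree in censoring class the quantified one wins,
with a flag (the combination rule is a documented choice). Ion-ratio
confirmation passes iff |observed − reference| ≤ 0.30 × reference; the ±30%
relative tolerance is a common confirmatory-analysis default, exposed in
configuration, and single-transition analytes are "not evaluable" but still
quantified with a warning.

Isomer pairs that co-elute but share a sum transition (leucine/isoleucine:
the sum from m/z 132.1→89, isoleucine uniquely from 132.1→69) are resolved
by subtraction; negative differences are censored at zero with a flag, and
the pre-censoring sum is conserved by construction.

Trueness = round(100 × measured/certified), ties away from zero (matching
how certified-reference tables are printed); analytes below the detection
limit are excluded from the evaluable count, and the summary counts values
inside 70–130%.

## Synthetic-data generator

The generator emulates the statistical structure the analysis assumes, not
the physics. Per analyte:

    area = drift(i) · matrix_factor(dilution) · (a·c + b·c²) · LN(1, rsd)
           + N(0, σ_baseline),  floored at 0,

with c the measurement-solution concentration. Defaults (held fixed as the
study conditions): slope a uniform in 500–2000 area/(µg/L), linear response
(b = 0), measurement rsd 5% (constant CV — matching the observation that
precision is roughly level-independent at the high end while baseline noise
limits the low end), baseline σ = 0.3·a (placing S/N ≈ 3 near 1 µg/L),
native plasma concentrations log-uniform in 2–20 mg/L (so the 1:100
dilution stays quantifiable), carryover fraction uniform in 0–2%, drift
linear from 100% to 80% across a sequence (the minimal model a bracket
correction can represent), and qualifier/quantifier ratio uniform in
0.2–0.9. Matrix factors are per dilution: the 1:5 factor is drawn
per analyte (default uniform in 0.5–1.3) and the 1:100 factor is
1 + 0.25·(f₅ − 1) — dilution removes about three quarters of the deviation,
emulating the reported improvement of recoveries upon 1:100 dilution while
acknowledging that preparation losses would not dilute away. Calibration
standards are injected once per level per bracket (replicate counts for
standards are not part of the assay description; single injections with
bracketing are the documented default). Blanks receive the carryover
fraction of the previous injection's area, so consecutive blanks decay
geometrically (f·A, f²·A).

What the generator does **not** emulate: chromatographic peak shapes,
retention-time variability, integration artifacts, ionization physics, or
heteroscedastic noise beyond the two-component (CV + baseline) model.
Passing parameter-recovery tests therefore demonstrates the correctness of
the statistical machinery under the stated model, not robustness to real
chromatography.

## Accuracy expectations and problem sizes

Under the default conditions (5% CV, 6 × 3 standard addition), the
level-wise recovery estimator has a Monte-Carlo error floor of ≈ 2.6
percentage points MAE — dominated by the native-concentration estimate
(three replicates, amplified by c_NS/c_A at the low spiking levels) and the
per-observation noise. Any additional concentration-scale error adds on
top, which is why the parameter-recovery check is performed at the
estimator level while the full pipeline (simulation → drift correction →
two-bracket calibration → recovery → two-dilution quantification with
duplicate averaging) is checked against a 15% accuracy band, which absorbs
the scale variance (≈ 2.5%), duplicate-averaged measurement noise (≈ 3.5%)
and the residual 1:100 matrix bias left uncorrected by the
only-outside-70–130 correction rule.

Test and acceptance runs use 100-analyte panels with ~80-injection
sequences (≈ 16k peak rows) and 100-registry scheduler sweeps; these sizes
keep the whole suite in a few seconds while leaving the Monte-Carlo margins
quoted above.

## Known limitations

* The dwell allocation is a model of undisclosed vendor behavior; absolute
  dwell minima of a real method table are not reproducible from structure
  alone.
* The carryover-plateau LLOQ fallback checks only the bottom of the grid;
  pathological non-monotone series elsewhere are not detected.
* Working-range calibration grids are geometric interpolations between the
  documented endpoints (0.03–25000 µg/L HILIC, 0.1–50000 µg/L RP); real
  per-analyte working ranges are narrower and analyte-specific.
* Drift correction assumes multiplicative, slowly varying drift; step
  changes (e.g. after source cleaning) violate the interpolation.
* Recovery correction uses the matching dilution's R_A; pooling across
  dilutions is not implemented.
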