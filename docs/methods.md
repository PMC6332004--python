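# Methods

## Scope and data model

The package analyses two-compartment (transwell) transport experiments.
A measurement series is the cumulative amount of compound in the
receiver compartment over time for one insert (replicate), one
direction (AP→BL or BL→AP), one donor concentration. Internal units are
fixed — amounts in µmol, time in seconds, concentrations in µmol/cm³ —
and the only unit conversions (minutes→seconds, µM→µmol/cm³, i.e. ÷1000)
happen once, at the object boundary. This removes the classic silent
1000× error between µM and µmol/mL pipelines.

## Apparent permeability

`Papp = (dQ/dt)/(A·C0)` with the appearance rate `dQ/dt` estimated by
**through-origin** least squares of cumulative amount on time
(`Σtq/Σt²`). The origin is forced because `Q(0) = 0` is physical, not
statistical; granting an intercept would let early-time noise masquerade
as instantaneous transport. A single-timepoint endpoint experiment
(the common 90-minute design) reduces automatically to `Q/t`; multi-point
time courses use the regression. Replicates aggregate to mean ± sample
SD (ddof = 1).

The through-origin estimator is exact under sink conditions and biased
low under receiver saturation: for the two-compartment closed form the
single-point estimate carries a factor `(1 − e^(−kt))/(kt)` (≈ 0.86 at
90 min for Papp = 2×10⁻⁵ cm/s with the default geometry). This is a
property of the estimator the assay community uses, not a defect to be
corrected here; the simulator makes the bias visible and the tests pin
its early-time limit (< 1% at 1 min).

Defaults: insert area 1.12 cm² (standard 12-mm insert; the
diameter-only spec of the hardware leaves area as a config field),
apical volume 0.5 mL, basolateral 1.5 mL, TEER gate strictly above
1000 Ω·cm². Receiver sampling is treated as non-depleting; no
sampling-volume correction is applied by default.

## Calibration and QC

Unweighted OLS per compound (a 1/x-weighted option exists but is off by
default, matching how plain linear regressions are reported for these
assays); `r` is the Pearson correlation of (concentration, area).
Back-calculation inverts the line and **flags** out-of-range values with
a warning rather than clipping — the measurement is preserved, the
analyst is informed. QC metrics at a nominal level: intraday RSD =
pooled within-day SD / grand mean; interday RSD = SD of day means /
grand mean (the simplest reading of "interday precision"; no ANOVA
variance decomposition); accuracy = grand mean / nominal; freeze–thaw
stability = post-cycle mean / baseline mean with a ±5% acceptance
window.

## Classification

* Absorption classes use strict inequalities: well if mean AP→BL Papp
  > 1×10⁻⁵ cm/s, poor if < 1×10⁻⁶ cm/s, else moderate. Boundary values
  are moderate by construction. Under this strict rule, a compound with
  Papp 10.42×10⁻⁶ cm/s classifies "well" even when a narrative source
  might group it as moderate — the rule, not the narrative, governs.
* Efflux ratio = mean(BL→AP)/mean(AP→BL). Its SD comes from paired
  per-replicate ratios when insert pairing is available (same replicate
  index in both directions), else from first-order error propagation,
  and the result is labelled with which method produced it.
* P-gp candidate band: ratio ≥ 1.9 or ≤ 0.55 (both config-exposed).
  This operationalizes "asymmetry near 2-fold, or near 0.5-fold";
  note a ratio of 0.68 falls outside the band although an
  inhibitor experiment on such a compound may still be scientifically
  reasonable — the band is a screen, not a verdict.
* Inhibition contrast: percent change of the arm-mean ratios plus a
  Welch (unequal-variance) two-sample t-test on per-replicate ratios at
  α = 0.01. The test choice is a package decision; the reporting
  convention it supports is "significant at p < 0.01". With a single
  replicate per arm only the percent change is reported.
* The reference table's compound 3 prints an efflux ratio (0.96)
  inconsistent with the ratio of its printed directional means
  (27.38/37.10 ≈ 0.74). The pipeline always computes from the means and
  raises a `ratio_discrepant` flag; the printed value is never used as
  ground truth.
* The rhodamine-123 control: the ratio of printed arm means under
  verapamil is 8.51/5.36 = 1.588, while the published per-replicate
  mean rounds to 1.58 — the two agree at one-decimal precision, which is
  the precision at which that quantity is checked.

## The lipophilicity–permeability sigmoid

`y = log10(Papp·MW^0.5)` vs `x = log D (pH 7.4)`. Two unit-amplitude
logistic branches with a shared value at the breakpoint `x0`:

    left  (x ≤ x0): 1/(1 + e^−(b1·x − a1)) + c
    right (x > x0): 1/(1 + e^(b2·x − a2))  + c

The right offset is **structurally derived**, `a2 = (b1+b2)·x0 − a1`, so
every representable model is continuous at `x0` to machine precision
(for the reference parameterization both exponent arguments equal 5
there). `c` is a vertical offset added to the unit-amplitude sigmoid;
the amplitude is fixed at 1 by default with an opt-in to free it.

Fitting: bounded least squares (`scipy.optimize.least_squares`, trf)
over (b1, a1, b2, c) with b1, b2 ∈ (0, 20], c ∈ [−8, 0], a1 free, from
16 deterministic starts (a 4×4 grid of slope pairs, a1 anchored at the
left-side median, c at min(y)); no stochastic jitter, so the fit is a
pure function of the data. Breakpoint fixed at 2.5 by default, optional
grid scan by SSE. Degeneracy (constant y, or a slope pinned at its
bound) is flagged, not silently returned. Noiseless model-generated
points are recovered to ≲1×10⁻¹⁴ per parameter.

Refitting the packaged reference points (12 compounds) reproduces the
reference offset `c = −4.227` only to ≈0.3: the original fit's molecular
weights and goodness of fit are unpublished, and the data's dynamic
range (≈0.74 log units) is smaller than the model amplitude (1), which
lets `c` trade off against the slopes. The refit is therefore treated as
a soft consistency check — its deviation is reported, never asserted to
zero.

Band assignment (`permeability_band`): a log D value is on the
"high-plateau" when `|df/dx|` of the model is below 0.6 per log D unit,
otherwise "descending-left/right" of the breakpoint. The 0.6 default was
calibrated on the reference model so that the moderate-lipophilicity
compounds (log D 1.0–3.5, derivative magnitude ≤ 0.59) sit on the
plateau and the extremes (log D 0.63 and ≥ 3.7, derivative ≥ 0.64) sit
on the flanks; a much smaller threshold (e.g. 0.1) would misplace the
plateau members at log D 1.09 and 3.40. The threshold is config-exposed
and is a descriptive tuning constant, not a physical quantity.

## Molecular-weight fixture

Molecular weights are inputs, never computed from structures. The
shipped fixture derives them from molecular formulas (e.g. umbelliferone
C9H6O3 = 162.14, bergapten C12H8O4 = 216.19). Angepubebisin's formula is
not published; its entry is an assumed-formula stand-in flagged
`source = assumed_formula`. Because MW enters only as `log10(MW^0.5)`, a
±25% MW error moves a point by ≤ ~0.05 log units.

## Synthetic-data generator

The generator emulates exactly the statistical structure the estimators
assume, with defaults set to the study conditions the package targets:
donor 50 µM, 90-minute endpoint, n = 6 replicates, 5% CV, 12-well
geometry.

* **Sink**: `Q(t) = Papp·A·C0·t` (default mode — the regime in which the
  Papp estimator is unbiased).
* **Non-sink**: `Q(t) = C0·Vd·(Vr/(Vd+Vr))·(1 − e^(−kt))`,
  `k = Papp·A·(1/Vd + 1/Vr)` — two well-mixed compartments, mass
  conserved exactly (donor + receiver = dose at every time; no cell
  compartment).
* **Efflux**: phenomenological direction multiplier;
  `Papp(BL→AP) = Papp(AP→BL)·(1 + (m−1)/(1 + C0/Km))`, Km = ∞ by
  default. An inhibitor arm scales the asymmetric component by
  `(1 − inhibitor_effect)`; `inhibitor_effect = 1` restores symmetry.
  This is deliberately not a mechanistic transporter model — it is the
  minimal structure that exercises every classifier path with known
  truth.
* **Noise**: multiplicative log-normal with exact unit mean
  (`σ² = ln(1+CV²)`), because detector peak-area error scales with
  signal. One scenario seed spawns an independent `default_rng` stream
  per (arm, direction, replicate), so any subset of the design is
  reproducible regardless of how much of it is generated.

What the generator does **not** emulate: chromatographic integration
error structure beyond CV scaling, TEER dynamics, paracellular vs
transcellular routes, cell-compartment retention, inter-day batch
effects. Passing tests therefore demonstrate correctness of the
estimator chain under the assay's idealized kinetics, not robustness to
every artefact of real chromatography.

## Statistical calibration checks and problem sizes

The suite and the reproduction script use Monte-Carlo sizes chosen to
give stable binomial/ordering decisions at small cost: 200 repeats per
noise level for the fitter noise-scaling check, 500 repeats for
detection power of a fully reversed 2-fold efflux (observed power
≈100%), and 2000 repeats for the type-I rate of the Welch contrast under
a symmetric-transport null at α = 0.01 (observed ≈1.4%, within binomial
noise of nominal; the per-replicate ratio of two log-normals is mildly
heavy-tailed, which with n = 6 keeps the realized rate near but not
exactly at 1%).

## Known limitations

* Papp from a 90-minute endpoint inherits the saturation bias described
  above whenever sink conditions fail; the package reports what the
  assay convention computes.
* The interday RSD is the SD of day means, which conflates within- and
  between-day components when day sizes differ.
* Error propagation for the efflux-ratio SD is first-order and ignores
  the ratio's skew at large CVs.
* The QSPR model is descriptive; no applicability-domain model is built,
  and predictions outside the fitted log D range only trigger the
  plateau/flank band logic, not a warning system.
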