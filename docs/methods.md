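# Methods

## Scope

`beadquant` implements the analysis chain of a suspension bead-array
(xMAP-style) assay for individual miRNAs: a generative simulator of the
assay, the median-fluorescence processing pipeline (background correction,
spike normalization, replicate summary with error propagation), a
two-segment calibration fit with linear-range detection, mismatch-probe
specificity scoring, TaqMan-style 2^-ΔΔCt relative quantification, and
cross-platform Spearman concordance.  No real instrument data ship with the
package; all analyses run on synthetic plates whose generative truth is
recorded alongside the events, so every pipeline stage can be validated
against a known answer.

## Measurement model

Each well of a 96-well plate contains a mixture of colour-coded microsphere
sets ("bead regions", default codes {1, 21, 51, 57}), each coupled to one
DNA capture probe.  A flow analyzer classifies beads by region and records
the reporter (phycoerythrin) fluorescence of 100 events per region per
well; the assay's primary measurement is the median fluorescence intensity
(MFI) of those events.  Groups with fewer than 100 events are flagged
`low_count` and excluded by default.

### Signal vs target amount

The probe-bound signal S(C) for target amount C (fmol) follows, on
log10–log10 axes, two connected straight lines anchored at the saturation
knot:

    log10 S = log10(mfi_at_knot) + s1 · (log10 C − log10 knot)   for C ≤ knot
    log10 S = log10(mfi_at_knot) + s2 · (log10 C − log10 knot)   for C > knot

with defaults s1 = 0.94, s2 = 0.15, knot = 18.75 fmol, mfi_at_knot = 3000.
An alternative Langmuir-isotherm mode (bmax·C/(kd + C)) is provided; its
log-log slope tends to 1 in the dilute limit, so the modes agree at low C
(checked numerically at C = kd/10⁴).

### Noise structure

* **Event scatter** — lognormal, median-parameterized, fractional CV
  `event_cv` (default 0.25).  Median parameterization is deliberate: the
  pipeline summarizes events by the median, which is then an unbiased
  estimator of the model signal.
* **Background** — median `bg_median` = 30 MFI.  Its well-to-well
  variability (`bg_well_sd` = 4 MFI) is expressed in the dedicated
  no-target wells from which the background model is estimated; in target
  wells the background contributes its median on top of the probe signal.
  Rationale: the background model is *defined* by the no-target wells, and
  the default background scale is calibrated so that the 3σ detection rule
  lands between the 7th and 8th points of the default dilution series —
  placing the bottom titration point at the noise floor.  Spreading the
  well-level term into target wells as well would make the detection limit
  a coin flip at these defaults rather than a property of the design.
* **Labeling efficiency** — one lognormal factor per sample (σ =
  `labeling_eff_sd` = 0.3) multiplying the *signal* of every probe in that
  sample's wells, spike included.  Because the factor scales miRNA and
  spike signal identically, the per-well miRNA/spike ratio cancels it
  exactly — this is the property spike normalization exists to exploit, and
  it is asserted in the tests.
* **Probe aging** — conjugates retain full signal for `stable_days` = 35
  days; afterwards signal decays as exp(−`aging_lambda`·(day − 35)) with
  λ = 0.004/day, so retention ≈ 0.94 at day 50 and ≈ 0.84 at day 80.

### Simulated experiments

* **Calibration** — geometric dilution series, default 8 points, 4-fold,
  from 300 fmol (series members include 18.75 and 0.0732 fmol; the terminal
  point is 18.3 amol).  3 replicate wells per amount plus 16 no-target
  wells (two plate columns; the count is a plate-design choice, made once,
  large enough to stabilize the mean + 3σ background threshold).  Only the
  calibration region carries signal; the other regions read background.
* **Specificity** — one miRNA per plate: perfect-match, 1-mismatch and
  2-mismatch probes plus the spike region, target at 18.75 fmol (inside the
  linear range).  Mismatch probes bind at a configured fraction of the PM
  signal: `eff_2mm` defaults (miR-27a 0.38, miR-199a 0.15) encode the
  observed 62%/85% two-mismatch drops; `eff_1mm` defaults (0.70, 0.55) are
  placeholders satisfying PM > 1MM > 2MM, since no one-mismatch number is
  printed anywhere.  The complex-RNA mode adds per-sample latent abundances
  and labeling factors.
* **Expression** — 7 cell lines + a pooled reference (POOL = arithmetic
  mean of the 7 latents per miRNA), 3 wells per sample, 4 regions per well
  (3 miRNAs + spike).  Expression wells use a *linear* response
  (MFI = gain·latent·factor + background): the assay is operated inside its
  linear dynamic range, and a slope-1 response is what makes the recovered
  log2(sample/POOL) equal the latent log-ratio exactly at zero noise — the
  identity the end-to-end tests assert.  The panel's latent values are
  synthetic, fixed numbers with miR-23a/miR-27a elevated ~4–6× and miR-199a
  reduced ~4× in the two fusion-positive lines (RH4, RH30).
* **Matched platforms** — microarray log2 ratios are the latent log-ratio
  plus Normal noise (SD 0.25); TaqMan Ct is 30 − log2(latent) plus Normal
  noise (SD 0.15) in triplicate, with constant RNU6B control rows (Ct 20).
  These SDs are function parameters, not assay-config fields.

All randomness in a simulation flows from one integer seed through a single
`numpy` generator, so identical seed + config reproduces a plate bitwise.

## Processing pipeline

1. **MFI** — median over events per (well, region); < 100 events ⇒
   `low_count`.
2. **Background correction** — per region, subtract the mean MFI of the
   no-target wells; readings below that mean are flagged
   `below_background`.  Flagged rows are kept in the tables with their
   reason code rather than dropped silently.
3. **Spike normalization** — per well, net miRNA MFI divided by net spike
   MFI (ratio first, then averaged across wells — not ratio of averages).
   Wells with a failed or non-positive spike are excluded with a warning.
4. **Replicate summary** — per (sample, miRNA): mean and SD (ddof = 1) over
   wells; ratio R = mean_sample/mean_reference; relative SDs combined in
   quadrature, relSD_R = √(relSD_s² + relSD_ref²); log2_ratio = log2 R with
   log2_sd = relSD_R/ln 2 (delta method); 95% CI = mean ± t₀.₉₇₅,ₙ₋₁·SD/√n
   on the normalized scale.  The quadrature-on-relative-SDs reading of
   "quadratic propagation", and the log2 mapping, are package decisions;
   the CI uses Student t with n − 1 df (n = 3 wells is typical).
5. **Specificity** — pct_of_pm = 100·mean(norm_MM)/mean(norm_PM),
   drop = 100 − pct; significance by a one-sided Welch two-sample t test
   (MM < PM), α = 0.05.  Welch is a choice: the source analyses report
   "p < 0.05" without naming a test.  No multiple-testing correction (two
   mismatch probes per miRNA).

## Calibration fit and linear range

The fit works on per-amount replicate means (arithmetic mean of
background-corrected MFI, then log10).  Every observed amount that leaves
at least 3 points per side is a knot candidate; the knot point belongs to
both segments; each side gets an unconstrained OLS line; the knot with the
smallest total SSE wins, ties breaking toward the larger knot (the
conservative, wider-linear-range claim).  R² = 1 − SSE/SST over all points.
Restricting knots to observed amounts mirrors reporting the saturation
onset as a measured concentration; no continuity constraint is imposed
because none is implied by two independently drawn lines.

The limit of detection is the smallest measured amount whose **raw** MFI
exceeds mean + 3·SD of the background wells in *every* replicate well; the
3σ rule is the conventional choice, adopted explicitly because no formal
sensitivity rule is stated for the assay.  The upper bound of the linear
range is the fitted knot by construction.

Bead stability: retention(day) = geometric mean over amounts of
meanMFI(day)/meanMFI(reference day); a day is "stable" at retention ≥ 0.90
(configurable).  Amount grids must match across days; non-positive means
are excluded from the geometric mean.

## Relative quantification and concordance

ΔCt = mean Ct(target) − mean Ct(RNU6B) per sample; ΔΔCt vs the calibrator;
RQ = 2^−ΔΔCt.  Samples missing the control are reported with NA, not
dropped.  Concordance is the per-miRNA Spearman ρ (average ranks for ties)
over the 7 cell lines shared by each platform pair — the POOL is excluded
because it is the bead/array reference.  All platforms are placed on a log2
scale before ranking (log2 ratios for bead/array, −ΔΔCt for qPCR); ranks
are invariant to this, but plots and tables stay comparable.

## Numerical choices and degenerate inputs

* Segmented-fit SSE ties are resolved at relative tolerance 1e−9 toward the
  larger knot (exact ties occur on noise-free single-line data).
* Background SD with a single background well is 0 (the threshold reduces
  to the mean); the fit requires ≥ 6 distinct amounts and positive
  corrected MFIs; `detect_linear_range` raises "below detection" when no
  sub-knot amount clears the threshold.
* Samples with a single surviving well are reported with NA SD/CI; the
  reference sample must keep ≥ 2 wells.
* Ct values are valid in (0, 45) cycles; event indices must be dense 1..n.

## What the generator does and does not emulate

It emulates: saturating signal vs amount, median-based readout with
lognormal event scatter, region-specific background with no-target wells,
mismatch-efficiency signal loss, spike-cancellable labeling variation,
probe aging, a two-group expression panel, and monotone-linked microarray
and qPCR readouts.  It does **not** emulate sequence-driven
cross-hybridization (efficiencies are configured, not predicted),
PCR-cycle amplification bias, plate/batch effects, bead-count variation
between wells, or carry-over between regions.  Passing tests therefore
demonstrate the correctness and calibration of the *analysis* under the
stated generative model, not the behaviour of the wet assay on real RNA.

## Problem sizes

Default analyses use one 96-well plate per experiment (8 × 3 calibration
wells + 16 background; 8 samples × 3 wells + 16 background for expression),
100 events per bead region, and 50 seeded repetitions where a Monte-Carlo
mean is reported.  These sizes match the plate design the assay describes
and keep every analysis script and the test suite fast on a single CPU.

## Known limitations

* The 1-mismatch efficiencies and all panel latents are synthetic; only the
  2-mismatch drops, the calibration slopes/knot/R², the linear-range
  endpoints, the 35-day stability window and the probe sequences are
  anchored to reported assay characteristics.
* The printed cross-platform correlations for the original cell-line panel
  cannot be reproduced (those data were never deposited); concordance here
  is validated on simulated platforms only.
* No 4PL/5PL calibration or inverse concentration prediction; the curve is
  used only to state the dynamic range.
* Duplex thermodynamics (ΔG, Tm, LNA chemistry) are out of scope.
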