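# beadquant

Analysis pipeline for suspension bead-array (Luminex xMAP-style)
quantification of individual miRNAs, with a fully specified synthetic-assay
generator for validation.

Bead arrays couple DNA capture probes to colour-coded microspheres; a flow
analyzer reads ~100 beads per probe per well and reports the median
fluorescence intensity (MFI).  Turning those event streams into expression
values requires a chain of small but consequential steps — median
summarization, background subtraction, spike-in normalization, replicate
averaging with error propagation — plus assay characterization: a
calibration curve with a linear range, mismatch-probe specificity, and
agreement with orthogonal platforms (microarray, TaqMan qPCR).  `beadquant`
implements that chain as a tested library, a CLI, and a set of analysis
scripts, for anyone processing bead-array miRNA data or studying the
statistical behaviour of such pipelines.

## The model in brief

* **Calibration.**  On log10–log10 axes the probe signal S(C) for target
  amount C follows two straight lines meeting at a saturation knot:
  slope s₁ ≈ 0.94 below the knot (proportional phase) and s₂ ≈ 0.15 above
  it (plateau).  The fit searches every observed amount as the knot,
  minimizes total OLS SSE, and reports slopes, knot and R².  The linear
  dynamic range runs from the 3σ limit of detection (smallest amount whose
  raw MFI exceeds mean + 3·SD of the no-target wells in every replicate)
  up to the knot — with default settings, 0.073 to 18.75 fmol.
* **Quantification.**  Per well, net MFI (background-subtracted) of each
  miRNA is divided by the net MFI of a pre-labeling spike-in control; the
  per-sample labeling efficiency cancels in this ratio.  Replicate wells
  are summarized by mean ± SD; relative SDs of test and reference combine
  in quadrature, relSD_R = √(relSD_s² + relSD_ref²), and expression is
  reported as log2(sample/POOL) with log2_sd = relSD_R/ln 2 and a Student-t
  95% CI.
* **Specificity.**  Mismatch capture probes are scored as a percentage of
  the perfect-match signal after the full pipeline; two-mismatch probes
  lose ~62% (miR-27a) and ~85% (miR-199a) of the signal under the default
  simulation.
* **Cross-platform.**  qPCR is analyzed by 2^−ΔΔCt against an endogenous
  control (RNU6B) and a calibrator sample; platforms are compared per
  miRNA by Spearman rank correlation over the shared samples.

See `docs/methods.md` for the full generative model, parameter defaults
and design decisions.

## Worked example

The `demo` subcommand runs the whole synthetic workflow from one seed:

```sh
$ beadquant demo --seed 1 --out demo_out
calibration: slopes 0.958/0.132, knot 18.75 fmol, R^2 0.9997, linear range 0.0732422-18.75 fmol
   mirna     probe_id  pct_of_pm  drop_pct  p_value  n
 miR-27a  miR-27a-1MM  68.190506 31.809494 0.001716  3
 miR-27a  miR-27a-2MM  35.490094 64.509906 0.001167  3
miR-199a miR-199a-1MM  53.566960 46.433040 0.000798  3
miR-199a miR-199a-2MM  13.976466 86.023534 0.000862  3
   mirna platform_a platform_b      rho  n_samples
miR-199a microarray       qpcr 0.964286          7
 miR-23a microarray       qpcr 0.928571          7
 miR-27a microarray       qpcr 0.892857          7
miR-199a microarray       xmap 1.000000          7
 miR-23a microarray       xmap 0.928571          7
 miR-27a microarray       xmap 1.000000          7
miR-199a       qpcr       xmap 0.964286          7
 miR-23a       qpcr       xmap 1.000000          7
 miR-27a       qpcr       xmap 0.892857          7
```

Reading the output: the noisy titration recovers the generating calibration
(true slopes 0.94/0.15) with R² well above 0.99 and the linear range at its
design endpoints; the mismatch probes lose 32–86% of the perfect-match
signal (each decrease Welch-significant, p < 0.05, n = 3 wells); and the
three simulated platforms rank the seven cell lines almost identically
(ρ ≥ 0.89 per miRNA).  Re-running with the same seed reproduces every file
bit-for-bit; result tables and a run manifest land in `demo_out/`.

The same stages are available as individual subcommands (`simulate`, `mfi`,
`calibrate`, `quantify`, `specificity`, `ddct`, `concord`) over CSV/TSV
inputs, and as numbered drivers under `analysis/` that write their tables
to `results/`:

```sh
python analysis/01_simulate_assay.py --seed 1
python analysis/02_calibration_range_stability.py --seed 1
python analysis/03_mismatch_specificity.py --seed 1
python analysis/04_expression_crossplatform.py --seed 1
```

## Layout

```
src/beadquant/     probekit, simassay, beadio, calibrate, quantify,
                   relquant, workflow, cli  (+ packaged probe table)
analysis/          numbered narrative drivers over the library
scripts/           acceptance.py
tests/             pytest suite (unit, property and end-to-end tests)
docs/methods.md    model, parameters, design decisions, limitations
```
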