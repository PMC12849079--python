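# Methods notes

## Assay model

A plate run is a collection of wells on one injection schedule:
`n_basal` readings before the first injection and `n_post` readings
after each injection, at `interval_min` minutes. The default schedule is
the classical mito stress test on nerve fragments — 5 basal readings,
then 8 readings after each of oligomycin A (5 µM), FCCP (2.5 µM) and
rotenone + antimycin A (5 µM each), at 6-minute intervals (29 readings).
Reading indices are 1-based in files and API; missing readings are
explicit NaN/empty fields and make dependent quantities undefined —
aberrant traces are excluded, never repaired or imputed.

All metric window values are elements of the trace (no interpolation).
"Last OCR before Omy" is read literally as the reading at index
`n_basal`; a basal-window-mean variant is available via
`basal_mode="mean"`. The min/max searches cover the full 8-reading
phase windows; no readings are discarded for mixing time.

## Quality control

The screen for an appropriate inhibitor response is quantified with
four configurable rules evaluated on raw (pre-adjustment) OCR:

| rule | default | meaning |
|---|---|---|
| `omy_max_ratio` | 0.9 | min post-Omy / last basal must fall below (Omy must lower OCR) |
| `fccp_min_ratio` | 1.2 | max post-FCCP / min post-Omy must exceed (FCCP must raise OCR) |
| `rotaa_max_ratio` | 0.9 | min post-Rot/AA / max post-FCCP must fall below |
| `min_basal_ocr` | 5 pmol O₂/min | absolute signal floor |

The ratio rules are invariant under positive rescaling of a trace; only
the absolute floor is not. Rot/AA-pretreated negative controls cannot
respond by design and are exempt. QC runs before baseline adjustment so
adjustment can never induce an exclusion. Under the default noise model
(multiplicative CV 0.05), roughly 85–90% of perfectly flat
non-responder traces are caught: a flat trace's Omy ratio concentrates
near 0.93 and noise occasionally pushes it under the 0.9 threshold, so
the exclusion count tracks, slightly under-counts, the injected
non-responder rate. Tightening `omy_max_ratio` trades this against
false exclusions of weak responders.

## Baseline adjustment

The default `group_offset` mode shifts every included well's trace
additively so its basal-window mean equals the group mean of
basal-window means (ECAR with its own group mean). This preserves the
group's pointwise mean trace exactly and every within-well difference,
hence basal, ATP, leak, maximal, spare and coupling; the absolute NMR
shifts by the per-well offset. The alignment anchor is the basal-window
mean rather than the single last basal reading: a single-reading anchor
would both be maximally noise-sensitive and force every well's
last-basal value to the identical number, destroying the across-well
basal dispersion that the z-scores standardize against. A `percent`
mode (readings as % of own basal mean) and `none` are available; units
after `percent` are % of baseline, so reported metrics change units
accordingly.

## MEF normalization

`MEF_sample = Σ abundance(annotated mitochondrial proteins) / Σ
abundance(all proteins)`, averaged over an animal's replicate samples.
Factors are per animal, not per well: the proteomics derives from a
separate fragment of the same nerve, so fragment-level factors do not
exist. The default `relative_mef` mode divides each animal's traces by
`MEF_animal / geometric-mean MEF` of the cohort, preserving cohort
scale and units (an arithmetic-mean reference is available); the
geometric mean makes the correction symmetric in log space.
`absolute_mef` divides by the MEF itself and changes units to rates per
unit mitochondrial-protein fraction. All modes are per-well scalar
divisions, so spare capacity, coupling efficiency and the reference-based
toxicity scores (with references rebuilt on the same normalized data)
are invariant.

## Reference lines and toxicity scores

Reference lines are built after QC, baseline adjustment and
normalization, in that order: the positive line averages the designated
control group's included standard wells; the negative line averages the
Rot/AA-pretreated wells of all animals. MTI numerators/denominators use
window extrema of the averaged mean trace ("minimal OCR after FCCP from
the negative reference line" = min over the FCCP window of the negative
mean trace). The z-score reference mean and SD are computed across the
positive member wells' own per-well values (last basal, FCCP-window
max) — the only level at which an averaged line has a dispersion; by
construction the positive members' mean z is 0. Degenerate references
(non-positive MTI denominators, member SD ≈ 0) raise rather than return
unbounded scores.

## Statistics

Animals are the statistical unit everywhere; technical-replicate wells
(left/right sides pooled) are averaged per animal first. Two-group
comparisons use the unpaired two-tailed Student's (pooled-variance)
t-test, with Welch behind a flag. Two-factor designs (genotype × week
for blood glucose and body weight) use two-way ANOVA with pairwise
comparisons based on the residual mean square and Šídák adjustment
`1 − (1 − p)^m` over the within-level family (four comparisons in a
2×2 design). Hyperglycemia is blood glucose strictly above 16.7 mM
(murine renal threshold); readings at the 33.3 mM meter ceiling are
flagged censored. Significance tiers: `*` < 0.05, `**` < 0.01,
`***` < 0.001.

## Synthetic data generator

Each well follows piecewise exponential-approach kinetics between four
plateaus (basal B, post-Omy O, post-FCCP F, Rot/AA floor R): within a
phase with target P the noise-free level at the t-th reading is
`P + (L0 − P)·exp(−τ·t)`. Defaults emulate the nerve-fragment study:

- plateaus B=30, O=14, F=70, R=10 pmol O₂/min; basal ECAR 30 mpH/min;
  τ = 1.0 per reading (extrema late in each 8-reading window);
- 2 genotype groups × 12 animals × (5 fragments × 2 nerve sides + 1
  Rot/AA-pretreated negative control);
- multiplicative Gaussian reading noise, CV 0.05 (respirometry
  variability scales with signal);
- between-animal variability: a truncated-normal factor (CV 0.10) on
  the mitochondrial plateau components above R, so animals differ in
  level but not in dimensionless metrics;
- genotype deficit (default factor 0.85) applied the same way:
  `B' = R + f·(B−R)` etc., giving exactly f-fold lower basal, ATP, leak
  and maximal respiration with unchanged spare, coupling and NMR — the
  diabetic-nerve signature;
- non-responder wells (flat at B) injected with probability 0.05 to
  exercise QC; negative controls sit at R in every phase;
- per-animal MEF drawn N(0.15, 0.02); proteomics tables (triplicate per
  animal, 400 proteins, 25% annotated mitochondrial) are renormalized so
  each sample's mitochondrial share equals the draw exactly, making MEF
  recovery exact by construction;
- phenotype draws use the emulated strain values (control ~7.5 mM
  glucose at both weeks; diabetic 20.1 → 30.5 mM, censored at 33.3 mM;
  body weights 21→25 g vs 37→45 g, the week-15 values being generator
  assumptions).

The generator does not model instrument drift, plate-edge effects, O₂
diffusion physics, ECAR injection responses (ECAR is flat at its basal
plateau) or correlated noise; passing tests therefore validate the
analysis arithmetic and pipeline behaviour, not robustness to those
real-data artifacts.

Noise, non-responder probability and the week-15 body weights are
generator assumptions, not measured facts. All draws derive from one
seed through fixed subsidiary streams, so plate, proteomics and
phenotype are jointly reproducible and the MEF draws are shared between
the plate and proteomics simulators.

## Numerical choices and known limitations

- Plateaus count as attained when `τ · n_post ≥ 25` (residual < 1e-11 of
  the gap); the analytic plateau oracle applies in that regime. The
  default τ=1.0 leaves ~5e-3 residual approach in window extrema.
- Window extremum estimators are upward/downward biased under noise:
  the max over ~6 near-plateau readings with σ = 0.05·level biases
  maximal respiration by ≈ +1.2σ (≈ +4 pmol O₂/min at F=70), several
  times its pooled standard error. Basal (+0.7) and ATP (+0.9) are
  biased less than 3 pooled SE. This is a property of the max/min
  window definitions themselves and affects any analysis using them;
  comparisons between groups are largely unaffected because the bias is
  common to both.
- Long-CSV floats are serialized with shortest round-trip `repr` and
  parsed with correctly-rounded `float()`, so write→read→write is
  byte-identical and read(write(run)) == run exactly.
- Group comparison sizes used by the calibration checks: type-I rate on
  6 animals/group × 4 standard wells (500 null cohorts in the test
  suite, 200 in the acceptance script); power on the full 12-animal
  design (100 cohorts). The t-test is exact under the generator's
  near-normal animal-level distribution, observed rejection ≈ 5%.
- MEF normalization divides by a per-animal factor that, in the
  generator, is statistically independent of the respiration level, so
  `relative_mef` adds ≈13% CV to animal-level metrics rather than
  removing variance; with real data the factor is expected to correlate
  with mitochondrial content and reduce variance. Calibration/power
  checks therefore run without MEF normalization.
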