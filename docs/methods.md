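# Methods

This note records the models, numerical conventions and design choices
behind `csfnmr`, and what the synthetic-data experiments do and do not
demonstrate.

## Spectral model and preprocessing

A spectrum is a uniformly sampled chemical-shift trace, stored with the ppm
axis descending (display convention); ascending files are flipped on read.
Axis uniformity is enforced to a relative tolerance of 1e-9. Baseline
correction and phasing are assumed done upstream in the acquisition
software; an optional 3rd-order polynomial detrend is provided but off by
default.

**Alignment.** Chemical shifts wander slightly between samples (pH, ionic
strength, temperature), so spectra are aligned before bucketing. We use a
segment-wise integer-shift scheme in the icoshift/RSPA family — the simplest
method that implements non-linear (piecewise) alignment: the spectrum is cut
into contiguous segments of ~0.08 ppm; each segment is shifted by up to
±0.01 ppm (whole grid points) to maximise its *normalised* cross-correlation
with the point-wise median spectrum, and vacated points are filled by linear
interpolation from the segment edges. Normalisation of the correlation
matters: the raw inner product would reward dragging a taller neighbouring
peak into the segment. Ties prefer the smaller |shift|, so identical or flat
spectra pass through unchanged and the grid never changes length.

**Bucketing.** Buckets are half-open intervals [b, b + 0.02) ppm tiled from
0.2 to 9.6, integrated by the trapezoidal rule over in-bucket grid points
(linear in the intensities, robust to grid density). A bucket is dropped
when its interval overlaps — with positive measure — an exclusion window:
residual water (4.30–5.00 ppm) and the methanol contaminant singlet
(3.34–3.38 ppm) by default. This yields 435 variables with the water window
alone and 433 with both; both counts are exposed because the analysis text
that motivated them is ambiguous about the order of the two exclusions.
Spectra are not normalised (e.g. to TSP) before bucketing; group effects in
the generator are injected on the concentration scale, and quantification
normalises to the control mean, so a global intensity normalisation would
cancel anyway.

## Chemometrics

**Pareto scaling.** x′ = (x − x̄)/√s with the sample SD (n − 1). The square
root damps the dominance of intense resonances without amplifying baseline
noise the way unit-variance scaling does. Zero-variance columns are centred,
left unscaled (divisor 1) and flagged, keeping bucket indices stable.
Note that Pareto scaling is only *partially* scale-invariant: multiplying a
column by α multiplies its scaled values by √α, so the absolute intensity
scale of different resonances still influences the model (this is true of
the method itself, not an artefact of this implementation).

**PLS-DA.** The response is the 0/1 group indicator (groups in sorted label
order), centred; q² is invariant to affine recoding. Components come from
sequential NIPALS PLS1: w = Xᵀy normalised, t = Xw, p = Xᵀt/(tᵀt),
c = yᵀt/(tᵀt), then X and y are deflated. One component is the default —
the discrimination problems this package targets are reported as
one-component models — with the component count a parameter throughout.
The one-component weight equals the closed-form PLS1 solution w ∝ Xᵀy,
which the tests use as an independent oracle.

**q² cross-validation.** Stratified 7-fold CV: within each group, samples
are assigned to folds round-robin in input order (deterministic without a
seed; a seeded shuffle is optional). Per fold the scaling is refit on the
training samples only — the source analyses do not state this, but
anything else leaks held-out information. q² = 1 − PRESS/SS with SS the
total squared deviation of the 0/1 response from its overall mean (the
overall-SS convention; commercial software may use per-round SS, a
difference that is small at these fold counts).

**VIP.** VIPⱼ = √(p·Σₐ SSYₐ(wⱼₐ/‖wₐ‖)² / Σₐ SSYₐ) with
SSYₐ = cₐ²·tₐᵀtₐ; mean(VIP²) = 1 identically. Selection uses a strict
threshold (VIP > 2).

**Permutation validation.** Group labels are permuted uniformly at random
(sizes preserved) and the *entire* pipeline — fold re-stratification on the
permuted labels, per-fold rescaling, fit, q² — is rerun for each of the 200
permutations. Re-stratifying matters: reusing the genuine fold partition
would make the genuine q² (whose folds are balanced by construction)
stochastically larger than the permuted ones under the null, biasing the
test anti-conservative. With re-stratification, genuine and permuted q² are
exchangeable under label exchangeability, and the strict nearest-rank
95th-percentile criterion fires with probability 10/201 ≈ 4.98%, which the
calibration test verifies empirically. Significance ⇔ genuine q² strictly
above the 95th percentile.

## Study-design logic

One sample per patient: the visit with maximal months-from-enrolment, ties
broken by later disease duration, then lexically first sample id. Nested
cohorts use an inclusive threshold on months-from-enrolment ("≥ X months"),
or a strict threshold on disease duration ("> 5 years"); all controls are
always included, and the five PLS (primary lateral sclerosis) patients are
appended to a model only when requested, without threshold filtering. The
progression rate is (48 − ALSFRS-R)/duration in points/month; the slow/fast
split puts the boundary rate 1.0 in the slow group (the printed interval is
0–1), configurable.

## Synthetic data

The generator emulates 700-MHz CSF spectra well enough to exercise every
pipeline stage with known truth; it is not a physical NMR simulation.

* **Lineshape**: Lorentzian, FWHM 0.0021 ppm (≈1.5 Hz at 700 MHz), on a
  default grid of 32768 points spanning −0.2 to 10.0 ppm. Glucose is a comb
  of lines covering its seven bucket regions rather than an exact coupled
  multiplet — quantification sums whole regions, so J-coupling fidelity
  would add cost without changing any tested quantity.
* **Amplitudes**: a metabolite's total integral at ratio 1 is its typical
  CSF concentration times the proton count of the modelled resonances
  (¹H integral ∝ concentration × protons): lactate 1.6 mM × 4H, citrate
  0.3 mM × 4H, glucose 3.3 mM × 6H, ethanol 0.1 mM × 5H. Because Pareto
  scaling is only partially scale-invariant, these relative magnitudes are
  part of the model's behaviour, which is why they are derived from CSF
  chemistry rather than set arbitrarily.
* **Group structure**: each sample draws a per-metabolite scale factor from
  a truncated normal (>0) with the group's ratio-vs-control mean and SD
  (control SDs 0.14/0.17/0.08/0.09 for lactate/citrate/glucose/ethanol).
  Draws are independent across metabolites and across visits; real
  metabolomes are correlated between metabolites and within patients over
  time, so passing tests show the pipeline recovers the injected
  first-order structure, not that it would behave identically on real
  longitudinal covariance.
* **Nuisance structure**: TSP reference singlet fixed at 0 ppm, a broad
  Gaussian residual-water hump confined to the 4.30–5.00 ppm window, a
  methanol singlet at 3.36 ppm with random amplitude (both fall in excluded
  windows), additive Gaussian noise (SD 0.002, high-SNR cryoprobe regime)
  and chemical-shift jitter: a whole-spectrum shift ~N(0, 0.002 ppm) plus
  per-metabolite shifts ~N(0, 0.001 ppm).
* **Longitudinal roster**: attrition is deterministic — each ALS patient is
  pre-assigned a maximum follow-up stratum (20/6/3/5/6 patients with last
  visits at 0/6/12/18/24 months) so the nested cohort sizes 40/20/14/11/6
  are exact. Case visits at ≥6/≥12/≥18 months draw from the corresponding
  effect column; baseline visits use half the ≥6-months effect (the
  baseline-only contrast is reported as weak), and PLS patients use the
  long-duration column. Disease duration at enrolment and progression rate
  are truncated normals consistent with the published summary moments, and
  ALSFRS-R per visit is derived from them, so the progression-rate formula
  is exactly invertible on synthetic data.

## Problem sizes and numerics

The recovery experiments use 20 independent cohorts per condition:
14-vs-14 cohorts for the q² experiments (median q² ≈ 0.45–0.50 at the
≥12-months effect sizes, matching the significance regime the method is
meant to detect; q² ≤ 0 for most null cohorts) and 20-vs-14 cohorts for
ratio recovery (seed-averaged case means within ±0.05 of the generative
means). Permutation calibration uses 500 independent 28 × 435 noise
datasets with 200 permutations each. Tolerances: axis uniformity and
bucket-edge comparisons 1e-9; NIPALS rank guard 1e-12; the closed-form
PLS1 oracle is checked to 1e-8; Dunnett p-values use a fixed-seed
quasi-Monte-Carlo integration so reruns are byte-identical.

## Known limitations

* Alignment shifts whole segments by integer grid points; sub-grid shifts
  and peak-shape changes (pH-dependent citrate movement, say) are not
  modelled or corrected.
* The ANOVA/Dunnett comparison is applied to nested (overlapping) cohorts
  exactly as in the emulated design; the groups are not independent, so the
  familywise guarantee is nominal within one model's contrast set only.
* JCAMP-DX support covers AFFN `(X++(Y..Y))` records only — enough for
  exported 1D traces, not compressed (DIF/DUP) files.
* The synthetic generator's independence assumptions (between metabolites,
  between visits) make its cohorts somewhat easier than real ones at equal
  effect sizes; conclusions about absolute power on clinical data should
  come from clinical data.
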