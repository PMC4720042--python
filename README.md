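# csfnmr

Chemometric discrimination of cerebrospinal-fluid (CSF) ¹H-NMR metabolomic
profiles, built for longitudinal case-control studies of amyotrophic lateral
sclerosis (ALS) and implemented as a reusable, tested Python pipeline.

Neurochemical biomarkers for ALS are sought in CSF because it sits closest to
the degenerating tissue. High-field ¹H-NMR spectroscopy measures dozens of
small-molecule metabolites in a single non-destructive acquisition; the
question is whether the spectra of patients and controls separate, and which
metabolites drive the separation. This package implements the standard
chemometric workflow for that question:

1. **Preprocessing** — segment-wise cross-correlation peak alignment, then
   reduction of each spectrum to fixed-width 0.02-ppm buckets integrated
   between δ 0.2 and 9.6 ppm (trapezoidal rule), dropping the residual-water
   window (4.30–5.00 ppm) and a methanol contaminant window (3.34–3.38 ppm).
   Default bucketing yields 435 variables after the water exclusion, 433 with
   both exclusions.
2. **Modelling** — Pareto scaling (x′ = (x − x̄)/√s) followed by a
   one-component PLS-DA (NIPALS PLS1 on the centred 0/1 group indicator).
   Predictive ability is the cross-validated

   q² = 1 − PRESS/SS,

   from stratified 7-fold cross-validation (one seventh of the samples
   withheld per round, scaling refit per training fold); q² > 0.4 is treated
   as the significance threshold for biological data.
3. **Validation** — a pseudo-Monte-Carlo permutation test: the full
   scale-fit-q² pipeline is rerun under 200 random group relabellings and the
   model is accepted when the genuine q² exceeds the 95th percentile of the
   permuted values.
4. **Interpretation** — variable importance in projection (VIP; buckets with
   VIP > 2 are selected, mean VIP² = 1 by construction), metabolite
   annotation of selected buckets, summed-integral quantification of lactate,
   citrate, glucose and ethanol, normalisation to the control-group mean, and
   one-way ANOVA with Dunnett many-to-one comparison against control.
5. **Study design** — longitudinal visit handling: one sample per patient
   (the most advanced visit), nested case cohorts by minimum follow-up,
   ALSFRS-R progression rate (48 − score)/duration with a 1 point/month
   slow/fast split.

Because clinical CSF spectra cannot be redistributed, the package ships a
first-class synthetic generator (`csfnmr.synthetic`): Lorentzian multiplets
for the four discriminating metabolites at realistic CSF proportions, TSP
reference, residual water, methanol contamination, noise and chemical-shift
jitter, with group effects injected on the concentration scale and a
longitudinal roster whose nested cohort sizes (40/20/14/11/6 ALS cases,
5 PLS, 14 controls) match the study design it emulates.

## Worked example

```python
import numpy as np
from csfnmr import (align_spectra, build_bucket_table, generate_case_control,
                    pareto_scale, fit_plsda, q2_cross_validate,
                    permutation_validate, vip_scores, annotate_buckets)

spectra, truth = generate_case_control(14, 14, effect="als_ge12", seed=1)
spectra = align_spectra(spectra)
table = build_bucket_table(spectra)          # 28 samples x 433 buckets
y = np.array([sp.group_label for sp in spectra])

q2 = q2_cross_validate(table.values, y)      # 7-fold, one component
model = fit_plsda(pareto_scale(table.values), y)
perm = permutation_validate(table.values, y, n_perm=200, seed=1)
vip = vip_scores(model)

print(f"q2 = {q2:.3f}, significant: {perm.significant}")
for j in vip.selected[:5]:
    mid = table.bucket_midpoints[j]
    print(f"  {mid:.2f} ppm  VIP {vip.vip[j]:.2f}  {annotate_buckets([mid])[0]}")
```

Output:

```
q2 = 0.469, significant: True
  1.19 ppm  VIP 3.31  Ethanol
  1.33 ppm  VIP 8.88  Lactic acid
  2.65 ppm  VIP 6.59  Citric acid
  3.25 ppm  VIP 3.36  Glucose
  3.27 ppm  VIP 3.90  Glucose
```

The model separates the synthetic case group from controls above the
q² = 0.4 significance threshold, survives the 200-permutation test, and the
buckets that carry the separation (24 selected in this run) all sit inside
the ethanol, lactate, citrate and glucose resonance regions.

The same workflow is available from a shell:

```sh
csfnmr -v run-all --seed 1 -o results/run1          # full pipeline + report
csfnmr simulate --seed 1 -o data/                   # spectra + roster only
csfnmr preprocess -i data/spectra -o buckets.tsv
csfnmr fit -t buckets.tsv -r data/roster.csv --min-months 12 -o model.json
```

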