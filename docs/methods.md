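# Methods

## Mock-community validation model

A blend of `N` pure cultures with weights `w_i` (g) and potencies `T_i`
(TFU/g) has predicted relative abundances

    a_i = w_i T_i / Σ_j w_j T_j .

The prediction is scale-invariant in the potencies, so only potency
*ratios* matter; the default six-strain panel therefore carries
representative lyophilised-culture potencies of order 1e10 TFU/g.

The spike design follows the validation experiment's geometry: an
equal-weight blend (total/N grams each) plus, per strain, a blend with
that strain at 100 g and every other at 4 g, 120 g total. With six
strains this yields seven mixes and 42 predicted fractions.

**Error budget.** Flow-cytometry potency readings have a
reproducibility standard deviation `S_R` in log10 units. A one-sigma
reading is off by the factor `10^S_R`, giving a relative error
`|1 − 10^S_R|` (the magnitude is used; the raw difference is negative).
Distributing one mis-measured component against the remaining `N − 1`
gives the per-fraction budget `|1 − 10^S_R| / (N − 1)`. The budget is a
deliberately conservative bound: simulated measurements (below) land
well inside it.

**Measurement simulation.** Observed profiles are modelled as
predictions computed from perturbed potencies `T_i · 10^ε_i`,
`ε_i ~ N(0, S_R²)` i.i.d., then renormalised. One draw per strain per
replicate (a potency is measured once and reused across mixes, as in
the validation experiment). No inter-strain covariance is modelled —
only the marginal `S_R` is available. Agreement is the MAE pooled over
all mix × taxon pairs, not per-mix averages of averages.

## KIDMED index

Sixteen yes/no items; 12 score +1 on "yes", 4 score −1, "no" scores 0;
totals lie in −4..12 with categories ≥8 / 4–7 / ≤3. The four negative
items of the shipped default table are frequent fast food, skipped
breakfast, commercial pastries for breakfast, and daily sweets; the
item table is data, so any published variant can be loaded. Missing
answers are rejected by default; a lenient mode scores the answered
items and flags the record incomplete.

## Synthetic cohort generator

The generator emulates the study conditions; it is a testing substrate,
not an attempt to reproduce unpublished individual-level values.

* **Demographics.** Groups control/T1D/obese with n = 40/40/18 (the
  overall count of 98 follows the study total; the published control
  sex split of 22/17 is kept as a fraction). Ages are normal with the
  published group moments, truncated to the 7–17 y recruitment window
  (this shifts the obese mean down by ≈0.25 y — an accepted consequence
  of truncation); BMI is normal truncated below 10 kg/m²; HbA1c
  (7.09 ± 2.01%) exists only in the T1D group.
* **Microbiome.** Zero-inflated compositional draws over eight
  (sub)species: per taxon a Bernoulli presence draw (baseline 0.9),
  then gamma variables with shape `concentration × base_weight ×
  multiplier`, renormalised per row. The control base composition is
  dominated by *longum* subs. *longum* (0.25) and *adolescentis*
  (0.20) with minor *animalis* fractions; concentration 15 gives the
  broad overdispersed spread typical of compositional abundance data.
* **Metabolites.** Log-normal concentrations (log-SD 0.6, i.e. CV
  ≈ 65%) around group-scaled medians, multiplied by a per-participant
  log-normal creatinine level (median 1 g/L, log-SD 0.4) and then
  creatinine-normalised to mmol/g — the normalisation step is exercised
  exactly as for spot urine samples.
* **Effect template.** Controls are the baseline (all multipliers 1).
  Obesity: *infantis* and *breve* ×2, *bifidum* and *longum* subs.
  *longum* ×0.5, *bifidum* presence 0.9 → 0.6; valeric acid ×1.5
  (placing obese between control and T1D), valine and isoleucine ×0.5,
  leucine ×0.7 (the study reports its decrease as weaker); KIDMED +2
  points. T1D: *adolescentis* and *pseudocatenulatum* ×1.5 — kept
  milder than the obesity effects because the study describes the T1D
  microbiome shift as secondary, and the first latent variable of the
  microbiome PLS-DA should carry the obesity axis; valeric ×2.5 and
  propionic/butyric/heptanoic ×2, remaining SCFAs ×1.3. Magnitudes are
  synthetic choices (the source figures are boxplots without printed
  effect sizes); only the directions are study findings.
* **KIDMED answers.** Positive items have baseline yes-probability 0.5,
  negative items 0.3 (expected score 4.8, mid "needs improvement");
  a group's score shift is spread uniformly over the twelve positive
  items' probabilities.

Everything is driven by one `numpy` Generator: a cohort is a pure
function of (design, template, seed). What passing tests on this
substrate show is that the *pipeline* detects effects of the encoded
kind and size at the study's sample sizes and is calibrated under the
null — not that the real data contain them; real stool compositions
have inter-taxon correlation structure, and real questionnaire items
have heterogeneous marginal rates, which the generator does not model.

## Statistical pipeline

* **Rank-sum tests** are two-sided Wilcoxon rank-sum (Mann–Whitney):
  exact permutation null when the combined n ≤ 12 with no ties, else
  normal approximation with tie and continuity corrections. When every
  pooled observation is tied the p-value is defined as 1 (the
  tie-corrected variance degenerates). No multiplicity correction is
  applied anywhere, matching the study's analysis; a Benjamini–
  Hochberg column is available behind a flag that defaults off.
* **Zeros are data**: absent taxa enter the tests as tied zeros, never
  as missing values, so "appears less often" and "less abundant" both
  move the statistic.
* **χ² independence** is the Pearson statistic without continuity
  correction.
* **Spearman** is the Pearson correlation of mid-ranks with the
  two-sided t-approximation on n − 2 degrees of freedom (used both for
  correlation matrices and their significance; constant input is
  rejected explicitly). Matrix cells with fewer than three pairwise-
  complete observations are reported NaN.
* **PLS-DA** is the classical two-block NIPALS with regression
  deflation, written here rather than delegated. The feature block is
  autoscaled (zero mean, unit variance, n−1 denominator); the one-hot
  class block is autoscaled too, which gives every class equal pull on
  the latent variables despite the 18-vs-40 group imbalance — without
  it the smallest class is under-weighted and the first latent
  variable need not carry the obesity axis. Determinism: the starting
  y-score is the class column with the largest residual variance, and
  each weight vector's sign is fixed so its largest-magnitude entry is
  positive. Convergence: relative change of the score vector below
  1e-10, iteration cap 2000 (the inner power iteration can need
  several hundred rounds when two discriminating directions are
  near-degenerate); failure raises with the iteration count. Score
  orthogonality and the deflation residual are verified to 1e-8.
  Per-component explained X variance is reported; it is typically but
  not necessarily non-increasing, since components maximise covariance
  with the class block, not X variance. Model validation follows the
  study: Spearman correlation of LV1 scores with BMI.

## Problem sizes

The Monte-Carlo studies use 200 replicates for the mock-mix budget
coverage, 500 for the type-I calibration (18 000 pooled tests), and 50
full cohort replicates for effect-direction recovery; the rank-sum
oracle sweep is exhaustive over all 2 026 tie-free configurations with
combined n ≤ 10. These sizes give the proportions a standard error
small against the margins tested while keeping the full run in the
tens of seconds.

## Known limitations

* Compositional draws are Dirichlet-style and therefore carry only the
  negative correlation the simplex imposes; real microbiome data have
  richer covariance.
* The error budget treats `S_R` as the only uncertainty source;
  weighing error and assay noise are not modelled separately.
* The exact rank-sum path requires tie-free data; tied small samples
  fall back to the corrected normal approximation.
* PLS-DA numbers are not bit-identical to any particular external
  implementation (conventions differ in block scaling and sign);
  agreement is asserted at the level of invariants, score equality up
  to sign against an independent NIPALS, and loading rankings.
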