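# Methods

## Data model

One row of the feature table is one semen sample: donor identifier,
treatment label (`Fresh`, `CTRL-` = HF-20 extender alone, `CTRL+` =
commercial INRA Freeze, or HF-20 plus Matcha / Spirulina / Horseradish /
Quercetin extract), donor age in years, and 14 quantitative features —
CASA kinematics TM and PM (%), VCL, VSL, VAP (µm/s); the JC-1 MMP ratio
(a.u.); LPO, ROS and NO fluorescence (a.u.); TUNEL and SCSA DNA
fragmentation indices (%); and the holotomography-derived whole-cell,
post-acrosomal/midpiece and nuclear-region volumes (µm³). Percentages
must lie in [0, 100], volumes are strictly positive, and the two
subcellular volumes never exceed the whole-cell volume; violations are
rejected at read time with the offending row index. The table is agnostic
about whether a row is one sample or one replicate measurement; the
generator makes the replicate count explicit.

The modelling feature vector is the 14 features plus age (15 columns).
Age is included by default because donor age is a legitimate part of a
sample's provenance signature; since it is constant within a donor it can
partially identify donors, and `CVConfig(include_age=False)` removes it
when that leakage-like behaviour is unwanted.

## Synthetic cohorts

The generator emulates a split-ejaculate design: each donor's ejaculate
is divided across all seven conditions, so donor effects are crossed with
treatment. Feature values are additive on the measurement scale:

    value = baseline + donor_offset(donor) + 1[frozen]·freeze_shift
            + antiox_shift(treatment) + noise

with donor offsets drawn once per (donor, feature), percentages clipped
to [0, 100] and volumes floored at 10⁻³ µm³. Generation on the raw scale
with post-hoc clipping (rather than logit/arcsine-scale generation) is
deliberate: it is the simplest structure that reproduces the qualitative
contrasts of interest, and the ANOVA stage re-transforms percentages
itself. One RNG stream is consumed in a fixed order — donor offsets,
ages, residual noise — so changing the replicate count never changes the
donor offsets, and identical configurations produce byte-identical CSVs.

The default effect profile encodes the study conditions the package is
built around:

* **donor SD = 1.5 × residual noise SD on every feature** — donor
  identity is the dominant variance source;
* **freeze shift = −1.5 × noise SD** on TM, PM, VCL, VSL, VAP, MMP,
  whole-cell and midpiece volume, **+1.5 × noise SD** on LPO, ROS, NO and
  both DFIs (freezing depresses motility and bioenergetics and elevates
  stress and DNA damage), and **exactly 0 on nuclear volume**;
* **antioxidant shifts ≤ 0.2 × noise SD**, concentrated on the midpiece
  volume, with Matcha/Horseradish losing twice as much midpiece volume
  (−0.20 × noise SD) as Spirulina/Quercetin (−0.10), and CTRL+ in
  between — so antioxidant-specific structure exists but stays near the
  detection floor.

Baseline magnitudes (e.g. TM 80 %, VCL 150 µm/s, whole-cell volume
28 µm³, midpiece 6.5 µm³, nucleus 4.5 µm³) are plausible literature-scale
values for equine semen chosen once for realism; no fidelity to any
particular dataset's unpublished group means is claimed. Under these
defaults fewer than 1 % of percentage draws hit the [0, 100] bounds.

Ages are sampled without replacement from 4–17 years where possible and
are constant per donor. `null_cohort` produces a label-free control: all
donor, freeze and antioxidant effects zeroed *and* ages drawn
independently per row — a per-donor constant age would by itself identify
donors, which is exactly what a null cohort must not allow. Null cohorts
back the leakage and calibration tests.

What the generator does **not** emulate: the 30-tomogram-per-sample
imaging hierarchy (it emits sample-level features directly), skewed or
heavy-tailed assay distributions, donor-by-treatment interactions, and
batch/session effects. Passing tests therefore demonstrate correctness of
the statistical machinery under a Gaussian hierarchical model, not
robustness to every real-data pathology.

## Classification pipeline

Standardisation uses the sample (n−1) standard deviation; zero-variance
columns are flagged and transform to 0. PCA is computed by SVD of the
centred matrix (numerically preferable to forming the covariance; an
oracle test enforces equivalence with its eigendecomposition) with a
deterministic sign convention: the largest-magnitude loading of each
component is positive. LDA uses per-class means, empirical priors and the
pooled within-class covariance Σ = Σ_c (n_c−1)S_c/(N−C) plus a ridge
λ·tr(Σ)/p·I with λ = 10⁻⁶ — minimal, scale-aware protection against
singular covariances in small inner folds, disclosed in the fitted model.
If Σ is identically zero (every class a single point) the identity is
used, reducing LDA to nearest class mean. Priors are empirical rather
than uniform because outer folds need not be balanced. Prediction ties
break by class-label order; kNN (k = 5 default) breaks vote ties by
smallest mean neighbour distance, then label order. SVMs are not
implemented; the classifier slot accepts any fit/predict object.

Folds are stratified by the target label by default. The design has 10
donor classes of 21 rows each; unstratified 5-fold splits can leave a
class absent from a training split, making the procedure undefined, so
stratification is the minimal fix and is exposed as a flag. The stratified
assignment places each shuffled class member into the currently
least-filled fold, keeping per-class fold counts within one of each
other. A single master seed spawns independent child seeds for the outer
partition and each outer fold's inner search, so inner folds never reuse
outer assignments and every run is exactly reproducible.

The inner loop evaluates each candidate PC count on the same inner fold
plan (a paired comparison), slicing the leading columns of one maximal-
rank PCA fit per inner fold — mathematically identical to refitting at
each candidate since truncated SVDs nest. Infeasible candidates (those
exceeding the inner-training rank) are dropped; accuracy ties go to the
smallest candidate, favouring parsimony. The fixed-PC mode is exactly
equivalent to a singleton grid, and a test asserts bit-level equality.

Two accuracy aggregations exist: the mean of outer-fold accuracies
(the headline number, `mean_accuracy`) and the pooled out-of-fold
accuracy (trace/total of the pooled confusion matrix,
`pooled_accuracy`). With stratified folds of near-equal size they differ
little; both are always reported.

## Permutation test

Each of B permutations shuffles the label vector, re-draws the fold
partition from a derived seed (so no single arbitrary partition is frozen
into the null), reruns the full fixed-PC pipeline, and records the mean
outer-fold accuracy. The p-value is the proportion of null accuracies
greater than or equal to the observed one, ties counted. The uncorrected
m/B estimator is the default; the (m+1)/(B+1) bias-corrected variant is
behind a flag. Permutations rerun the fixed-PC pipeline rather than the
nested grid search: the search is label-dependent only through a single
integer and rerunning it ~1000 times is disproportionate; `nested=True`
enables the full search where wanted. Calibration on null cohorts is
slightly conservative (permutation p-values are stochastically ≥ uniform
in finite samples), which the calibration test allows for.

## Volumetric statistics

Percentage features are arcsine-square-root transformed
(arcsin √(p/100)) before testing — the classical variance-stabilising
form; volumes are analysed untransformed. The multivariate path does
*not* arcsine-transform anything: it standardises raw features, keeping
the two stages' preprocessing contracts separate.

Shapiro–Wilk runs per group (n ≥ 3 and non-degenerate required, otherwise
flagged untestable), Levene's test (mean-centred) checks homogeneity;
both at α = 0.05. Failures annotate the result but do not divert to
nonparametric alternatives. The one-way ANOVA computes the between/within
decomposition explicitly (the identity SS_total = SS_between + SS_within
is asserted in tests to 10⁻⁹ relative tolerance) with the p-value from
the F distribution; the degenerate all-constant case returns F = 0,
p = 1. Post hoc comparisons are classical Bonferroni: pooled-variance t
tests with df = N − k, raw p × k(k−1)/2 capped at 1, tiered at ns /
p ≤ 0.05 / p ≤ 0.01 (the letter-display convention reduced to tiers);
Welch per-pair tests are available behind a flag. Tail probabilities come
from scipy; the decomposition and adjustment are in-repo so the pooled-
variance post hoc contract is explicit.

## Determinism and problem sizes

Every stochastic step (cohort generation, fold assignment, permutation
shuffles) derives from explicit integer seeds; the full pipeline rerun
with an identical configuration reproduces every JSON artifact byte for
byte. The test suite and the acceptance script run the analyses at the
study's design scale (210 rows); calibration and power checks use 10–20
independent cohorts and B = 200 permutations, while the acceptance script
uses the study-scale B = 1000 for its single-cohort permutation tests.

## Known limitations

* The Gaussian additive generator cannot probe robustness to outliers,
  skew, or missing data (missing values are rejected, not imputed).
* Donor and treatment are analysed as separate one-way layouts; there is
  no mixed-effects or donor-by-treatment interaction model. In such a
  layout the donor variance inflates the within-group variance of
  treatment contrasts, which materially limits the power of the pairwise
  volume comparisons at realistic donor-effect sizes — visible in the
  power checks and worth remembering when interpreting treatment-level
  ANOVAs on donor-structured data.
* With donor effects on every feature at 1.5 × noise and freeze shifts of
  the same size, the Fresh class's population-limit F1 under the 1:6
  class imbalance is about 0.77–0.85: perfect Fresh separation requires
  freeze effects well above that regime.
* No leave-one-donor-out CV and no repeated CV; both are natural
  extensions.
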