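# Methods

This note documents the statistical models, the synthetic-data design and
the numerical conventions behind `crossmeth`, in the spirit of the model
documentation shipped with simulation and statistics packages: what is
computed, under which assumptions, and what the bundled tests do and do not
demonstrate about real data.

## Data model and conventions

All stages operate on beta values — methylation proportions in [0, 1],
probes as rows, samples as columns — with aligned probe and sample indices
across matrices. "% DNA methylation" is beta × 100. Matched designs pair one
blood and one sperm sample per individual; pairing is positional unless an
explicit individual → (blood, sperm) map is given. The array-wide
significance threshold defaults to *P* < 9×10⁻⁸ throughout
(`paired.EPIC_ALPHA`), the accepted genome-wide level for EPIC-scale
site-wise testing.

Medians and quantiles use linear interpolation between order statistics
(NumPy's default, R type 7); this matters because methylation categories and
the variability filter sit directly on quantile boundaries. Category
boundaries are: low iff median < 0.20, high iff median > 0.80, intermediate
otherwise (both boundaries fall into intermediate). The variability
criterion keeps a probe iff its 10th–90th percentile span is ≥ 0.05 in
*both* tissues, with the boundary inclusive up to a 1e-12 float guard.

Fisher exact tests report the sample odds ratio a·d / (b·c) (∞ or 0 when a
margin or off-diagonal cell is empty) and a two-sided p. Reported p-values
are floored at 1×10⁻⁵⁰ (`p_floored`) following the "P < 1e-50" reporting
convention; raw values are retained on the result objects.

## Quality control

Probe filters run in a fixed order so per-filter counts are reproducible:
detection-p → bead count → SNP proximity → exclusion lists, each probe
attributed to the first filter that removes it.

* detection-p: removed when *more than* 5% of samples have detection
  *P* > 0.05 (strict inequality: 6/100 failing samples removes, 5/100 does
  not);
* bead count: removed when bead count < 3 in ≥ 5% of samples. The
  sample-fraction convention for the bead rule is a package decision
  (mirroring the detection-p convention) and is recorded in the QC report;
* SNP proximity: any annotated SNP within 10 bp of the CpG site;
* exclusion lists: externally curated probe-ID sets (cross-reactive probes,
  published SNP lists), counted per list.

Sample outliers are flagged on the leading principal components by two
rules: PC1 outside median ± 2×IQR, and robust distance of the (PC1, PC2)
score from the coordinate-wise median above 5 MADs. By default both rules
must agree (`combine="intersection"`); union or single-rule behaviour is
configurable. The second rule replaces high-dimensional outlier detectors
that operate on raw intensities, which this package does not consume.

Normalization is between-sample quantile normalization stratified by probe
chemistry (Type I vs Type II): within each stratum every sample is mapped
onto the stratum's mean quantile profile. This keeps the essential property
of type-aware array harmonisation — the two chemistries, which differ in
dynamic range, are never mixed — while operating on betas rather than raw
intensities; it is deliberately *not* an intensity-level background
equalisation, and the deviation is intentional because the package's input
contract is beta matrices. Ranks within sample and stratum are preserved
exactly; ties are broken by stable sort order, deterministically.

Genotype concordance of a claimed pair is the Pearson correlation of its
betas over the array's non-CpG genotyping probes: concordant iff r ≥ 0.9,
"indeterminate" when either vector is constant.

## Paired differential methylation

Site-wise: one-sample *t* on the per-pair differences (sperm − blood),
pairwise-complete per probe, df = n_pairs − 1, two-sided p; probes with
fewer than 4 complete pairs report NaN and never count as significant. The
pairwise-complete policy maximises data use; the per-probe pair count is
reported alongside. All-zero difference vectors report t = 0, p = 1. No
variance moderation is applied — the matched design calls for a plain paired
test, and with ~47 pairs the gain from shrinkage would not justify the
added model assumptions.

Region-wise: the pairing unit is the probe — its cross-sample median in
sperm versus in blood — with one paired *t* per region class and effect =
mean(median_sperm − median_blood). Regions with fewer than 4 probes report
NaN with a warning.

## Covariation and modality

Per-site Pearson correlation across matched pairs; two-sided p from
t = r·√((n−2)/(1−r²)) on n − 2 df; zero variance in either tissue gives
r = NaN. The permutation null re-pairs the tissues by a uniform random
shuffle of the sperm sample order (the identity permutation is not
excluded; at n = 47 it contributes < 10⁻⁵⁹ of draws) and pools r across
permutations × probes; the generator is seeded and bit-reproducible. For
independent tissues the pooled Fisher z = atanh(r) should have SD
≈ 1/√(n−3), which the tests verify within 10%.

Two independent modality classifiers are applied to significantly
correlated sites:

1. **2-D clustering.** A generalized-ESD screen on Euclidean distances from
   the coordinate-wise median (up to ⌈0.1·n⌉ outliers, α = 0.05) flags
   candidate outliers. k ∈ {2, 3} clusterings (PAM k-medoids by default;
   k-means switchable) are compared by average silhouette width; the
   winning solution is demoted (3 → 2 → unimodal) while its
   between-to-within cluster sum-of-squares ratio is below 2. This
   variance-ratio demotion replaces a manual cluster-reassignment step with
   a deterministic rule using the same ratio-< 2 trigger, since
   reproducibility requires removing the human step. A multimodal call is
   *outlier-driven* when its smallest cluster holds ≤ max(1, 0.05·n)
   points; unimodal calls are never outlier-driven (there is no structure
   to drive), though the ESD indices are reported.
2. **1-D gap hunting** per tissue: sort the values and open a group at
   every gap > 0.05 between consecutive sorted values; ≥ 3 groups are
   reported as trimodal with the count retained; the same smallest-group
   rule sets the outlier flag.

Nearest-SNP annotation takes per-probe offsets (bp from the interrogated
CpG, within the 50 bp probe footprint) and reports min |offset| plus a
category: `cpg_site` when the SNP hits the interrogated dinucleotide
(offsets 0/1 for Type II, exactly 0 for Type I), `single_base_extension`
for offset −1 on Type I probes, `probe_body` otherwise, `none` with
distance ∞ for SNP-free probes. The Type II dinucleotide rule subsumes its
extension base; the Type I conventions are documented package choices.
Genetic enrichments (CorSIV- or mQTL-style flags) are Fisher tests of
correlated sites against the non-correlated variable background, first
restricting both sets to the probes on which the flag is defined (needed
for 450K-derived annotations).

## EWAS models

All designs are intercept-first with dummy-coded categoricals (reference
level dropped) and the obesity indicator coded lean = 0, so positive
effects mean higher methylation in the obese group. Rank-deficient designs
raise an error naming the offending columns. Estimated cell fractions enter
blood models as 5 of the 6 proportions (the largest-mean cell type is
dropped) to avoid the sum constraint's collinearity with the intercept.

* **Single-tissue**: per-probe OLS, effect = predictor coefficient,
  two-sided t p-values. Batch is included as a covariate in the bundled
  pipeline's single-tissue models: the generator plants batch effects by
  default and omitting a known design variable is not defensible, even
  though the replication-style analysis could arguably drop it.
* **Mixed model**: methylation ~ tissue + age + batch + obesity +
  (1 | individual). For the balanced complete-pair design this is fitted in
  closed form by the pair-mean / pair-difference decomposition:
  individual-level coefficients come from OLS of pair means (identical to
  the REML fixed effects), tissue from the differences, and the variance
  components from the two strata (σ² = var(d)/2, τ² = max(s²_mean − σ²/2,
  0)). Wald p-values use Satterthwaite df, which for between-individual
  coefficients in this design are exactly n_individuals − p_between; when
  the τ² estimate hits the zero boundary the fixed effects coincide with
  pooled OLS, as they should. A per-probe `statsmodels` MixedLM fallback
  (`method="mixedlm"`, normal-approximation p, convergence flag) handles
  unbalanced data and serves as an independent cross-check in the tests.
  The Satterthwaite convention was chosen over the normal approximation
  because it is exactly calibrated: at the bundled cohort sizes (40–90
  individuals) normal-approximation p-values reject at 5.3–5.7% instead of
  5%, while the cost is slightly lower tail power at the 9×10⁻⁸ threshold
  (analytically ≈ 0.77 instead of ≈ 0.84 for a 2% shift at 68 lean + 22
  obese, noise SD 0.01, intercept SD 0.01). Calibration was judged the
  non-negotiable property.
* **Interaction scan**: per-probe OLS of blood on sperm × obesity + age +
  batch; the reported effect is the interaction coefficient. The
  leave-one-out diagnostic is the maximal change in the interaction t
  statistic when any single pair is removed, computed by closed-form
  downdates of (X'X)⁻¹ and the RSS — cross-tissue interactions in small
  cohorts are typically driven by one or two outlying individuals, and this
  diagnostic quantifies that directly.
* **Cell composition**: non-negative least squares of each sample on the
  reference profiles over shared probes, followed by Euclidean projection
  onto {x ≥ 0, Σx ≤ 1}; the RMS residual is reported per sample. This is a
  simplification of the full constrained quadratic program of
  reference-based deconvolution; its accuracy contract is the round-trip
  property (Dirichlet mixtures of 6 profiles at noise SD 0.02 recovered
  with MAE < 0.05, typically ≈ 0.001).
* **Prior-study comparison**: two-sided Wilcoxon rank-sum of the prior
  set's p-value ranks against all remaining probes, and Spearman rank
  correlation of effect sizes over the intersection (rank-based to tolerate
  study-specific scale biases).

## Epigenetic clocks

A clock is intercept + Σ coefficient·beta with an output transform. The
log-linear-age transform maps s < 0 to (1+A)·eˢ − 1 and s ≥ 0 to
(1+A)·s + A (A = `adult_age`, default 20); it is continuous and strictly
increasing with both branches meeting at A. Published coefficient sets are
consumed as CSVs (header block + probe/coefficient rows), never bundled —
they are external models; all bundled testing uses synthetic clocks.
Missing cells are imputed by the probe's cohort mean; probes absent from
the matrix entirely are imputed at beta 0.5 with a warning, and fewer than
80% of clock probes present is an error. Age acceleration is the OLS
residual of DNAm age on chronological age (plus optional covariates such as
estimated cell fractions for blood; sperm accelerations adjust for
chronological age only, since blood cell composition has no meaning there).
Acceleration–trait associations are one simple OLS per trait, emitted as a
(clock × tissue) × trait grid; constant traits give NaN and an all-zero
acceleration vector reports slope 0, p = 1.

## The synthetic-data generator

`synth.generate_cohort` emulates the structures that matched two-tissue
array studies must handle. Design choices, with defaults:

* **Baselines**: per-probe baseline betas drawn from a low/mid/high mixture
  whose weights depend on CpG region and tissue — islands mostly
  unmethylated (more strongly so in sperm), open sea mostly methylated
  (more strongly in sperm) — producing the polarised sperm profile (more
  median mass < 0.2 and > 0.8 than blood) and hypomethylated islands /
  hypermethylated open sea in sperm relative to blood. 36% of null probes
  share one baseline across tissues so that a realistic minority of sites
  is non-differential. `polarised=False` collapses sperm baselines onto
  blood's, giving a no-tissue-difference null cohort.
* **Noise**: additive Gaussian on the proportion scale (default SD 0.02),
  clipped to [0, 1] — chosen over a logit-normal model so planted effects
  stay interpretable as "% DNA methylation". Within-tissue technical
  variance is not calibrated to any particular study; it is a free
  parameter.
* **SNP-driven classes**: one Hardy–Weinberg genotype per individual
  (default MAF 0.3) shared by both tissues; trimodal sites place the three
  dosages at betas 0.08/0.50/0.92, bimodal sites at 0.15/0.85/0.85, and the
  negative-correlation class applies the dosage effect with opposite sign
  in the two tissues — the simplest mechanism producing significant
  negative cross-tissue correlations.
* **Outlier-driven class**: a low baseline with one randomly chosen
  individual displaced by +0.5 in both tissues.
* **Imprinted class**: beta 0.5 in blood, 0.02 in sperm — the idealised
  somatic hemi-methylation / gametic erasure pattern.
* **Obesity class**: +0.02 beta in the obese group (the last `n_obese`
  individuals), in both tissues, so the cross-tissue mixed model is the
  best-powered detector.
* **Batch effects**: a per-(probe, batch) offset (SD 0.005) applied
  identically to both tissues of an individual — absorbed by a batch
  covariate, invisible to paired tests, and small enough not to distort the
  permutation null.
* **Individual random intercepts** (`individual_sd`, default 0): a shared
  per-individual offset across both tissues. Off by default because the
  emulated biology has essentially no cross-tissue covariation at
  non-genetic sites; parameter-recovery simulations for the mixed model
  switch it on (0.01).
* **QC failures**: 0.5% of probe × sample cells get a failed detection p
  (> 0.05) and, independently, a bead count < 3, so the QC filters have
  work to do. Phenotypes (age, BMI, waist, HOMA-IR, fasting insulin) and
  Dirichlet cell fractions are drawn per individual; cell-mixture structure
  in betas lives in `generate_reference_profiles` (marker-block profiles,
  Dirichlet mixing), which keeps the null-calibration contracts of the
  cohort matrices clean.

Everything is driven by one `numpy` Generator seeded from `SimConfig.seed`;
identical configurations are bit-reproducible.

**What passing tests do and do not show.** The generator's planted classes
are idealised: genotype levels are exact, imprinting is perfectly clean,
and noise is homoscedastic. Passing the recovery tests therefore
demonstrates correctness of the algorithms under their stated assumptions —
not that real arrays, with probe-specific variance, cellular heterogeneity
and intensity-level artefacts, would yield the same recovery rates. In
particular the synthetic PC1 tissue separation (~94% of variance) and the
near-perfect deconvolution and clock round trips are upper bounds set by
the clean simulation, and the fraction of correlated sites among variable
probes depends directly on the configured class fractions.

## Problem sizes and desk-scale choices

The bundled test suite and `scripts/acceptance.py` run at desk scale, chosen
to make Monte-Carlo bands tight while keeping the whole suite fast on a
single CPU: 50,000-probe cohorts with 47 pairs for calibration and the
discovery-style pipeline, 20,000 probes for the null and obesity stages, a
90-man obesity cohort (68 lean / 22 obese) matching the study-scale sample
split, 25–30 permutations × 400–500 probes (≥ 10⁴ pooled draws) for the
permutation null, and 250–400 simulated probes for per-class recovery
rates (3-SD binomial bands).

## Known limitations

* No intensity-level processing: idat parsing, dye-bias and background
  correction are out of scope; inputs are beta matrices.
* The closed-form mixed model requires complete balanced pairs with
  individual-level covariates; anything else falls back to the slower
  per-probe MixedLM path with normal-approximation p-values.
* Genome-build liftover is not provided; annotation and interval inputs
  must share a build.
* The generator does not simulate probe hybridisation chemistry,
  cross-reactive probes, or within-tissue cell-composition gradients at
  non-marker probes.
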