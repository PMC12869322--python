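# Methods

This note documents the statistical models implemented in `fcselect`, the
choices made where the design was genuinely open, what the synthetic
generators do and do not emulate, and the package's known limitations.

## FC construction (`fc_core`)

An ROI run is a frames × regions matrix with a repetition time (TR) and a
per-frame framewise-displacement (FD) series. The processing chain is

1. **Nuisance regression** — ordinary least squares of every region on the
   supplied regressor matrix plus an intercept (e.g. 6 motion parameters,
   global signal, aCompCor components, 12 columns in the reference
   configuration); residuals are exactly orthogonal to the regressor span.
   Rank-deficient designs are solved in the least-norm sense with a
   warning rather than rejected.
2. **Band-pass** — first-order Butterworth, 0.01–0.08 Hz, applied
   forward-backward (`filtfilt`) so filtering is zero-phase and
   shift-invariant. Phase handling is unspecified in common descriptions
   of the procedure; zero-phase is chosen because scrubbing after a
   phase-shifting filter would misalign frames and FD values.
3. **Scrubbing** — frames with FD strictly greater than 0.5 mm are
   removed (strict inequality, matching the rule "FD > 0.5 mm"). An
   all-censored run raises an explicit empty-run error.
4. **Run exclusion** — either the mean + 3 SD rule on censored fractions
   across runs (sample SD, ddof = 1) or a minimum retained duration
   (default 4 minutes).
5. **Correlation** — Fisher z = atanh(r) of the Pearson correlation of
   every region pair on the retained frames. A correlation within 1e−12
   of ±1 is an error naming the pair (infinite z signals degenerate
   input); callers may opt into clipping at ±(1 − 1e−7) with
   `tolerant=True`, but silent clipping is deliberately not the default.

The processing order (regression → filter → scrub → correlate) keeps the
filter operating on a complete, evenly sampled series; correlations use
retained frames only.

**Vectorization convention.** Region labels are 1-based in I/O; features
are ordered column-major over the strict lower triangle:
(2,1), (3,1), …, (R,1), (3,2), …. The bijection `pair_index` /
`inverse_pair_index` is exact and round-trip tested; R = 379 gives the
reference 71,631 features. The order must be fixed bit-exactly for
cross-run comparability, and nothing in the field fixes one convention,
so this package's choice is normative for its own files.

## ComBat harmonization (`harmonize`)

Per feature f and site b, the location/scale model
y = α_f + X β_f + γ_bf + δ_bf ε is fitted exactly as in the standard
parametric empirical-Bayes ComBat: least-squares estimation of site and
covariate effects on the full design, standardization by the pooled
residual variance (computed with 1/N, matching the reference
implementation), per-site means/variances on the standardized scale,
normal/inverse-gamma moment-matched priors across features, and the
iterative posterior solution for γ*, δ*. Only the site terms are removed
at apply time; covariate effects (diagnosis, age, sex) are estimated
jointly and restored, so biological variance is preserved. The
implementation agrees with Bioconductor `sva::ComBat` to ~1e−6 on shared
inputs (a regression test keeps it that way), and with `eb=False` it
reduces exactly to per-site standardization around the covariate-adjusted
grand mean.

*Repeated harmonization.* Re-fitting and re-applying ComBat to already
harmonized data is idempotent only up to a deterministic factor: the
reference convention mixes a 1/N pooled variance with ddof-1 per-site
variances, so each pass rescales residual deviations by
√((N−S)/N) (S sites). The tests assert convergence at that tolerance
rather than machine precision; matching the reference implementation was
judged more valuable than exact idempotence.

*Traveling-subject bias.* When the same participants are scanned at many
sites, the per-site measurement bias of each FC is estimated directly by
least squares under the additive two-way model
value = μ + participant + site + residual, with the site effects
re-centred to a run-count-weighted zero mean, and subtracted from
clinical data. This additive decomposition is a deliberate
simplification of full traveling-subject GLM harmonization (which also
models sampling bias and disorder terms); it is exact for the additive
generative model used here and is flagged as an approximation in the
API documentation. Estimation requires a connected participant-site
incidence graph, otherwise biases are not comparable across components.

## PCA-based selection (`pca_select`)

PCA is computed by SVD of the centred data matrix; features are not
standardized because all FCs share the Fisher-z scale. At most n−1
components are kept. Component signs are fixed by making each
component's largest-|weight| entry positive — results cannot depend on
sign because over/under-connectivity labels come from group means, not
weight signs.

Screening tests per factor type: pooled-variance two-sample t for binary
factors (Welch by flag; the pooled form is the classical default),
Pearson r with pairwise deletion of missing values for continuous
factors, one-way ANOVA for sites. BH-FDR correction is applied across
components *within* each factor; for weight-based selection it is
applied across all m features. Weight standardization uses the sample
SD of the weights (not the theoretical 1/√m scale of an orthonormal
vector); with heavy-tailed true loadings the sample SD is inflated by
the signal itself, which makes the selection slightly conservative —
accepted and documented rather than corrected.

Ties in explained variance among significant components are broken
toward the lower component index with a warning (measure-zero event).
The "aggressive" variant thresholds |z| at a configurable percentile
instead of the BH criterion, since no principled relaxed threshold is
available.

Null behaviour: on pure-noise data the component screen controls the
family-level false-positive rate through BH across components, so the
pipeline returns a null result (no component, no features) in ≳ 95% of
runs at q = 0.05; this is verified on 200 replicate cohorts.

## Baselines and the ensemble classifier (`baselines`)

The univariate baseline tests every FC with a two-sample t-test and
keeps the significant set under BH-FDR, Bonferroni, or no correction.
The LASSO baseline draws repeated balanced subsamples (equal patient and
control counts, undersampling the majority class), fits an L1-penalized
logistic regression per subsample with the penalty chosen by internal
cross-validation over a small grid, and selects the features whose
coefficients are non-zero in at least a threshold number of subsamples.
Defaults are 100 subsamples, fraction 0.8 of the minority class, 10-fold
CV, threshold one half — the published descriptions of such pipelines do
not fix these knobs, so they are explicit, configurable assumptions.

The diagnostic marker is an ensemble of such members whose probabilities
are averaged. When an inner feature-selection hook is supplied (PCA
selection or t-tests), it runs *inside* each member's training subsample,
so held-out rows never influence feature choice or fit — the no-leakage
contract. A sentinel test enforces it: overwriting one validation-set
feature with the test labels must not raise the validation AUC. A member
whose selector returns no features falls back to all features and logs.
Metrics follow the standard definitions (rank-statistic AUC, confusion
matrix at the 0.5 probability threshold, closed-form MCC; degenerate MCC
denominators return 0).

## Effect sizes and variance decomposition (`evaluate`)

Hedge's g is the patient-minus-control standardized mean difference with
the small-sample factor J = 1 − 3/(4N − 9); Cohen's d is available by
flag. Method summaries average |g| over the selected features because
selections mix over- and under-connectivity (signed summaries by flag).
Cross-dataset consistency is the plain Pearson correlation of the two
per-feature g vectors.

Traveling-subject variance decomposition fits, per FC, the additive
model value = μ + participant + scanner + protocol + residual by least
squares with sum-to-zero constraints. A factor's variability is the
sample SD of its fitted level effects; the session factor is the
run-level residual SD. This "SD of level effects" definition is an
explicit approximation to full variance-component estimation: level
estimates absorb part of the residual noise, so a factor with few levels
or few runs per level is biased upward by its estimation error in
quadrature (≈ +10% for 75 participants × 6 runs at the default noise
levels), and a true-zero factor reports its noise floor rather than
exactly 0. Estimates are averaged across FC features when a scalar
summary is needed, which suppresses the sampling error of SDs over as
few as 3–6 levels.

## Synthetic generators (`synthgen`)

**Clinical cohorts** are generated directly on the Fisher-z scale — no
time-series simulation — under a sparse latent-factor model: a disorder
factor (group mean shift `disorder_effect`, within-subject SD
`latent_sd`) loads on `n_disorder_fcs` features with unit or lognormal
loading magnitudes; sites contribute additive offsets and multiplicative
scales per (site, feature), exactly the ComBat model, so harmonization
is testable; age and sex load on dense random directions; the rest is
i.i.d. Gaussian noise. With `latent_sd=0` (the default) the per-feature
population Hedge's g equals `disorder_effect`, which calibrates every
effect-size oracle in the tests. Paired discovery/validation cohorts
share the planted indices and loadings but draw independent subjects and
site realizations.

**The confounded benchmark** (`ClinicalSimConfig.confounded_benchmark`)
defines the conditions for the robustness comparison between selectors.
Its design encodes, one mechanism each, the three reasons supervised
selectors overfit multi-site data:

* the disorder factor is *noisy* (`latent_sd=1`, effect 0.7, per-FC
  g ≈ 0.5), so the planted features share within-group variability and
  no classifier can separate the groups perfectly by combining them —
  the regime in which confound proxies genuinely add discovery-set
  accuracy;
* a small block of 8 *distractor* features carries a site offset (1.2)
  that, through diagnosis-biased site assignment (confound strength
  0.8), produces an apparent discovery g ≈ 0.87 — larger than any true
  feature — with no counterpart in a validation cohort with unbiased
  assignment;
* a broad block of 400 *weak* features (apparent g ≈ 0.25, on
  low-variance features) carried by a second confounded covariate
  inflates the liberal FDR selection without surviving Bonferroni or
  attracting L1 members.

Loadings are lognormal (sd 0.5) so a few true features are individually
strong enough for the LASSO to select them stably — heterogeneous
loading magnitudes are also the realistic case. The comparison runs the
subsampled LASSO at desk scale (10 subsamples, fraction 0.6, 7-of-10
stability threshold, 4-fold CV; `BENCHMARK_LASSO_PARAMS`). Because
single-pair orderings fluctuate — the LASSO-vs-PCA discovery lead and
the Bonferroni-vs-LASSO validation gap each flip on roughly one seed in
five — the characteristic ordering (validation mean |g|:
PCA > Bonferroni > LASSO ≥ FDR; discovery mean |g|: LASSO first; PCA
selections far more stable across the pair than LASSO's) is asserted on
means over five replicate pairs.

**Traveling-subject data** follow the additive model
value = μ + participant + scanner + protocol + session (+ optional
extra noise), with scanners and protocols assigned per site and a
hub-and-spoke visiting scheme (each participant visits one of three hub
sites plus random spokes; full crossing available by flag). Defaults —
75 participants, 3 sites each, 2 runs per visit, factor SDs
0.17 / 0.06 / 0.19 / 0.05 — reproduce the magnitudes reported for
repeat-measurement FC variability at that design size. `sd_noise`
defaults to 0 because the session term already is the run-level
residual.

**What the generators do not emulate:** BOLD autocorrelation and
spectral structure (except in the deliberately small `gen_roi_timeseries`
helper), realistic FC covariance between features beyond the planted
low-rank structure, head-motion artifacts correlated with diagnosis,
atlas geometry, and non-Gaussian site effects. Passing tests therefore
demonstrate the *statistical machinery* — calibration, null control,
recovery, ordering under the modelled confounds — not performance on
real connectomes.

## Problem sizes and numerical choices

Test and reference workflows run at 1,000 features and 400 subjects
(null control: 200 replicates at 200 subjects; variance decomposition:
450 runs × 100 features), sizes at which every planted property is
measurable with comfortable Monte-Carlo margins on a single CPU in
about two minutes. The full 71,631-feature scale is supported but not
exercised by default. Tolerances: orthonormality and oracle equivalence
at 1e−8; ComBat site-mean equalization at 1e−6 (shrinkage-free run);
EB convergence at relative 1e−4 (the reference implementation's
criterion); |r| = 1 detection at 1e−12.

## Known limitations

* PCA maximizes variance, not biological relevance; the diagnosis
  component's explained variance is necessarily small in a
  high-dimensional FC space, and the method inherits PCA's blindness to
  whether variance is biological or confound-driven. The component
  *screen* against site/motion/demographics mitigates but does not
  remove this.
* The traveling-subject harmonization and the variance decomposition
  both use additive fixed-effect approximations, not the full GLM /
  variance-component machinery of dedicated tools.
* The ensemble-LASSO subsampling scheme is one published-style
  configuration among many; its defaults are assumptions, not a
  reproduction of any specific supplement.
* Selection stability conclusions from the benchmark depend on the
  planted confound mechanisms; other confound structures (e.g.
  motion-diagnosis coupling) are not modelled.
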