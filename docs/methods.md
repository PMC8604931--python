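# Methods

`psiscreen` implements the chemometric workflow used to screen small
case-control cohorts measured by ambient mass spectrometry (e.g. paper-spray
ionization of blood plasma): a sample × m/z intensity matrix is
baseline-corrected and normalized, split once into training and test sets by
the Kennard-Stone algorithm, reduced by PCA scores or by SPA/GA variable
selection, and classified by LDA, QDA or a polynomial-kernel SVM.  Because
studies of this kind rarely deposit raw spectra, the package ships a
synthetic cohort generator with known ground truth; every pipeline stage is
validated against it and against brute-force oracles.

## Data model

The central object is the `SpectraMatrix`: rows are individual spectra,
columns an ordered m/z grid, plus a replicate map (spectrum → subject) and a
subject-level class map (`control` / `case`).  Raw centroided peak lists are
placed on a common grid by summing intensities into half-open bins
`[mz_min + k·w, mz_min + (k+1)·w)`; the lower edge is inclusive so no peak
is counted twice, and peaks at or beyond the upper boundary are dropped and
counted in the log.  On the default unit-width grid starting at an integer
(50–1000 Th, 950 variables, matching the ">900 variables" scale of
unit-resolution ion-trap data) columns are labelled by their integer lower
edge, so a peak at 118.3 Th contributes to variable "118".  Missing cells in
a CSV matrix are an error, never a silent zero: zero-filling would distort
the subsequent normalization.

## Preprocessing

Baseline correction is automatic weighted least squares (AWLS): fit a
polynomial of order `baseline_order` (default 2) by weighted least squares,
then down-weight points above the fit with `w = exp(-(y-b)/s)` where `s` is
the standard deviation of the negative residuals, keep full weight at or
below the fit, and iterate until the baseline changes by less than
`baseline_tol` (default 1e-6, relative) or `baseline_max_iter` (default 100)
is reached.  The exponential asymmetric weighting is the standard "automatic"
behaviour of this family of estimators; the exact weighting scheme of
commercial implementations is unpublished, so the match is qualitative, not
bit-exact, and all parameters are exposed in the config.  Corrected
intensities are *not* clipped at zero — clipping would bias the vector
normalization that follows — and this is documented so users can clip
explicitly when they need non-negative spectra.  A spectrum that is pure
baseline corrects to numerical noise and is rejected as degenerate rather
than normalized into garbage.

Vector normalization scales each corrected spectrum to unit Euclidean norm.
The order is fixed: baseline first, normalization second.

The polynomial fit is exact (zero residual) whenever the input is itself a
polynomial of degree ≤ `baseline_order`; on drift-plus-peaks synthetic
spectra the recovered baseline deviates from the generating drift by less
than 2% of the drift range at peak-free points (the acceptance suite checks
this).  The estimator carries a small negative bias of order the noise SD —
points above the fit are down-weighted asymmetrically — so the 2% bound
presumes drift ranges comfortably above the noise floor, which is the regime
baseline correction is for.

## Sample selection

Kennard-Stone is the deterministic maximin rule: start with the two most
distant points (Euclidean), then repeatedly add the point maximizing the
minimum distance to the selected set; ties break toward the lowest row
index.  The train/test split runs Kennard-Stone *per class* so both classes
appear on both sides, and *at subject level* on replicate-averaged rows:
all replicates of one subject inherit its assignment, because replicates of
the same subject straddling the split would leak identity and inflate test
accuracy.  A `level="spectrum"` option mimics the laxer per-spectrum
reading.  The per-class training count is `round_half_up(fraction · n)`;
with 10 subjects per class and fraction 0.7 this gives 7 training + 3 test
subjects per class (21 + 9 spectra a side with triplicates).

## PCA

PCA is a mean-centered SVD (scikit-learn's exact solver behind the module
surface); component k explains `σ_k²/Σσ_j² × 100` percent of the total
variance.  Loading signs follow a fixed convention — the largest-magnitude
element of each loading is positive — so plots and regression tests are
stable.  Whenever PCA feeds a classifier it is fitted on training rows only
and test rows are projected; the exploratory all-data score plot is a
separate, clearly-labelled use.  Score-plot confidence ellipses scale the
2×2 score covariance eigendecomposition by the chi-square(2) quantile
(5.991 at 95%), the common convention for bivariate score clouds; a
Hotelling-T² scaling would differ at these small n but the chi-square form
is what score-plot ellipses conventionally show, and the choice is
documented here rather than configurable.  The difference-between-means
(DBM) profile is `mean(case) − mean(control)` on preprocessed intensities.

## Variable selection

Candidate subsets are scored on a validation partition disjoint from the
rows used to fit the discriminant: the training side is carved 70/30 by the
same subject-level Kennard-Stone into fit and validation rows, leaving the
test set untouched until final evaluation.  For LDA/QDA couplings the cost
is the Mahalanobis risk ratio

    G = (1/n_val) Σ_n  d²(x_n, μ_own) / min_{m≠own} d²(x_n, μ_m)

under the pooled covariance of the fit rows — zero when every validation
point sits on its own class mean, one when a point is equidistant between
classes.  A singular pooled covariance rejects the candidate (cost +∞).
For SVM couplings the cost is the validation error rate, since G presumes
class-mean/covariance structure an SVM does not use; as a consequence
LDA- and QDA-coupled selection coincide and the grid computes it once.

**SPA** grows a deterministic chain from every start column: at each step
append the column with the largest norm after projection onto the orthogonal
complement of the span of the chosen columns (exactly collinear columns are
never selected; ties go to the lowest m/z).  Every chain prefix up to
`spa_max_vars` (default 5) is scored and the global minimizer returned, ties
broken toward fewer variables then lexicographic m/z.

**GA** evolves binary chromosomes (bit = variable included) with binary
tournament selection, one-point crossover (probability 0.6), per-bit
mutation, elitism of one, and a fitness of `−(cost + 0.1 · max(0, k − 15))`
penalizing subsets beyond 15 active variables.  Chromosomes are initialized
sparse (~8 active bits) so early covariances stay invertible; an all-zero
chromosome is reseeded with one active bit.  The default per-bit mutation
rate is 0.005: on a 950-bit chromosome that is ~5 expected flips, inside the
1/L–5/L range GA practice recommends, whereas rates an order of magnitude
higher flip so many bits per child that the search degenerates into a random
walk unable to refine sparse solutions.  The GA is stochastic, so it runs
three independent seeded executions by default; all three subsets are
reported (and their union), the best-cost run feeding the classifier.

Selection in a 950-variable space with ~14 training subjects overfits the
small validation set easily; the GA in particular can return plausible-cost
noise subsets.  This is a faithful property of the method at this sample
size, visible in the comparison grid as GA rows trailing SPA rows, and is
why the permutation control exists.

## Classifiers

LDA and QDA are Mahalanobis discriminants, predicting the class minimizing

    LDA:  (x−μ_k)ᵀ Σ⁻¹ (x−μ_k) − 2 ln π_k          (pooled Σ)
    QDA:  (x−μ_k)ᵀ Σ_k⁻¹ (x−μ_k) + ln|Σ_k| − 2 ln π_k

with empirical priors by default (equal priors are an option).  Singular
covariances are ridge-regularized with `λ = 1e-8 · trace(Σ)/p`, escalated
tenfold until the Cholesky factorization succeeds; every regularization is
logged, never silent.  A covariance-similarity diagnostic (relative
Frobenius spread of the class covariances) is exposed because QDA's extra
parameters only help when the classes actually differ in variance
structure — when they do not, QDA tends to fit noise and underperform LDA.

The SVM is a soft-margin machine with the polynomial kernel
`(xᵀz + c0)^degree` — degree 2, c0 = 1, C = 1 by default, all configurable;
scikit-learn's libsvm backend is used with its gamma pinned to 1 so the
kernel matches that form exactly.  Models serialize to a documented JSON
schema (means/covariances or support vectors/dual coefficients) and
deserialized copies reproduce predictions exactly.

## Evaluation

Figures of merit are exact integer confusion counts per class —
`sensitivity = 100·TP/(TP+FN)`, `specificity = 100·TN/(TN+FP)`, accuracy
`(TP+TN)/n` — reported at both spectrum level and subject level (majority
vote over a subject's replicates, ties counted as misclassified: the
conservative rule).  Percentages are reported rounded to two decimals
(11/12 → 91.67).  A class absent from the truth yields NaN with a warning,
never a silent zero.

The comparison grid crosses {PCA, SPA, GA} × {LDA, QDA, SVM} into exactly
nine named models sharing one split; a single model's failure is recorded in
its row and the grid continues.

Two confounding checks:

* **Label swap** — refit the entire pipeline (selection included) with the
  two class names exchanged.  Class membership is unchanged, so the split
  and the selected variables are identical, and for a deterministic model
  the per-class figures of merit exchange exactly between the two runs; this
  is asserted as an exact test.
* **Permutation null** — shuffle subject labels (replicates move with their
  subject), re-run the full pipeline per permutation (split, selection,
  fit), and report the null accuracy distribution and the empirical p-value
  `(b+1)/(n_perm+1)`.

## Synthetic cohorts

The generator emulates the target study design: 10 + 10 subjects, triplicate
spectra, 950 unit-resolution bins (50–1000 Th).  Each cohort has ~40 shared
peaks at fixed positions with lognormal subject-level heights (CV 0.25),
two class-discriminative peaks at the canonical recurrent positions m/z 118
and 77 (base height 60, CV 0.3; the full canonical set 65/77/118/173/360/
390/475 is exported for custom designs), a quadratic baseline
(25 − 30t + 15t² on the scaled axis) with 10% per-subject jitter, additive
per-bin Gaussian noise (SD 1), 10% per-replicate multiplicative height
jitter, and a within-subject correlation of 0.7 realized by blending a
subject-shared noise field with fresh replicate noise.  Peaks are placed at
exact grid centers by default so ground-truth variables are unambiguous; an
off-center mode exercises the binning edge cases.  Intensities are floored
at zero after noise (ion counts cannot be negative), which slightly
truncates the noise distribution.

The class effect is calibrated, not nominal: after the no-effect cohort is
realized, the pooled within-class SD of the subject-averaged intensity at
each planted bin is measured and `direction · Δ · SD` added to every case
replicate at that bin.  Adding a constant leaves the within-class SD
unchanged, so the planted standardized mean difference equals the configured
Δ up to sampling noise (verified within 20% over 50 seeds).  The default
Δ = 5 is a strong, cleanly recoverable effect — the regime in which the
reference workflow reports perfect SPA-LDA classification.

What the generator does **not** emulate: isotope envelopes, adduct and
in-source fragment clusters, chemical-noise structure correlated across
bins, m/z calibration drift, batch effects, or any real biological
covariance between metabolites.  Passing tests therefore demonstrate that
the algorithms recover the signals they are designed for under the stated
noise model — not that any particular clinical classification is valid.

## Problem sizes and numerical choices

Simulation-based checks use 50 seed-swept cohorts for the SPA-LDA recovery
and null-control studies (full 950-bin design), with reduced GA settings
(population 20, 30 generations) in the null grid; module-level stochastic
checks use reduced grids (120–200 bins) and ~10 cohorts, sizes chosen to
exercise the same code paths at sub-minute cost.  `scripts/acceptance.py`
re-runs the headline studies at 20 strong and 10 null cohorts.  Convergence
and degeneracy handling: AWLS stops on a 1e-6 relative baseline change;
risk-cost candidates with singular covariance are rejected with +∞; LDA/QDA
ridge policy as above; Kennard-Stone and SPA ties break toward the lowest
index/m/z so every result is reproducible bit-for-bit.

## Annotation

Selected variables can be matched against a local compound table
(name, monoisotopic mass, class): the expected adduct m/z is
`mass + 1.007276` (M+H) or `mass − 1.007276` (M−H) and hits are all
compounds within an absolute tolerance (default ±0.01 Th).  Matching
unit-resolution integer queries against a ±0.01 tolerance is an
inconsistency of precisions — the report warns rather than resolves it, and
likewise leaves to the user the choice of searching positive-mode adducts
for negative-mode acquisitions.  A tiny bundled demo table (literature
monoisotopic masses, including two LysoPC species) exists for documentation
examples only; no live database queries are made.

## Known limitations

* With 20 subjects, test-set figures of merit are quantized in steps of
  1/9 spectra (1/3 subjects) per class; "100%" is a weak statement and the
  permutation control is the honest significance check.  The permutation
  p-value itself is bounded below by 0.01 at 99 permutations and, at this
  cohort size, permutations that overlap the true labeling in 8+ of 10
  subjects retain most of a strong planted signal — so even a perfectly
  classified cohort can show p ≈ 0.03–0.07.
* SPA chains rarely contain more than one planted variable (shared peaks
  dominate projection norms), so the final discriminant often works on a
  single selected bin with ~Δ/2 SD margins per class; with lognormal
  subject-level heights the skewed control tail then crosses the LDA
  midpoint boundary in a minority of cohorts, capping the rate of perfectly
  classified cohorts below what Gaussian intuition suggests.  The acceptance
  script measures this rate (`spa_lda_perfect_classification_pct`).
* The AWLS weighting matches the published behaviour of the estimator
  family, not any specific commercial implementation bit-for-bit.
* GA selection results depend on seeds; three runs are reported rather than
  pretending determinism.
* Subject-level counting uses majority vote with ties-as-errors; other
  conventions can be reconstructed from the exported confusion counts.
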