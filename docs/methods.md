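# Methods

This note documents the models, numerical conventions and design choices
behind soletrace, and what the synthetic-data generator does and does not
emulate.

## Elliptical Fourier analysis

Outlines are closed simple polygons stored counterclockwise. Coefficients
are the classical chain-integral elliptical Fourier descriptors of the
arc-length–parameterized polygon, computed in closed form per segment (no
quadrature error); the DC terms (a0, c0) are retained for reconstruction.
One consequence of arc-length parameterization worth knowing: a polygonal
*ellipse* is not exactly a single harmonic (the angle-uniform vertices are
not arc-length-uniform), so tests against "pure ellipse" expectations use a
~1% tolerance; the circle is exact.

Normalization follows the standard first-harmonic procedure: a start-point
phase rotation puts the trace origin on the semi-major axis of the
first-harmonic ellipse, a frame rotation aligns that axis with x, and all
coefficients are divided by the semi-major length, leaving a_1 = 1,
b_1 = c_1 = 0. Two conventions make the result deterministic:

* the phase solution is forced to the semi-major (not semi-minor) axis by
  comparing the two candidate axis lengths;
* the residual joint ambiguity (start point shifted half a period plus a
  180° frame rotation), which flips the sign of every even harmonic, is
  resolved by requiring the first even-harmonic coefficient with magnitude
  above 1e-7 to be positive.

Left-side otoliths are mirrored about the vertical axis before
normalization, so both sides share one frame and side enters downstream
models only as a covariate. Normalization is undefined when the first
harmonic is (near-)circular — the orientation and start angle then carry no
information; sole-like outlines (axis ratio ≥ ~1.1) are far from this
degeneracy.

Cumulative Fourier power is reported as a *ratio* to the total power at
K_max = 99. The power criterion is stated in the field as an absolute sum
equal to a percentage; only the ratio reading yields a percentage, so that
is what is implemented. Harmonic 1 is included in the sum (it dominates the
total, which makes the ratio conservative: the higher-harmonic tail must be
genuinely small before the threshold is met). The descriptor matrix for PCA
uses harmonics 2..n only (harmonic 1 is fixed by normalization up to the
aspect ratio d_1); PCA is centered but not variance-scaled, since all
coefficients share the same (dimensionless) units.

Otolith length L0 is the maximum Feret diameter (ties broken by smallest
angle to the x-axis) and width l0 the maximal extent perpendicular to the L0
direction. For real otoliths these are anatomical (antero-posterior /
ventro-dorsal) axes; for synthetic outlines the Feret convention is the
operational stand-in. The five shape indices follow their closed-form
definitions; circularity × form coefficient = 4π identically, which the
tests assert on every generated otolith. The redundancy screen drops an
index only when it correlates (|r| > 0.8) with *two or more* others — a
single strongly correlated pair is kept intact.

## Shape statistics

The redundancy analysis is multivariate least squares of the centered shape
matrix on the coded design (factors dummy-coded, numeric covariates as-is),
partitioning total inertia into constrained and residual parts. Term tests
are *marginal* (each term against the model containing all others), with
pseudo-F = (SS_term/df_term)/(SS_res/df_res). Null distributions come from
Freedman–Lane permutation: residuals of the reduced model are permuted and
added back to its fitted values, and p = (1 + #{F* ≥ F}) / (1 + n_perm),
default n_perm = 999. Marginal tests with reduced-model residual
permutation were chosen as the most conservative option for unbalanced
designs; whether term tests are sequential or marginal is a genuinely open
choice in this kind of analysis and is therefore configurable by refitting
with a different term set.

Per-index linear models use sum-to-zero contrasts; Type III (partial) F
statistics are only valid under that coding, and `anova_type3` refuses
treatment-coded fits. Tukey HSD uses the fitted model's residual mean square
and degrees of freedom, raw level means, and the harmonic mean of level
sizes for unbalanced data (the agricolae-style convention); grouping letters
are the compact letter display. Both otoliths of a fish enter the models as
rows with Side as a fixed covariate; no fish-level random effect is fitted.

`residualize` computes column-wise OLS residuals on Length + Sex + Side
(never Subunit), optionally fitting the confound model on a training subset
only and applying it to all rows — the leakage-safe mode used inside
cross-validation folds.

## Population genetics

Weir–Cockerham variance components (a, b, c) are computed per locus from
subpopulation sample sizes, allele frequencies and observed heterozygote
proportions, with missing genotypes excluded locus-wise; the multilocus θ
is the ratio of sums Σa / Σ(a+b+c), never the mean of per-locus ratios.
Monomorphic or insufficiently observed loci contribute zeros to both sums.
Pairwise values recompute the components on each subunit pair. Negative
estimates are reported as computed. Confidence intervals are percentile
bootstrap over loci (default 1000 replicates), for the global value and each
pair, with significance flagged when the CI excludes zero; bootstrapping
over loci (rather than individuals) matches the CI-per-pair output format
this estimator is usually reported with.

The HWE exact test enumerates heterozygote configurations conditional on
allele counts (log-space for stability). QC thresholds (MAF, missingness,
HWE α) are deliberately configurable stand-ins for a full SNP-calling
filter cascade, which is out of scope.

DAPC mean-imputes missing genotypes per locus (imputation is used for
PCA/LDA only, never for θ), centers, reduces by PCA and fits LDA on the
retained scores. The retained-PC count is chosen by stratified 90/10
holdout cross-validation over a grid of multiples of 5 up to max_pc
(default 30), refined around the arg-max; the selection metric is highest
mean correct assignment, with the RMSE of the per-split rates reported
alongside.

## Assignment framework

Standard stratified K-fold cross-validation (default K = 3): K−1 folds
train, one tests, rotating, so each individual is predicted exactly once
per pass. All preprocessing — PCA to 95% cumulative variance (capped at
n_train − #classes) for genotypes, confound residualization for otolith
indices, centering — is fitted on training rows only. The classifier is
pooled-covariance Gaussian LDA with priors proportional to training counts
(configurable to uniform); proportional priors reproduce the documented
attraction of predictions toward the largest subunit under unbalanced
sampling. Posterior argmax ties are broken by the fixed class order (order
of first appearance, i.e. SW, NE, UK for the study design) and counted in
the output. The assignment matrix averages per-test assignment fractions
over folds × repetitions (default 30 repeated passes populate the sd);
residualization is fold-internal because global residualization would leak
subunit-correlated confound structure into the training data.

The otolith feature set for assignment is the five shape indices
(residualized), since in weakly structured data the scalar indices carry
the spatial signal while the Fourier PCs do not; Fourier-PC features can be
passed explicitly to `run_assignment` instead.

## Synthetic-data generator

Genotypes follow the Balding–Nichols island model. Its F parameter equals
the expected F_ST, which makes parameter recovery a clean acceptance
surface: simulated at F ∈ {0, 0.0045, 0.02, 0.05} with the default design
(47/31/42 individuals, 2902 loci), mean θ̂ tracks F within Monte-Carlo
tolerance. The default fst_target (0.0045) and sampling design are the
study conditions being emulated. The generator draws ancestral frequencies
uniformly on maf_range = (0.05, 0.5); there is no linkage, selection or
missingness structure beyond an optional uniform missing rate.

Otolith outlines are synthesized directly in elliptical-Fourier space (no
images): harmonic 1 is an ellipse with axis ratio 1.35 ± 3% CV (a realistic
sole-like elongation), harmonics 2–6 carry fixed bumps for the
characteristic outline asymmetry, and harmonics 7–10 / 13–16 form two
perimeter-roughness bands. Covariates act through two channels:

* **elongation** (axis ratio): sex and any `ellipticity` shape effect —
  moves ellipticity and roundness;
* **roughness frequency mix** w ∈ [0,1]: subunit (`circularity` effect),
  side and year shift wobble energy from the low to the high band at
  constant radial amplitude. Perimeter grows with the square of the wobble
  frequency while extents and area stay put, so circularity and the form
  coefficient respond while rectangularity, ellipticity and roundness do
  not. The high band is de-rated by 0.85 to equalize the expected Feret
  extents between bands (higher-frequency wobble has more peaks and would
  otherwise inflate the max-extent statistics slightly).

Otolith size is pinned to the allometric target L0 = l0_intercept +
allometry_slope × length (defaults 2.5 mm + 0.05 mm/cm, ~1% residual CV), so
an OLS regression of L0 on fish length recovers the slope. Left otoliths
are exact mirrors of the right when side_effect = 0 and otherwise get the
side shift on the roughness mix. The default effect sizes (SW +0.15,
UK +0.075 on the mix; side 0.05; year 0.03/step; mix jitter sd 0.08) were
chosen once so that, at roughly 300 fish, Type III ANOVA detects the
subunit difference in circularity and form coefficient but not in
rectangularity, and Tukey HSD separates SW from NE — the qualitative
pattern the analysis is designed to detect. No published effect sizes exist
for these shape differences, so the defaults are a modelling choice, not an
inference about any real stock.

What passing tests on this generator do **not** show: robustness to
digitization noise and image-processing artifacts, anatomical axis
conventions, LD between loci, genotyping error, or fish-level dependence
between the two otoliths beyond the shared shape draw.

## Numerical choices and problem sizes

Tolerances: normalization invariance is asserted to 1e-6; oracle
equivalences (LDA posteriors vs explicit Gaussian Bayes, PCA vs dense
eigendecomposition, Type III vs full-vs-reduced RSS) to 1e-8–1e-10;
round-trip reconstruction error is measured as mean distance from the
reconstructed points to the original curve (pointwise comparison would
conflate a tangential reparameterization with shape error) and asserted
below 0.1% of L0.

The test suite scales simulations to what the checks need: 20 seeds for
F_ST recovery, 200 replicates for bootstrap-CI coverage and for
permutation-p uniformity (n_perm = 199 there; the 1/200 granularity is
negligible against the KS critical value), 50 replicates at 300 fish for
the ANOVA pattern, and 10 seeds per F level for assignment monotonicity.
The acceptance script uses one 512-point contour, 500 otoliths and 200
otoliths for its three quantities.

## Known limitations

* Plain RDA (no partialling-out of covariates); a partial RDA would change
  the term tests under strong confounding.
* Tukey HSD uses raw level means with the model MSE, not covariate-adjusted
  means; with strong covariate imbalance between subunits the two differ.
* The bootstrap CI treats loci as exchangeable (no LD blocks).
* First-harmonic normalization is undefined for near-circular outlines and
  unstable for outlines with k-fold rotational symmetry.
* The generator's two-channel effect structure cannot produce arbitrary
  patterns across the five indices (e.g. a subunit effect on rectangularity
  alone).
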