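# Methods

`twingrowth` models how additive-genetic (A), shared-environment (C) and
unique-environment (E) influences on fetal growth change over gestation,
using the classical twin design applied to longitudinal ultrasound biometry.
This note records the models, the generative assumptions behind the
synthetic cohorts, the numerical choices, and the limits of what the test
suite demonstrates.

## The twin ACE model

For a trait value standardized at one gestational anchor age, the
phenotypic variance is decomposed as sigma²_A + sigma²_C + sigma²_E.
Monozygotic (MZ) co-twins share their additive-genetic component entirely
(kinship r = 1), dizygotic (DZ) co-twins share half of it (r = 0.5), and
both zygosities share C fully — the equal-environment assumption for
*in-utero* exposures. A pair is therefore bivariate normal with co-twin
covariance r·sigma²_A + sigma²_C, and the zygosity contrast identifies the
standardized fractions

    h² = sigma²_A / V,  c² = sigma²_C / V,  e² = sigma²_E / V.

E absorbs measurement error and, in dichorionic twins, the private
placental environment. Estimation is by maximum likelihood over pairs, with
covariates in the mean profiled out by GLS at every evaluation, five
starting points (Falconer moment estimates 2(rMZ − rDZ) and 2rDZ − rMZ,
equal split, E-only, and A-/C-leaning splits) plus the nested AE/CE optima
as additional starts. Because the nested models are refit first and their
solutions seed the full fit, the likelihood ordering ACE ≥ AE, CE ≥ E holds
by construction. Pairs with one missing co-twin contribute marginal
univariate terms (maximum likelihood under missing-at-random) rather than
being dropped.

Testing sigma²_A = 0 (or sigma²_C = 0) places the parameter on the boundary
of its space, so the LRT null distribution is the 50:50 mixture of a point
mass at zero and chi-square(1); T = 0 is reported as p = 1, the
conservative convention. Bivariate fits parameterize the 2x2 cross-trait
blocks Sigma_A and Sigma_C by Cholesky factors (PSD by construction) and
floor Sigma_E's diagonal at 1e-6 to keep the 4x4 pair covariance
invertible. The genetic correlation rho_G = Sigma_A[0,1] /
sqrt(Sigma_A[0,0]·Sigma_A[1,1]) is tested with a plain chi-square(1) LRT
(zero genetic covariance is interior to the parameter space); when a
marginal sigma²_A collapses to the boundary, rho_G is reported undefined
rather than fabricated. The internal trait order is canonicalized before
optimization, which makes the fit exactly symmetric in the order the caller
passes the two traits.

## Preprocessing: rank-based inverse-normal transform

Anchor values are transformed per trait per anchor across all fetuses with
Blom scores, Phi^-1((rank − 3/8)/(n + 1/4)), ties receiving average ranks.
Covariates (maternal age, pre-pregnancy BMI, smoking, alcohol, race,
parity, gravidity, employment, education, marital status, fetal sex) are
then adjusted *inside* the ACE mean model — the transform-then-adjust
order used by variance-component packages whose inverse-normalization
operates on the raw trait. Rank transformation makes all results invariant
to affine rescaling of the raw trait.

## Growth trajectories

Visits are modelled per trait, pooled across zygosities, as

    y = natural_spline(GA)·gamma + X·beta
        + pair-level (b0 + b1·g + b2·g² + b3·g³) + fetus intercept + eps,

with g = (GA − 26)/10 centred and scaled to condition the cubic terms. The
natural cubic spline has interior knots at 16, 22, 28 and 34 weeks (one per
visit cluster) and boundary knots at 11 and 41 weeks, linear beyond the
boundary. Estimation is REML via `statsmodels` MixedLM (pair-level 4x4
unstructured random-effect covariance through `re_formula`, iid
fetus-within-pair intercept through `vc_formula`); if L-BFGS does not
converge the fit is retried with BFGS and Powell and the best restricted
likelihood kept. EFW is modelled on the log scale (its SD grows in
proportion to its mean); AC, HL and FL on the raw scale. Noise-free inputs
whose OLS residual vanishes short-circuit to the exact least-squares
solution with all variance components zero, avoiding a degenerate REML
problem.

Anchor predictions are fixed part + pair-BLUP polynomial + fetus-BLUP
intercept, **plus a conditional residual term**: the fetus's observed
residuals around its individualized trajectory are interpolated linearly in
GA to the anchor (held constant beyond the observed range). The rationale
is that within-fetus deviations are serially correlated — growth deviations
persist between adjacent visits — so the conditional expectation at an
anchor should borrow the nearby observed deviation rather than assume pure
white noise. Without this term the single gestation-constant fetus
intercept flattens the within-pair variance profile across anchors, and
anchor-specific h²/c² estimates collapse toward a gestation-wide average;
with it, anchor-specific fractions are recovered. `conditional=False`
restores the plain BLUP rule. Predictions at anchors beyond a fetus's last
visit (typically the 38w6d anchor, since mean delivery is ~35.7 weeks) are
flagged `extrapolated` and included in ACE fits by default, with a switch
to exclude them.

## The synthetic cohort generator

The generator emulates the design of a prospective dichorionic-twin cohort:

* **Design.** 15 MZ + 133 DZ pairs by default; one initial sonogram with GA
  uniform on [11w0d, 13w6d] (the scheduling window; the within-window
  distribution is an assumption) plus schedule A (16, 20, 24, 28, 32, 35
  weeks) or B (18, 22, 26, 30, 34, 36), equally likely. Delivery GA is
  Normal(35.7, 3.7) truncated to [28, 41] weeks; later visits are dropped.
* **Mean curves.** Monotone cubic (PCHIP) interpolation of log mean through
  the four anchor means per trait, linear continuation on the log scale
  outside the anchor range. Head circumference anchors are derived in
  closed form so that the Hadlock formula applied to the per-anchor
  HC/AC/FL means reproduces the EFW anchor means exactly; the EFW mean
  curve is then defined as the Hadlock composition of the HC/AC/FL curves,
  which keeps all five curves mutually consistent at every GA.
* **Variance structure.** Fractions (h², c², e²) are defined on the log
  scale at each anchor; the total log-SD is set from the anchor coefficient
  of variation via s = sqrt(log(1 + CV²)), and values carry the −s²/2
  lognormal mean correction so anchor means are reproduced exactly in
  expectation. A is drawn with cross-trait correlation per anchor from the
  genetic-correlation plan and cross-anchor persistence 0.9 (genes are the
  same genome throughout gestation; the residual non-persistence reflects
  developmental gene-expression turnover). C is one pair-level draw shared
  across anchors with cross-trait correlation 0.7-0.9; E is fetus-specific
  with cross-anchor persistence 0.5 (persistent placental factors mixed
  with transient ones) and high EFW-AC/FL overlap. Between anchors a
  fetus's standardized latent score is interpolated linearly in GA.
* **Covariates.** Maternal age Normal(31.8, 6.1), BMI Normal(26.7, 6.3)
  truncated at 15, binary covariates at the cohort's DZ frequencies, fetal
  sex shared within MZ pairs and independent in DZ pairs. Default per-SD
  effects (age 0.20, sex 0.20, race 0.15) jointly explain ~9.3% of
  phenotypic variance, inside the 6.1-11.1% range the analysis targets.
  The combined latent score is standardized so the trait CVs match the
  anchor table regardless of covariate effects.
* **Measurement.** Multiplicative visit-level noise with CV 2% for the
  measured biometrics (AC, HL, FL; HC inherits noise through the
  inversion). EFW carries no noise of its own — it is a derived quantity —
  so each visit's HC is computed by inverting the Hadlock identity for the
  fetus's EFW given the observed AC/FL, with a 5 mm floor (hit on ~1e-5 of
  rows, where EFW is recomputed from the floored HC so the identity is
  exact on every row).
* **Reproducibility.** One master seed; per-pair substreams derive from
  (seed, pair index), so enlarging a cohort never perturbs existing pairs.

What the generator does *not* emulate: monochorionic placentation,
sex-specific variance structure, gene-environment interaction, maternal
genetic effects, visit-time jitter around the scheduled weeks, missing
visits other than by delivery, and real ultrasound error structure
(operator and machine effects). Passing recovery tests therefore show that
the estimators are correct under the stated generative model, not that the
printed variance fractions are reproducible from real data — the study's
raw data are not public, which is why recovery-from-known-truth is the
validation strategy.

## Twin-design power

The non-centrality route builds the model-implied standardized co-twin
covariance matrices under the truth, fits the null-constrained model to
those population matrices by minimizing the pair-count-weighted Gaussian ML
discrepancy F = tr(S·Sigma^-1) − ln|S·Sigma^-1| − p, and uses the minimized
weighted discrepancy as the expected-LRT non-centrality lambda. Critical
values come from the boundary mixtures (50:50 {chi²0, chi²1} for one
component; 1/4, 1/2, 1/4 over {chi²0, chi²1, chi²2} for the joint familial
test). For a single component the alternative distribution is the exact
one-sided form T = max(0, Z + sqrt(lambda))², giving power =
Phi(sqrt(lambda) − sqrt(c)) — continuous in lambda and exactly alpha at
lambda = 0. For the joint test the noncentral chi-square(2) tail is used
(with the null mixture at lambda = 0); the exact chi-bar-squared alternative
depends on the direction of the mean shift, not only lambda, and the 2-df
tail is the standard practical approximation. The simulation route draws
single-anchor cohorts, fits full and null models by ML and counts
rejections; its empirical size is nominal in the regime where the mixture
asymptotics apply (500+ pairs per zygosity are used for size checks).

The headline design question — can 15 MZ + 133 DZ pairs detect 25%
additive-genetic plus 50% shared-environment variance at alpha = 0.05 —
is read as the joint familial-variance test (ACE vs E-only), the reading
that quantifies both components together; the single-component tests are
exposed alongside.

## Numerical choices and degenerate inputs

* Variance optimizations use L-BFGS-B with box constraints
  sigma² in [0, 10·total variance] and sigma²_E floored at 1e-10·variance;
  convergence tolerances 1e-12 (ftol) / 1e-9 (gtol), with a tight polishing
  pass for bivariate fits.
* If the full ACE optimum lands below a nested optimum (possible only
  through optimizer failure), the nested solution with the dropped
  component at zero replaces it, keeping p-values well defined.
* Identical co-twin values in both zygosities drive c² to 1 (the boundary);
  all-identical trait values are rejected by the transform (no rank
  information).
* Problem sizes in tests and the acceptance study: recovery cohorts use
  500 MZ + 1500 DZ pairs averaged over five seeds; oracle and correlation
  checks use 2000+2000 pairs; LRT size uses 2000 replicates. These sizes
  put Monte-Carlo error well inside the tolerances being asserted.

## Known limitations

* The growth model's within-pair deviation is a single intercept (plus the
  conditional residual term); anchor-specific E is recovered through the
  conditioning, not through the random-effects structure itself.
* Genetic correlations near |rho_G| = 1 are boundary estimates; they are
  reported as estimated (flagged when undefined), not constrained.
* The bivariate module fits one trait pair at a time; no joint model of
  all four traits, no dominance (ADE), no sex-limitation models, and no
  longitudinal same-trait genetic correlations.
* Power calculations ignore covariates and assume complete pairs.
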