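# Methods

`befmeta` implements the inference chain used in cross-study syntheses of how
chemical stressors and nutrient enrichment affect decomposer communities
(invertebrates, fungi, bacteria) and litter decomposition, together with a
synthetic-data generator that makes every stage testable against known ground
truth. This note describes the statistical model, the generator, the numerical
choices and the known limitations.

## Effect sizes

All analyses run on Fisher-z transformed correlation coefficients, which
accommodate heterogeneous designs and outcome metrics on a single scale.

* **Control-treatment studies** (two groups): Hedges'
  d = J (x̄_t − x̄_c)/s_pooled with the small-sample correction
  J = 1 − 3/(4(n_t+n_c−2)−1), converted to a correlation
  r = d/√(d² + a), a = (n_t+n_c)²/(n_t n_c), then z = atanh(r) with
  n_eff = n_t + n_c.
* **Gradient studies** (≥4 driver levels): Pearson correlation between the
  per-level outcome means and the driver concentrations, then atanh;
  n_eff = number of levels (the correlation's sample size; the source
  material is silent, so this is our convention).
* Sampling variance is var(z) = 1/(n_eff − 3) uniformly for both routes,
  consistent with weighting on "the variance in z-transformed correlation
  coefficients"; the alternative of propagating var(d) through the d→r map
  is not used.
* **Direction convention:** positive z always means "the response increases
  with the driver level". Decomposition reported as proportion of mass
  *remaining* is sign-flipped (and flagged); mass loss reported with a
  measurement time is first converted to decay rates k = −ln(remaining)/t
  (SDs by the delta method).
* |r| ≥ 0.999 is clipped to ±0.999 before atanh with a logged warning: four
  collinear gradient points legitimately produce r = ±1 and must not crash a
  batch.
* Missing SDs are imputed from the ordinary-least-squares fit of sd on mean
  over the known pairs of the same driver × response dataset (≥3 pairs
  required, predictions floored at 1e-6); imputed records carry an
  `sd_approximated` flag so sensitivity reruns can drop them.
* When one observation is reported at several time points, only the last is
  kept (long-term response).
* The log response ratio ln(x̄_t/x̄_c) with delta-method variance is
  available as an alternative effect size for sensitivity analyses; it is
  undefined for gradient designs and non-positive means, which are logged
  exclusions.

## Intensity standardization

Stressor and nutrient levels are standardized as
intensity = log₁₀([compound]_treatment / [compound]_criteria) against
regulator-issued environmental quality criteria (ECHA, USEPA, WFD, ...): 0 at
the criterion, ±1 per order of magnitude. The log base is configurable (the
defining equation's base is ambiguous in the literature; base 10 gives the
intensity an interpretable unit) and is recorded in every output table since
it rescales slopes. With several compounds, the maximum standardized
intensity defines the observation; ties break to the first compound in input
order, logged. Criteria are caller-supplied; no lookup is performed.

## Multilevel weighted meta-analysis

Effect sizes are modelled as
y_i = x_i'β + u_study(i) (+ w_i) + e_i with u ~ N(0, τ²),
w ~ N(0, σ²_obs) (optional observation-level component) and e_i ~ N(0, v_i)
with the sampling variances v_i known. Variance components are estimated by
profiled REML (ML available), β by GLS given the components. Moderators use
treatment contrasts with the alphabetically first level as reference; grand
means per group are linear combinations of the coefficients, not refits.
Moderator tests are Wald chi-square (QM) statistics; confidence intervals are
normal-based (no Knapp–Hartung adjustment, matching the common default for
this model family). Model AICs are computed under ML — refitting the
variance components if the primary fit was REML — because mediation compares
models with different fixed effects; k counts fixed effects plus free
variance components.

Numerics: the marginal covariance is block-diagonal by study with a
rank-one (compound-symmetry) block structure, so each likelihood evaluation
uses per-study Sherman–Morrison identities and costs O(n p²); the kernel is
JIT-compiled with numba when available (a numerically identical numpy path
is used otherwise and for all reported quantities). Components are optimized
on the square-root scale (smooth [0, ∞) reparametrization) with a small
Nelder–Mead (objective tolerance 1e-9, simplex tolerance 1e-5, ≤500
iterations) warm-started from related fits; cold starts are retried from
small and moderate heterogeneity. REML log-likelihoods include the
+½log|X'X| constant so they are directly comparable with metafor's `rma.mv`
(one test cross-checks coefficients, SEs, components, log-likelihood and ML
AIC against it). Rank-deficient designs raise an error naming the aliased
terms. Egger's regression (z/SE on 1/SE, t-test of the intercept on k−2 df)
and funnel tables provide the publication-bias diagnostics.

## Piecewise SEM and mediation

The mediation question — does the driver's effect on decomposition run
through its effect on decomposer diversity/abundance? — is answered with a
piecewise SEM of two weighted multilevel sub-models with nested case-study /
observation random intercepts and known sampling variances:

    zLD ~ zB + intensity + study_type
    zB  ~ intensity + study_type + taxon_group (+ diversity_metric)

fitted separately for the four driver × response-family datasets (the
diversity-metric term only enters diversity datasets). Because one
decomposition measurement is often matched to several biodiversity
observations, the SEM is averaged over stratified resamples (default 1000):
each iteration keeps one uniformly drawn biodiversity effect per
decomposition measurement, refits everything, and coefficients, SEs,
Fisher's C and AICs are averaged arithmetically; the p-value of C is
computed from the mean C at the graph's fixed degrees of freedom.
Per-iteration residuals are averaged per observation for diagnostics.
Iterations whose fits fail are skipped; more than 10% failures abort.

Goodness of fit uses directed-separation tests: each missing edge implies a
conditional-independence claim (x ⟂ y | parents of y, with y the
topologically later, endogenous node), tested as the Wald p-value of x added
to y's sub-model; C = −2Σln p is chi-square with 2k df under the model. A
brute-force enumerator of this convention is kept in the test suite as the
oracle. The mediation rule compares the full graph with the graph lacking
zB → zLD: the path is supported when the reduced model fits poorly
(p(C) < 0.05) and is not better by 2 or more AIC units, where a model's AIC
is the sum of its sub-models' ML AICs, and ΔAIC is reported as
reduced − full (positive = reduced worse). Standardized paths multiply the
coefficient by sd(predictor)/sd(outcome) computed from each resampled table
and are averaged; the indirect effect is the product of the standardized
intensity→zB and zB→zLD paths, the direct effect the standardized
intensity→zLD path. Between-model comparisons of path strength should use
the unstandardized column.

`mediation_analysis` fuses the full- and reduced-graph loops over shared
resamples (the zB sub-model and the reduced model's zB claim — which equals
the full zLD model — are fitted once), and is identical to two
`run_resampled_sem` calls with the same seed.

## Synthetic-data generator

The generator emulates the statistical skeleton such syntheses assume:
~69 case studies contributing 4–15 biodiversity/abundance observations each
(~660 total), one driver per study, intensities ~ U(−2, 3) (below to well
above the quality criteria), within-study duplication of decomposition
measurements (1–4 biodiversity observations per litterbag), within-
observation sample sizes n ∈ [4, 30] (typical of field studies; exposed in
the config), study-level heterogeneity τ = 0.2 and observation-level
σ_obs = 0.2, and moderator labels drawn from configurable category
probabilities. Default grand means (stressors clearly negative, nutrients
near zero) and paths (0.42 biodiversity→decomposition, −0.05 direct) are on
the scale of published syntheses.

Two design choices matter for interpretation:

* **Decomposition responds to the realized biodiversity effect.** Each
  litterbag's biodiversity response is realized once (latent mean + one
  sampling deviation); duplicate rows re-measure that realized value with
  small reporting jitter (sd 0.03), and the decomposition equation uses the
  realized value. The raw-study generator does the analogous thing at the
  summary level (the decomposition target is built from the z values implied
  by the emitted group summaries). Had the structural path been placed on
  the *latent* effect instead, the regression of observed z_LD on observed
  z_B would estimate an attenuated coefficient (classical errors in
  variables) and no analysis chain could recover the generating path — an
  undesirable property for a validation testbed. The flip side is that the
  generator does not emulate predictor measurement error; on real data the
  fitted paths remain attenuated estimates of any latent relationship.
* **Independent study intercepts per equation.** The biodiversity and
  decomposition equations receive independent study-level intercepts, so
  both exhibit the within-study dependence the random effects must absorb,
  without making the zB regressor endogenous to the zLD equation's random
  intercept.

Moderator labels carry no effects by default, giving a known null for
moderator tests and d-separation claims. Publication bias is simulated by
retaining each effect with probability expit(strength·(z/SE − 1)) — near 1
for clearly positive-significant effects, smaller otherwise; strength 0 is
the identity. This selection mechanism is a stand-in for detection tests
only (the analysis never models selection). Decomposition rows left without
partners after selection are dropped to preserve the linkage invariant.

What the generator does not emulate: taxonomic composition, litter
chemistry, geography, correlated moderators, non-monotone dose responses,
and (by design) predictor-side measurement error. Passing recovery tests
therefore validates the implementation of the estimators, not the method's
robustness to those features of real data.

## Validation problem sizes

The validation suite and `scripts/acceptance.py` use: 100 random instances
for the fixed-effect oracle (agreement ≤1e-8); 20 instances of ≤10 studies
for the REML-vs-grid check (grid step 1e-4); 10⁴ simulations for Fisher's C
calibration; 50 replicates of 80-study datasets with duplicates 1–4 at 200
resampling iterations for path coverage, mediation power (path 0.5) and size
(path 0); and 200 replicates of ~100 null effects with selection strength 8
for Egger detection. These sizes keep the whole validation run at a few
minutes on one CPU while leaving the Monte-Carlo error well below the
margins being checked.

## Known limitations

* Wald-type SEs ignore variance-component uncertainty; with ~80 studies the
  nominal 95% intervals for SEM paths cover slightly below nominal (the
  acceptance run reports the measured coverage). This matches the behaviour
  of the standard tools for this model class.
* Averaging SEs across resampling iterations is a simple mean; no
  between-iteration variance inflation is added.
* The d-separation conditioning convention (parents of the child node) is
  one of several in use; the enumerator and tests pin it down explicitly.
* No multiple-testing adjustment is applied across moderator tests; p-values
  are per test.
* Gradient correlations use raw concentrations; generators and analyses
  agree on this convention, but strongly log-spaced designs make r a
  nonlinear summary of the underlying trend.
* lnRR sensitivity reruns cover control-treatment records only; gradient
  records are excluded with logged reasons.
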