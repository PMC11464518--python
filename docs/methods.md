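# Methods notes

## Parenclitic mapping

The reference population is defined as the patients censored alive at the
28-day horizon (`event == 0`); patients transplanted within the horizon
count as events on the transplant day and are therefore never part of the
reference. For every unordered pair of analysis variables an OLS line is
fitted on pairwise-complete reference rows, and the two-tailed Pearson
p-value is compared against `alpha / C(p, 2)`. The Bonferroni denominator
is always the full `C(p, 2)`, even when some pairs cannot be fitted
(fewer than 3 complete rows, or a constant variable): keeping the
denominator fixed is conservative and makes the threshold independent of
data quality.

Three deviation conventions are implemented and recorded in every output:

- `standardized_residual` (default): `|residual| / s`, with `s` the
  reference residual SD on `n − 2` degrees of freedom. Scale-free across
  axes and consistent with the downstream Z transformation.
- `raw_residual`: `|residual|` in the units of the response variable.
  Published per-axis deviation magnitudes differ by two orders of
  magnitude across axes, which suggests raw-unit residuals were used in
  at least some prior work, so the convention is selectable rather than
  hard-coded.
- `orthogonal`: perpendicular distance to the line after z-scoring both
  coordinates on the reference scales. This removes the dependence on the
  regression direction.

Regression direction is fixed and documented: in the axis label `δ-A/B`,
B is regressed on A, with variables processed in sorted order. The
deviation matrix is invariant to cohort row order and variable list
order.

## Synthetic cohorts

The generator draws a latent multivariate Gaussian per group with a block
compound-symmetry correlation matrix (blocks = organ systems;
`within_block_corr` default 0.5, `between_block_corr` default 0.1), then
maps each coordinate affinely to published first-day ICU marginals for
paracetamol-ALF survivors. Right-skewed laboratory values (ALT, AST, ALP,
bilirubin, INR, urea, creatinine, phosphate, lactate) are exponentiated
from the Gaussian scale, i.e. modelled log-normal with moment- or
quartile-matched parameters; only marginal summaries are published, so
log-normal marginals are this package's realism choice. Non-survivors get
location shifts (in survivor-SD units on the generation scale) matched to
the published group differences, and the correlations of the configured
`decoupled_pairs` are multiplied by `decoupling_factor` (default 0 on the
pH/bicarbonate, lactate/glucose and SpO₂/respiratory-rate axes, i.e. full
decoupling), with a Higham-style projection to the nearest correlation
matrix when the edit leaves the positive-definite cone.

Event times: survivors are administratively censored at
`followup_days = 28`. Non-survivor times are truncated-exponential on
(0, 28] with rate `hazard_baseline · exp(Σ β_pair · δ_pair)` per day
(`hazard_baseline = 0.15/day`, matching a mean ICU stay of roughly a week
for non-survivors; `β = 0.4` per planted axis). Truncation (rather than
censoring the overflow) keeps the group label identical to event status
and makes the censoring invariant exact; with the default baseline the
probability mass beyond 28 days is ≪ 1%, so Cox fits on the non-survivor
stratum recover the generating β. The planted deviation of a pair is
`|z_B − ρ z_A| / √(1 − ρ²)` on the latent (survivor-standardised) scale —
the same functional form the analysis estimates from data.

GCS is rounded and clipped to [3, 15]; a few other variables are clipped
to clinically plausible ranges. Clipping is applied after the planted
deviations are computed, so the hazard is driven by the unclipped latent
values; `planted_truth` returns the stashed exact values and can
reconstruct them from observed data wherever no clip fired.

Missingness is MCAR at `missing_rate` (default 0) over the physiological
columns only, with per-row redraws so that no patient falls below 50%
non-missing. Informative missingness is out of scope. What the generator
does **not** emulate: repeated measurements and within-day dynamics,
treatment effects, informative censoring, nonlinear couplings, and
real-data marginal quirks beyond the first two moments — so passing tests
demonstrate method correctness under the stated generative assumptions,
not clinical performance.

## Severity scores

KCC is the count (0–4) of: arterial pH < 7.30, INR > 6.5, creatinine >
3.4 mg/dL, and GCS ≤ 8 (the West Haven grade III/IV proxy). All
inequalities are strict, as printed. The original dichotomous KCC cannot
produce the fractional summary statistics reported for ICU cohorts; the
count is an interpretation, documented as such. Missing inputs count as
criterion-unmet with a warning (configurable to a hard error).

SOFA uses the standard bandings for coagulation (platelets), liver
(bilirubin), CNS (GCS) and renal (creatinine). The cardiovascular
sub-score is MAP-based only (no vasopressor doses among first-day
variables) and the respiration sub-score is an optional pass-through,
since PaO₂/FiO₂ is not available; computed SOFA values are therefore
lower bounds on the full score.

## Network topology

Edges of the group correlation network require a Bonferroni-significant
two-tailed Pearson p-value; the edge weight is r. Community detection is
standard (unweighted) clique percolation at an explicit clique size `k` —
`k` is never defaulted, because reasonable published analyses have used
both k = 3 and k = 5 — with an optional absolute-weight edge pre-filter.

**Caveat — heavy-tailed variables.** The normal-theory Pearson p-value is
anti-conservative for severely log-normal marginals (σ ≈ 1.1–1.3 gives
extreme kurtosis): under an identity correlation the measured family-wise
false-edge rate was ~0.06–0.10 instead of ≤ 0.05 at n = 200–1000. This is
a property of the test, not of the Bonferroni selection; with Gaussian
marginals the FWER is at its nominal level. Users analysing raw skewed
laboratory values should interpret borderline edges cautiously (or
pre-transform).

## PCA stage

Correlation-matrix PCA; Kaiser retention (eigenvalue > 1); varimax with
Kaiser row-normalisation (rows scaled to unit communality before
rotation, unscaled after), convergence handled by the GPA rotation
routine; component scores by the regression (Thurstone) method,
`scores = Z R⁻¹ L`. Sign indeterminacy is resolved by making the
largest-|loading| variable of each component load positively. Which
variables enter the PCA is a configuration input.

## Survival evaluation

- Group comparisons: Shapiro–Wilk (5%) on both groups gates t-test vs
  Mann–Whitney; Levene's test chooses the equal/unequal-variance t form;
  chi-squared (uncorrected) for categorical variables.
- Deviations and component scores are Z-transformed (mean 0, SD 1,
  `n − 1` denominator) before Cox fits; SOFA and KCC enter on their
  natural integer scales, so composite coefficients are per-point.
- Cox fits maximise the partial likelihood by damped Newton iterations
  with an analytic gradient and finite-difference observed information;
  Breslow tie handling is the default, Efron is available, and the choice
  is recorded in the output. Wald SEs, HRs and 95% CIs per term.
  Divergent coefficients (|β| > 50) or SEs (> 50) abort with a
  separation diagnostic. Covariates are centred internally for numerical
  stability; results are unaffected.
- Composite scores are exactly `β₁·SOFA + β₂·δ` with the multivariate
  betas, δ on its z-scale.
- ROC: AUC by the Mann–Whitney rank statistic (tied pairs count ½);
  the cutoff maximises Youden's J over midpoints between adjacent
  distinct scores, ties broken toward higher specificity; PPV/NPV at the
  empirical prevalence.
- Brier scores use model-based 28-day event probabilities
  `1 − exp(−H₀(28)·exp(lp))` with the Breslow baseline cumulative hazard
  (default), or a recalibrated logistic fit (`brier_method="logistic"`),
  since the exact construction used with commercial software is not
  standardised.
- IDI is the change in discrimination slope; NRI is the continuous
  (category-free) variant — no published risk categories exist for this
  setting. P-values use the standard asymptotic variances.
- Kaplan–Meier estimation and the Mantel–Cox test go through lifelines.
- Two-tailed p < 0.05 throughout.

The full-pipeline driver treats the censored group as the reference, runs
every significant axis (plus any externally supplied index columns, e.g.
PCA scores) through comparison → univariate Cox → multivariate Cox vs
SOFA + KCC → composite ROC/Brier → IDI/NRI → KM at the composite cutoff,
and emits machine-readable tables. Different deviation axes are never
combined in one model (they are statistically dependent by construction).

## Problem sizes used in the test suite

Replicate-based properties run at sizes chosen to keep the full suite
fast while leaving comfortable statistical margins: planted-decoupling
recovery at 500 patients/group over 50 seeds; null calibration on a
12-variable subset at 200/150 per group over 200 replicates (type-I
band 0.025–0.075; FWER held to the one-sided 95% binomial band around
0.05); hazard-coefficient recovery at 2000 non-survivors over 50 seeds
(within 2 SE in ≥ 80%); brute-force clique-percolation equivalence on 100
random graphs of ≤ 12 nodes for k ∈ {3, 4, 5}.

## Known limitations

- The cardiovascular/respiration SOFA simplifications above.
- Pearson-based edge selection is anti-conservative on heavy-tailed raw
  variables (see caveat).
- Exponential (constant-hazard) event times; no competing risks or
  time-varying covariates.
- The synthetic marginals are approximations from published summary
  statistics; correlation magnitudes between specific real variable pairs
  are not reproduced, only the block/decoupling structure the method
  consumes.
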