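# Methods

This note documents the statistical procedures the package implements, the
defaults it fixes where a choice had to be made, the numerical details, and
the known limits of what the simulation studies demonstrate.

## Structural models

All simulated data follow linear structural models with two exposures, an
outcome, L mutually independent SNPs and a latent confounder U entering
every equation. Genotypes are additive dosages, Binomial(2, maf) per SNP
with maf drawn uniformly per SNP from `maf_range` (default (0.1, 0.4)); any
column-independent dosage distribution leaves the theory unchanged. The
secondary exposure X2 plays one of four roles relative to X1 and Y:

| scenario   | extra structure                              | generation order |
|------------|----------------------------------------------|------------------|
| confounder | X2 → X1 (α2)                                 | X2, X1, Y        |
| collider   | X1 → X2 (α1) and Y → X2 (γy); β2 = 0         | X1, Y, X2        |
| pleiotropy | X1 ⊥ X2 given G                              | X1, X2, Y        |
| mediator   | X1 → X2 (α1)                                 | X1, X2, Y        |

The collider's generation order is forced (Y must exist before the variable
it causes), and the model requires β2 = 0 — X2 must not feed back into Y.
The direct effect of X1 is β1 in every scenario; the total effect in the
mediator scenario is β1 + α1 β2.

SNPs are partitioned into `l1` affecting only X1, `l2` only X2 and `l12`
both (default 10/10/10, L = 30). Defaults, fixed once: β0 = 0, β1 = 1,
β2 = 0.5, α1 = α2 = γy = 0.5, sd(U) = sd(vx1) = sd(vx2) = sd(vy) = 1
(unit-variance convention), nonzero π entries ~ U(0.1, 0.3), which puts each
exposure's instrument R² near 15% — a strongly instrumented regime by the
F > 10 rule of thumb. The identification designs (`both_identified`,
`x1_unidentified`, `x2_unidentified`, `jointly_unidentified`) use the
pleiotropy structure with all L SNPs affecting both exposures and a shared
confounder; `jointly_unidentified` sets π1 = δ·π2 exactly (default δ = 1),
so each exposure is individually predicted but the pair is not jointly
predictable.

## Summary statistics

Joint mode regresses each exposure (and the outcome) on all SNPs plus an
intercept; univariable mode runs per-SNP simple regressions. Sampling
variances take [(W′W)⁻¹]jj — the (j, j) element of the inverted
cross-product of the intercept-augmented design, not the reciprocal of the
(j, j) element — times the mean squared residual, and the cross-exposure
covariance σ12j uses the mean residual cross-product. The residual divisor
is 1/n rather than 1/(n − L − 1); the difference is O(L/n) and is one reason
the simulated Q means sit a fraction of a percent above their χ² reference
at moderate n. The covariance status of a summary table is an explicit
tri-state: computed from individual data (*known*), *assumed zero* as an
analytical choice, or *unknown* (tables loaded without covariance columns);
it is never silently imputed.

## Estimators

* **TSLS** is the classical two-stage construction; standard errors use
  second-stage residuals recomputed at the observed exposures.
* **IVW / MVMR-IVW** combine SNPs with first-order weights 1/σ²yj; the
  covariance-aware weighting is deliberately reserved for the Q diagnostics,
  mirroring the separation of estimation and diagnosis. Standard errors use
  a multiplicative residual scale floored at 1 (random-effects style); the
  construction of summary-data standard errors is a package choice, not a
  published prescription. 95% intervals are normal-theory.
* **MVMR-Egger** re-orients each SNP so its association with a chosen
  exposure is nonnegative (flipping the whole SNP row preserves all
  variances), then adds an intercept whose deviation from zero indicates
  directional pleiotropy.
* Wald ratios drop SNPs with |π̂| < 1e−12 rather than emit infinities.

## Strength diagnostics

The conditional F statistic follows the four-step recipe (regress the other
exposures on the instruments; TSLS the target on those fitted values; save
residuals at the observed exposures; F-test the residuals on the
instruments) with the step-3 statistic rescaled by L/(L − K + 1) and
numerator df L − K + 1 — the degrees-of-freedom correction isolated in one
place. One caveat established during development: the recipe's auxiliary
TSLS requires the other exposures to be at least weakly instrumented; if an
exposure is *completely* unrelated to G the auxiliary δ̂ has no probability
limit and the statistic is not comparable to the conventional F.

For the summary-data statistic Qx1, δ̂ is computed as an iteratively
re-weighted fixed point (weights 1/σ²x1(δ) refreshed each step, seeded at
the 1/σ²1j-weighted slope), then refined to the **local** minimizer of
Qx(δ) in the surrounding basin (bounded scalar minimization, tolerance
1e−12). Global minimization over δ would be wrong: under a strongly
identified alternative Qx(δ) decays monotonically toward a degenerate
asymptote of size ≈ Σ π̂²/σ² ~ χ²L as |δ| → ∞, so an unbounded search
collapses exactly the large Qx values that signal identification. When the
basin scan finds its minimum on the window edge (the monotone-escape case)
the fixed point is kept. Negative σ²x1(δ) — possible only with inconsistent
user-supplied covariances — is a hard error, not a clamp. For K > 2
exposures δ generalizes to a (K−1)-vector fitted by the same iterative GLS;
the df stays L − 1, an extrapolation of the two-exposure theory.

## Validity diagnostics

QA uses modified-iterative weighting: starting from the MVMR-IVW fit,
alternate re-computing 1/σ²Aj at the current estimates and re-fitting the
weighted regression, until the estimates move < 1e−8 (cap 200 iterations).
An optional `minimize=True` refines the converged estimates by direct
numerical minimization of QA — the fully analytical variant — and is kept
optional. The +2β̂1β̂2σ12j sign in σ²Aj (opposite to the −2δ̂σ12j of the
strength variant) is implemented as the statistic is defined; the two
weights arise from variances of a difference and of a sum respectively. The
standard-weighted Q (weights 1/σ²yj only) is provided for comparison but
carries no p-value, since it is over-dispersed relative to χ².

## Calibration harnesses and the scales used

* **Under-identification nulls**: full pipeline per repetition (simulate,
  joint summaries with known covariance, Qx1/Qx2 against the χ²(L−1) 95%
  point). The package's desk-scale runs keep the original 1000–1500
  repetitions (so a ~5% rejection rate is estimated to ~0.6 points) and
  reduce the per-repetition sample size to n = 10 000 with L = 100; the
  Monte-Carlo mean of Qx1 sits within ~1.5% of L − 1 = 99 and the rejection
  rate within ~1.5 percentage points of nominal under both null designs. Under strong identification rejection is 100%
  and the Q values grow with n and the π magnitudes, so their absolute size
  is parameterization-specific.
* **QA null**: generated directly at the summary level with the quoted
  configuration (L = 100, β1 = β2 = 1, σ²1j = σ²2j = 0.02, σ12j = 0).
  The unstated quantities are module defaults: true π ~ U(0.5, 1.5) and
  σ²yj = 0.02. The π scale matters: it must keep the instruments strong,
  because weak-instrument bias in β̂ inflates mean QA (~3.5% at
  π ~ U(0.2, 0.6)); the chosen range reproduces the correct χ²(98) null
  (mean within ~0.5%, rejection ≈ 5%).
* **Estimand recovery**: 500 repetitions per scenario at n = 10 000.
  Multivariable TSLS/IVW recover the direct effect and univariable MR with
  all SNPs is materially biased wherever shared SNPs open a pleiotropic
  path.

## Known limitations

* **Finite-sample IV bias.** Classical TSLS with L = 30 instruments at
  n = 10 000 and R² ≈ 15% is biased toward OLS by roughly
  (L − K − 1)/μ² of the OLS bias (μ² the concentration parameter): about
  +0.6% in the confounder/pleiotropy scenarios and −1.5% in the collider
  scenario, vanishing as n grows (collider mean 0.985 at n = 10 000 →
  0.996 at n = 40 000). Consequently "unbiasedness" holds asymptotically,
  and mean-recovery checks tighter than this inherent bias (e.g. 3
  Monte-Carlo standard errors with many repetitions) will fail at this
  sample size for any realistic parameterization — most visibly for the
  collider. No bias-corrected (LIML/jackknife) variant is implemented.
* The simulator emulates linear structural equations with homoscedastic
  Gaussian noise, unrelated (LD-free) SNPs and continuous outcomes; it does
  not emulate LD structure, binary traits, selection beyond the collider
  equation, or assortative mating, so passing tests say nothing about those
  complications in real data.
* The summary-data strength test is a test of identification (can the SNPs
  explain any conditional variation), not a graded weak-instrument test;
  no critical-value theory beyond the χ² comparison is provided.
* Robust estimators for >50% invalid instruments (median/mode-based) and
  outlier-SNP removal policies are out of scope.
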