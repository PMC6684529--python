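# Methods

## The estimator

`eslreg` fits the linear model y_i = x_i'β + ε_i when the errors are
not normal — typically a mostly-Gaussian error law contaminated by a
heavy-tailed component, as seen in clinical outcome scores.  Instead of
minimising squared error, it maximises

    l_n(β) = Σ_i exp(−(y_i − x_i'β)² / γ),

equivalently minimising the total exponential squared loss
Φ_γ(t) = 1 − exp(−t²/γ).  Because Φ_γ is bounded by 1, a single gross
outlier can shift the objective by at most one unit, capping its
influence; the breakdown point of the full procedure approaches 50%.
The tuning parameter γ trades efficiency against robustness: as
γ → ∞ the weights exp(−r²/γ) → 1 and the estimator reduces to ordinary
least squares; small γ aggressively down-weights large residuals.

Stationary points of l_n satisfy the weighted normal equations
X'WXβ = X'Wy with W = diag(exp(−r_i²/γ)), so the fixed-γ maximiser is
computed by iteratively reweighted least squares (IRLS).  Each
iteration solves the weighted normal equations at the current weights
and moves toward that solution, halving the step (up to 30 times) if
the raw step would decrease the objective; accepted iterations are
therefore monotone ascent.  The objective is multimodal, and the solver
reports convergence to the local maximum reachable from its start;
optional jittered restarts (off by default) probe nearby basins.

## Initial estimate

The outer algorithm starts from an MM-estimate: an S-stage selects,
among 500 seeded elemental p-point exact fits, the candidate with the
smallest Tukey-bisquare M-scale (c0 = 1.547, consistency b = 0.5 — the
50%-breakdown configuration) and refines it by reweighted steps that
keep the scale decreasing; an M-stage then runs bisquare IRLS at
c1 = 4.685 (95% Gaussian efficiency) with the S-scale held fixed.
These constants are the conventional MM configuration; the subsample
sequence is fully determined by the seed, so the estimate is
reproducible bit-for-bit.

## Tuning-parameter selection

At the current coefficients the residual scale is the normalised MAD,
S_n = 1.4826 · median|r_i − median(r)|, and observations with
|r_i| ≥ 2.5·S_n form the pseudo-outlier set (size m).  Flagging is
two-sided: the loss is symmetric, so negative gross residuals count.

A candidate γ is admissible when the feasibility functional

    ζ(γ) = 2m/n + (2/n) Σ_{non-outliers} Φ_γ(r_i)

lies in (0, 1]; ζ is decreasing in γ and lies in
[2m/n, 2m/n + 2(n−m)/n], so the constraint mainly rules out very small
γ (which would treat every observation as an outlier).  Among
admissible candidates, γ minimises the determinant of the estimated
asymptotic covariance — the sandwich V(γ) = I1⁻¹ Σ I1⁻¹ with

* I1 = a(γ) · (X'X/n), a(γ) = −(1/n) Σ (2/γ) e^{−r²/γ} (2r²/γ − 1),
  the separable mean curvature of the objective, negated so that I1 is
  positive definite near a maximum;
* Σ the empirical covariance (denominator n−1) of the per-observation
  score contributions (2 r_i/γ) e^{−r_i²/γ} x_i.

Candidates with non-positive curvature or an I1 condition number above
1e12 are treated as infeasible.  Determinants are compared on the log
scale (slogdet) to avoid underflow at p = 10; exact ties resolve to the
larger γ (the more efficient choice).  If no candidate is feasible the
fitter raises an error carrying the full (γ, ζ, det V) table.

The candidate grid is 40 geometrically spaced points from S_n²/50 to
200·S_n², recomputed from the current residuals each outer iteration;
γ competes with r² inside an exponent, so the squared robust residual
scale is its natural unit.  When S_n = 0 (a majority of identical
residuals) the residual standard deviation anchors the grid instead.
Numerical evaluation of the population quantity
E[ψ²]/(E[ψ'])² shows the determinant rule lands where it should: under
an 80/20 normal/Cauchy error mixture the variance-minimising γ is
≈ 10 for unit-variance residuals, and the selected values concentrate
there.

The outer loop alternates selection and re-maximisation until the
Euclidean norm of the coefficient change falls below 1e-2 (at most 50
outer iterations; inner IRLS tolerance 1e-8, at most 200 iterations —
the inner solve must be tighter than the outer rule).  If the start
already fits the data exactly there is nothing to tune and the loop
reports convergence immediately.

## Bootstrap inference

Confidence intervals are equal-tailed percentile intervals (type-7
interpolated order statistics) over B case-resampled datasets: rows
drawn with replacement, the full pipeline — including γ re-selection —
re-run per resample.  Case resampling is used rather than residual
resampling because the latter assumes the homoscedastic-normal
structure the estimator is designed to escape.  Default B = 1000,
level 0.95.  Resample fits are warm-started at the full-data estimate
instead of re-running the MM subsampling stage; this substitutes the
initial value only and leaves the rest of the pipeline untouched.
Resamples whose fit fails (rank-deficient resampled design, degenerate
weighting, empty feasible set) are skipped and counted; results with
more than 5% failures are flagged unreliable.  A coefficient is called
significant when its interval excludes 0; no multiplicity adjustment
is applied.

## The Monte-Carlo benchmark

`SimulationDesign` defaults encode the benchmark study: n = 300;
six i.i.d. N(0,1) continuous covariates; one categorical covariate
uniform on {1,…,4} dummy-coded against the last level; true
coefficients (1, 1.2, 1.4, 1.6, 1.8, 2, 2.2, 2.4, 2.6, 2.8) with the
intercept first; errors standard normal except on a seeded
simple-random subset of exactly round(contamination · n) rows, whose
errors are replaced by Student t(1) (Cauchy) draws; contamination
levels 10/20/30%; 100 replications.  Summaries report, per estimator
and coefficient, the mean, bias = mean − truth, the (R−1)-denominator
SD, and MSE = average squared error, which satisfy
mse = bias² + sd²(R−1)/R identically.  Because t(1) has no moments,
OLS summary cells are dominated by the luck of the draw and are only
meaningful as a contrast, never as point targets.

## Synthetic trial fixture

`mci_like_frame` emulates a two-arm, eight-centre randomised trial
table (2:1 allocation): age ≈ N(63, 8²), height/weight giving
plausible BMI, baseline cognitive score ADAS1 ≈ N(15, 6²), binary
gender/education/occupation/drug, centre frequencies matching the
pooled arm sizes, and an outcome built from a linear predictor plus a
mixture error — 90% N(0, 3.3²), 10% scaled t(2) — so that residual
normality tests reject, as they do in real cognitive-score data.  The
default treatment effect is 0 (the null an equivalence-style trial
expects); the generating coefficients are fixed constants of the
module.  It is a synthetic stand-in: it reproduces marginal shapes and
the error mixture, not the correlation structure, missingness, or
centre-by-arm idiosyncrasies of any real trial, so tests that pass on
it demonstrate algorithmic behaviour, not clinical validity.

## Problem sizes used in the shipped checks

The test suite runs the benchmark at R = 100 replications per
contamination level, and the bootstrap-coverage check at 150 outer
replications × B = 150 resamples on the clean design (the monitored
coefficient is the first dummy indicator, a binary covariate standing
in for a treatment arm).  The acceptance script uses R = 100 and a
100 × 120 coverage study.  These sizes give Monte-Carlo standard
errors of about 7% on an SD cell and about 1.8 points on a coverage
percentage.

## Known limitations

* The objective is non-convex; all convergence statements are local.
  The MM start makes the reached maximum reliably the robust one in
  our experiments, but no global guarantee exists.
* The determinant criterion uses an estimated, noisy sandwich; the
  selected γ scatters over roughly a factor of three between
  replications.  The variance curve is flat near its minimum, so the
  effect on the estimates is small.
* Sandwich-based Wald intervals are deliberately not exposed; only
  bootstrap intervals are provided.
* Heteroscedastic or dependent errors are outside the model; the
  generator and the theory both assume i.i.d. errors independent of
  the covariates.
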