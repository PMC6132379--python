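# Methods

## Model and estimator

The package estimates the sparse linear model `y = Xβ₀ + ε` with `n`
observations and `p` covariates, `p < n` but growing with `n` (the regime of
interest is `p = O(√n)`).  The first `k` coefficients are nonzero, the rest
are zero; the errors are i.i.d. with no moment assumptions beyond those the
chosen loss requires.

Estimation is penalized M-estimation.  For a convex residual loss `ρ` with
score (subderivative) `φ`, the one-step LLA estimator solves

    β̂ = argmin_β (1/n) Σᵢ ρ(yᵢ − xᵢᵀβ) + Σⱼ wⱼ |βⱼ|,   wⱼ = p′_λ(|β̃ⱼ|),

where `p_λ` is the SCAD penalty (shape `a`, default 3.7 — the standard
choice motivated by Bayes-risk arguments) and `β̃` the non-penalized pilot
M-estimate with the same loss.  The LLA weights are computed **once** at the
pilot; an iterate-until-stable mode exists (`lla_fit(..., iterate=True)`)
but is off by default, since the one-step estimator is the defined object
and already enjoys the oracle property.  With convex `ρ` the weighted
problem is convex, so the computed minimizer is global.

Supported losses and their scores:

| family   | ρ(r)                          | φ(r)                | parameters |
|----------|-------------------------------|---------------------|------------|
| lad      | \|r\|                         | sign(r)             | —          |
| quantile | αr⁺ + (1−α)(−r)⁺              | α·1{r>0} − (1−α)·1{r<0} | α ∈ (0,1) |
| huber    | r²/2 (\|r\|≤c), c\|r\|−c²/2   | clip(r, −c, c)      | c > 0      |
| lq       | \|r\|^q                       | q\|r\|^{q−1}sign(r) | q ∈ [1,2]  |
| ols      | r²                            | 2r                  | —          |

At kinks the score uses the midpoint of the subdifferential (0 for LAD,
α − 1/2 for the check loss).  LAD is implemented as its own family rather
than aliased to `quantile(α=1/2)`; the two are proportional (factor 1/2) and
the proportionality is tested.  The Huber knot defaults to `c = 1.345`, the
classical constant giving 95% efficiency under Gaussian errors; it is a free
parameter of `LossSpec`.

No intercept is added and no column standardization is applied by default,
matching the mean-zero generator; `add_constant=True` on the model inserts
one explicitly for real data.

## Solvers and numerical choices

* **LAD / quantile (and L₁):** exact linear program.  Residuals are split as
  `r = u − v` and coefficients as `β = β⁺ − β⁻` (all nonnegative), making
  the weighted-ℓ1 term linear; HiGHS solves the LP (presolve disabled — it
  is a net cost on these dense equality-constrained instances).  Basic
  solutions carry exact zeros.
* **Huber / OLS:** FISTA with soft-thresholding by `step · wⱼ`,
  `step = n / (Lip(φ) · λ_max(XᵀX))`.  Convergence is declared when the
  fixed-point residual of the prox-gradient map falls below
  `1e-10 · max(1, ‖β‖_∞)` (an optimality certificate, tighter than an
  objective-change rule), capped at 10⁴ iterations; non-convergence is
  flagged on the result, never silent.
* **L_q, 1 < q < 2:** the gradient is not Lipschitz at 0, so the split
  formulation is minimized by L-BFGS-B under nonnegativity bounds.
* **Zero threshold:** `|βⱼ| < 1e-8 · max(1, ‖β̂‖_∞)` snaps to exactly 0 —
  far below any signal scale in the study (smallest signal 1.0).
* **Pilot:** the unpenalized fit (`w = 0`) via the same machinery; plain
  least squares for `ols`.  A rank-deficient design falls back to a
  ridge-stabilized IRLS pilot (ridge `1e-6 · tr(XᵀX)/p`) with a warning;
  the penalized problem itself is never modified.  `n ≤ p` is rejected.
* **Optimality certificate:** `subgradient_gap` computes, per coordinate,
  the interval sum of `−xᵢⱼ·[φ₋(rᵢ), φ₊(rᵢ)]/n` and measures how far
  `−wⱼ·sign(βⱼ)` (or the interval `[−wⱼ, wⱼ]` at zero coordinates) falls
  outside it.  Residuals within `1e-7 · max(1, ‖y‖_∞)` of zero are treated
  as exact kinks, since LP solutions zero them only to solver precision.
  The condition is necessary at any optimum; global optimality is verified
  separately against exhaustive-grid search on small fixtures.

Two degenerate-input conventions are worth noting.  At `λ = λ_max` the zero
vector satisfies stationarity with *equality*, so the objective is flat
along one coordinate and the LP may return a tied nonzero vertex; tests
assert optimality of 0 rather than uniqueness.  On near-flat valleys the
exhaustive-grid argmin is itself not unique, so solver-vs-grid agreement is
asserted as "at least as good an objective, within two grid steps per
coordinate".

## Tuning

λ is selected by BIC over a data-driven grid:

* `BIC(λ) = ln(max(avg loss, 1e-12)) + df·ln(n)/n`, with `df` the number of
  nonzero coefficients (generalized degrees of freedom) and the `1e-12`
  clamp keeping perfect toy fits finite;
* grid: 50 log-spaced points spanning three decades below
  `λ_max = max_j (1/n)|Σᵢ xᵢⱼ φ(yᵢ)|`, the smallest λ at which the all-zero
  vector is stationary under constant weights;
* the pilot is computed once per dataset and shared across the grid
  (one-step semantics); ties in BIC go to the larger λ, i.e. the sparser
  model, and selection is invariant to grid ordering.

The Lasso baseline uses squared loss with constant weights λ and the same
BIC rule on the squared-loss scale.  This keeps the baseline internally
consistent; published Lasso rows obtained with other tuning procedures need
not match.

## Synthetic data

The generator reproduces the study conditions exactly: rows of `X` i.i.d.
`N(0, Σ)` with `Σᵢⱼ = 0.5^{|i−j|}` (via the Cholesky factor applied to
standard normals), `β₀ = (−2, 2.5, 3, −1, 0, …, 0)`, `p = [2√n]` with
*half-up* rounding (floor would give 44/52 instead of 45/53 at n = 500/700),
and errors from `N(0,1)`, Student `t₅` (used raw, variance 5/3, no
rescaling), or the contaminated mixture `0.9·N(0,1) + 0.1·N(0,9)` with
"N(0,9)" read as variance 9 (sd 3).  Replicate `r` of a study seeded with
`s` uses the stream `SeedSequence([s, r])`, so replicates are independent
and every table is a deterministic function of the master seed.

What the generator does **not** emulate: heteroscedastic or dependent
errors, heavy-tailed or non-Gaussian designs, intercepts, and measurement
error in `X`.  Passing tests therefore demonstrate correctness of the
estimator and its implementation under the stated design, not robustness to
those departures.

## Simulation study and metrics

`run_experiment` compares three methods per setting — the one-step LLA
estimator (BIC-tuned), the Lasso baseline, and the infeasible Oracle
(unpenalized M-fit on the true support, off-support coefficients exactly
zero) — over seeded replicates, reporting EE (median ‖β̂−β₀‖₂), PE (median
n⁻¹‖y−Xβ̂‖²), C and IC (mean counts of correctly/incorrectly zeroed
coefficients) and CP = 100·C/(p−k).  Medians use the midpoint convention
for even replicate counts.  Failed replicates are excluded with a logged
count, never silently dropped.  The default replicate count is 500; the
end-to-end checks and the reproduction script use 100 replicates per
setting, which keeps each setting within minutes on one CPU at Monte-Carlo
noise well below the one-percentage-point assertion bands.

## Empirical theory checks

Two asymptotic properties are verified by simulation rather than proof:

* **Rate:** at fixed `p = 8`, LAD loss and `N(0,1)` errors, the median
  `‖β̂−β₀‖` over 200 replicates should shrink by ≈ 2.0 per fourfold increase
  of `n` (checked band [1.6, 2.6]) across `n ∈ {100, 400, 1600}`.  Here λ
  follows the deterministic decay `λₙ = √(ln n / n)` — satisfying the
  required `λₙ → 0` — rather than a per-replicate BIC search, which would
  multiply the cost ~50-fold without changing the rate.
* **Asymptotic normality of the oracle refit:** for the LAD refit on the
  true support at `n = 500`, the statistic
  `z = √n · u'(β̂₍₁₎−β₀₍₁₎)/sₙ` with `u = e₁` and
  `sₙ² = σ²γ⁻²·u'D₁₁⁻¹u` (`D₁₁ = X₍₁₎ᵀX₍₁₎/n` realized per replicate) is
  approximately standard normal; empirical 95% CI coverage over 500
  replicates must fall in [0.92, 0.98].  For LAD under `N(0,1)` errors the
  score moments are `σ² = E[sign²(ε)] = 1` and `γ = 2f(0) = √(2/π) ≈
  0.79788`; the `γ⁻²` scaling is the classical M-estimation sandwich.

## Known limitations

* The printed EE/PE columns of the reference tables are on a scale
  inconsistent with their stated definitions (values near 10–24 where the
  definitions give ≈ 0.2–1); the definitions are implemented as stated and
  EE/PE magnitudes are not matched against those tables.
* `p ≥ n` problems are out of scope (no screening step is provided).
* The LP route scales as a dense `n×(2n+2p)` program; for `n` in the tens
  of thousands a specialized quantile-regression solver would be
  preferable.
* Only one-step (optionally iterated) LLA is provided; direct nonconvex
  SCAD optimization is intentionally absent.
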