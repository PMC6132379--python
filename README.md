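# robsel — robust variable selection in high-dimensional linear models

`robsel` implements penalized M-estimation for the sparse linear model
`y = Xβ + ε` when the number of covariates `p` grows with the sample size
(`p = O(√n)`) and most coefficients are zero.  It targets settings where
least squares is a poor choice — heavy-tailed or contaminated errors — by
letting the residual loss be any of the classical convex robust losses:
least absolute deviation (LAD), the quantile check loss, Huber, or `L_q`
(`1 ≤ q ≤ 2`).

## The estimator

The fitted coefficient vector solves the convex program

    β̂ = argmin_β  (1/n) Σᵢ ρ(yᵢ − xᵢᵀβ)  +  Σⱼ p′_λ(|β̃ⱼ|) · |βⱼ|

where `ρ` is the chosen loss, `p_λ` is the SCAD penalty with shape `a = 3.7`,
and `β̃` is the **non-penalized pilot** M-estimate of the same loss.  This is
the one-step local linear approximation (LLA) of the SCAD-penalized
objective: the nonconvex penalty is replaced by its tangent line at the
pilot, giving a weighted-ℓ1 problem.  Because `p′_λ` vanishes beyond `aλ`,
coefficients with large pilot values are left unshrunk while the rest
receive (up to) the full lasso weight — the mechanism behind the estimator's
oracle property: with probability tending to one it selects exactly the true
support and estimates the nonzero part as efficiently as if the support were
known.

Piecewise-linear losses (LAD/quantile) are solved exactly as a linear
program (HiGHS), smooth losses by accelerated proximal gradient; the tuning
parameter λ is selected by BIC with generalized degrees of freedom,

    BIC(λ) = ln( (1/n) Σᵢ ρ(yᵢ − xᵢᵀβ̂_λ) ) + |Â_λ| · ln(n)/n.

## Worked example

```python
import numpy as np
from robsel import PenalizedMRegression, SimConfig, make_dataset

X, y, beta0 = make_dataset(SimConfig(n=200, error_dist="mixture", seed=42))
res = PenalizedMRegression(y, X, loss="lad").fit()   # BIC-tuned one-step LLA
print(res.summary())
```

```
Penalized M-Regression Results (one-step LLA, SCAD)
=======================================================
Loss family:       lad
No. observations:  200
No. covariates:    28
SCAD a:            3.7
lambda:            0.242916  (BIC-selected)
Active set size:   4
Objective:         0.913599
Converged:         True
-------------------------------------------------------
        coef      estimate   active
          x1     -1.918248      yes
          x2      2.646475      yes
          x3      2.706560      yes
          x4     -1.016822      yes
          x5      0.000000
...
```

Here the data have 28 covariates of which only the first four matter
(true values −2, 2.5, 3, −1) and 10% of the errors are drawn from the
wide contaminating component.  The BIC-selected fit recovers exactly the
four signal coefficients, with all 24 noise coefficients estimated as
exactly zero.

The same machinery runs from the shell:

```bash
robsel make-data --n 200 --error mixture --seed 42 --out-prefix data
robsel fit --x data.X.csv --y data.y.csv --loss lad --bic --out fit.json
robsel run-sim --loss lad --error normal --n 200 --reps 500 --seed 1 --out table.csv
```

`run-sim` reproduces the Monte-Carlo comparison of the LLA estimator with
the Lasso and the infeasible Oracle benchmark (the unpenalized fit on the
true support), reporting the median estimation error (EE), median prediction
error (PE), and the average counts of correctly/incorrectly zeroed
coefficients (C, IC) with the percentage CP = 100·C/(p−k).

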