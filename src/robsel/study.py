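"""Empirical property studies of the one-step LLA estimator.

These routines measure, by seeded Monte-Carlo simulation, the finite-sample
behaviour that the estimator's asymptotic theory predicts:

* root-(n/p) consistency — the estimation error ||beta_hat - beta0|| should
  halve for every fourfold increase of n at fixed p;
* the oracle property — the refit on the true support is asymptotically
  normal with the classical M-estimation sandwich variance, so the
  standardized statistic should give nominal confidence-interval coverage.

For the rate study the tuning parameter follows the deterministic decay
lambda_n = sqrt(ln n / n) (one LLA fit per replicate), which satisfies the
lambda_n -> 0 requirement without a per-replicate grid search.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from .losses import LossSpec
from .penalty import SCADPenalty
from .simulate import SimConfig, child_rng, make_dataset
from .solvers import lla_fit
from .experiment import oracle_fit

__all__ = ["rate_medians", "rate_ratios", "oracle_refit_coverage", "GAMMA_LAD_NORMAL"]

# gamma = 2 * f(0) for the LAD score under N(0,1) errors: 2/sqrt(2*pi)
GAMMA_LAD_NORMAL = 0.79788


def rate_medians(ns=(100, 400, 1600), p: int = 8, n_reps: int = 200,
                 seed: int = 0, loss: LossSpec = LossSpec("lad")) -> dict[int, float]:
    """Median ||beta_hat - beta0||_2 of the LLA fit at each sample size.

    Fixed p, N(0,1) errors, lambda_n = sqrt(ln n / n).
    """
    out: dict[int, float] = {}
    for n in ns:
        lam = float(np.sqrt(np.log(n) / n))
        errs = np.empty(n_reps)
        for r in range(n_reps):
            rng = child_rng(seed + n, r)
            X, y, beta0 = make_dataset(SimConfig(n=n, p=p, error_dist="normal"), rng=rng)
            fit = lla_fit(loss, SCADPenalty(lam=lam), X, y)
            errs[r] = np.linalg.norm(fit.beta - beta0)
        out[n] = float(np.median(errs))
    return out


def rate_ratios(medians: dict[int, float]) -> list[float]:
    """Error-shrink factors between consecutive sample sizes (theory: 2.0
    per 4x increase of n)."""
    ns = sorted(medians)
    return [medians[a] / medians[b] for a, b in zip(ns, ns[1:])]


def oracle_refit_coverage(n: int = 500, n_reps: int = 500, seed: int = 0,
                          level: float = 0.95,
                          gamma: float = GAMMA_LAD_NORMAL,
                          sigma2: float = 1.0) -> float:
    """Empirical CI coverage of the oracle-support LAD refit.

    For each replicate the statistic

        z = sqrt(n) * u'(beta_hat_(1) - beta0_(1)) / s_n,
        s_n^2 = sigma^2 * gamma^{-2} * u' D11^{-1} u,   u = e_1,

    with D11 = X_(1)'X_(1)/n the realized support Gram matrix, is compared
    with the standard normal quantile; the fraction of |z| below it is
    returned.  gamma = 2 f_eps(0) and sigma^2 = E[phi^2(eps)] are the score
    moments (0.79788 and 1 for LAD with N(0,1) errors).
    """
    loss = LossSpec("lad")
    zcrit = stats.norm.ppf(0.5 + level / 2)
    u_first = 0
    hits = 0
    for r in range(n_reps):
        rng = child_rng(seed, r)
        X, y, beta0 = make_dataset(SimConfig(n=n, error_dist="normal"), rng=rng)
        supp = np.flatnonzero(beta0 != 0)
        fit = oracle_fit(loss, X, y, supp)
        X1 = X[:, supp]
        D11 = X1.T @ X1 / n
        e1 = np.zeros(supp.size)
        e1[u_first] = 1.0
        sn2 = sigma2 / gamma**2 * float(e1 @ np.linalg.solve(D11, e1))
        z = np.sqrt(n) * float((fit.beta[supp] - beta0[supp]) @ e1) / np.sqrt(sn2)
        hits += abs(z) <= zcrit
    return hits / n_reps
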