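"""Solvers for the LLA-penalized M-estimation objective.

The objective is

    Q_n(b) = (1/n) sum_i rho(y_i - x_i'b) + sum_j w_j |b_j|,

with nonnegative weights ``w_j`` (in the one-step LLA these are the SCAD
derivative evaluated at a non-penalized pilot estimate).  Because rho is
convex the objective is convex and every local minimizer is global.

Two solver routes are used:

* piecewise-linear losses (LAD, quantile, Lq with q=1) are cast as a linear
  program by residual splitting (r = u - v) and coefficient splitting
  (b = b+ - b-), solved with HiGHS; basic solutions carry exact zeros;
* smooth losses with Lipschitz score (Huber, OLS, Lq with q=2) are solved by
  accelerated proximal gradient (FISTA) with soft-thresholding; Lq with
  1 < q < 2 (non-Lipschitz gradient at 0) by L-BFGS-B on the split
  coefficients.

Coefficients below ``1e-8 * max(1, ||b||_inf)`` are snapped to exactly 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import sparse
from scipy.optimize import linprog, minimize

from .losses import LossSpec
from .penalty import SCADPenalty

__all__ = [
    "FitResult",
    "PilotEstimate",
    "fit_unpenalized",
    "fit_weighted_l1",
    "lla_fit",
    "brute_force_objective_min",
    "objective_value",
    "subgradient_gap",
]

ZERO_TOL = 1e-8
FISTA_MAXIT = 10_000


@dataclass
class PilotEstimate:
    """Non-penalized M-estimate used to build LLA weights."""

    beta_tilde: np.ndarray
    loss: LossSpec


@dataclass
class FitResult:
    """Result of a (possibly weighted-L1 penalized) M-estimation fit.

    ``beta`` is zero-thresholded: every index outside ``active_set`` holds an
    exact 0.  ``objective`` is Q_n re-evaluated at ``beta``.
    """

    beta: np.ndarray
    active_set: np.ndarray
    objective: float
    converged: bool
    iterations: int
    solver: str
    weights: Optional[np.ndarray] = None
    pilot: Optional[PilotEstimate] = None


def objective_value(loss: LossSpec, X, y, beta, w=None) -> float:
    """Evaluate Q_n(beta) = mean loss + weighted-L1 penalty."""
    beta = np.asarray(beta, dtype=float)
    r = np.asarray(y, dtype=float) - np.asarray(X, dtype=float) @ beta
    val = float(np.mean(loss.value(r)))
    if w is not None:
        val += float(np.sum(np.asarray(w, dtype=float) * np.abs(beta)))
    return val


def _snap_zeros(beta: np.ndarray) -> np.ndarray:
    scale = float(np.max(np.abs(beta))) if beta.size else 0.0
    thr = ZERO_TOL * max(1.0, scale)
    out = beta.copy()
    out[np.abs(out) < thr] = 0.0
    return out


def _result(loss, X, y, beta, w, converged, iterations, solver, pilot=None) -> FitResult:
    beta = _snap_zeros(np.asarray(beta, dtype=float))
    active = np.flatnonzero(beta != 0.0)
    obj = objective_value(loss, X, y, beta, w)
    return FitResult(
        beta=beta,
        active_set=active,
        objective=obj,
        converged=converged,
        iterations=iterations,
        solver=solver,
        weights=None if w is None else np.asarray(w, dtype=float),
        pilot=pilot,
    )


# --------------------------------------------------------------------- LP route
def _solve_lp(loss: LossSpec, X, y, w) -> tuple[np.ndarray, bool, int]:
    """Weighted-L1 fit for piecewise-linear losses as a HiGHS LP.

    Variables (b+, b-, u, v), all >= 0, with X(b+ - b-) + u - v = y.
    LAD residual cost is (u+v)/n; the check loss costs alpha*u + (1-alpha)*v
    per unit (u is the positive residual part).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if loss.family == "quantile":
        cu, cv = loss.alpha / n, (1.0 - loss.alpha) / n
    else:  # lad or lq q=1
        cu = cv = 1.0 / n
    w = np.asarray(w, dtype=float)
    c = np.concatenate([w, w, np.full(n, cu), np.full(n, cv)])
    A = sparse.hstack(
        [sparse.csr_matrix(X), -sparse.csr_matrix(X),
         sparse.eye(n, format="csr"), -sparse.eye(n, format="csr")],
        format="csr",
    )
    res = linprog(c, A_eq=A, b_eq=y, bounds=(0, None), method="highs",
                  options={"presolve": False})
    if res.status != 0:
        return np.zeros(p), False, int(getattr(res, "nit", 0))
    beta = res.x[:p] - res.x[p:2 * p]
    return beta, True, int(getattr(res, "nit", 0))


# ------------------------------------------------------------------ FISTA route
def _solve_fista(loss: LossSpec, X, y, w, beta0=None) -> tuple[np.ndarray, bool, int]:
    """Accelerated proximal gradient for smooth losses with Lipschitz score."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    w = np.asarray(w, dtype=float)
    lip = loss.score_lipschitz
    assert lip is not None
    # largest eigenvalue of X'X/n times Lip(phi) bounds the gradient Lipschitz constant
    smax = np.linalg.norm(X, 2)
    L = lip * smax * smax / n
    step = 1.0 / L

    def grad(b):
        return -(X.T @ loss.score(y - X @ b)) / n

    def prox(b):
        return np.sign(b) * np.maximum(np.abs(b) - step * w, 0.0)

    beta = np.zeros(p) if beta0 is None else np.asarray(beta0, dtype=float).copy()
    z = beta.copy()
    t = 1.0
    for it in range(1, FISTA_MAXIT + 1):
        beta_new = prox(z - step * grad(z))
        t_new = 0.5 * (1.0 + np.sqrt(1.0 + 4.0 * t * t))
        z = beta_new + ((t - 1.0) / t_new) * (beta_new - beta)
        beta, t = beta_new, t_new
        # fixed-point residual of the prox-gradient map certifies optimality
        resid = np.max(np.abs(beta - prox(beta - step * grad(beta))))
        if resid <= 1e-10 * max(1.0, float(np.max(np.abs(beta)))):
            return beta, True, it
    return beta, False, FISTA_MAXIT


# ---------------------------------------------------------------- L-BFGS route
def _solve_split_lbfgs(loss: LossSpec, X, y, w) -> tuple[np.ndarray, bool, int]:
    """Split-coefficient L-BFGS-B for smooth losses without a Lipschitz score
    (Lq with 1 < q < 2); the weighted-L1 term is linear on (b+, b-) >= 0."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    w = np.asarray(w, dtype=float)

    def fun(z):
        bp, bm = z[:p], z[p:]
        b = bp - bm
        r = y - X @ b
        f = float(np.mean(loss.value(r))) + float(w @ (bp + bm))
        g_b = -(X.T @ loss.score(r)) / n
        return f, np.concatenate([g_b + w, -g_b + w])

    z0 = np.zeros(2 * p)
    res = minimize(fun, z0, jac=True, method="L-BFGS-B",
                   bounds=[(0, None)] * (2 * p),
                   options={"maxiter": FISTA_MAXIT, "ftol": 1e-14, "gtol": 1e-10})
    beta = res.x[:p] - res.x[p:]
    return beta, bool(res.success), int(res.nit)


# -------------------------------------------------------------- ridge IRLS pilot
def _irls_ridge(loss: LossSpec, X, y, delta, max_iter=200, tol=1e-10) -> np.ndarray:
    """Ridge-stabilized pilot fit by iteratively reweighted least squares.

    Minimizes mean rho(y - Xb) + delta ||b||^2 using the score-ratio weights
    phi(r)/r; used only when X is rank deficient.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    beta = np.linalg.solve(X.T @ X / n + 2 * delta * np.eye(p), X.T @ y / n)
    for _ in range(max_iter):
        r = y - X @ beta
        with np.errstate(divide="ignore", invalid="ignore"):
            wt = np.asarray(loss.score(r), dtype=float) / r
        wt[~np.isfinite(wt)] = _score_ratio_at_zero(loss)
        A = (X.T * wt) @ X / n + 2 * delta * np.eye(p)
        b = (X.T @ (wt * y)) / n
        beta_new = np.linalg.solve(A, b)
        if np.max(np.abs(beta_new - beta)) < tol * max(1.0, np.max(np.abs(beta))):
            return beta_new
        beta = beta_new
    return beta


def _score_ratio_at_zero(loss: LossSpec) -> float:
    # limit of phi(r)/r as r -> 0 where finite, else a large capped value
    if loss.family in ("huber",):
        return 1.0
    if loss.family == "ols" or (loss.family == "lq" and loss.q == 2.0):
        return 2.0
    return 1e8


# ------------------------------------------------------------------- public API
def fit_unpenalized(loss: LossSpec, X, y) -> PilotEstimate:
    """Non-penalized M-estimate: argmin (1/n) sum rho(y_i - x_i'b).

    This is the pilot at which the LLA weights are evaluated.  Requires
    n > p (the method targets the p = O(sqrt(n)) regime); a rank-deficient
    design falls back to a ridge-stabilized fit with a warning.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be a 2-D design matrix")
    n, p = X.shape
    if n <= p:
        raise ValueError(f"need n > p for the non-penalized pilot (got n={n}, p={p})")
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
        raise ValueError("X and y must be finite")
    if np.linalg.matrix_rank(X) < p:
        delta = 1e-6 * np.trace(X.T @ X) / p
        warnings.warn("design matrix is rank deficient; pilot uses a ridge-stabilized fit")
        beta = _irls_ridge(loss, X, y, delta / n)
        return PilotEstimate(beta_tilde=beta, loss=loss)
    if loss.family == "ols" or (loss.family == "lq" and loss.q == 2.0):
        beta = np.linalg.lstsq(X, y, rcond=None)[0]
        return PilotEstimate(beta_tilde=beta, loss=loss)
    fit = fit_weighted_l1(loss, X, y, np.zeros(p), snap=False)
    return PilotEstimate(beta_tilde=fit.beta, loss=loss)


def fit_weighted_l1(loss: LossSpec, X, y, w, snap=True) -> FitResult:
    """Global minimizer of (1/n) sum rho(y_i - x_i'b) + sum_j w_j |b_j|."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    w = np.atleast_1d(np.asarray(w, dtype=float))
    n, p = X.shape
    if w.shape != (p,):
        raise ValueError(f"weights must have length p={p}, got shape {w.shape}")
    if np.any(w < 0) or not np.all(np.isfinite(w)):
        raise ValueError("weights must be finite and nonnegative")

    if loss.is_piecewise_linear:
        beta, ok, nit = _solve_lp(loss, X, y, w)
        tag = "highs-lp"
    elif loss.score_lipschitz is not None:
        beta, ok, nit = _solve_fista(loss, X, y, w)
        tag = "fista"
    else:
        beta, ok, nit = _solve_split_lbfgs(loss, X, y, w)
        tag = "lbfgsb-split"
    if not ok:
        warnings.warn(f"{tag} solver did not report convergence")
    if not snap:
        active = np.flatnonzero(beta != 0.0)
        return FitResult(beta=beta, active_set=active,
                         objective=objective_value(loss, X, y, beta, w),
                         converged=ok, iterations=nit, solver=tag,
                         weights=w)
    return _result(loss, X, y, beta, w, ok, nit, tag)


def lla_fit(loss: LossSpec, pen: SCADPenalty, X, y,
            pilot: Optional[PilotEstimate] = None,
            iterate: bool = False, max_steps: int = 20,
            tol: float = 1e-8) -> FitResult:
    """One-step LLA estimator.

    Computes LLA weights ``w_j = p'_lam(|pilot_j|)`` at the non-penalized
    pilot (fitted with the same loss when not supplied) and solves the
    resulting convex weighted-L1 problem.  ``iterate=True`` re-evaluates the
    weights at successive estimates until the coefficient vector stabilizes
    (off by default: the one-step estimator is the object of interest).
    """
    X = np.asarray(X, dtype=float)
    if pilot is None:
        pilot = fit_unpenalized(loss, X, y)
    w = pen.lla_weights(pilot.beta_tilde)
    fit = fit_weighted_l1(loss, X, y, w)
    fit.pilot = pilot
    if iterate:
        for _ in range(max_steps - 1):
            w = pen.lla_weights(fit.beta)
            fit_new = fit_weighted_l1(loss, X, y, w)
            fit_new.pilot = pilot
            if np.max(np.abs(fit_new.beta - fit.beta)) < tol:
                return fit_new
            fit = fit_new
    return fit


def brute_force_objective_min(loss: LossSpec, pen_weights, X, y,
                              box: float = 3.0, step: float = 0.01) -> np.ndarray:
    """Exhaustive grid minimizer of the weighted-L1 objective (test oracle).

    Searches the cube [-box, box]^p at the given step.  Refuses p > 3: the
    cost grows as (2*box/step)^p.
    """
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if p > 3:
        raise ValueError(f"brute force search is limited to p <= 3, got p={p}")
    w = np.atleast_1d(np.asarray(pen_weights, dtype=float))
    y = np.asarray(y, dtype=float)
    axis = np.arange(-box, box + step / 2, step)
    grids = np.meshgrid(*([axis] * p), indexing="ij")
    B = np.stack([g.ravel() for g in grids], axis=1)  # (m, p)
    best_val, best_idx = np.inf, 0
    chunk = max(1, 2_000_000 // max(1, X.shape[0]))
    for start in range(0, B.shape[0], chunk):
        Bc = B[start:start + chunk]
        R = y[None, :] - Bc @ X.T
        obj = np.mean(loss.value(R), axis=1) + np.abs(Bc) @ w
        i = int(np.argmin(obj))
        if obj[i] < best_val:
            best_val, best_idx = float(obj[i]), start + i
    return B[best_idx]


def subgradient_gap(loss: LossSpec, X, y, w, beta, kink_tol: float = 1e-7) -> float:
    """Max coordinatewise violation of the first-order optimality condition.

    For each j the subdifferential of the data term along coordinate j is the
    interval sum of ``-x_ij * [phi-(r_i), phi+(r_i)] / n``.  Optimality
    requires -w_j*sign(beta_j) (or any point of [-w_j, w_j] when beta_j = 0)
    to fall inside it; the returned gap is the largest distance by which that
    fails (0 at an exact optimum).

    Residuals within ``kink_tol * max(1, ||y||_inf)`` of zero are treated as
    sitting exactly at a kink (LP basic solutions zero them only to solver
    precision).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    beta = np.asarray(beta, dtype=float)
    w = np.atleast_1d(np.asarray(w, dtype=float))
    n = X.shape[0]
    r = y - X @ beta
    r = np.where(np.abs(r) < kink_tol * max(1.0, float(np.max(np.abs(y)))), 0.0, r)
    lo_s, hi_s = loss.score_interval(r)
    # interval for g_j = -(1/n) sum_i x_ij * phi(r_i)
    neg = -X / n
    lo = np.where(neg >= 0, neg * lo_s[:, None], neg * hi_s[:, None]).sum(axis=0)
    hi = np.where(neg >= 0, neg * hi_s[:, None], neg * lo_s[:, None]).sum(axis=0)
    target = np.where(beta > 0, -w, np.where(beta < 0, w, 0.0))
    slack = np.where(beta == 0, w, 0.0)
    gap = np.maximum(lo - (target + slack), (target - slack) - hi)
    return float(np.max(np.maximum(gap, 0.0)))
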