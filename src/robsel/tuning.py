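"""BIC selection of the SCAD tuning parameter lambda.

The criterion scored on each penalized fit is

    BIC(lam) = ln( (1/n) sum_i rho(y_i - x_i' beta_hat) ) + DF_lam * ln(n)/n

where DF_lam is the generalized degrees of freedom — the number of nonzero
estimated coefficients.  The pilot estimate is computed once per dataset and
shared across the whole lambda grid, matching the one-step LLA semantics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .losses import LossSpec
from .penalty import SCADPenalty, DEFAULT_A
from .solvers import FitResult, PilotEstimate, fit_unpenalized, lla_fit

__all__ = ["BICRecord", "bic_score", "lambda_grid", "select_by_bic"]

LOG_CLAMP = 1e-12  # keeps BIC finite on perfect fits
GRID_DECADES = 3
GRID_SIZE = 50


@dataclass
class BICRecord:
    """BIC bookkeeping for one lambda on the grid."""

    lam: float
    score: float
    df: int
    fit: FitResult


def bic_score(loss: LossSpec, X, y, fit: FitResult) -> float:
    """BIC of a fit: log average loss plus df * ln(n)/n."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = X.shape[0]
    avg = float(np.mean(loss.value(y - X @ fit.beta)))
    df = int(fit.active_set.size)
    return float(np.log(max(avg, LOG_CLAMP)) + df * np.log(n) / n)


def lambda_grid(loss: LossSpec, X, y, n_grid: int = GRID_SIZE) -> np.ndarray:
    """Decreasing log-spaced grid on [lam_max/10^3, lam_max].

    lam_max = max_j (1/n) |sum_i x_ij * phi(y_i)| is the smallest lambda at
    which the all-zero vector is stationary when every weight equals lambda.
    """
    if n_grid < 2:
        raise ValueError("n_grid must be at least 2")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = X.shape[0]
    lam_max = float(np.max(np.abs(X.T @ loss.score(y))) / n)
    if lam_max <= 0:
        warnings.warn("degenerate response (score vanishes at beta=0); single-point grid")
        return np.array([1.0])
    return np.geomspace(lam_max, lam_max / 10.0**GRID_DECADES, n_grid)


def select_by_bic(
    loss: LossSpec,
    X,
    y,
    grid: Optional[Sequence[float]] = None,
    a: float = DEFAULT_A,
    pilot: Optional[PilotEstimate] = None,
) -> tuple[SCADPenalty, FitResult, list[BICRecord]]:
    """Fit the one-step LLA estimator on a lambda grid and pick by BIC.

    A single pilot is fitted once and reused for every lambda.  Ties in the
    BIC score go to the larger lambda (the sparser model); the result is
    invariant to the ordering of the supplied grid.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if grid is None:
        grid = lambda_grid(loss, X, y)
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("lambda grid is empty")
    if pilot is None:
        pilot = fit_unpenalized(loss, X, y)

    records: list[BICRecord] = []
    failures: list[tuple[float, Exception]] = []
    for lam in grid:
        pen = SCADPenalty(lam=float(lam), a=a)
        try:
            fit = lla_fit(loss, pen, X, y, pilot=pilot)
        except Exception as exc:  # pragma: no cover - defensive
            failures.append((float(lam), exc))
            continue
        records.append(BICRecord(lam=float(lam), score=bic_score(loss, X, y, fit),
                                 df=int(fit.active_set.size), fit=fit))
    if not records:
        raise RuntimeError(f"all {len(failures)} lambda fits failed; first: {failures[0]}")

    best = records[0]
    for rec in records[1:]:
        if rec.score < best.score - 1e-12:
            best = rec
        elif abs(rec.score - best.score) <= 1e-12 and rec.lam > best.lam:
            best = rec
    return SCADPenalty(lam=best.lam, a=a), best.fit, records
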