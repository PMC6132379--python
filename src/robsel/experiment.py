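"""Monte-Carlo comparison of LLA, Lasso and the Oracle benchmark.

For each (sample size, loss, error distribution) setting, ``run_experiment``
draws seeded replicates from the synthetic model, fits the requested
methods, and aggregates five measures across replicates:

* EE — median of ||beta_hat - beta0||_2 (estimation error);
* PE — median of n^{-1} ||y - X beta_hat||^2 (prediction error);
* C  — mean number of true-zero coefficients estimated as exactly zero;
* IC — mean number of true-nonzero coefficients estimated as zero;
* CP — 100 * C / (p - k), the percentage of true zeros correctly found.

Methods:

* ``lla``    — one-step LLA SCAD M-estimator, lambda chosen by BIC;
* ``lasso``  — squared-loss fit with constant L1 weights, same BIC rule;
* ``oracle`` — the infeasible benchmark fitted on the true support only.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .losses import LossSpec
from .penalty import DEFAULT_A
from .simulate import SimConfig, child_rng, make_dataset
from .solvers import FitResult, fit_unpenalized, fit_weighted_l1
from .tuning import lambda_grid, select_by_bic

__all__ = [
    "MetricRow",
    "selection_counts",
    "replicate_metrics",
    "oracle_fit",
    "lasso_baseline",
    "run_experiment",
    "write_table",
    "METHODS",
]

logger = logging.getLogger(__name__)

METHODS = ("oracle", "lasso", "lla")
DEFAULT_REPS = 500


@dataclass
class MetricRow:
    """One (setting x method) row of the results table."""

    n: int
    p: int
    loss: str
    error_dist: str
    method: str
    EE: float
    PE: float
    C: float
    IC: float
    CP: float
    n_reps: int
    n_failed: int = 0


def selection_counts(beta_hat, beta0) -> tuple[int, int]:
    """(C, IC): true zeros estimated as zero, true signals estimated as zero."""
    beta_hat = np.asarray(beta_hat, dtype=float)
    beta0 = np.asarray(beta0, dtype=float)
    if beta_hat.shape != beta0.shape:
        raise ValueError(f"shape mismatch: {beta_hat.shape} vs {beta0.shape}")
    c = int(np.sum((beta0 == 0) & (beta_hat == 0)))
    ic = int(np.sum((beta0 != 0) & (beta_hat == 0)))
    return c, ic


def replicate_metrics(beta_hat, beta0, X, y) -> tuple[float, float, int, int]:
    """Per-replicate terms (ee, pe, C, IC); medians/means are taken downstream."""
    beta_hat = np.asarray(beta_hat, dtype=float)
    beta0 = np.asarray(beta0, dtype=float)
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.shape != (y.size, beta_hat.size):
        raise ValueError("inconsistent shapes among X, y, beta_hat")
    ee = float(np.linalg.norm(beta_hat - beta0))
    resid = y - X @ beta_hat
    pe = float(resid @ resid / y.size)
    c, ic = selection_counts(beta_hat, beta0)
    return ee, pe, c, ic


def oracle_fit(loss: LossSpec, X, y, true_support) -> FitResult:
    """Infeasible benchmark: unpenalized M-fit on the true support columns."""
    X = np.asarray(X, dtype=float)
    support = np.asarray(true_support, dtype=int)
    pilot = fit_unpenalized(loss, X[:, support], y)
    beta = np.zeros(X.shape[1])
    beta[support] = pilot.beta_tilde
    from .solvers import objective_value

    return FitResult(beta=beta, active_set=np.flatnonzero(beta != 0.0),
                     objective=objective_value(loss, X, y, beta),
                     converged=True, iterations=0, solver="oracle")


def lasso_baseline(X, y, grid: Optional[Sequence[float]] = None) -> FitResult:
    """Plain Lasso: squared loss with constant weights lambda, BIC-tuned.

    Solved through the same weighted-L1 machinery with loss="ols"; the BIC
    rule is the squared-loss version of the one used for LLA.
    """
    from .tuning import bic_score  # local import to avoid cycle

    loss = LossSpec(family="ols")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if grid is None:
        grid = lambda_grid(loss, X, y)
    best_fit, best_score, best_lam = None, np.inf, None
    for lam in np.asarray(grid, dtype=float):
        fit = fit_weighted_l1(loss, X, y, np.full(X.shape[1], lam))
        score = bic_score(loss, X, y, fit)
        if score < best_score - 1e-12 or (
            abs(score - best_score) <= 1e-12 and best_lam is not None and lam > best_lam
        ):
            best_fit, best_score, best_lam = fit, score, lam
    assert best_fit is not None
    return best_fit


def _fit_method(method: str, loss: LossSpec, X, y, beta0, a: float) -> np.ndarray:
    if method == "oracle":
        return oracle_fit(loss, X, y, np.flatnonzero(beta0 != 0)).beta
    if method == "lasso":
        return lasso_baseline(X, y).beta
    if method == "lla":
        _, fit, _ = select_by_bic(loss, X, y, a=a)
        return fit.beta
    raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")


def run_experiment(
    settings: Sequence[SimConfig],
    loss: LossSpec,
    methods: Sequence[str] = METHODS,
    n_reps: int = DEFAULT_REPS,
    master_seed: int = 0,
    a: float = DEFAULT_A,
) -> list[MetricRow]:
    """Run the full comparison and return one MetricRow per setting x method.

    Replicate r of every setting draws its data from the child stream
    ``SeedSequence([master_seed + setting_index, r])``; the whole table is a
    deterministic function of ``master_seed``.  A replicate whose fit raises
    is excluded from the aggregates and counted in ``n_failed``.
    """
    rows: list[MetricRow] = []
    for s_idx, cfg in enumerate(settings):
        per_method: dict[str, list[tuple[float, float, int, int]]] = {m: [] for m in methods}
        failed: dict[str, int] = {m: 0 for m in methods}
        for r in range(n_reps):
            rng = child_rng(master_seed + s_idx, r)
            X, y, beta0 = make_dataset(cfg, rng=rng)
            for m in methods:
                try:
                    beta_hat = _fit_method(m, loss, X, y, beta0, a)
                except Exception:
                    logger.exception("replicate %d failed for method %s", r, m)
                    failed[m] += 1
                    continue
                per_method[m].append(replicate_metrics(beta_hat, beta0, X, y))
            logger.debug("setting %d replicate %d/%d done", s_idx, r + 1, n_reps)
        for m in methods:
            vals = np.asarray(per_method[m], dtype=float)
            if vals.size == 0:
                raise RuntimeError(f"all replicates failed for method {m}")
            c_mean = float(np.mean(vals[:, 2]))
            rows.append(MetricRow(
                n=cfg.n, p=cfg.p, loss=loss.family, error_dist=cfg.error_dist,
                method=m,
                EE=float(np.median(vals[:, 0])),
                PE=float(np.median(vals[:, 1])),
                C=c_mean,
                IC=float(np.mean(vals[:, 3])),
                CP=100.0 * c_mean / (cfg.p - cfg.k),
                n_reps=int(vals.shape[0]),
                n_failed=failed[m],
            ))
    return rows


def rows_to_frame(rows: Sequence[MetricRow]) -> pd.DataFrame:
    return pd.DataFrame([asdict(r) for r in rows])


def write_table(rows: Sequence[MetricRow], path) -> None:
    """Write the results as a 4-decimal CSV plus a full-precision JSON twin."""
    if not rows:
        raise ValueError("no rows to write")
    path = Path(path)
    df = rows_to_frame(rows)
    out = df.copy()
    for col in ("EE", "PE", "C", "IC"):
        out[col] = out[col].map(lambda v: f"{v:.4f}")
    out["CP"] = df["CP"].map(lambda v: f"{v:.2f}%")
    out.to_csv(path, index=False)
    path.with_suffix(".json").write_text(json.dumps(
        [asdict(r) for r in rows], indent=2) + "\n")
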