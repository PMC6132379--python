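"""Model/Results interface for the one-step LLA SCAD M-estimator.

The estimator solves

    min_b  (1/n) sum_i rho(y_i - x_i'b) + sum_j p'_lam(|b_tilde_j|) |b_j|,

where rho is a convex loss, p_lam the SCAD penalty and b_tilde the
non-penalized pilot estimate of the same loss.  Because the SCAD derivative
vanishes on large pilot coefficients, strong signals are left unshrunk while
small pilot coefficients receive (up to) the full lasso weight — the
mechanism behind the estimator's oracle behaviour.

The model holds data and configuration; ``fit`` returns a results object
carrying the estimate, its active set, the BIC path when tuned, and a
``summary()`` table.  No intercept and no column standardization are applied
by default (the generator's mean-zero, no-intercept convention); pass
``add_constant=True`` / standardize upstream for real data.
"""

from __future__ import annotations

from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .losses import LossSpec
from .penalty import SCADPenalty, DEFAULT_A
from .solvers import FitResult, PilotEstimate, fit_unpenalized, lla_fit
from .tuning import BICRecord, select_by_bic, lambda_grid

__all__ = ["PenalizedMRegression", "PenalizedMRegressionResults"]


class PenalizedMRegression:
    """Penalized M-estimation of a sparse linear model.

    Parameters
    ----------
    endog : array_like, shape (n,)
        Response vector.
    exog : array_like, shape (n, p)
        Design matrix, no implied intercept column.
    loss : str or LossSpec
        Convex residual loss; one of ``lad`` (default), ``quantile``,
        ``huber``, ``lq``, ``ols``.  Loss parameters (quantile level
        ``alpha``, Huber knot ``c``, power ``q``) are keyword arguments.
    a : float
        SCAD shape parameter (> 2), default 3.7.
    add_constant : bool
        Prepend a column of ones (off by default; the constant is penalized
        like any coefficient unless it survives through the pilot).
    """

    def __init__(self, endog, exog, loss: Union[str, LossSpec] = "lad",
                 a: float = DEFAULT_A, add_constant: bool = False, **loss_kwargs):
        self.loss = loss if isinstance(loss, LossSpec) else LossSpec(family=loss, **loss_kwargs)
        self.endog = np.asarray(endog, dtype=float)
        exog = np.asarray(exog, dtype=float)
        if exog.ndim == 1:
            exog = exog[:, None]
        if add_constant:
            exog = np.column_stack([np.ones(len(exog)), exog])
        self.exog = exog
        self.a = float(a)
        self.exog_names = [f"x{j + 1}" for j in range(exog.shape[1])]
        if add_constant:
            self.exog_names[0] = "const"

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, response: str, **kwargs):
        """Build the model from a DataFrame; all non-response columns are
        covariates, in column order."""
        y = data[response].to_numpy(dtype=float)
        Xdf = data.drop(columns=[response])
        model = cls(y, Xdf.to_numpy(dtype=float), **kwargs)
        names = list(Xdf.columns)
        if kwargs.get("add_constant"):
            names = ["const"] + names
        model.exog_names = [str(c) for c in names]
        return model

    # ------------------------------------------------------------------- fits
    def fit(self, lam: Optional[float] = None,
            grid: Optional[Sequence[float]] = None,
            pilot: Optional[PilotEstimate] = None) -> "PenalizedMRegressionResults":
        """Fit the one-step LLA estimator.

        With ``lam`` given, fits at that fixed tuning parameter; otherwise
        lambda is selected by BIC over ``grid`` (a data-driven log-spaced
        grid when omitted).
        """
        if lam is not None:
            pen = SCADPenalty(lam=float(lam), a=self.a)
            if pilot is None:
                pilot = fit_unpenalized(self.loss, self.exog, self.endog)
            fit = lla_fit(self.loss, pen, self.exog, self.endog, pilot=pilot)
            return PenalizedMRegressionResults(self, fit, pen, records=None)
        pen, fit, records = select_by_bic(self.loss, self.exog, self.endog,
                                          grid=grid, a=self.a, pilot=pilot)
        return PenalizedMRegressionResults(self, fit, pen, records=records)

    def fit_unpenalized(self) -> PilotEstimate:
        """The non-penalized pilot M-estimate of the full model."""
        return fit_unpenalized(self.loss, self.exog, self.endog)


class PenalizedMRegressionResults:
    """Fit results: coefficient estimates, active set, diagnostics."""

    def __init__(self, model: PenalizedMRegression, fit: FitResult,
                 penalty: SCADPenalty, records: Optional[list[BICRecord]]):
        self.model = model
        self._fit = fit
        self.penalty = penalty
        self._records = records

    # -------------------------------------------------------------- accessors
    @property
    def params(self) -> np.ndarray:
        """Estimated coefficient vector (zero-thresholded)."""
        return self._fit.beta

    @property
    def active_set(self) -> np.ndarray:
        """Indices of nonzero estimated coefficients."""
        return self._fit.active_set

    @property
    def objective(self) -> float:
        """Value of the penalized objective at the estimate."""
        return self._fit.objective

    @property
    def df_model(self) -> int:
        return int(self._fit.active_set.size)

    @property
    def converged(self) -> bool:
        return self._fit.converged

    @property
    def pilot(self) -> Optional[PilotEstimate]:
        return self._fit.pilot

    @property
    def bic_path(self) -> Optional[pd.DataFrame]:
        """(lambda, df, BIC) path when lambda was tuned, else None."""
        if self._records is None:
            return None
        return pd.DataFrame({
            "lam": [r.lam for r in self._records],
            "df": [r.df for r in self._records],
            "bic": [r.score for r in self._records],
        })

    def predict(self, exog=None) -> np.ndarray:
        X = self.model.exog if exog is None else np.asarray(exog, dtype=float)
        return X @ self.params

    @property
    def resid(self) -> np.ndarray:
        return self.model.endog - self.predict()

    # ---------------------------------------------------------------- summary
    def summary(self) -> str:
        """Plain-text summary table of the fit."""
        m = self.model
        lines = [
            "Penalized M-Regression Results (one-step LLA, SCAD)",
            "=" * 55,
            f"Loss family:       {m.loss.family}",
            f"No. observations:  {len(m.endog)}",
            f"No. covariates:    {m.exog.shape[1]}",
            f"SCAD a:            {m.a:g}",
            f"lambda:            {self.penalty.lam:.6g}"
            + ("  (BIC-selected)" if self._records is not None else "  (fixed)"),
            f"Active set size:   {self.df_model}",
            f"Objective:         {self.objective:.6g}",
            f"Converged:         {self.converged}",
            "-" * 55,
            f"{'coef':>12}  {'estimate':>12}  {'active':>7}",
        ]
        for j, name in enumerate(m.exog_names):
            act = "yes" if self.params[j] != 0 else ""
            lines.append(f"{name:>12}  {self.params[j]:>12.6f}  {act:>7}")
        lines.append("=" * 55)
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover
        return (f"<PenalizedMRegressionResults loss={self.model.loss.family} "
                f"lam={self.penalty.lam:.4g} df={self.df_model}>")
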