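"""Convex loss families for M-estimation.

M-estimation minimizes an empirical average ``(1/n) sum_i rho(y_i - x_i'b)``
of a convex loss ``rho`` applied to residuals.  The families implemented here
are the classical robust-regression losses:

``lad``
    least absolute deviation, ``rho(r) = |r|``; robust to heavy tails.
``quantile``
    check loss ``rho_a(r) = a*r+ + (1-a)*(-r)+`` whose minimizer estimates
    the ``a``-quantile; ``a = 1/2`` is proportional to LAD (factor 1/2).
``huber``
    quadratic ``r^2/2`` inside ``[-c, c]``, linear ``c|r| - c^2/2`` outside;
    interpolates between OLS and LAD behaviour.
``lq``
    power loss ``|r|^q`` with ``1 <= q <= 2`` (``q=1`` is LAD, ``q=2`` OLS).
``ols``
    squared error ``r^2``.

Each :class:`LossSpec` evaluates the loss (:meth:`LossSpec.value`) and a
score, i.e. an element of the subdifferential (:meth:`LossSpec.score`), both
vectorized elementwise over residual arrays.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = ["LossSpec", "FAMILIES"]

FAMILIES = ("lad", "quantile", "huber", "lq", "ols")

# classical 95%-efficiency Huber constant
DEFAULT_HUBER_C = 1.345


@dataclass(frozen=True)
class LossSpec:
    """A convex residual loss rho and its score function phi.

    Parameters
    ----------
    family : str
        One of ``lad``, ``quantile``, ``huber``, ``lq``, ``ols``.
    alpha : float
        Quantile level in (0, 1); only used for ``family="quantile"``.
    c : float
        Positive Huber knot; only used for ``family="huber"``.
    q : float
        Power in [1, 2]; only used for ``family="lq"``.
    """

    family: str = "lad"
    alpha: float = 0.5
    c: float = DEFAULT_HUBER_C
    q: float = 1.5

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(
                f"unknown loss family {self.family!r}; expected one of {FAMILIES}"
            )
        if self.family == "quantile" and not 0.0 < self.alpha < 1.0:
            raise ValueError(f"quantile level alpha must lie in (0,1), got {self.alpha}")
        if self.family == "huber" and not self.c > 0:
            raise ValueError(f"Huber knot c must be positive, got {self.c}")
        if self.family == "lq" and not 1.0 <= self.q <= 2.0:
            raise ValueError(f"Lq exponent q must lie in [1,2], got {self.q}")

    # ------------------------------------------------------------------ value
    def value(self, r):
        """Evaluate rho(r) elementwise; returns scalar for scalar input."""
        r = np.asarray(r, dtype=float)
        if self.family == "lad":
            out = np.abs(r)
        elif self.family == "quantile":
            out = self.alpha * np.maximum(r, 0.0) + (1.0 - self.alpha) * np.maximum(-r, 0.0)
        elif self.family == "huber":
            a = np.abs(r)
            out = np.where(a <= self.c, 0.5 * r * r, self.c * a - 0.5 * self.c**2)
        elif self.family == "lq":
            out = np.abs(r) ** self.q
        else:  # ols
            out = r * r
        return out if out.ndim else float(out)

    # ------------------------------------------------------------------ score
    def score(self, r):
        """An element of the subdifferential of rho at r.

        At kinks the midpoint of the subdifferential is returned: 0 for LAD,
        ``alpha - 1/2`` for the check loss.
        """
        r = np.asarray(r, dtype=float)
        if self.family == "lad":
            out = np.sign(r)
        elif self.family == "quantile":
            out = np.where(r > 0, self.alpha, np.where(r < 0, self.alpha - 1.0, self.alpha - 0.5))
        elif self.family == "huber":
            out = np.clip(r, -self.c, self.c)
        elif self.family == "lq":
            if self.q == 1.0:
                out = np.sign(r)
            else:
                out = self.q * np.abs(r) ** (self.q - 1.0) * np.sign(r)
        else:  # ols
            out = 2.0 * r
        return out if out.ndim else float(out)

    def score_interval(self, r):
        """Left and right derivatives (phi-, phi+) of rho at r.

        Used by optimality certificates; the subdifferential at r is the
        closed interval [phi-(r), phi+(r)].
        """
        r = np.asarray(r, dtype=float)
        if self.family == "lad":
            lo = np.where(r > 0, 1.0, np.where(r < 0, -1.0, -1.0))
            hi = np.where(r > 0, 1.0, np.where(r < 0, -1.0, 1.0))
        elif self.family == "quantile":
            a = self.alpha
            lo = np.where(r > 0, a, np.where(r < 0, a - 1.0, a - 1.0))
            hi = np.where(r > 0, a, np.where(r < 0, a - 1.0, a))
        elif self.family == "lq" and self.q == 1.0:
            lo = np.where(r > 0, 1.0, -1.0)
            hi = np.where(r < 0, -1.0, 1.0)
        else:  # smooth everywhere
            s = self.score(r)
            lo = hi = np.asarray(s, dtype=float)
        return lo, hi

    # ------------------------------------------------------------- attributes
    @property
    def is_smooth(self) -> bool:
        """True when rho is differentiable everywhere (huber, ols, lq q>1)."""
        return self.family in ("huber", "ols") or (self.family == "lq" and self.q > 1.0)

    @property
    def is_piecewise_linear(self) -> bool:
        """True when rho is piecewise linear (lad, quantile, lq q=1)."""
        return self.family in ("lad", "quantile") or (self.family == "lq" and self.q == 1.0)

    @property
    def score_bound(self) -> Optional[float]:
        """sup |phi| when finite (bounded-score losses), else None."""
        if self.family == "lad" or (self.family == "lq" and self.q == 1.0):
            return 1.0
        if self.family == "quantile":
            return max(self.alpha, 1.0 - self.alpha)
        if self.family == "huber":
            return self.c
        return None

    @property
    def score_lipschitz(self) -> Optional[float]:
        """Lipschitz constant of phi when available (huber: 1, ols/lq q=2: 2)."""
        if self.family == "huber":
            return 1.0
        if self.family == "ols" or (self.family == "lq" and self.q == 2.0):
            return 2.0
        return None
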