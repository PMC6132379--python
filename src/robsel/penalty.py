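"""SCAD penalty and the local linear approximation (LLA) weights.

The smoothly clipped absolute deviation (SCAD) penalty is the three-piece
function

    p_lam(b) = lam*b                                   0 <= b <= lam
             = -(b^2 - 2*a*lam*b + lam^2)/(2*(a-1))    lam < b < a*lam
             = (a+1)*lam^2 / 2                         b >= a*lam

with derivative

    p'_lam(b) = lam                  b <= lam
              = (a*lam - b)/(a-1)    lam < b <= a*lam
              = 0                    b > a*lam

for shape parameter a > 2 (default 3.7).  Unlike the lasso, the derivative
vanishes beyond ``a*lam``, so large coefficients are not shrunk.

The LLA replaces the nonconvex term ``p_lam(|b_j|)`` by the linear
majorant ``p'_lam(|pilot_j|) * |b_j|`` at a pilot estimate, turning the
penalized problem into a convex weighted-L1 fit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["SCADPenalty"]

DEFAULT_A = 3.7


@dataclass(frozen=True)
class SCADPenalty:
    """SCAD penalty with tuning parameter ``lam`` and shape ``a`` (> 2)."""

    lam: float
    a: float = DEFAULT_A

    def __post_init__(self) -> None:
        if self.lam < 0:
            raise ValueError(f"lam must be nonnegative, got {self.lam}")
        if not self.a > 2:
            raise ValueError(f"SCAD shape a must exceed 2, got {self.a}")

    def value(self, b):
        """p_lam(b) for b >= 0 (callers pass |beta|); vectorized."""
        b = np.asarray(b, dtype=float)
        if np.any(b < 0):
            raise ValueError("SCAD value is defined for nonnegative arguments")
        lam, a = self.lam, self.a
        out = np.where(
            b <= lam,
            lam * b,
            np.where(
                b < a * lam,
                -(b * b - 2 * a * lam * b + lam * lam) / (2 * (a - 1)),
                (a + 1) * lam * lam / 2,
            ),
        )
        return out if out.ndim else float(out)

    def derivative(self, b):
        """p'_lam(b) for b >= 0; in [0, lam], zero beyond a*lam; vectorized."""
        b = np.asarray(b, dtype=float)
        if np.any(b < 0):
            raise ValueError("SCAD derivative is defined for nonnegative arguments")
        lam, a = self.lam, self.a
        out = np.where(
            b <= lam,
            lam,
            np.where(b <= a * lam, (a * lam - b) / (a - 1), 0.0),
        )
        return out if out.ndim else float(out)

    def lla_weights(self, pilot) -> np.ndarray:
        """Weighted-L1 weights ``w_j = p'_lam(|pilot_j|)`` for the LLA fit."""
        pilot = np.asarray(pilot, dtype=float)
        return np.atleast_1d(self.derivative(np.abs(pilot)))
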