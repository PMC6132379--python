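"""Synthetic data generator for the simulation study.

Data follow the sparse linear model ``y = X b0 + e`` with

* design rows i.i.d. p-variate normal, mean zero, AR(1)-structured
  covariance ``Sigma_ij = rho^{|i-j|}`` (default rho = 0.5);
* true coefficients ``b0 = (-2, 2.5, 3, -1, 0, ..., 0)`` (k = 4 signals);
* errors i.i.d. from N(0,1), Student t with 5 df, or the contaminated
  normal mixture 0.9 N(0,1) + 0.1 N(0, 9) ("N(0,9)" read as variance 9);
* covariate count tied to the sample size by ``p = [2 sqrt(n)]``
  (round half up), the p = O(sqrt(n)) growth regime.

All draws go through numpy Generators; replicate r of a study derives its
stream from ``SeedSequence([master_seed, r])`` so replicates are independent
and every run is reproducible bit for bit.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np

__all__ = [
    "SimConfig",
    "dimension_rule",
    "make_design",
    "draw_errors",
    "make_dataset",
    "child_rng",
    "BETA_NONZERO",
    "ERROR_DISTS",
]

BETA_NONZERO = (-2.0, 2.5, 3.0, -1.0)
ERROR_DISTS = ("normal", "t5", "mixture")


def dimension_rule(n: int) -> int:
    """Covariate count p = [2 sqrt(n)], rounding half up.

    Half-up rounding (not floor) reproduces p = 28, 45, 53 at
    n = 200, 500, 700.
    """
    if n < 4:
        raise ValueError("need n >= 4")
    return int(math.floor(2.0 * math.sqrt(n) + 0.5))


def child_rng(master_seed: int, replicate: int) -> np.random.Generator:
    """Independent stream for one replicate of a seeded study."""
    return np.random.default_rng(np.random.SeedSequence([master_seed, replicate]))


@dataclass(frozen=True)
class SimConfig:
    """Configuration of one synthetic dataset.

    ``p`` defaults to the dimension rule; ``beta0`` has the k signal values
    in the leading coordinates and zeros elsewhere.
    """

    n: int
    p: Optional[int] = None
    k: int = 4
    rho_corr: float = 0.5
    error_dist: str = "normal"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.p is None:
            object.__setattr__(self, "p", dimension_rule(self.n))
        if not 0.0 <= self.rho_corr < 1.0:
            raise ValueError(f"rho_corr must lie in [0,1), got {self.rho_corr}")
        if self.error_dist not in ERROR_DISTS:
            raise ValueError(f"unknown error_dist {self.error_dist!r}; expected {ERROR_DISTS}")
        if not self.p < self.n:
            raise ValueError(f"need p < n, got p={self.p}, n={self.n}")
        if self.k > self.p:
            raise ValueError("k cannot exceed p")

    @property
    def beta0(self) -> np.ndarray:
        b = np.zeros(self.p)
        b[: self.k] = BETA_NONZERO[: self.k]
        return b

    def to_json(self) -> str:
        return json.dumps({"n": self.n, "p": self.p, "k": self.k,
                           "rho_corr": self.rho_corr, "error_dist": self.error_dist,
                           "seed": self.seed})


def make_design(n: int, p: int, rho_corr: float, rng) -> np.ndarray:
    """n x p design with i.i.d. N(0, Sigma) rows, Sigma_ij = rho^{|i-j|}.

    Generated as Z L' where Z is i.i.d. standard normal and L the Cholesky
    factor of Sigma.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    idx = np.arange(p)
    sigma = rho_corr ** np.abs(np.subtract.outer(idx, idx))
    L = np.linalg.cholesky(sigma)
    return rng.standard_normal((n, p)) @ L.T


def draw_errors(error_dist: str, n: int, rng) -> np.ndarray:
    """i.i.d. errors: N(0,1), t_5 (raw, variance 5/3), or the 0.9/0.1
    normal mixture with contaminating variance 9."""
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    if error_dist == "normal":
        return rng.standard_normal(n)
    if error_dist == "t5":
        return rng.standard_t(5, size=n)
    if error_dist == "mixture":
        contaminated = rng.random(n) < 0.1
        e = rng.standard_normal(n)
        return np.where(contaminated, 3.0 * e, e)
    raise ValueError(f"unknown error_dist {error_dist!r}; expected {ERROR_DISTS}")


def make_dataset(cfg: SimConfig, rng=None) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Draw (X, y, beta0) from the configured model y = X beta0 + e.

    The same config (same seed) always produces bit-identical output.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    X = make_design(cfg.n, cfg.p, cfg.rho_corr, rng)
    e = draw_errors(cfg.error_dist, cfg.n, rng)
    beta0 = cfg.beta0
    return X, X @ beta0 + e, beta0


def export_dataset(cfg: SimConfig, prefix) -> None:
    """Write X and y as headerless CSV plus a JSON sidecar with the config."""
    prefix = Path(prefix)
    X, y, _ = make_dataset(cfg)
    np.savetxt(prefix.with_suffix(".X.csv"), X, delimiter=",")
    np.savetxt(prefix.with_suffix(".y.csv"), y, delimiter=",")
    prefix.with_suffix(".json").write_text(cfg.to_json() + "\n")
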