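"""Stationary Fokker-Planck analysis of the reduced decision process.

Given the time-averaged drift mu_hat(c) and diffusion sigma2_hat(c) of the
1D decision diffusion on [-1, 1], this module computes

* the potential  U(c) = -int_{-1}^{c} 2 mu_hat / sigma2_hat ds, whose local
  minima are the metastable decision states (the paper-style forcing
  symbol clash is avoided: "potential" here, "forcing" in the SDE module);
* the stationary density  pi(x) = C exp(-U(x)) / sigma2_hat(x);
* the splitting probabilities  p_b(x) (absorb at +1 before -1) and
  p_a(x) = 1 - p_b(x), via the scale function

      p_b(x) = int_a^x exp(+U) ds / int_a^b exp(+U) ds,

  the standard exit-problem result for an Ito diffusion with two absorbing
  boundaries (exp(+U) is the reciprocal of the density integrand);
* decision metrics: the decision point x* where p_b = p_a = 1/2, the mean
  probability of a correct decision for a start drawn uniformly from the
  metastable band [-1/2, 1/2] (the integral of p_b over it), and the
  residual probability of revising a decision outside [-0.75, -0.25].

A Monte-Carlo absorption oracle cross-checks the analytic splitting
probabilities by direct simulation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.integrate import cumulative_trapezoid, trapezoid

from .efa_reduction import Coefficients1D

__all__ = [
    "PotentialProfile",
    "StationaryDensity",
    "SplittingProfile",
    "OracleResult",
    "potential",
    "stationary_density",
    "splitting_probability",
    "mc_splitting_oracle",
]


def _prepare(coeffs: Coefficients1D, refine: int, a: float, b: float):
    """Refined grid on [a, b] with interpolated, positivity-clamped coeffs."""
    if a >= b:
        raise ValueError("degenerate interval: need a < b")
    mu, s2 = coeffs.filled()
    K = len(coeffs.centers)
    grid = np.linspace(a, b, refine * K + 1)
    mu_g = np.interp(grid, coeffs.centers, mu)
    s2_g = np.interp(grid, coeffs.centers, s2)
    if np.any(s2_g <= 0):
        raise ValueError("diffusion must be positive on the interior grid")
    return grid, mu_g, s2_g


@dataclass
class PotentialProfile:
    grid: np.ndarray
    value: np.ndarray
    normalized: np.ndarray  # (value - min) / (max - min) in [0, 1]


@dataclass
class StationaryDensity:
    grid: np.ndarray
    pi: np.ndarray  # integrates to 1 on the grid


@dataclass
class SplittingProfile:
    """Splitting probabilities and the derived decision metrics.

    ``p_plus``/``p_minus`` are the probabilities of absorption at b (+1,
    the correct decision for the canonical forcing) and at a (-1).
    ``integral_mid`` is int_{-1/2}^{1/2} p_plus dc, the chance of a correct
    decision from a uniform start in the metastable band (band width 1, so
    the integral is itself the mean probability).  ``residual_revision``
    bounds the probability of overturning a decision when starting outside
    [-0.75, -0.25].
    """

    grid: np.ndarray
    p_plus: np.ndarray
    p_minus: np.ndarray
    a: float
    b: float
    decision_point: float
    integral_mid: float
    residual_revision: float

    def p_plus_at(self, x):
        return np.interp(x, self.grid, self.p_plus)


def potential(
    coeffs: Coefficients1D,
    refine: int = 10,
    a: float = -1.0,
    b: float = 1.0,
) -> PotentialProfile:
    """Potential U(c) = -cumulative integral of 2 mu_hat / sigma2_hat.

    The formal lower limit is replaced by the left domain edge; the
    resulting constant offset drops out of the normalised profile.
    Trapezoidal quadrature on the estimation grid refined ``refine``-fold.
    """
    grid, mu_g, s2_g = _prepare(coeffs, refine, a, b)
    u = -cumulative_trapezoid(2.0 * mu_g / s2_g, grid, initial=0.0)
    span = u.max() - u.min()
    norm = (u - u.min()) / span if span > 0 else np.zeros_like(u)
    return PotentialProfile(grid, u, norm)


def stationary_density(
    coeffs: Coefficients1D,
    refine: int = 10,
    a: float = -1.0,
    b: float = 1.0,
) -> StationaryDensity:
    """Stationary FPE density pi(x) = C exp(-U(x)) / sigma2_hat(x)."""
    prof = potential(coeffs, refine, a, b)
    _, _, s2_g = _prepare(coeffs, refine, a, b)
    logw = -prof.value - np.log(s2_g)
    w = np.exp(logw - logw.max())
    mass = trapezoid(w, prof.grid)
    if not np.isfinite(mass) or mass <= 0:
        raise ValueError("stationary density is not normalizable")
    return StationaryDensity(prof.grid, w / mass)


def splitting_probability(
    coeffs: Coefficients1D,
    a: float = -1.0,
    b: float = 1.0,
    refine: int = 10,
) -> SplittingProfile:
    """Analytic splitting probabilities via the scale function.

    p_plus(x) is the probability of hitting b before a when started at x;
    it is 0 at a, 1 at b and monotone nondecreasing.  The decision point is
    the root of p_plus = 1/2 (linear interpolation on the grid).
    """
    prof = potential(coeffs, refine, a, b)
    grid = prof.grid
    # scale density ~ exp(+U); shift by the max for overflow safety
    scale = np.exp(prof.value - prof.value.max())
    cum = cumulative_trapezoid(scale, grid, initial=0.0)
    p_plus = cum / cum[-1]
    p_minus = 1.0 - p_plus
    decision_point = float(np.interp(0.5, p_plus, grid))

    fine = np.linspace(-0.5, 0.5, 2001)
    if a <= -0.5 and b >= 0.5:
        integral_mid = float(trapezoid(np.interp(fine, grid, p_plus), fine))
    else:
        integral_mid = float("nan")
    right = grid > -0.25
    left = grid < -0.75
    if right.any() and left.any():
        residual = max(float(p_minus[right].max()), float(p_plus[left].max()))
    else:
        residual = float("nan")
    return SplittingProfile(
        grid=grid,
        p_plus=p_plus,
        p_minus=p_minus,
        a=a,
        b=b,
        decision_point=decision_point,
        integral_mid=integral_mid,
        residual_revision=residual,
    )


@dataclass
class OracleResult:
    """Empirical absorption statistics of the Monte-Carlo oracle."""

    fraction_b: float
    n_paths: int
    n_unabsorbed: int

    @property
    def binomial_sd(self) -> float:
        p = self.fraction_b
        return math.sqrt(max(p * (1.0 - p), 1e-12) / self.n_paths)


def mc_splitting_oracle(
    coeffs: Coefficients1D,
    x0: float,
    n_paths: int = 400,
    seed: int = 0,
    a: float = -1.0,
    b: float = 1.0,
    dt: float = 0.005,
    max_steps: int = 400_000,
) -> OracleResult:
    """Direct simulation of the exit problem: fraction of paths hitting b.

    Euler-Maruyama on the interpolated coefficients from x0 until
    absorption at a or b.  Paths still alive after ``max_steps`` are
    reported in ``n_unabsorbed`` (never silently dropped into either
    class); the fraction is computed over absorbed paths.
    """
    if not a < x0 < b:
        raise ValueError("x0 must lie strictly inside (a, b)")
    mu, s2 = coeffs.filled()
    centers = coeffs.centers
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    x = np.full(n_paths, float(x0))
    alive = np.ones(n_paths, dtype=bool)
    hit_b = np.zeros(n_paths, dtype=bool)
    sqdt = math.sqrt(dt)
    for _ in range(max_steps):
        idx = np.flatnonzero(alive)
        if idx.size == 0:
            break
        xi = x[idx]
        drift = np.interp(xi, centers, mu)
        sig = np.sqrt(np.interp(xi, centers, s2))
        xi = xi + drift * dt + sig * sqdt * rng.standard_normal(idx.size)
        x[idx] = xi
        up = xi >= b
        down = xi <= a
        hit_b[idx[up]] = True
        alive[idx[up | down]] = False
    n_unabsorbed = int(alive.sum())
    n_done = n_paths - n_unabsorbed
    if n_done == 0:
        raise RuntimeError("no path was absorbed within the step budget")
    return OracleResult(
        fraction_b=float(hit_b.sum()) / n_done,
        n_paths=n_done,
        n_unabsorbed=n_unabsorbed,
    )
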