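"""Equation-free reduction of the decision coordinate to a 1D Ito diffusion.

The full two-path process projects onto the scalar decision coordinate
c = (D1 - D2)/(D1 + D2).  Assuming c itself follows an Ito diffusion

    dc/dt = mu(c, t) + sigma(c, t) xi(t),

the drift and diffusion are estimated directly from simulated increments
(no closed-form reduction) via the binned conditional-moment estimators

    mu(x)      = < c(t+dt) - c(t) | c(t) = x > / dt
    sigma^2(x) = < [c(t+dt) - c(t) - mu(x) dt]^2 | c(t) = x > / dt.

Because the forcing makes the process time-inhomogeneous, increments are
grouped by the forcing regime active during their interval (dark/dark,
light/dark, light/light); each regime is time-homogeneous on its own.
Time-averaging the per-regime coefficients with the regime duration
weights yields a homogeneous surrogate process used by the
Fokker-Planck analysis in :mod:`physarum.fpe_analysis`.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd

from .twopath_sde import EnsembleResult, ForcingSpec

__all__ = [
    "DriftDiffusionTable",
    "Coefficients1D",
    "estimate_drift_diffusion",
    "time_average_coefficients",
    "simulate_reduced",
    "ReducedEnsemble",
    "simulate_ou",
    "fill_gaps",
]

REGIME_NAMES = ("dark/dark", "light/dark", "light/light")


def fill_gaps(centers: np.ndarray, values: np.ndarray) -> np.ndarray:
    """Fill NaN bins by linear interpolation from populated neighbours.

    Outside the outermost populated bin the value is clamped flat (constant
    extrapolation), matching the resolution actually supported by the data.
    """
    values = np.asarray(values, dtype=float)
    good = np.isfinite(values)
    if not good.any():
        raise ValueError("no populated bins to interpolate from")
    if good.all():
        return values.copy()
    return np.interp(centers, centers[good], values[good])


@dataclass
class Coefficients1D:
    """Drift/diffusion pair on a bin grid, with gap-filled interpolants."""

    centers: np.ndarray
    mu: np.ndarray
    sigma2: np.ndarray

    def filled(self) -> tuple[np.ndarray, np.ndarray]:
        mu = fill_gaps(self.centers, self.mu)
        s2 = fill_gaps(self.centers, self.sigma2)
        pos = s2 > 0
        if pos.any():
            # clamp vanishing boundary estimates to the smallest interior value
            s2[~pos] = s2[pos].min()
        return mu, s2

    def mu_at(self, x):
        mu, _ = self.filled()
        return np.interp(x, self.centers, mu)

    def sigma2_at(self, x):
        _, s2 = self.filled()
        return np.interp(x, self.centers, s2)


def estimate_from_series(
    series: np.ndarray,
    dt: float,
    bin_width: float,
    bounds: tuple[float, float] | None = None,
) -> tuple[Coefficients1D, np.ndarray]:
    """Regime-free conditional-moment estimation from raw 1D sample paths.

    ``series`` has shape (n_paths, n_times); all increments are pooled.
    Returns the binned coefficients and the per-bin sample counts.  This is
    the single-regime core of :func:`estimate_drift_diffusion`, also handy
    for validating the estimators on processes with known coefficients.
    """
    series = np.asarray(series, dtype=float)
    if series.ndim != 2 or series.shape[1] < 2:
        raise ValueError("series must be (n_paths, n_times >= 2)")
    x = series[:, :-1].ravel()
    dc = np.diff(series, axis=1).ravel()
    if bounds is None:
        bounds = (float(x.min()), float(x.max()) + 1e-12)
    lo, hi = bounds
    K = max(int(round((hi - lo) / bin_width)), 1)
    edges = np.linspace(lo, hi, K + 1)
    bins = np.clip(((x - lo) / (hi - lo) * K).astype(np.int64), 0, K - 1)
    counts = np.bincount(bins, minlength=K)
    s1 = np.bincount(bins, weights=dc, minlength=K)
    s2 = np.bincount(bins, weights=dc * dc, minlength=K)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_inc = s1 / counts
        var_inc = s2 / counts - mean_inc**2
    mu = np.where(counts > 0, mean_inc / dt, np.nan)
    sigma2 = np.where(counts > 1, np.maximum(var_inc, 0.0) / dt, np.nan)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return Coefficients1D(centers, mu, sigma2), counts


@dataclass
class DriftDiffusionTable:
    """Binned drift/diffusion estimates per forcing regime.

    ``mu[r, k]`` and ``sigma2[r, k]`` are the estimates for regime r in bin
    k (NaN flags an unpopulated bin — never silently zero), ``counts[r, k]``
    the number of increments that fed them.  ``weights`` are the regime
    duration fractions of the forcing cycle (they sum to 1).
    """

    bin_edges: np.ndarray
    mu: np.ndarray        # (3, K)
    sigma2: np.ndarray    # (3, K)
    counts: np.ndarray    # (3, K)
    weights: np.ndarray   # (3,)
    lag: float
    forcing: ForcingSpec = field(default_factory=ForcingSpec)

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def bin_width(self) -> float:
        return float(self.bin_edges[1] - self.bin_edges[0])

    def regime(self, r: int) -> Coefficients1D:
        return Coefficients1D(self.centers, self.mu[r], self.sigma2[r])

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r, name in enumerate(REGIME_NAMES):
            for k, center in enumerate(self.centers):
                rows.append(
                    (center, name, self.mu[r, k], self.sigma2[r, k],
                     int(self.counts[r, k]))
                )
        return pd.DataFrame(
            rows, columns=["bin_center", "regime", "mu", "sigma2", "n"]
        )

    def to_csv(self, path: str | Path) -> None:
        """CSV of the table plus a JSON sidecar with grid/weight metadata."""
        path = Path(path)
        self.to_frame().to_csv(path, index=False)
        meta = {
            "bin_width": self.bin_width,
            "lag": self.lag,
            "weights": self.weights.tolist(),
            "forcing": {
                "omega": self.forcing.omega,
                "br1": self.forcing.br1,
                "br2": self.forcing.br2,
                "beta1": self.forcing.beta1,
                "beta2": self.forcing.beta2,
            },
        }
        path.with_suffix(".json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def from_csv(cls, path: str | Path) -> "DriftDiffusionTable":
        path = Path(path)
        frame = pd.read_csv(path)
        meta = json.loads(path.with_suffix(".json").read_text())
        centers = np.sort(frame["bin_center"].unique())
        w = meta["bin_width"]
        edges = np.concatenate([centers - w / 2, [centers[-1] + w / 2]])
        K = len(centers)
        mu = np.full((3, K), np.nan)
        s2 = np.full((3, K), np.nan)
        counts = np.zeros((3, K), dtype=np.int64)
        for _, row in frame.iterrows():
            r = REGIME_NAMES.index(row["regime"])
            k = int(round((row["bin_center"] - centers[0]) / w))
            mu[r, k] = row["mu"]
            s2[r, k] = row["sigma2"]
            counts[r, k] = row["n"]
        return cls(
            bin_edges=edges, mu=mu, sigma2=s2, counts=counts,
            weights=np.asarray(meta["weights"]), lag=meta["lag"],
            forcing=ForcingSpec(**meta["forcing"]),
        )


def estimate_drift_diffusion(
    ensemble: EnsembleResult,
    bin_width: float = 0.04,
    lag_steps: int = 1,
    block: int = 512,
) -> DriftDiffusionTable:
    """Estimate per-regime drift and diffusion from ensemble increments.

    Increments c(t + lag) - c(t) are grouped by the bin containing c(t) and
    by the forcing regime active during the starting step.  Increments that
    begin after a path has committed (either branch absorbed, c frozen at
    +/-1) are excluded — they carry no dynamics.  The default lag is one
    integration step, for which no increment straddles a regime boundary.
    """
    if ensemble.c is None:
        raise ValueError("ensemble was not recorded in full; rerun with record='full'")
    if lag_steps < 1:
        raise ValueError("lag_steps must be >= 1")
    c = ensemble.c
    n_paths, n_times = c.shape
    n_starts = n_times - 1 - (lag_steps - 1)
    if n_starts <= 0:
        raise ValueError("ensemble too short for the requested lag")
    dt = float(ensemble.times[1] - ensemble.times[0])
    lag = lag_steps * dt

    K = int(round(2.0 / bin_width))
    edges = np.linspace(-1.0, 1.0, K + 1)
    counts = np.zeros(3 * K, dtype=np.int64)
    s1 = np.zeros(3 * K)
    s2 = np.zeros(3 * K)
    first = ensemble.first_decided[:, None]
    regime = ensemble.step_regime

    for start in range(0, n_starts, block):
        idx = np.arange(start, min(start + block, n_starts))
        x = c[:, idx].astype(np.float64)
        dc = c[:, idx + lag_steps].astype(np.float64) - x
        valid = idx[None, :] < first  # path not yet committed at t
        bins = np.clip(((x + 1.0) / bin_width).astype(np.int64), 0, K - 1)
        key = (regime[idx][None, :].astype(np.int64) * K + bins)[valid]
        w = dc[valid]
        counts += np.bincount(key, minlength=3 * K)
        s1 += np.bincount(key, weights=w, minlength=3 * K)
        s2 += np.bincount(key, weights=w * w, minlength=3 * K)

    counts = counts.reshape(3, K)
    s1 = s1.reshape(3, K)
    s2 = s2.reshape(3, K)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_inc = s1 / counts
        var_inc = s2 / counts - mean_inc**2
    mu = np.where(counts > 0, mean_inc / lag, np.nan)
    sigma2 = np.where(counts > 1, np.maximum(var_inc, 0.0) / lag, np.nan)
    return DriftDiffusionTable(
        bin_edges=edges,
        mu=mu,
        sigma2=sigma2,
        counts=counts,
        weights=ensemble.params.forcing.regime_weights,
        lag=lag,
        forcing=ensemble.params.forcing,
    )


def time_average_coefficients(table: DriftDiffusionTable) -> Coefficients1D:
    """Duration-weighted average of the per-regime coefficients.

    mu_hat = sum_r w_r mu_r and sigma2_hat = sum_r w_r sigma2_r with the
    regime weights w_r (1/2, 1/4, 1/4 for the canonical forcing).  A bin is
    NaN in the average wherever any regime is unpopulated there.
    """
    if np.any(~np.isfinite(table.mu).any(axis=1)):
        raise ValueError("a forcing regime has no populated bins at all")
    w = table.weights[:, None]
    mu_hat = np.sum(w * table.mu, axis=0)
    s2_hat = np.sum(w * table.sigma2, axis=0)
    return Coefficients1D(table.centers, mu_hat, s2_hat)


@dataclass
class ReducedEnsemble:
    """Ensemble of reduced 1D trajectories (boundaries at +/-1 absorbing)."""

    times: np.ndarray
    c: np.ndarray
    mean_c: np.ndarray
    sd_c: np.ndarray
    terminal_c: np.ndarray

    @property
    def terminal_mean_c(self) -> float:
        return float(np.mean(self.terminal_c))


def simulate_reduced(
    table: DriftDiffusionTable,
    c0: float,
    n_paths: int,
    t_end: float,
    seed: int = 0,
    mode: Literal["regime", "averaged"] = "regime",
    dt: float | None = None,
) -> ReducedEnsemble:
    """Forward-integrate the reduced 1D diffusion on the estimated grid.

    Euler-Maruyama stepping on piecewise-linearly interpolated coefficients;
    c = +/-1 are absorbing.  ``mode="regime"`` switches (mu_r, sigma_r) with
    the forcing phase; ``mode="averaged"`` uses the time-averaged pair
    throughout.  ``dt`` defaults to the estimation lag.
    """
    if not -1.0 < c0 < 1.0:
        raise ValueError("c0 must lie in (-1, 1)")
    if dt is None:
        dt = table.lag
    n_steps = int(round(t_end / dt))
    times = np.arange(n_steps + 1) * dt
    centers = table.centers

    if mode == "regime":
        pairs = [table.regime(r).filled() for r in range(3)]
        tau_mid = table.forcing.phase(times[:-1] + 0.5 * dt)
        step_regime = table.forcing.regime_of_phase(tau_mid)
    elif mode == "averaged":
        pairs = [time_average_coefficients(table).filled()]
        step_regime = np.zeros(n_steps, dtype=int)
    else:
        raise ValueError(f"unknown mode {mode!r}")

    rng = np.random.default_rng(np.random.SeedSequence(seed))
    x = np.full(n_paths, float(c0))
    alive = np.ones(n_paths, dtype=bool)
    c = np.empty((n_paths, n_steps + 1), dtype=np.float32)
    c[:, 0] = x
    sqdt = math.sqrt(dt)
    for k in range(n_steps):
        mu_k, s2_k = pairs[step_regime[k]]
        drift = np.interp(x, centers, mu_k)
        sig = np.sqrt(np.interp(x, centers, s2_k))
        x = np.where(
            alive,
            x + drift * dt + sig * sqdt * rng.standard_normal(n_paths),
            x,
        )
        hit = alive & (np.abs(x) >= 1.0)
        if hit.any():
            x[hit] = np.sign(x[hit])
            alive &= ~hit
        c[:, k + 1] = x
    return ReducedEnsemble(
        times=times,
        c=c,
        mean_c=c.mean(axis=0, dtype=np.float64),
        sd_c=c.std(axis=0, dtype=np.float64),
        terminal_c=x.copy(),
    )


def simulate_ou(
    theta: float = 1.0,
    s: float = 0.3,
    dt: float = 0.01,
    n_steps: int = 1000,
    n_paths: int = 100,
    x0: float = 0.0,
    seed: int = 0,
) -> np.ndarray:
    """Euler-Maruyama sample paths of dX = -theta X dt + s dW.

    Synthetic benchmark with known drift slope -theta and diffusion s^2,
    used to validate the conditional-moment estimators.  Returns an array
    of shape (n_paths, n_steps + 1).
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    x = np.empty((n_paths, n_steps + 1))
    x[:, 0] = x0
    sq = s * math.sqrt(dt)
    for k in range(n_steps):
        x[:, k + 1] = (
            x[:, k] - theta * x[:, k] * dt + sq * rng.standard_normal(n_paths)
        )
    return x
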