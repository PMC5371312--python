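"""Stochastic two-path decision model with intermittent-light forcing.

Two tubes of conductivity D1, D2 compete for flow between two food
sources.  Each branch i follows the Ito SDE

    dD_i = [ -delta D_i + f(share_i) + Phi_i(t, D_i) ] dt + sigma dW_i,

where ``share_i`` is the conductance share (D_i/L_i) / sum_j (D_j/L_j),
``Phi_i`` models photophobic thinning under intermittent light (branch i
is lit whenever the forcing phase tau = omega t mod 2pi exceeds its
darkness length br_i, contributing -beta_i D_i), and sigma is the
amplitude of the additive white noise (dW_i independent across the two
branches).  The boundary D_i = 0 is absorbing: a tube
that has fully retracted stays retracted, so the decision coordinate

    c = (D1 - D2) / (D1 + D2)  in  [-1, 1]

reaches exactly +/-1 once either branch dies.  The time-averaged risk
ratio rho = (beta1/beta2) * (2pi - br1)/(2pi - br2) compares the
integrated light dose on the two branches; rho < 1 means path 1 carries
the lower risk and c -> +1 is the correct decision.

The canonical parameter set is the default ``TwoPathParams()``: L = 1,
eps = 0.2, delta = 1, mu = 2, noise level 0.05, D0 = (0.5, 1), br1 = pi,
br2 = 3pi/2, omega = 10, beta1 = 0.25, beta2 = 0.6, dt = 2pi/(16 omega),
horizon 200 pi.  The noise level is calibrated so that, at these
parameters, decisions complete within the ~1000-cycle horizon and 88% of
realizations pick the lower-risk path; it enters the scheme as the
amplitude multiplying dW.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .network_model import ResponseParams

__all__ = [
    "ForcingSpec",
    "TwoPathParams",
    "PathResult",
    "EnsembleResult",
    "forcing_phi",
    "risk_ratio",
    "correctness",
    "simulate_path",
    "run_ensemble",
]

TWO_PI = 2.0 * math.pi


@dataclass(frozen=True)
class ForcingSpec:
    """Intermittent-lighting schedule.

    omega
        Angular frequency of the light cycle (period 2pi/omega); must be
        fast compared with the tube relaxation rate delta for the risk to
        be a genuinely time-variant signal.
    br1, br2
        Darkness-phase lengths of the two branches, 0 <= br1 <= br2 < 2pi.
        Branch i is lit while the phase tau = omega t mod 2pi exceeds br_i,
        so each cycle passes through dark/dark, light/dark and light/light
        regimes of durations br1, br2 - br1 and 2pi - br2.
    beta1, beta2
        Lighting intensities (extra thinning rates) on the two branches.
    """

    omega: float = 10.0
    br1: float = math.pi
    br2: float = 1.5 * math.pi
    beta1: float = 0.25
    beta2: float = 0.6

    def __post_init__(self) -> None:
        if self.omega <= 0:
            raise ValueError("omega must be > 0")
        if not (0 <= self.br1 <= self.br2 < TWO_PI):
            raise ValueError("need 0 <= br1 <= br2 < 2*pi")
        if self.beta1 < 0 or self.beta2 < 0:
            raise ValueError("lighting intensities must be >= 0")

    @property
    def period(self) -> float:
        return TWO_PI / self.omega

    def phase(self, t):
        """Forcing phase tau = omega t mod 2pi."""
        return np.mod(self.omega * np.asarray(t, dtype=float), TWO_PI)

    def regime_of_phase(self, tau):
        """0 = dark/dark, 1 = light/dark, 2 = light/light."""
        tau = np.asarray(tau, dtype=float)
        return (tau > self.br1).astype(int) + (tau > self.br2).astype(int)

    @property
    def regime_durations(self) -> np.ndarray:
        return np.array([self.br1, self.br2 - self.br1, TWO_PI - self.br2])

    @property
    def regime_weights(self) -> np.ndarray:
        """Fraction of the cycle spent in each regime (sums to 1)."""
        return self.regime_durations / TWO_PI


def forcing_phi(t, D, branch: int, spec: ForcingSpec):
    """Instantaneous lighting drift: -beta_i D while branch i is lit, else 0."""
    if branch not in (1, 2):
        raise ValueError("branch must be 1 or 2")
    d = np.asarray(D, dtype=float)
    if np.any(d < 0):
        raise ValueError("conductivity must be >= 0")
    br = spec.br1 if branch == 1 else spec.br2
    beta = spec.beta1 if branch == 1 else spec.beta2
    tau = spec.phase(t)
    out = np.where(tau > br, -beta * d, 0.0)
    return float(out) if out.ndim == 0 else out


def risk_ratio(spec: ForcingSpec) -> float:
    """Time-averaged forcing-magnitude ratio rho = <Phi_1>/<Phi_2>.

    rho = (beta1/beta2) * (2pi - br1) / (2pi - br2); rho < 1 means path 1
    receives the lower integrated light dose (lower risk).
    """
    if spec.beta2 == 0 or spec.br2 >= TWO_PI:
        raise ZeroDivisionError("path-2 risk vanishes; rho undefined")
    return (spec.beta1 / spec.beta2) * (TWO_PI - spec.br1) / (TWO_PI - spec.br2)


def correctness(D1, D2):
    """Decision coordinate c = (D1 - D2)/(D1 + D2) in [-1, 1]."""
    d1 = np.asarray(D1, dtype=float)
    d2 = np.asarray(D2, dtype=float)
    total = d1 + d2
    if np.any(total <= 0):
        raise ValueError("correctness undefined at D1 = D2 = 0")
    out = (d1 - d2) / total
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class TwoPathParams:
    """Full parameter record of the stochastic two-path experiment.

    Defaults are the canonical experiment (see module docstring).  ``dt``
    defaults to 1/16 of the forcing period so the regime boundaries at
    phases br1 = pi and br2 = 3pi/2 fall exactly on step edges.
    """

    response: ResponseParams = field(default_factory=ResponseParams)
    forcing: ForcingSpec = field(default_factory=ForcingSpec)
    L1: float = 1.0
    L2: float = 1.0
    noise: float = 0.05
    D1_0: float = 0.5
    D2_0: float = 1.0
    dt: float | None = None
    t_end: float = 200.0 * math.pi

    def __post_init__(self) -> None:
        if self.L1 <= 0 or self.L2 <= 0:
            raise ValueError("tube lengths must be > 0")
        if self.noise < 0:
            raise ValueError("noise must be >= 0")
        if self.dt is not None and self.dt <= 0:
            raise ValueError("dt must be > 0")
        if self.t_end <= 0:
            raise ValueError("t_end must be > 0")

    @property
    def step(self) -> float:
        """Integration step (defaults to one sixteenth of a forcing cycle)."""
        return self.dt if self.dt is not None else self.forcing.period / 16.0

    @property
    def sigma(self) -> float:
        """Amplitude of the additive noise term."""
        return self.noise

    @property
    def sigma2(self) -> float:
        """Variance scale of the additive noise (sigma squared)."""
        return self.noise**2


@dataclass
class PathResult:
    """One trajectory: times, branch conductivities and decision series."""

    times: np.ndarray
    D: np.ndarray  # (n_steps + 1, 2)
    c: np.ndarray
    seed: int


@dataclass
class EnsembleResult:
    """Ensemble of stochastic two-path trajectories plus derived series.

    ``c`` holds the full per-path decision series (float32) when recorded;
    ``first_decided[i]`` is the time index at which path i first committed
    (either branch absorbed at 0), or ``len(times)`` if it never did.
    ``step_regime[k]`` is the forcing regime applied during step k.
    """

    times: np.ndarray
    mean_c: np.ndarray
    sd_c: np.ndarray
    poincare_times: np.ndarray
    poincare_mean_c: np.ndarray
    terminal_c: np.ndarray
    terminal_D: np.ndarray
    labels: np.ndarray  # "path1" | "path2" | "undecided" per sample
    first_decided: np.ndarray
    step_regime: np.ndarray
    params: TwoPathParams
    base_seed: int
    c: np.ndarray | None = None

    @property
    def n_paths(self) -> int:
        return len(self.terminal_c)

    @property
    def fractions(self) -> dict[str, float]:
        n = self.n_paths
        return {
            lab: float(np.sum(self.labels == lab)) / n
            for lab in ("path1", "path2", "undecided")
        }

    @property
    def terminal_mean_c(self) -> float:
        return float(np.mean(self.terminal_c))


def _step_schedule(params: TwoPathParams):
    """Per-step lighting flags, evaluated at step midpoints.

    Evaluating the phase at the midpoint assigns each step the regime
    covering its interior, so with an integer number of steps per cycle no
    step straddles a regime boundary.
    """
    dt = params.step
    n_steps = int(round(params.t_end / dt))
    times = np.arange(n_steps + 1) * dt
    tau_mid = params.forcing.phase(times[:-1] + 0.5 * dt)
    lit1 = tau_mid > params.forcing.br1
    lit2 = tau_mid > params.forcing.br2
    regime = lit1.astype(np.int8) + lit2.astype(np.int8)
    return times, lit1, lit2, regime


def _simulate(
    params: TwoPathParams,
    n_paths: int,
    rng: np.random.Generator,
    record_c: bool = True,
    record_D: bool = False,
):
    """Vectorised Euler-Maruyama integration of the two-path SDE.

    The noise is additive, so the Milstein correction vanishes and this is
    simultaneously the Milstein scheme.  D = 0 is absorbing per branch.
    """
    p = params
    delta, eps, mu = p.response.delta, p.response.epsilon, p.response.mu
    beta1, beta2 = p.forcing.beta1, p.forcing.beta2
    dt = p.step
    times, lit1, lit2, regime = _step_schedule(p)
    n_steps = len(times) - 1
    sig_dt = p.sigma * math.sqrt(dt)

    D = np.empty((n_paths, 2))
    D[:, 0] = p.D1_0
    D[:, 1] = p.D2_0
    inv_L = np.array([1.0 / p.L1, 1.0 / p.L2])
    alive = D > 0

    c = np.empty((n_paths, n_steps + 1), dtype=np.float32) if record_c else None
    D_hist = np.empty((n_paths, n_steps + 1, 2)) if record_D else None
    c0 = (D[:, 0] - D[:, 1]) / (D[:, 0] + D[:, 1])
    if record_c:
        c[:, 0] = c0
    if record_D:
        D_hist[:, 0] = D
    first_decided = np.full(n_paths, n_steps + 1, dtype=np.int64)
    first_decided[~alive.all(axis=1)] = 0

    for k in range(n_steps):
        cond = D * inv_L
        total = cond[:, 0] + cond[:, 1]
        safe = total > 0
        share = np.divide(
            cond, total[:, None], out=np.zeros_like(cond), where=safe[:, None]
        )
        qm = share**mu
        drift = (1.0 + eps) * qm / (eps + qm) - delta * D
        if lit1[k]:
            drift[:, 0] -= beta1 * D[:, 0]
        if lit2[k]:
            drift[:, 1] -= beta2 * D[:, 1]
        if sig_dt > 0:
            D = D + drift * dt + sig_dt * rng.standard_normal((n_paths, 2))
        else:
            D = D + drift * dt
        D[~alive] = 0.0  # absorbed branches stay dead
        newly_dead = alive & (D <= 0)
        if newly_dead.any():
            D[newly_dead] = 0.0
            alive &= ~newly_dead
            just = newly_dead.any(axis=1) & (first_decided > k)
            first_decided[just] = k + 1
        total = D[:, 0] + D[:, 1]
        ck = np.divide(
            D[:, 0] - D[:, 1],
            total,
            out=np.zeros(n_paths),
            where=total > 0,
        )
        if record_c:
            c[:, k + 1] = ck
        if record_D:
            D_hist[:, k + 1] = D

    return {
        "times": times,
        "c": c,
        "D_hist": D_hist,
        "D_final": D,
        "terminal_c": ck.copy(),
        "first_decided": first_decided,
        "regime": regime,
    }


def simulate_path(
    params: TwoPathParams,
    seed: int,
    method: Literal["euler", "milstein"] = "euler",
) -> PathResult:
    """Integrate a single sample path (deterministic when the noise level is 0).

    ``method`` accepts "euler" or "milstein"; the two coincide because the
    noise is additive (the Milstein correction term is identically zero).
    """
    if method not in ("euler", "milstein"):
        raise ValueError(f"unknown method {method!r}")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    out = _simulate(params, 1, rng, record_c=True, record_D=True)
    return PathResult(
        times=out["times"],
        D=out["D_hist"][0],
        c=out["c"][0].astype(float),
        seed=seed,
    )


def run_ensemble(
    params: TwoPathParams,
    n_paths: int,
    base_seed: int = 0,
    record: Literal["full", "summary"] = "full",
    decision_threshold: float = 0.5,
) -> EnsembleResult:
    """Simulate an ensemble of independent sample paths.

    Noise for all paths is drawn from a single generator seeded by
    ``base_seed`` (paths are iid).  Terminal states are classified as
    ``path1`` (c > threshold), ``path2`` (c < -threshold) or ``undecided``.
    ``record="full"`` keeps the per-path decision series (float32), which
    the equation-free estimator needs; "summary" keeps only aggregates.
    """
    if n_paths < 1:
        raise ValueError("n_paths must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence(base_seed))
    out = _simulate(params, n_paths, rng, record_c=True, record_D=False)
    c = out["c"]
    mean_c = c.mean(axis=0, dtype=np.float64)
    sd_c = c.std(axis=0, dtype=np.float64)
    steps_per_cycle = max(int(round(params.forcing.period / params.step)), 1)
    poincare_idx = np.arange(0, c.shape[1], steps_per_cycle)
    terminal_c = out["terminal_c"]
    labels = np.where(
        terminal_c > decision_threshold,
        "path1",
        np.where(terminal_c < -decision_threshold, "path2", "undecided"),
    )
    return EnsembleResult(
        times=out["times"],
        mean_c=mean_c,
        sd_c=sd_c,
        poincare_times=out["times"][poincare_idx],
        poincare_mean_c=mean_c[poincare_idx],
        terminal_c=terminal_c,
        terminal_D=out["D_final"],
        labels=labels,
        first_decided=out["first_decided"],
        step_regime=out["regime"],
        params=params,
        base_seed=base_seed,
        c=c if record == "full" else None,
    )
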