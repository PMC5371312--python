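"""Equilibria, linear stability and basins of the deterministic two-path system.

For equal tube lengths the two-path dynamics

    dD_i/dt = -delta D_i + f(D_i / (D_1 + D_2)),   f(Q) = (1+eps)Q^2/(eps+Q^2)

has up to six equilibria: the trivial state, one on each axis (full
commitment to a single path), a symmetric interior state D1 = D2, and — for
eps < 1/4 — two further interior saddle points lying on rays D2 = a D1.
The branch ratios a solve the cubic

    eps a^3 + (eps-1) a^2 - (eps-1) a - eps = 0,

which factors as (a - 1)(eps a^2 + (2 eps - 1) a + eps) = 0, giving a1 = 1
and a_{2,3} = [(1-2 eps) +/- sqrt(1-4 eps)] / (2 eps) (real iff eps < 1/4,
with a2 a3 = 1).  The symmetric state loses stability in a sub-critical
pitchfork at eps = 1/4, where the Jacobian eigenvalue delta(2C - 1) with
C = 4 eps / (1 + 4 eps) crosses zero.  The rays D2 = a2 D1 and D2 = a3 D1
are invariant lines and delimit the three basins of attraction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .network_model import ResponseParams, two_path_rhs

__all__ = [
    "Equilibrium",
    "EquilibriumSet",
    "branch_ratio_roots",
    "equilibria",
    "jacobian",
    "classify_stability",
    "symmetric_eigenvalue",
    "critical_epsilon",
    "basin_of",
]

#: eps value at which the symmetric interior equilibrium loses stability
PITCHFORK_EPSILON = 0.25


@dataclass
class Equilibrium:
    """One equilibrium of the two-path system.

    ``a`` is the branch ratio D2/D1 where defined (None for the trivial and
    axis states).  ``stability`` is one of ``stable``, ``unstable``,
    ``saddle`` or ``marginal`` once classified.
    """

    D1: float
    D2: float
    a: float | None = None
    stability: str | None = None
    eigenvalues: tuple[float, float] | None = None
    kind: str = ""


@dataclass
class EquilibriumSet:
    epsilon: float
    delta: float
    equilibria: list[Equilibrium]

    def by_kind(self, kind: str) -> Equilibrium:
        for eq in self.equilibria:
            if eq.kind == kind:
                return eq
        raise KeyError(kind)

    def stable(self) -> list[Equilibrium]:
        return [e for e in self.equilibria if e.stability == "stable"]


def branch_ratio_roots(epsilon: float) -> tuple[float, ...]:
    """Real positive roots of the branch-ratio cubic.

    Returns ``(1.0, a2, a3)`` with a2 > 1 > a3 > 0 for eps < 1/4, and
    ``(1.0,)`` otherwise (the quadratic pair turns complex).
    """
    if epsilon <= 0:
        raise ValueError("epsilon must be > 0")
    if epsilon >= PITCHFORK_EPSILON:
        return (1.0,)
    disc = np.sqrt(1.0 - 4.0 * epsilon)
    a2 = ((1.0 - 2.0 * epsilon) + disc) / (2.0 * epsilon)
    a3 = ((1.0 - 2.0 * epsilon) - disc) / (2.0 * epsilon)
    return (1.0, a2, a3)


def _interior_point(a: float, epsilon: float, delta: float) -> tuple[float, float]:
    # delta*D1 = (1+eps) / (eps (1+a)^2 + 1); D2 = a D1
    d1 = (1.0 + epsilon) / (epsilon * (1.0 + a) ** 2 + 1.0) / delta
    return d1, a * d1


def equilibria(epsilon: float, delta: float = 1.0) -> EquilibriumSet:
    """Enumerate all equilibria (six for eps < 1/4, four otherwise).

    Coordinates scale as 1/delta; ``delta * D`` depends on eps only.
    """
    if epsilon <= 0 or delta <= 0:
        raise ValueError("epsilon and delta must be > 0")
    eqs = [
        Equilibrium(0.0, 0.0, kind="trivial"),
        Equilibrium(1.0 / delta, 0.0, kind="axis1"),
        Equilibrium(0.0, 1.0 / delta, kind="axis2"),
    ]
    roots = branch_ratio_roots(epsilon)
    d1, d2 = _interior_point(1.0, epsilon, delta)
    eqs.append(Equilibrium(d1, d2, a=1.0, kind="symmetric"))
    if len(roots) == 3:
        _, a2, a3 = roots
        for a, kind in ((a2, "saddle_a2"), (a3, "saddle_a3")):
            d1, d2 = _interior_point(a, epsilon, delta)
            eqs.append(Equilibrium(d1, d2, a=a, kind=kind))
    return EquilibriumSet(epsilon, delta, eqs)


def jacobian(
    D1: float, D2: float, epsilon: float, delta: float = 1.0
) -> np.ndarray:
    """Jacobian of the two-path drift at (D1, D2) (equal lengths, mu = 2).

    Diagonal entries carry the positive self-reinforcement term, the
    off-diagonals the (negative) cross-inhibition through the shared flux.
    """
    if D1 + D2 <= 0:
        raise ValueError("Jacobian undefined at D1 = D2 = 0")
    s = D1 + D2
    common = 2.0 * epsilon * (1.0 + epsilon) * s
    den1 = (D1**2 + epsilon * s**2) ** 2
    den2 = (D2**2 + epsilon * s**2) ** 2
    j11 = -delta + common * D1 * D2 / den1
    j12 = -common * D1**2 / den1
    j21 = -common * D2**2 / den2
    j22 = -delta + common * D1 * D2 / den2
    return np.array([[j11, j12], [j21, j22]])


def symmetric_eigenvalue(epsilon: float, delta: float = 1.0) -> float:
    """Unstable-direction eigenvalue delta*(2C - 1) at the symmetric state.

    C = 4 eps / (1 + 4 eps); the eigenvalue crosses zero at eps = 1/4
    (sub-critical pitchfork).  The other eigenvalue is -delta.
    """
    c = 4.0 * epsilon / (1.0 + 4.0 * epsilon)
    return delta * (2.0 * c - 1.0)


def critical_epsilon(lo: float = 0.01, hi: float = 0.49, tol: float = 1e-12) -> float:
    """Locate the pitchfork by bisecting the symmetric-state eigenvalue."""
    f_lo = symmetric_eigenvalue(lo)
    f_hi = symmetric_eigenvalue(hi)
    if f_lo * f_hi > 0:
        raise ValueError("bracket does not straddle the stability change")
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if symmetric_eigenvalue(mid) * f_lo <= 0:
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)


def classify_stability(
    eq_set: EquilibriumSet, marginal_tol: float = 1e-9
) -> EquilibriumSet:
    """Label every equilibrium by its linear stability.

    The trivial state is unstable (perturbations along either axis grow);
    the axis states have a double eigenvalue -delta; the symmetric state is
    stable iff eps < 1/4 (eigenvalues -delta and delta(2C-1)); the a2/a3
    points are classified numerically from the Jacobian (saddles on the
    basin boundaries).
    """
    eps, delta = eq_set.epsilon, eq_set.delta
    for eq in eq_set.equilibria:
        if eq.kind == "trivial":
            # Jacobian is singular at the origin; a perturbation eta along
            # either axis has dD/dt = -delta*eta + f(1) = 1 - delta*eta > 0
            # for eta < 1/delta, so the perturbation grows.
            eq.stability = "unstable"
            eq.eigenvalues = None
            continue
        if eq.kind in ("axis1", "axis2"):
            eq.eigenvalues = (-delta, -delta)
            eq.stability = "stable"
            continue
        if eq.kind == "symmetric":
            lam = symmetric_eigenvalue(eps, delta)
            eq.eigenvalues = (-delta, lam)
            if abs(lam) <= marginal_tol:
                eq.stability = "marginal"
            else:
                eq.stability = "stable" if lam < 0 else "unstable"
            continue
        # a2/a3 interior points: numerical eigenvalues of the Jacobian
        lam = np.linalg.eigvals(jacobian(eq.D1, eq.D2, eps, delta))
        lam = np.sort(np.real(lam))
        eq.eigenvalues = (float(lam[0]), float(lam[1]))
        if lam[0] < 0 < lam[1]:
            eq.stability = "saddle"
        elif np.all(lam < 0):
            eq.stability = "stable"
        else:
            eq.stability = "unstable"
    return eq_set


def basin_of(
    D1_0: float,
    D2_0: float,
    epsilon: float,
    boundary_tol: float = 1e-9,
) -> str:
    """Predict the attractor of an initial condition from the basin geometry.

    For eps < 1/4 the invariant rays D2 = a2 D1 and D2 = a3 D1 split the
    positive quadrant into three basins: above the a2 ray trajectories
    converge to the path-2 axis state, below the a3 ray to the path-1 axis
    state, and between the rays to the symmetric interior state.  For
    eps >= 1/4 the diagonal is the only separatrix.  Points on a separatrix
    (within ``boundary_tol`` relative to the state magnitude) are labelled
    ``"boundary"``.
    """
    if D1_0 < 0 or D2_0 < 0 or (D1_0 == 0 and D2_0 == 0):
        raise ValueError("initial condition must be non-negative and nonzero")
    scale = max(D1_0, D2_0)
    if epsilon >= PITCHFORK_EPSILON:
        if abs(D2_0 - D1_0) <= boundary_tol * scale:
            return "boundary"
        return "path1" if D1_0 > D2_0 else "path2"
    _, a2, a3 = branch_ratio_roots(epsilon)
    if abs(D2_0 - a2 * D1_0) <= boundary_tol * scale:
        return "boundary"
    if abs(D2_0 - a3 * D1_0) <= boundary_tol * scale:
        return "boundary"
    if D2_0 > a2 * D1_0:
        return "path2"
    if D2_0 < a3 * D1_0:
        return "path1"
    return "interior"


def rhs_residual(eq: Equilibrium, params: ResponseParams) -> float:
    """Max |dD/dt| at an equilibrium (0 up to round-off; trivial state exact)."""
    if eq.D1 == 0 and eq.D2 == 0:
        return 0.0
    r1, r2 = two_path_rhs(eq.D1, eq.D2, params)
    return max(abs(r1), abs(r2))
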