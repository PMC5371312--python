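# Methods

## The adaptive-network model

The plasmodium's tube network is a graph whose edges carry a length
`L_ij > 0` and a lumped conductivity `D_ij ≥ 0` (tube radius and
protoplasm viscosity enter only through `D`). Flow is quasi-steady: tube
adaptation is an order of magnitude slower than the protoplasmic shuttle
streaming, so the sources are treated as constant and the flow field is
recomputed as a steady Kirchhoff balance at every adaptation step. The
linear node system uses edge conductances `D_ij/L_ij`, net inflow `S0` at
N1 and outflow at N2 (volume conservation, `S1 + S2 = 0`), with the sink
pressure fixed to zero — the gauge does not affect fluxes. Nodes cut off
from the conducting component of the source are assigned zero pressure;
their edges carry no flux. We take `S0 = 1` so that, in the two-path
reduction, the flux shares of the branches sum to one and are exactly the
argument of the response function.

Adaptation follows `dD/dt = f(|Q|) − δD` with the saturating response
`f(Q) = (1+ε)Q^μ/(ε+Q^μ)`. Only the ratio of the two underlying sigmoid
parameters matters, which is why the response is parameterised by ε alone;
`f(0) = 0`, `f(1) = 1`, and `f → 1+ε` as `Q → ∞`. Defaults ε = 0.2 and
μ = 2 put the two-path system inside its tristable regime while staying
comparable with the established parameterisation of this model family.
Integration is explicit Euler with `dt = 0.01/δ` by default (well below
the relaxation time `1/δ`), alternating flow solve and conductivity
update, with `D` clipped at zero. Euler is deliberate: it matches the
order of the stochastic integrator used downstream, so the deterministic
limit of the SDE and the network integrator agree path-wise (this is
asserted by a test).

For general graphs the response argument is the absolute edge flux
`|Q_ij|`; on two parallel tubes with `S0 = 1` this coincides with the
conductance share `(D_i/L_i)/(D_1/L_1 + D_2/L_2)`, which is the form used
in the two-path functions.

The packaged maze is a synthetic stand-in arena: eight tubes, a unique
shortest N1–N2 route (total length 4) against two longer detours and a
cross-link. It exercises the qualitative prediction — adaptation starved
of flux retracts every tube off the shortest route — without claiming any
particular real arena's geometry.

## The stochastic two-path experiment

Each branch follows
`dD_i = [−δD_i + f(share_i) + Φ_i(t, D_i)] dt + σ dW_i` with independent
Brownian motions on the two branches (independence is the minimal
assumption; only temporal whiteness is physically motivated). The lighting
term is `Φ_i = −β_i D_i` while branch *i* is lit, i.e. while the phase
`τ = ωt mod 2π` exceeds the branch's darkness length `br_i`. Each cycle
passes through dark/dark, light/dark and light/light regimes with
durations `br1`, `br2 − br1`, `2π − br2`.

`D = 0` is absorbing per branch: the model equation sets the derivative to
zero at and below zero, and a fully retracted tube cannot regrow. This
one-sided boundary is what makes the decision coordinate
`c = (D1 − D2)/(D1 + D2)` reach exactly ±1 and renders the terminal mean
and the correct-decision fraction redundant (`mean c = 2·frac − 1` once no
path is undecided). Terminal classification thresholds (|c| > 0.5) are
plumbing; terminal states sit at ±1, so the labels are insensitive to the
threshold.

Canonical parameters: `L1 = L2 = 1`, ε = 0.2, δ = 1, μ = 2,
`D0 = (0.5, 1)` (so c₀ = −1/3, biased toward the *wrong* path),
`br1 = π`, `br2 = 3π/2`, ω = 10, β₁ = 0.25, β₂ = 0.6, horizon 200π. The
risk ratio is ρ = (β₁/β₂)·(2π−br₁)/(2π−br₂) = 5/6 < 1: path 1 carries the
lower time-integrated light dose and `c → +1` is the correct decision.

**Noise level.** The noise parameter defaults to 0.05 and enters the
scheme as the amplitude multiplying `dW` (per-step increment
`0.05·√dt·N(0,1)`). This level is calibrated against the canonical
experiment's behaviour: decisions complete gradually over hundreds of
forcing cycles, essentially no realization remains undecided at 200π, and
≈88–89% of realizations end on the lower-risk path despite the
wrong-biased start. A noise amplitude of √0.05 ≈ 0.22 would instead
swamp the forcing entirely (near-instant, initial-bias-dominated
decisions), and much smaller levels leave a large undecided fraction at
the horizon; see the sensitivity figures under "Known limitations".

**Integrator.** Euler–Maruyama with `dt = 2π/(16ω)` — sixteen steps per
forcing cycle, so the regime boundaries at phases π and 3π/2 fall exactly
on step edges. Because the noise is additive, the Milstein correction
vanishes and the scheme is simultaneously the Milstein scheme (asserted
path-wise by a test). The lighting state of a step is evaluated at the
step midpoint: each step is then assigned the regime covering its
interior, and no step straddles a regime boundary. Ensembles are
integrated vectorised over paths; noise for all paths is drawn from a
single generator seeded via `SeedSequence(base_seed)` (paths are iid),
while `simulate_path` gives per-seed reproducible single trajectories.

## Equilibria, stability and basins (deterministic system)

With equal lengths the two-path system has the trivial state, two axis
states `(1/δ, 0)`, `(0, 1/δ)`, a symmetric interior state
`δD = (1+ε)/(1+4ε)`, and — for ε < 1/4 — two further interior points on
the rays `D2 = a D1` where `a` solves
`εa³ + (ε−1)a² − (ε−1)a − ε = 0`. The cubic factors exactly as
`(a−1)(εa² + (2ε−1)a + ε)`, giving `a1 = 1` and
`a_{2,3} = [(1−2ε) ± √(1−4ε)]/(2ε)` with `a2·a3 = 1`; the closed-form
factorisation avoids root-finder tolerances. The Jacobian is implemented
in closed form with self-reinforcing diagonal and *negative*
cross-inhibition off-diagonal entries (verified against finite
differences); its eigenvalues at the axis points are (−δ, −δ) and at the
symmetric point (−δ, δ(2C−1)) with `C = 4ε/(1+4ε)`, so the symmetric
state loses stability in a sub-critical pitchfork exactly at ε = 1/4.
The `a2/a3` points are classified numerically from the Jacobian (they are
saddles sitting on the basin boundaries). The rays `D2 = a_{2,3} D1` are
invariant lines, so basin membership is decided by position relative to
them; points within a relative tolerance of a ray are labelled
`boundary` rather than guessed.

The equilibria of the *forced* regimes (a branch permanently lit shifts
the interior state) have no closed form here and are obtained numerically
when needed.

## Equation-free reduction

The decision coordinate is assumed to follow a 1D Itô diffusion
`dc = μ(c, τ) dt + σ(c, τ) dW`. Drift and diffusion are estimated from
simulated increments by binned conditional moments,
`μ(x) = ⟨Δc | c = x⟩/Δt` and `σ²(x) = Var(Δc | c = x)/Δt`, with bin width
0.04 over [−1, 1] and lag equal to one integration step. Because the
process is time-inhomogeneous, increments are grouped by the forcing
regime of their starting step; with midpoint regime assignment and 16
steps per cycle no increment straddles a regime boundary. Increments that
begin after a path has committed (c frozen at ±1) carry no dynamics and
are excluded. Unpopulated bins are flagged NaN, never zero-filled; when a
coefficient function is evaluated, interior gaps are filled by linear
interpolation between populated bins and the profile is clamped flat
beyond the outermost populated bin — constant extrapolation adds no model
assumption beyond the resolution the data support.

The time-homogeneous surrogate averages the per-regime coefficients with
the regime duration weights (1/2, 1/4, 1/4 for the canonical forcing).
The reduced process is re-simulated by Euler–Maruyama on the
piecewise-linearly interpolated coefficient grid, with ±1 absorbing,
either switching regimes with the phase or using the time-averaged pair.
The estimation defaults feed the full canonical ensemble (5000 paths) to
the estimator; the estimator itself is validated on a synthetic
Ornstein–Uhlenbeck benchmark with known coefficients.

## Stationary Fokker–Planck analysis

From the time-averaged coefficients the package computes the potential
`U(c) = −∫ 2μ̂/σ̂² ds` (integrated from the left domain edge; the formal
lower limit only shifts U by a constant, which the normalised profile
removes), the stationary density `π ∝ exp(−U)/σ̂²`, and the splitting
probabilities via the scale function,

    p_{+1}(x) = ∫_a^x exp(+U) ds / ∫_a^b exp(+U) ds ,

the standard exit-problem solution for two absorbing boundaries. The
scale-density convention (reciprocal of the stationary-density integrand)
is validated against a Monte-Carlo absorption oracle that simulates the
1D SDE to absorption and reports binomial confidence intervals; paths not
absorbed within the step budget are reported, never silently classified.
Quadrature is trapezoidal on the estimation grid refined tenfold by
linear interpolation — the coefficients are only bin-resolution accurate,
so higher-order quadrature would add no information. Exponentials are
max-shifted before exponentiation for overflow safety. Where boundary
σ̂² estimates vanish or are undefined they are clamped to the nearest
interior positive value; boundaries are absorbing throughout.

Decision metrics derived from the profile: the decision point `x*` where
`p_{+1} = 1/2` (linear interpolation of the monotone profile); the
integral of `p_{+1}` over [−1/2, 1/2], which is the mean probability of a
correct decision for a start drawn uniformly from the metastable band
(band width 1); and the residual revision probability,
`max( max_{x>−0.25} p_{−1}(x), max_{x<−0.75} p_{+1}(x) )`.

## What the synthetic generator does and does not emulate

The generator reproduces the *structure* of the proposed photophobic
two-choice experiment: competing tubes, intermittent asymmetric lighting,
additive fluctuations, absorbing retraction. It does not emulate shuttle
streaming oscillations (averaged out by constant sources), sensory-level
time averaging, multiplicative or colored noise, chirality or other
directional bias of a real plasmodium, or more than two competing paths.
Passing tests therefore demonstrate properties of this model class, not
of the organism; the package's claim is that *within the model*, noise is
necessary and sufficient for correct risk integration at these parameter
scales.

## Problem sizes

The canonical ensemble is 5000 paths × 16 000 steps (horizon 200π at 16
steps per cycle); the reduced-model comparison uses 500 paths; the
Monte-Carlo splitting oracle uses 250–400 paths per starting point at
`dt = 0.005`; estimator validation uses 10⁵ OU increments; basin-oracle
checks use 100 random initial conditions integrated to `t = 60/δ`. Unit
tests use shorter horizons (40π) and smaller ensembles (400 paths) of the
same generator.

## Known limitations

* The 1D reduction is an approximation: conditioning on `c` alone
  marginalises over the total conductivity, so the estimated σ̂²(c)
  includes projection variance. The reduced model reproduces the full
  model's terminal mean within sampling error, but its variance along the
  trajectory is systematically lower.
* The splitting-probability profile is exponentially sensitive to
  `2μ̂/σ̂²`. With coefficients estimated self-consistently from the
  canonical ensemble the transition from wrong to correct decision spans
  roughly [−0.7, −0.25] (decision point ≈ −0.48, mid-band correct
  probability ≈ 0.94, residual revision probability ≈ 0.03); the profile
  is consistent with the simulated ensembles — analytic `p_{+1}(−1/3)`
  ≈ 0.91 versus a simulated correct fraction ≈ 0.89 — but claims of a
  much sharper transition cannot be reproduced by this self-consistent
  chain, and would themselves contradict an 89% correct fraction from
  c₀ = −1/3.
* Noise-level sensitivity around the default (amplitude 0.05): at 0.035
  the transition sharpens (residual ≈ 0.001) but ~12% of paths remain
  undecided at the horizon; at 0.06 decisions are fast but the correct
  fraction drops to ~81%. The default sits where the decision statistics
  of the canonical experiment are reproduced.
* The deterministic maze claim (shortest-path survival) is exercised on
  the packaged arena only; with μ = 2 and strongly heterogeneous
  geometries, multi-path or non-shortest equilibria of the network model
  are possible.
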