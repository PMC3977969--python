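# Methods

## Model

A branch-payoff game on the unit strategy interval is defined by two affine
payoff branches: the focal player receives `g(x, y)` when its strategy lies
below the opponent's and `h(x, y)` when above. The discontinuous payoff
`h + (g − h)·H(y − x)` (Heaviside step `H`) is replaced by the expected
payoff under perception/implementation errors,

    E_k(x, y) = h(x, y) + (g(x, y) − h(x, y)) · f_k(y − x),

where the smoothing function `f_k` is the probability that errors award the
focal the "lower-strategy" branch. `f_k` is smooth, non-decreasing, has
`f_k(0) = 1/2`, tends to 0/1 at ∓∞, and converges to `H` as the sharpness
`k → ∞`. The shipped family is the logistic sigmoid in `k·x`; it satisfies
every property above, is complementary (`f_k(x) + f_k(−x) = 1`), and has
slope `f_k′(0) = k/4` — the only feature of the family the TD analysis
depends on. `k = ∞` is represented symbolically and dispatches to the exact
step with tie value `H(0) = 1/2`, so the discontinuous game is available as
a labeled series rather than as a large-`k` approximation. Logistic values
are computed through `scipy.special.expit`, which is overflow-safe for any
`k·x`.

Concrete games, both with the strategy interval normalized to `[0, 1]`:

* **Traveler's Dilemma** (reward/punishment `R`): `g = x + R`, `h = y − R`.
* **Minimum Effort Coordination** (effort cost `c`): `g = (1 − c)x`,
  `h = y − c·x`.

Because `f_k(0) = 1/2`, the diagonal payoff is the branch average, which
reproduces the original games' tie payoffs (`x` for TD, `x(1 − c)` for MEC)
at every `k`, including `∞`.

## Adaptive dynamics

Invasion fitness of a rare mutant `u` in a resident-`x` population is
`S_x(u) = E(u, x) − E(x, x)`; the selection gradient is its mutant-direction
derivative at `u = x`, with closed form

    D(x) = ∂₁h + (∂₁g − ∂₁h)·f_k(0) − (g − h)·f_k′(0)   (diagonal values).

For TD this is the constant `1/2 − 2R·f_k′(0)`; for MEC, `1/2 − c`,
independent of the smoothing. Neither game has singular strategies (the
gradients do not depend on `x`), so strategies run monotonically to an
endpoint: claims rise iff `R < 1/(4 f_k′(0))` (`= 1/k` for the logistic
family) and efforts rise iff `c < 1/2`.

Custom games with user-supplied branches can have interior zeros of `D`.
These are located by a 101-point grid scan with bisection refinement
(`|D| < 1e−10` or bracket `< 1e−12`) and classified by two central-difference
second-order quantities (step `1e−5`): `dD/dx < 0` gives convergence
stability, negative mutant-direction curvature of `S_x` gives an ESS, and a
convergence-stable fitness minimum is a branching point. Quantities within
`1e−7` of zero are flagged indeterminate; these tolerances separate the test
games' order-1 curvatures from finite-difference noise. MEC at `c = 1/2`
has `D ≡ 0`; since a root list cannot represent a neutral continuum, the
finder warns (`DegenerateGradientWarning`) and returns no roots, and
classification reports indeterminate flags.

The canonical equation `dx/dt = D(x)` is integrated by fixed-step classical
Runge–Kutta (default step 0.01) with the state clipped to `[0, 1]` after
every stage: the strategy space is a closed interval and the endpoints are
absorbing.

## Agent-based model

The population occupies the vertices of a graph; the same graph serves for
interaction and updating. One generation is `N` asynchronous interaction
steps followed by `N` asynchronous update steps, both sampling the
population with replacement. An interaction step draws a focal vertex
uniformly, a co-player uniformly from its neighbors, and **overwrites** the
focal's stored payoff with the payoff from that single game (only the focal
is credited; unsampled vertices keep their stale payoff, initially 0). An
accumulate mode is available behind a flag but is off by default. An update
step draws focal `i` and neighbor `j` and lets `i` adopt `j`'s strategy with
the Fermi probability `1/(1 + exp(−β(π_j − π_i)))` (selection strength
`β`), or with the replicator probability `max(0, π_j − π_i)/Δmax`, where
`Δmax` is the payoff-range width of the discontinuous game (`(−R, 1+R)` for
TD, `(−c, 1−c)` for MEC). For small `k` the smoothed MEC payoff can slightly
exceed that range (the payoff is a pointwise convex combination of `g` and
`h`, and `max h = 1`), so the replicator probability is clamped to `[0, 1]`.

Mutation: under the Fermi rule, when adoption occurs, with probability `μ`
the adopted value is replaced by a draw from `Normal(s_j, σ)` clamped to
`[0, 1]`. Under the replicator rule mutation instead fires with probability
`μ` per update step regardless of adoption. This asymmetry is deliberate:
proportional imitation never copies at payoff ties, so from the monomorphic
start (one uniform strategy for all, payoffs equalizing within a few
generations) adoption-gated mutation would freeze the replicator dynamics
permanently, with no channel left for variation; per-step exploration is
the standard way to keep the mutation supply open, and with it the two
rules produce the same evolutionary outcomes.

The population starts monomorphic at a single uniform draw from `[0, 1]`.
One master seed spawns labeled sub-streams (graph construction,
initialization, dynamics), making every trajectory bit-reproducible from
the configuration alone.

### Default parameters

| parameter | default | meaning |
|---|---|---|
| `μ` | 0.01 | mutation probability per imitation/update event |
| `σ` | 0.05 | mutation standard deviation (strategy units) |
| `β` | 10 | Fermi selection strength |
| `k` | 20 | smoothing sharpness (TD threshold `R* = 0.05`) |
| tail fraction | 0.1 | final fraction of generations averaged |
| histogram bins | 30 | uniform on `[0, 1]` |

`σ = 0.05` was chosen from a drift-speed analysis: the mean strategy moves
per generation at a rate set by the mutation supply (∝ `μ·σ²·N` with a
selection bias ∝ `β·D·σ`), and `σ` an order of magnitude smaller leaves the
population pinned near its starting strategy for far longer than any
practical run length, whereas 0.05 equilibrates in a few hundred
generations while keeping mutation noise well below the strategy scale.

### Graphs

Complete; random regular of degree 10 (networkx pairing construction,
resampled with an incremented sub-seed until connected); scale-free by
Barabási–Albert preferential attachment with 5 edges per arrival (mean
degree ≈ 10, the canonical generator for that constraint); and square
periodic lattices with von Neumann (4) or Moore (8) neighborhoods.
Lattices require a perfect-square `N` with side ≥ 3 (smaller tori fold
diagonal neighbors together).

### Problem-size presets

`scale="paper"` uses `N = 900` (lattices) / `N = 1000` (other kinds) and
20000 generations — the published sweeps' generation count with population
sizes chosen as round numbers of the order typical for this literature.
`scale="test"` uses `N = 196/200` and 2000 generations, sized so the full
acceptance suite runs in minutes; at the shipped defaults the dynamics
equilibrates well within 2000 generations, so the two scales give the same
classifications. Sweeps default to 21 parameter values (step 0.05) and
10 runs per point with deterministic per-cell seeds.

## What the simulations do and do not show

The agent-based model verifies the direction-of-selection predictions
(high/low outcomes on each side of the analytic thresholds), their
robustness across network topologies and update rules, and the contrast
between smoothed and discontinuous TD games. It is a model of imitation
with errors, not of human learning: no claim is made about transient
time scales, about the sharpness of the empirical transition, or about
finite discrete strategy sets (the discrete games are analyzed only via
exhaustive Nash enumeration). Near-threshold parameters (`R ≈ 1/k`,
`c ≈ 1/2`) are nearly neutral and their outcomes are seed-dependent by
construction; tests therefore probe well-separated parameter values and
use majority votes over seeds.

## Known limitations

* The adaptive-dynamics classifier handles monomorphic resident
  populations only; post-branching dimorphic dynamics are out of scope.
* Interaction and updating graphs are identical by construction.
* The replicator rule's per-step mutation makes its stationary variance
  slightly larger than the Fermi rule's at equal `μ, σ`; classifications
  are unaffected.
* `payoff_bounds` reports the discontinuous game's tight range; for small
  `k` the smoothed MEC payoff can exceed it slightly (see above).
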