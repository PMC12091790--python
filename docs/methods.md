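# Methods

## Model

The package implements a discrete-time, two-layer coupled model of
epidemic spreading and protective behavior. The two layers are undirected
simple graphs on the same `N` individuals with identity coupling: the
*upper* layer carries the behavior game (whose payoffs are compared along
its edges), the *lower* layer carries transmission. Each individual holds
one joint state in {M, U} × {S, E, I, R}; both E (pre-symptomatic) and I
(symptomatic) transmit.

One step applies three sub-transitions in a fixed order:

1. **Game switching.** Each individual flips its behavior state with a
   probability blending a Fermi imitation term and a risk-perception term
   (below).
2. **Government intervention.** Each U individual remains U with
   probability `w(z) = H(θ − z) · m(z)`, `m(z) = 1/(1+e^{−δ(z−0.5)})`, and
   is converted to M otherwise. The Heaviside convention is `H(x) = 1` for
   `x > 0` and `0` for `x ≤ 0`, so at prevalence `z ≥ θ` conversion is
   certain (strict control). The government never demotes M individuals.
3. **Epidemic transition.** A susceptible escapes each infectious
   neighbor independently, with per-contact escape factor `1 − β^M` or
   `1 − β^U` chosen by its *post-intervention* behavior state; then E→I
   with probability σ and I→R with probability μ; R is absorbing.

The deterministic engine (`mumseir.mmca`) propagates, per node, the joint
probability distribution over the eight states; the update factorizes as
the 2×2 behavior chain (game then government) followed by the 4×4
epidemic chain conditioned on the post-intervention behavior state. The
agent-based engine (`mumseir.mc`) performs the same three stages
synchronously on discrete states, with all behavioral quantities computed
from the start-of-step snapshot, so both engines estimate the same
process.

### Payoffs, cost, and perception

The benefit of protection for node `i` is the one-step gain in escape
probability, `b_i = q_i^M − q_i^U ≥ 0`. Its cost is
`c(t) = c₀ + Σ_{τ=1..t} a^{t−τ} φ e^{−t/η}` (closed form
`c₀ + φ e^{−t/η}(1−a^t)/(1−a)` for `a < 1`): past effort accumulates
geometrically but is damped by a compliance-fatigue factor at the current
step, so the cost relaxes back to `c₀`. Total payoff
`D_i = Σ_{j∈N(i)} b_j s_j − c(t) s_i + b_i s_i` uses binary strategies in
the agent-based engine and the current probability of being M in the
deterministic engine (expected-strategy closure — exact on deterministic
states). The Fermi term `F_i = 1/(1+e^{−(D_i−D̄_i)/ω})` compares `D_i`
with the mean payoff of its upper-layer neighbors; an isolated node is its
own reference, giving `F = 1/2`.

With perceived risk `r(z) = η z^α` (and `r(0) = 0`), the switching
probabilities are

- adopt protection (U→M): `ζ F_i + (1 − ζ)(1 − r)`
- abandon protection (M→U): `ζ F_i + (1 − ζ) r`

The perception channel therefore pulls individuals *toward* compliance at
low prevalence and erodes it at high prevalence. This assignment is a
deliberate design choice: it pins the post-epidemic equilibrium — at the
baseline parameters the uniform fixed point is
`p^U = w(0)·ζ/2 ≈ 0.109`, i.e. an 89/11 protected/unprotected split —
and makes the compliance level respond to the game weight ζ in the
intuitive direction (a larger game weight weakens ambient compliance
pressure and enlarges outbreaks). The opposite assignment would instead
equilibrate near 67/33 and reverse the ζ response. A consequence worth
knowing: with this choice a larger risk-importance exponent α (risk
discounted more heavily) slightly *reduces* the attack rate at the
baseline, because lower perceived risk strengthens the `(1−ζ)(1−r)`
adoption term mid-epidemic.

One parameter, η, deliberately serves double duty as the cost-fatigue
scale and the perception gain; the two roles never interact in the same
expression.

### Epidemic threshold

Near onset the infection probabilities vanish: `z = 0`, `q = 1`, `b = 0`,
`c(t) → c₀`. The behavior layer then has a self-consistent disease-free
fixed point `p^U_i` (iterated to `1e−10`; from a uniform start the payoff
gaps vanish, `F = 1/2`, and the fixed point is uniform:
`p^U = w(0)·ζ/2`). Linearizing the exposed-mass dynamics around this
state gives an eigenvalue condition on
`C_ij = (k p_i^M + p_i^U) B_ji`, and the threshold
`β_c = μσ/(Λ_max(C)(μ+σ))`; `1/σ + 1/μ` is the mean infectious lifetime,
so `β_c · lifetime · Λ_max(C) = 1` at criticality. `Λ_max` is the Perron
root of the nonnegative matrix `C`, computed densely below 600 nodes and
by sparse Arnoldi iteration (deterministic start vector) above.

Because the disease-free limit sets `r = 0`, makes `H(θ − 0) = 1` for any
admissible `θ > 0`, and cancels `c₀` out of the Fermi term at the uniform
fixed point, the threshold responds to ζ, δ, k, σ, μ and the topology but
is exactly *flat* in α, θ, and `c₀`. Threshold sweeps therefore check
weak (non-strict) monotonicity.

## Parameters

| name | meaning | default | admissible |
|---|---|---|---|
| `beta_U` | per-contact infection probability, unprotected | 0.5 | [0,1] |
| `k` | protection decay factor, `β^M = k β^U` | 0.4 | [0,1] |
| `sigma` | E→I progression probability | 0.3 | [0,1] |
| `mu` | I→R recovery probability | 0.5 | [0,1] |
| `omega` | Fermi noise scale | 0.5 | >0 |
| `c0` | immediate protection cost | 0.5 | [0,1] |
| `a` | cost accumulation factor | 0.5 | [0,1] |
| `phi` | accumulated-cost scale | 0.5 | [0,1] |
| `eta` | compliance/attention factor | 0.5 | (0,1] |
| `alpha` | risk-importance exponent | 1.0 | >0 |
| `zeta` | game weight vs perception weight | 0.5 | [0,1] |
| `delta` | government control steepness | 0.5 | >0 |
| `theta` | strict-control prevalence threshold | 0.5 | (0,1] |

All defaults together are the baseline operating point used by the
experiment drivers and the acceptance script.

## Synthetic networks and initial conditions

All experiments run on synthetic two-layer Barabási–Albert networks:
each layer an independent preferential-attachment draw with `m = 3`
(mean degree ≈ 6), 1000 nodes at full scale, with a `shared` flag for
identical layers. BA topology supplies the heavy-tailed degree
heterogeneity that drives hub-dominated spreading; it does *not* emulate
clustering, degree correlations between layers, communities, or temporal
contact structure, so passing tests demonstrate internal consistency of
the model and engines, not fidelity to any empirical contact network.

Deterministic runs start every node with the same probabilities
(all-U; 98% S, 2% E) — a realization-free choice, so ensemble averaging
varies only the network draw. The agent-based engine seeds exact rounded
counts on uniformly chosen nodes. Ensembles of 100 realizations are the
full-scale study condition; the test suite scales some checks to N=500
(engine comparison, trend grids with ensembles of 20, threshold
bracketing) and N≤4 for the brute-force oracle.

## Numerical choices

- Escape products are computed in log space (O(N²) dense), with factors
  clipped to [0,1] and a `1e−300` floor before the log; an exact zero
  factor underflows to `q = 0` as it should.
- Per-node probability sums are required to stay within `1e−10` of 1 at
  every step (violation raises); no renormalization is performed.
- Convergence: L∞ change over all 8N probabilities below `1e−6` (default),
  capped at 10000 steps. Non-convergence is flagged, not raised, since the
  threshold-gated intervention can sustain limit cycles; in that case the
  reported steady state is a trailing 100-step time average instead of the
  final state. At `tol = 1e−6` a residual O(1e−5) of E/I mass may still be
  in flight when a run stops — relevant when comparing against exact
  bookkeeping identities.
- Randomness: every ensemble spawns child seeds from one master seed
  (`numpy.random.SeedSequence`); agent-based draws are made stage by
  stage, each stage vectorised in node-index order, so all runs are
  bit-reproducible.
- Isolated nodes: escape probability 1, Fermi reference equals own payoff.

## Known limitations

- The deterministic engine is a mean-field closure: it ignores dynamical
  correlations between neighbors, and its bias relative to the agent-based
  engine is largest for slow outbreaks (small `k`), where the averaged
  recovered-fraction curves can differ transiently by up to ~0.05 at
  N=500. The time-averaged gap shrinks with N.
- Because E and I are equally infectious, a faster progression rate σ
  *shortens* the mean infectious lifetime and lowers the final attack —
  while simultaneously raising the threshold. Intuition imported from
  models where only I transmits does not carry over.
- At the baseline `β^U = 0.5` the epidemic is deeply supercritical
  (final recovered fraction ≈ 0.99), so the behavioral cost parameters
  (`c0`, α) move the attack rate only at the 1e−3 level; their effects are
  better resolved near the threshold.
- Weighted, directed, temporal, and higher-order networks are out of
  scope, as are continuous-time (event-driven) dynamics and fitting to
  empirical data.
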