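# Methods

## The model

`aesthlearn` simulates how an agent's aesthetic values — predicted
rewards attached to sensory statistics — form through reward learning.
The sensory input is two-dimensional, `u = (u_b, u_c)` with `u_b` visual
balance and `u_c` visual complexity, both confined to [0, 1]. A linear
internal model with weights `w = (w_b, w_c)` predicts reward as

    v = m̄(u_c) · (w · u)

where `m̄` is the motivation — the propensity to act on the input — which
gates both the obtained reward (`r = m r*`, with `r*` the reward a fully
motivated agent would receive) and, through the prediction error
`δ = r − v = m (r* − w·u)`, the rate of learning. Weights follow the
discretized delta rule

    w(t_{k+1}) = w(t_k) + ε · m̄(u) · (r* − w·u) · u

with unit time step, so `ε` is both the discretization product and the
effective learning-rate constant. With `m̄ = 0` learning freezes: an
unmotivated agent neither acts nor learns.

Stochasticity enters through three channels, all drawn fresh each step:

* **Inputs** — `(u_b, u_c)` from a bivariate Gaussian with means
  `(μ_b, μ_c)`, standard deviations `(σ_ub, σ_uc)` and correlation `ρ`,
  truncated to the unit square and renormalized. The standard negative
  correlation (ρ = −0.5) encodes that more organized (balanced) images
  tend to carry less information (complexity).
* **Rewards** — two independent components conditioned on the input and
  summed: a linear function of balance, mean `−α + 2α·u_b`, and an
  inverted-U function of complexity, mean `φ + β·exp(−(u_c−γ)²/(2θ²))`,
  each with additive untruncated Gaussian noise (s.d. `σ_rb*`, `σ_rc*`) —
  rewards can be negative. The offset `φ(β, γ, θ)` is derived, not set:
  it is the unique value making the mean complexity reward integrate to
  zero over [0, 1], mirroring the zero-integral balance line, so both
  structures deliver positive and negative reward in equal amounts. It is
  computed in closed form through the Gaussian error function and
  cross-checked against adaptive quadrature in the tests.
* **Motivation** — treated in mean field: the deterministic function
  `m̄(u_c) = m_min + (m_max−m_min)·exp(−(u_c−μ_m)²/(2σ_m²))`, independent
  of balance, peaking at the preferred complexity `μ_m`. Motivation still
  fluctuates over time because the inputs do. Sampling motivation noise
  around the mean field is an open hook, deliberately not implemented.

## Standard parameters

All experiments build on one standard set: sensory
`[μ_b, μ_c, σ_ub, σ_uc, ρ] = [0.5, 0.5, 0.2, 0.2, −0.5]`; reward
`[α, σ_rb*, β, γ, θ, σ_rc*] = [0.6, 0.1, 1, 0.75, 0.1, 0.1]`; motivation
`[m_min, m_max, μ_m, σ_m] = [0.1, 0.6, 0.65, 0.1]`; `w(t_0) = [0, 0]`,
`ε = 0.01`, unit time step. The zero initial weights represent an agent
with no prior knowledge of either variable. Parameter invariants
(positive widths, `|ρ| < 1`, `0 ≤ m_min ≤ m_max ≤ 1`, `γ ∈ [0, 1]`) are
enforced by a reporting validator rather than constructor exceptions, so
invalid sets can be built, inspected and diagnosed. `θ` is taken
positive; only `θ²` enters the reward curve, so a sign would be
unidentifiable anyway. Means outside [0, 1] are allowed with a warning —
the truncation constrains samples, not means.

## Equilibrium analysis

Because `δ u` is an unbiased estimate of (half) the negative gradient of

    E(w) = ⟨(r − v)²/m⟩ = E_u[ m̄(u)·((r̄*(u) − w·u)² + σ_rb*² + σ_rc*²) ]

the learner performs stochastic gradient descent on E (the division by
`m` cancels one motivation factor since `r − v = m(r* − w·u)`). E is the
positive quadratic form `w'Aw − 2b'w + c` with
`A = E_u[m̄ u u']` and `b = E_u[m̄ r̄* u]`, so the unique fixed point is
`w* = A⁻¹b` — a motivation-weighted least-squares solution. The moments
are computed with a Gauss-Legendre product rule on the unit square
(order 80 per axis by default; the θ = 0.1 reward bump needs fine
resolution, and order-doubling leaves `w*` unchanged to ~1e−15). The
normalization of the truncated density cancels in `A⁻¹b` but is carried
explicitly so that E itself is on the correct scale; a Monte-Carlo
estimator of E over sensory draws serves as an independent cross-check.

The eigenvalue ratio of A (≈ 15 at standard parameters) is the
anisotropy of the error bowl — the "hammock": a stiff direction near the
diagonal of weight space and a shallow bed along its perpendicular. This
shape produces the fast-then-slow learning phases and the curved descent
trajectories. Per sample, all weight pairs with `m̄ u · w = v` produce
the same value (the solution hyperplane, coefficients `a_i = m̄ u_i`);
each update moves `w` along the hyperplane normal and multiplies the
sample residual by exactly `1 − ε m̄ ‖u‖²`, an identity the tests check
to 1e−12.

## Simulation procedure and numerics

Each step: draw the input, draw both reward components given it, sum
them, evaluate `m̄`, update the weights. One seeded RNG stream drives
everything; for speed it is consumed in blocks (all inputs, then all
balance noise, then all complexity noise) rather than interleaved per
step — runs are bit-reproducible from the seed either way, and the tests
assert byte-identical re-runs. Input sampling is by rejection from the
untruncated Gaussian (exact for the renormalized-restriction definition;
acceptance ≈ 97% at standard parameters), with a budget of 1000·n
proposals before a degenerate-parameters error. Weights beyond 10⁶ in
magnitude abort with a step-size diagnostic. A trajectory records, per
step, the post-update weights together with the sample, reward,
motivation, value and prediction error that produced them; recording can
be thinned (the weight-cloud window starts at step 10,000 and keeps
every 200th step to 30,000).

## Experiments and problem sizes

The figure-style experiments run 30,000 steps, the horizon the
sample-cloud illustration and the cloud-recording window imply; it is
config-exposed. Equilibrium checks (simulated cloud centers vs. `w*`)
instead use 60,000 steps with a last-third averaging window: the shallow
eigen-mode of A has time constant ≈ 1/(ε·λ_min) ≈ 8·10³ steps, so the
burn-in covers ≥ 7 time constants and the residual transient is well
inside the across-seed standard error (with only ~3.6 time constants at
the 30,000-step horizon, a transient bias comparable to 3 SE remains —
an equilibrium claim tested there would be confounded). Cloud-center
claims use 10 replicate seeds and a 3-standard-error criterion; the
"stable cloud" has no sharper published definition, so this choice is
ours.

The competition ablations hold everything standard except: A removes the
input correlation (ρ = 0); B makes the reward structures identical
(complexity reward replaced by the same linear form and noise as
balance); C fixes motivation at 1; D = C+B, E = C+A, F = A+B. "Apparent
competition" is operationalized as two numbers computed on the late
third of a run: the separation `mean(w_c) − mean(w_b)` and the Pearson
correlation of per-step weight increments. Variant D is exactly
exchange-symmetric, so its fixed point has zero separation. Variant E is
not: the second-moment matrix is near-singular (det ≈ 0.02), and the
small asymmetry between the linear and inverted-U reward structures
(`b_c − b_b ≈ 0.005`) is amplified into `w* = [0.015, 0.144]` — a
separation as large as the standard run's, confirmed independently by
quadrature and by simulation. Under this operationalization, constant
motivation plus uncorrelated inputs does **not** eliminate the
separation; it does eliminate the standard run's non-monotone
one-rises-while-the-other-falls character only in the symmetric variant
D. This is a known limitation of reading "no apparent competition" off
cloud plots: the separation metric makes the claim precise, and for
variant E the precise claim is false.

The individuality sweeps vary the motivation peak
`μ_m ∈ {0.4, 0.6, 0.85}` and the balance-reward slope
`α ∈ {0.5, 1.25, 1.7}`; equilibrium complexity and balance weights
increase monotonically along the respective sweeps, and the simulated
clouds follow. The value-probe experiment evaluates
`V(u) = m̄(u_c)(w·u)` on a grid and at five probes (the density mode and
the four quadrant centers — probe locations are configurable since no
canonical set exists): at the standard fixed point the landscape's
maximum sits at high balance and near-preferred complexity
(≈ (1, 0.65)), not at the most probable input (0.5, 0.5), and carries
roughly 3× the value — the peak-shift / value-exaggeration effect.

## What the generator does and does not emulate

The synthetic environment is the study condition, not a calibration
target: Gaussian input statistics, linear-plus-bump rewards and a
single-peak motivation are parsimonious stand-ins for real image
statistics, social reward schedules and interoceptive states. Passing
tests therefore demonstrate the internal consistency of the learning
dynamics and their analytic characterization — not that real aesthetic
preferences follow these particular functional forms. Population-level
sampling of individuals from background distributions is out of scope
(backgrounds are labels); sweeps over hand-set parameter lists stand in
for societies. Only the two-dimensional visual instance ships, although
the update rule itself is dimension-agnostic; nonlinear value functions
are not implemented.

## Known limitations

* The constant-step stochastic approximation hovers near `w*` with an
  O(ε) bias and never converges exactly; all equilibrium statements are
  statistical.
* The expected-error functional is reported undefined for motivation
  identically zero (the time average conditions on motivated steps)
  rather than 0/0.
* An "isotropic" error bowl is unattainable for inputs supported on the
  unit square: `E[u_b u_c] > 0` always stiffens the diagonal direction,
  so even fully exchange-symmetric setups have anisotropy ≫ 1 (the
  symmetric consequence that does hold — principal axes exactly on the
  diagonal/antidiagonal — is what the tests assert).
* Quadrature orders below ~40 per axis under-resolve the θ = 0.1 reward
  bump; the default order 80 is checked by order doubling.
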