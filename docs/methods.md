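# Methods

## Model and assumptions

Two species compete for a common resource pool within one generation of a
seasonally reproducing life cycle. The assumptions, in the order they enter:

1. **Quantised acquisition.** An individual of species *i* can only acquire a
   fixed amount `u_i` of resource per acquisition event. This is an idealised
   device for controlling within-species allocation inequality with a single
   parameter: at fixed total resource, larger units mean fewer, lumpier
   allocations and a larger coefficient of variation between individuals.
2. **Random sequential allocation.** Individuals are drawn one at a time,
   each draw independent, with probability proportional to per-individual
   weights `α_i` (constant within a species). A drawn individual takes a full
   unit while the remainder allows; a remainder exactly equal to the unit
   counts as a full unit (half-open interval convention). Otherwise the drawn
   individual consumes the whole remainder as a *leftover*, which ends the
   process and never counts toward reproduction — even if the other species'
   smaller unit would still have fit. If the remainder hits exactly zero the
   process ends with no leftover recipient (probability zero under an
   exponential pool; it matters only in fixed-resource tests).
3. **Threshold reproduction.** An individual reproduces iff it holds at least
   `s_i` full units (actual requirement `w_i = u_i s_i`), leaving `λ_i`
   offspring on average.
4. **Maximum-entropy resource pool.** Only the mean `R̄` of the pool is
   known, so `R` is taken exponential with mean `R̄` — the least-biased
   distribution consistent with that knowledge. All closed forms below depend
   on this choice; the fixed-`R` laws are also implemented and connected to
   the exponential-`R` laws by an explicitly tested mixture identity.

Under these assumptions the expected next-generation sizes are exactly a
Hassell–Comins map with `a_i = e^{u_i/R̄} − 1`, `θ_i = s_i`, and
`b₁₂ = [(1−e^{−u₂/R̄})/(1−e^{−u₁/R̄})](α₂/α₁)` (so `b₁₂b₂₁ = 1`). The
package treats the closed forms, the exact allocation laws, and the
individual-based simulator as three independent routes to the same
quantities, and its test suite and `verify` command are built around their
cross-agreement.

## Parameters

| parameter | meaning | units | typical default |
|---|---|---|---|
| `u_i` | resource-unit size | resource | 1–2 |
| `s_i` | units required to reproduce | count, ≥ 1 | 1–2 |
| `λ_i` | offspring per reproducer | count | 2 |
| `α_i` | per-individual selection weight | relative | 1 |
| `R̄` | mean total resource | resource | 10–50 |
| `N_i` | population size | count | 5–20 |

Only `α₂/α₁` matters. `u_i/R̄` controls both the intraspecific coefficient
and the inequality level; the *constrained* parameterisation
(`ConstrainedSpec`) varies `s₁` (hence `u₁`) while holding fixed the expected
maximum number of reproducers `k₁` (via `s₁(e^{u₁/R̄}−1) = 1/k₁`) and the
interspecific coefficient `b₁₂` (via `α₂/α₁`), which isolates the pure effect
of within-species inequality on the reproduction curve.

## Map variants

`expected_next_generation` dispatches on a variant name: `general` (the
reference form), `equal_unit` (exact reduction at `u₁=u₂`, where `b₁₂`
collapses to `α₂/α₁`), `small_unit` (first-order Taylor form in `u_i/R̄`),
`constrained` (the general map rewritten through `k_i = 1/(s_i a_i)`),
`scramble_contest` and `double_scramble` (the `s→∞`, fixed-`w` Ricker
limits, with limit coefficients `b₁₂ = (1−e^{−u₂/R̄})R̄α₂/(u₁α₁)` and
`u₂α₂/(u₁α₁)` respectively), and the phenomenological Hassell forms. The
limit variants are their own closed forms, not large-`s` approximations; in
config files `s: inf` routes to them.

Convergence rate to the scramble limit: the constrained map is exactly
`[1+c/s₁]^{−s₁}` with `c = (N₁+b₁₂N₂)/k₁`, so its relative deviation from
the Ricker form `e^{−c}` is `exp(c²/2s₁ − …) − 1 ≈ c²/2s₁` — about 2.3% at
`s₁ = 200`, `c = 3`, falling as `1/s₁`. The verification registry asserts
this exact rate rather than a tighter bound the mathematics does not permit.

## Distributions and truncation policy

All allocation laws are standard distributions and their compounds
(binomial, geometric on `{0,1,2,…}`, negative-binomial-like joint law), and
their pmf evaluation goes through `scipy.stats` / `scipy.special` in log
space. Geometric supports include zero, as forced by the positive
probability of an individual (or a species) acquiring no unit. Infinite
supports are truncated adaptively from the geometric ratio so the omitted
tail is below a requested bound (default `1e-12`, split across the two
marginals for the joint law); the bound is carried on every returned `Pmf`
/ `JointPmf`, and a grid-size cap raises an error rather than silently
degrading the tail. The enumeration oracle folds the tail into an explicit
error bound `λ_i N_i × tail` on each expectation.

The mean of the marginal unit-count law is implemented as
`m̄₁ = [(e^{u₁/R̄}−1)(N₁+b₁₂N₂)]^{−1}` (and `M̄₁ = N₁ m̄₁`). This is the form
that (a) equals the exact mean `x/(1−x−y)` of the geometric marginal
(verified symbolically and numerically), (b) reduces to `M̄ᵐᵃˣ` for a lone
species, and (c) makes the geometric tail reproduce the closed-form
reproduction probability exactly. An alternative display of the same mean
circulates with `(1−e^{−u₁/R̄})` in that position; it is larger by the factor
`e^{u₁/R̄}` and inconsistent with the three properties above. The `verify`
report computes both and surfaces the discrepancy rather than adopting
either silently.

## Simulator design

`simulate_allocation_sequential` exploits the fact that the species sequence
of the draws is independent of the running remainder: a block of at most
`⌊R/u_min⌋ + 1` draws is generated up front, the terminal draw is located on
the cumulative consumption, and the counted units are assigned to
individuals multinomially (uniform within species, as conditioning requires)
— distributionally identical to a literal one-draw-at-a-time loop and an
order of magnitude faster. Individuals are distinguishable for bookkeeping
only; permutation invariance of all summaries is tested.

Offspring are deterministic `λ_i × reproducers` by default, since the model's
object is the expectation; `sampled` mode draws Poisson(`λ_i`) offspring per
reproducer and is documented as an extension (only the mean is part of the
model). Each Monte-Carlo replicate uses an independent substream derived
from `(seed, replicate)`, so runs are reproducible and replicates
order-independent.

Monte-Carlo problem sizes: the verification presets use 10⁵ replicates at
populations of 10–40 individuals and `R̄` up to 50, which puts standard
errors near 0.3% of the means — small enough that a systematic error of one
standard error would be caught, while a full preset battery completes in
well under a minute. Iterating the expectation map over generations
(`map --steps`) treats an expected size as a realised one; that substitution
is exact only in the large-population limit, and the CLI logs a warning
rather than taking a position on its validity for finite populations.

## What the generator emulates — and what it does not

The simulator realises the model's idealisations exactly: quantised
acquisition with a species-constant unit size, a memoryless (exponential)
resource pool, selection probabilities independent of holdings, and no
spatial or temporal structure within a generation. Real systems violate all
four in various ways — acquisition rates that grow with holdings
("rich-get-richer") would produce far stronger inequality, resource pools
need not be exponential, and site or patch structure changes the
combinatorics. Passing tests therefore certify the internal consistency of
the derivation (simulation ↔ exact laws ↔ closed forms), not the fidelity of
any of these assumptions to field data. Fitting to data, multi-species
extensions, and the long-run dynamics of the iterated maps
(stability/bifurcation/coexistence) are out of scope.

## Numerical choices

- `e^x − 1` and `1 − e^{−x}` always via `expm1`; powers `(1+z)^{−s}` via
  `exp(−s·log1p(z))`, stable for `u/R̄` down to 10⁻¹² and `s` in the
  hundreds.
- Peak finding on reproduction curves: grid argmax (first occurrence, i.e.
  ties toward smaller `N₁`) refined by bounded scalar minimisation with
  `xatol = 1e−10 × max(1, N₁ᵐᵃˣ)`; boundary argmaxima report no peak, which
  distinguishes monotone (contest) from overcompensating (scramble) curves.
- Degenerate inputs: `N_i = 0` gives `f_i = 0` with no special-casing;
  empty-community selection, non-integer simulator states, `λ ≤ 1` fixed
  points, `u₁ ≠ u₂` pre-divided allocation, and unreachable truncation
  targets all raise `ValidationError`.
- The mixture identity (fixed-`R` law integrated against the exponential
  density) is checked by adaptive quadrature with breakpoints at the
  termination-interval edges, tolerance `1e−12` absolute per entry.
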