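# Methods

## The game

Each plant follows one of two heritable strategies: BVOC **emitter** (E) or
**non-emitter** (N). Herbivory removes a fraction `p` of seed output. An
emitter's own signal reduces its damage by the intra-communication factor
`alpha1 < 1`; every emitting neighbor within signaling range reduces
anyone's damage by the inter-communication factor `alpha2 < 1` per emitter,
compounding to `alpha2**M` over `M` emitters. Emission costs a fraction `c`
of seed output. With `fhat` the seed output absent herbivory and cost,

    f_E = (1 - p * alpha1 * a2hat) * (1 - c) * fhat
    f_N = (1 - p * a2hat) * fhat,            a2hat = alpha2**M.

`fhat` is a common positive factor of every fitness; it cancels from the
lattice colonization probabilities and from the sign of the replicator
dynamics, so it never changes a reported outcome. It defaults to 1 and is
kept as a parameter for fidelity to the fitness definitions. Herbivory is
deterministic in expectation — `p` enters fitness only as a multiplicative
damage factor; herbivores do not move or crowd.

## Lattice model

A periodic L×L square grid (torus, Chebyshev metric); each site is vacant,
E, or N. One synchronous generation:

1. **Fitness** at every occupied site from the emitter count `M` within the
   Moore radius `r_bvoc`, focal site excluded.
2. **Mortality**: every occupied site dies independently with probability
   `d`. Dead plants contribute nothing to any seed pool this generation.
3. **Colonization**: every vacant site (pre-existing or newly vacated)
   draws once from {E, N} with probabilities equal to each strategy's share
   of summed post-mortality fitness within the Moore radius `r_d`. The two
   shares sum to 1 whenever any occupied site is in range, so a reachable
   vacant site is always colonized; a site with an empty pool stays vacant.

Design choices where the update rule was genuinely open:

- **Self-counting.** The focal plant is excluded from `M`: its own-signal
  benefit is exactly what `alpha1` models, and counting self in `M` would
  double it. `count_emitters_in_range` takes an `include_self` flag so the
  alternative is testable.
- **Step ordering.** Fitness is evaluated on the pre-mortality state
  (plants signaled while alive), dead plants disperse no seeds, and
  same-generation vacancies are immediately colonizable. This follows the
  enumerated fitness → death → occupation protocol.
- **Measurement timing.** Emitter frequency is the E share of occupied
  sites at the end of a generation — after colonization, before the next
  mortality — when the lattice is (near-)fully occupied.
- **Extinction.** Stochastic loss of either strategy (or of the whole
  population) is a legitimate outcome; runs are never restarted. Sparse
  seedings (default density 0.001 per type) lose one type before
  establishment in a noticeable fraction of replicates; experiment
  summaries count such replicates at frequency 0 (for emitter loss) rather
  than discarding them.
- **RNG.** A master seed spawns per-replicate `numpy` SeedSequence
  substreams; replicate k of cell j uses child `j * n_replicates + k` in
  row-major cell order, so every experiment is bit-reproducible.

Neighborhood sums are plain convolutions with a ones kernel in wrap mode
(`scipy.ndimage.convolve`), which is what keeps a 50×50, 5,000-step run to
about two seconds. Radii must satisfy `r < L/2`, otherwise the periodic
wrap would let a neighborhood count a site twice.

## Mean-field (random distribution) model

With plants randomly distributed, the number of emitters among the `n`
individuals in signaling range is Binomial(n, x_E), and the expected gross
inter-communication effect has the closed form

    a2bar(x_E) = (1 + (alpha2 - 1) * x_E) ** n.

The module keeps an explicit term-by-term binomial sum
(`binomial_gross_inter_oracle`, exact integer binomial coefficients) purely
as an independent cross-check of the closed form; the test suite verifies
agreement to 1e-12 over random draws.

Replicator dynamics dx_E/dt = g(x_E) = x_E (1 − x_E)(f_E − f_N) has fixed
points x_E = 0, x_E = 1 and, when the coexistence band

    (alpha2**n p - c)/(alpha2**n p (1-c)) < alpha1 < (p - c)/(p (1 - c))

holds, the interior root x_E* = ((c/(p(1+(c-1)alpha1)))**(1/n) - 1) /
(alpha2 - 1), at which f_E = f_N. The upper bound is the emission
viability threshold: above it emission cannot pay even with no
inter-communication. Stability (ESS) is decided by the sign of dg/dx_E
computed by central finite difference with h = 1e-6 — the finite
difference is the contract, and tests confirm it matches the analytic band
structure and the basins found by forward integration. A parameter point
within 1e-9 of a band edge is labeled *marginal* and carries no stability
claim. Nonpositive radicands in the interior-root formula (possible only
outside the admitted parameter ranges) report absence instead of raising.

Forward integration uses `scipy.integrate.solve_ivp` (explicit adaptive
RK45, rtol 1e-9), with the state clipped to [0, 1] against round-off and an
optional early stop once |g| < 1e-13 (the flow has reached an equilibrium
to machine resolution; the converged point is appended to the returned
samples).

## Experiments and their scale

Phase diagrams sweep (alpha1, alpha2); the lattice version reports
mean ± sd of the final emitter frequency over independent replicates per
cell, the mean-field version the stable equilibrium density. Lattice cells
are labeled emitter-only above mean frequency 0.95, non-emitter-only below
0.05, coexistence between — the cutoffs are a package choice, made
explicit as constants.

The default experiment profile is desk-scale: L = 50, 5,000 steps,
10 replicates, 0.1 grid step (for orderings between spatial-range arms,
3,000 steps, which is ~150 mortality generations at d = 0.05 and past
visual stationarity of the trajectories). The full-scale design —
L = 100, 30,000 steps, 10 replicates — runs through the same `SimConfig`
interface; regime structure is already stable at desk scale, only the
per-cell noise differs.

The spatial-range experiments compare the four Moore-radius combinations
(r_bvoc, r_d) ∈ {1,2}². To make "clumped distributions" quantitative, the
package adds a join-count statistic — the fraction of same-strategy pairs
among occupied Moore-1 neighbor pairs — with its closed-form expectation
under random labeling (hypergeometric: [nE(nE−1)+nN(nN−1)]/[m(m−1)]) as
the well-mixed reference. The statistic is an addition beyond the source
figures, which show snapshots only.

Focal parameter choices used throughout tests and the acceptance script:
c = 0.1, p = 0.4, d = 0.05, n = 8 (the lattice analogue of the Moore-1
neighborhood). The coexistence checks use (alpha1, alpha2) = (0.7, 0.9) —
chosen a priori as the most balanced cell, since the mean-field interior
equilibrium passes 1/2 at alpha1 ≈ 0.69 for alpha2 = 0.9 — together with
(0.5, 0.9).

## What the sparse-seeding start does and does not emulate

The default initial condition seeds each type at density 0.001 into a
vacant lattice, emulating rare colonists invading open habitat. It makes
early stochastic loss of a strategy part of the measured behavior, as in
the modeled system. It does not emulate established mixed stands; for
those, start from higher densities via `SimConfig`.

## Known limitations

- **Strategy exchangeability fails on the lattice even at alpha1 = 1,
  c = 0.** Sitewise fitness is then identical for E and N, but fitness
  still rises with the number of emitting neighbors, and local dispersal
  keeps emitters next to emitters — so emitters preferentially capture the
  public good and hold a systematic advantage (measured mean final
  frequency ≈ 0.63 at p = 0.4, alpha2 = 0.9 on a 40×40 lattice, decaying
  to ≈ 0.51 as p → 0, which confirms the update rule itself is
  label-symmetric). The test suite keeps a strict two-standard-error
  symmetry check at these parameters; it fails for this model-level
  reason, and the corresponding exact symmetry (g ≡ 0) is verified in the
  mean-field model instead.
- The mean-field model is deterministic and infinite-population; no
  finite-population (Moran/Wright–Fisher) variant is provided.
- Herbivore behavior (movement, aggregation, preference) and qualitative
  BVOC blend differences are outside both models.
- Lattice regime reproduction is qualitative (three regions, orderings
  between spatial ranges); per-cell frequencies are stochastic and depend
  on replicate count and grid resolution.
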