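# Methods

## Length-of-stay model

The package models an adoptable animal's length of stay (LOS) as a
geometric random variable: the animal is adopted on each day with
constant odds `D` (probability `P = D/(1+D)`), so the expected stay is
`L = 1/P = 1 + 1/D`. Constant odds is a deliberate baseline — it assumes
the shelter maintains each animal's initial adoptability — and makes the
model memoryless, so every result applies equally to animals already in
care and to new arrivals. The intended range is `L >= 2` (daily odds at
most 1); `los_to_odds` accepts shorter stays but warns, because with
adoption odds above one per day the daily time step is coarse.

Interventions act multiplicatively on the odds. This models anything
that changes adopter traffic or attention by a uniform factor (kennel
visibility, generic promotion); it does not model interventions whose
effect differs by animal. Three formulations of the per-day-of-use
LOS impact are implemented:

* `X(A, D) = (1 − A)/(1 + AD)` — proportional odds, one day of
  marketing (identical to the per-day normalized impact of marketing
  continued until adoption);
* `Y(A, λ) = 1 − A` — continuous exponential LOS with the rate scaled
  by `A`. The function takes and validates a rate argument precisely to
  document that the result does not depend on it. The same baseline
  independence holds for a Weibull LOS when the intervention scales the
  scale parameter and leaves the shape parameter alone; the package
  records that fact here but implements no Weibull sampling or fitting;
* `Z(A, D) = ((1+D)^(1−A) − 1)/D` — constant hazard within each day's
  fixed adoption window, which maps baseline odds through
  `D_A = (1+D)^A − 1`. Only the product of rate and window length
  enters, so the window length is never a parameter.

`Z` is evaluated via `expm1((1−A)·log1p(D))/D`: the naive power form
loses precision exactly in the small-`D` regime where `Z ≈ X ≈ 1 − A`
is the interesting comparison. The two forms printed in the algebra
(`((1+D)^(1−A) − 1)/D` and `(1 + 1/D)/(1+D)^A − 1/D`) agree to machine
precision; the test suite checks this. Note the agreement of `Z` with
`X` at small `D` is first-order: `Z − X = A(1−A)D/2 + O(D²)`, so at
`D = 10⁻³` the gap is below 10⁻³ for modest boosts (`A <= 1.8`) but
grows to ~10⁻² at `A = 5`. Both converge to `1 − A` as `D → 0`.

## Scenario layer

A scenario is a set of kennel tiers (capacity, odds multiplier `A`,
preference rank; at most one tier — the overflow tier, which must be the
least preferred — may be unbounded), a set of animal tracks (baseline
LOS in a reference `A = 1` kennel, mean daily intake), and a priority
mode. Overflow is modeled with unbounded capacity because it represents
last-resort housing that absorbs arbitrary spillover. Priority `"S"`
orders tracks for assignment by baseline LOS descending (slowest first),
`"F"` ascending; with more than two tracks the same ordering generalizes,
and ties keep the configured order. When ranks are omitted from a config
file, tiers default to descending multiplier order. Rank ties are a
validation error rather than broken arbitrarily: allocation must be
deterministic.

## Steady-state allocator

At steady state each track's adoption flow equals its intake rate, and
census = flow × LOS per cell (Little's law). The allocator is a greedy
waterfall: tiers in preference order; within a tier the priority track's
remaining flow is placed first; a placement is `min(remaining flow,
remaining capacity / cell LOS)`, so each tier fills completely before
flow spills to the next. Fractional census and flow are expected — the
tableau is a deterministic expectation, not a head count. No flow is
ever held back from a preferred tier to improve the global census; the
allocator is strictly greedy, matching the two fixed policies it is
meant to compare. If capacity runs out with no unbounded tier, the
solver raises and reports the unplaced flow per track.

The allocator is verified cell-by-cell against an independent
exact-rational (Fraction) implementation and against the published
allocation for the bundled example shelter.

## Monte Carlo simulator

One simulated day runs, in this order: adoptions (per-cell binomial with
probability `P(A·D)`), optional upgrades, intakes (per-track Poisson,
priority track placed first, each arrival to the best-ranked vacant
tier, falling through to overflow). Intra-day timing is deliberately not
modeled. In a fully bounded shelter, arrivals beyond capacity are turned
away; the bundled example always has an unbounded overflow tier.

**Upgrade rule.** Receiving tiers are processed best rank first. Each
receiver pulls priority-track animals from lower tiers (best-ranked
donor first, so vacancies cascade downward); non-priority-track animals
are moved only *out of the overflow tier*, never between regular kennel
classes. The narrow rule is an allocation-policy choice the simulator
commits to: kennel moves serve the policy under test, so the targeted
track chases every better vacancy, while other animals are relocated
only to get them out of emergency housing. The choice matters: measured
on the example shelter (20,000 samples), with both tracks freely
upgradeable the F-priority total census with upgrades falls to ~26.7 and
the S-vs-F gap to ~0.67; with upgrades restricted to the priority track
alone the gap balloons to ~3.1; the rescue rule gives ~27.1 and ~1.1,
the values the acceptance checks pin.

**Protocol.** Each replicate starts from the steady-state tableau
rounded to integers (nearest integer, halves away from zero; if rounding
overfills a bounded tier the non-priority track is decremented first),
burns in for 142 days, and records the terminal state as one sample.
The 142-day default is several multiples of the longest relevant
relaxation time on the example shelter (a 27-day slow-track stay in a
standard kennel), which obliterates the initial state — and therefore
also makes results insensitive to the exact discretization rule.
Defaults are 90,000 samples (standard error ≈ 0.02
on the example shelter's census total); the acceptance script uses
20,000 (SE ≈ 0.05), which resolves the ~1-animal priority gaps to a few
percent at a fraction of the cost.

**Vectorization and RNG.** Replicates are independent, so they are
simulated as a batch: occupancy is an `(n, tiers, tracks)` integer array
advanced one day at a time with vectorized binomial/Poisson draws; the
priority logic is a small fixed loop over tiers and tracks. A master
seed spawns one `numpy` `SeedSequence` child stream per batch of at most
15,000 replicates (rather than one per sample), which keeps the batch
kernel vectorized while remaining bit-reproducible for a given seed and
settings; batches could be farmed out to parallel workers without
changing results.

## What the simulations do and do not show

The example shelter is constructed, not fitted to a real facility: two
homogeneous tracks, Poisson intakes, multiplier values in the range of
published kennel-visibility effects. Within those assumptions the
simulator shows that discreteness and stochasticity preserve the
steady-state conclusion (S priority keeps the census lower) and add a
variance-driven phenomenon the deterministic analysis misses: sporadic
overflow use raises the mean census by about one animal even when
steady-state capacity suffices. The model excludes outcomes other than
adoption (euthanasia, transfers, return to owner), time-varying odds,
animal-level covariates, and any ranking of interventions themselves —
it compares allocations of a given intervention only. Cell-level Monte
Carlo occupancies depend on the exact upgrade and discretization
conventions above; totals and priority gaps are robust to them.
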