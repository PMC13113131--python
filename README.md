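# sheltersim

Discrete-time modeling of animal-shelter length of stay (LOS), marketing
impact, and in-care census.

Animal shelters have a fixed stock of adoption-promoting resources — one
spotlight kennel, a handful of high-visibility showcase kennels, a daily
social-media feature. `sheltersim` is for shelter analysts and population
-management researchers who want to reason quantitatively about where
those resources do the most good: on *fast-track* animals (expected to be
adopted quickly) or *slow-track* animals (expected to stay long).

## The model

A day is the unit of time. An available animal is adopted on any given
day with constant odds *D*, so its LOS is geometric:

    P(D) = D / (1 + D)        daily adoption probability
    Q(D) = 1 / (1 + D)        daily non-adoption probability
    L(D) = 1 / P(D) = 1 + 1/D expected LOS (days)

A marketing intervention multiplies the daily odds by a factor *A* (a
showcase kennel might have *A* = 1.5; non-viewable overflow housing
*A* = 0.5). One day of marketing changes the expected LOS by

    X(A, D) = (1 − A) / (1 + A·D)

which is also the LOS change *per day of use* of an intervention kept in
place until adoption. |X| increases with the baseline LOS, with limit
*A* − 1 — so a limited daily resource buys more census reduction when
aimed at longer-stay animals. Two alternative formulations bracket this
result: under a continuous exponential (or Weibull, scale-shifted) LOS
the per-day impact is 1 − *A* regardless of baseline, and under a
constant hazard confined to each day's adoption window the impact
Z(A, D) = ((1+D)^(1−A) − 1)/D behaves like X. The discreteness of the day
is what makes baseline LOS matter.

On top of this algebra the package provides:

* a **scenario** layer (YAML-configurable kennel tiers with capacities and
  odds multipliers; animal tracks with baseline LOS and Poisson intake
  rates; an S/F priority policy assigning slow- or fast-track animals
  preferentially to the best kennels);
* a deterministic **steady-state allocator** — a greedy waterfall over
  tiers where each cell obeys Little's law, census = flow × LOS;
* a stochastic **Monte Carlo simulator** — binomial adoptions, optional
  kennel upgrades, Poisson intakes — estimating mean census per
  (tier, track) cell from independent burned-in replicates.

## Worked example

The bundled example shelter has 1 spotlight kennel (*A* = 3), 7 showcase
kennels (*A* = 1.5), 18 standard kennels (*A* = 1) and unbounded overflow
(*A* = 0.5), with a slow track (L = 27, one intake/day) and a fast track
(L = 3, one intake/day):

```sh
sheltersim steady-state --out steady.csv
```

```
In-care census: S priority
       spotlight  showcase  standard  overflow  Total
slow         1.0       7.0      13.9       0.0   21.9
fast         0.0       0.0       3.0       0.0    3.0
Total        1.0       7.0      16.9       0.0   24.9

In-care census: F priority
       spotlight  showcase  standard  overflow  Total
slow         0.0      6.07      18.0      0.13  24.20
fast         1.0      0.93       0.0      0.00   1.93
Total        1.0      7.00      18.0      0.13  26.13
...
Total census gap (F minus S priority): 1.23
```

Giving the preferred kennels to slow-track animals (S priority) keeps
the shelter census 1.23 animals (≈5%) lower than prioritizing fast-track
animals, even though F priority generates far more adoptions *out of the
spotlight kennel* (0.600/day vs 0.103/day) — a reminder that flow through
prestige kennels is a misleading local metric.

The stochastic version of the same comparison (about 15 s for the full
90,000-sample protocol):

```sh
sheltersim simulate --samples 90000 --seed 1 --out mc.csv
```

prints mean census tables for both priorities; random fluctuations push
occasional intakes into overflow, raising the total by about one animal
over the steady state, and the S-over-F advantage persists (≈1.0 with
upgrades enabled, ≈1.4 without). Impact-curve tables for the X and Z
families are produced by `sheltersim curves`.

Library use mirrors the CLI:

```python
from sheltersim import example_scenario, solve_steady_state, census_gap

tableau = solve_steady_state(example_scenario("S"))
print(tableau.total_census)        # 24.897...
print(census_gap(example_scenario()))  # 1.230...
```

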