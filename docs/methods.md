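# Methods

## Model

A single-file pore is `i` ordered slots, each one water-molecule diameter
wide (so the pore length is `i·d_w` and `i = N_p` when full). A slot holds
exactly one of three objects: an ordinary water molecule, the tracer (an
isotopic label — dynamically identical to water, distinguishable only for
counting), or a vacancy. Two structural assumptions define the state
space: at most one tracer and at most one vacancy in the pore at any time.
Water molecules are indistinguishable, so a state is fully described by
the tracer and vacancy positions; enumeration therefore constructs the
`1 + i + i + i(i−1) = i² + i + 1` states directly rather than filtering
the `3^i` slot assignments (the test suite keeps the product filter as an
independent oracle up to i = 7).

Classification is relative to a fixed exit side, the right end (slot `i`);
left-moving transport is handled in the simulator by the mirrored event
rules, not by mirrored state classes. The four tracer-state classes are:
diffusion tracer states (tracer present; `i²`), diffusion tracer exit
states (tracer in slot `i`; `i`), osmotic tracer states (tracer present,
no vacancy; `i`), osmotic tracer exit states (full pore, tracer in slot
`i`; always 1).

## Ratio predictions

The occupancy-state argument forms P_f/P_d as the ratio of reciprocal
state counts, `(1/n_f)/(1/n_d)` or equivalently `(1/n_fex)/(1/n_dex)`,
evaluated from the enumerated census — deliberately not from the closed
forms, so any counting defect would propagate into the ratio. Both routes
give `i` exactly, as does the mean-occupancy relation `⟨n⟩ + 1` with
`⟨n⟩ = i − 1` for a pore allowed a single vacancy. The competing
literature expressions `i − 1`, `i + 1` and `(i² + 1)/(i + 1)` are carried
alongside for comparison; all values are exact rationals internally.

Display rounding is half-up to two decimals with trailing zeros trimmed
(`5/3 → 1.67`, `50/8 → 6.25`, `101/11 → 9.18`). Published comparisons of
these expressions sometimes print individual entries at coarser precision
(e.g. 9.2); the uniform two-decimal rule is kept here and comparisons
against printed values are made at each entry's printed precision.

Two limiting membranes bracket the model but contain no pore to count: a
bare lipid bilayer, where P_f/P_d = 1, and a wall with a simple hole,
where the single-file constraint is absent. Both are documentation
constants, not model outputs.

## Kinetics

The simulator realises the two proposed mechanisms as a continuous-time
Markov chain over the full occupancy-state space:

* **Knock-on collision**, rate `k_coll · a_side` per side. On a full pore
  the collision ejects the far-end molecule (the striker does not enter),
  creating a vacancy at the far end. On a pore with a vacancy anywhere
  except the struck end, it advances the single molecule on the striker's
  side of the vacancy, stepping the vacancy one slot toward the striker.
  Momentum transfer is taken to require contiguity from the struck end:
  a full column for ejection, the adjacent molecule for the vacancy step.
* **Brownian hop**, rate `k_hop` per eligible molecule, into an adjacent
  vacancy, both directions.
* **Brownian escape**, rate `k_exit` per end, only from a full pore — the
  minimal rule that preserves the one-vacancy constraint dynamically.
* **Entry**, rate `k_enter · a_side`, filling a vacant end slot. Left
  entrants are tracers with probability `tracer_fraction_L` when no tracer
  is inside; the right reservoir is tracer-free. A tracer that returns to
  the left reservoir rejoins the pool (identity is not tracked across
  reservoir residence), keeping the boundary conditions stationary.

Concerted multi-molecule fluctuations are represented as sequences of
single hops; no compound event type is introduced because no rate could be
assigned to one.

### Parameters

Time is dimensionless; the rates set the scale. Defaults: `k_coll = 1`,
`k_hop = 1`, `k_enter = 1`, `k_exit = 0.1`, `a_R = 1`,
`tracer_fraction_L = 0.1`. The ordering `k_exit < k_hop` is enforced at
validation: escaping a full pore crosses a higher barrier than moving
into an internal vacancy, which is what makes the vacancy long-lived at
equilibrium. Activities enter linearly in both collision and entry rates
(an osmotic gradient raises the entrance-side collision *and* entry
frequency). Gradient runs default to `a_L = 2, a_R = 1`.

Run defaults: horizon `t_max = 100000`, `burn_in = 1000` discarded, 20
equal time batches for batch-means standard errors. At the default rates
and i = 3 this yields roughly 300 completed tracer translocations and
~4·10⁵ events per run (well under a second), which keeps the 3-SE
oracle comparisons meaningful; runs below 100 translocations carry a
`low_precision` flag rather than raising.

### Estimators and counting conventions

Crossings are counted at the exit-side boundary: `n_water_LR` molecules
out to the right, `n_water_RL` in from the right. In the stationary state
the expected net flux is identical at either boundary, and the exact
solver computes the same functional, so simulator and oracle are directly
comparable. A completed tracer translocation is a tracer leaving to the
right (tracers only enter from the left). The estimators are the standard
tracer-flux construction:

* `P_d = (tracer L→R rate) / tracer_fraction_L`, from an equilibrium run
  (`a_L = a_R`);
* `P_f = (net water flux) / (a_L − a_R)`, from a gradient run;
* `P_f/P_d` from one run of each with otherwise identical parameters,
  with the standard error propagated from both batch-means errors.

Vacancy lifetimes are measured per episode, from the event that creates a
vacancy in a full pore to the entry that restores it; episodes straddling
the burn-in boundary or the horizon are discarded (a small censoring bias,
negligible at the default horizon).

### Exact oracle

For `i ≤ 6` the generator matrix over all `i² + i + 1` states is built
from the same event rules and `πQ = 0, Σπ = 1` is solved directly; the
stationary distribution yields exact net flux, tracer translocation rate
and full-pore probability. Reducible generators (more than one recurrent
class, e.g. no vacancy-creating events) raise a diagnostic listing the
states outside the main class. Because the tracer is dynamically identical
to water, the label-blind dynamics is left-right symmetric at equal
activities, so the exact equilibrium net flux is zero to solver precision
(~1e-12) even with a one-sided tracer source — a structural check the test
suite applies alongside mirror symmetry of the tracer-free stationary
distribution.

## What the simulations show (and do not)

The counting identity P_f/P_d = N_p is exact and parameter-free. The
simulated ratio is regime-dependent: at the default order-one rates it
exceeds N_p (≈ 4.7, 8.6, 19.8 for i = 2, 3, 5) while reproducing the
qualitative claims — the ratio grows with pore length, the equilibrium
tracer rate falls with pore length (the vacancy forces the tracer to
sample more states), and the mean vacancy lifetime under a two-fold
gradient is shorter than at equilibrium. No claim is made that a
particular rate regime makes the simulated ratio equal N_p exactly; the
oracle is provided to explore that question quantitatively.

The generator emulates idealised single-file exclusion kinetics. It has no
molecular forces, water geometry, hydrogen bonding, pore-wall energetics,
charged species, or hydraulic pressure term distinct from activity
scaling; agreement between simulator and oracle validates the stochastic
implementation, not the fidelity of the event rules to any real channel.

## Numerical choices

Exact rationals (`fractions.Fraction`) for all ratio algebra; the
stationary solve replaces one balance equation with the normalisation row
and uses a dense LU solve (the state space is ≤ 43 states at i = 6), with
negative round-off clipped and renormalised. The Gillespie loop uses the
stdlib Mersenne Twister seeded from `params.seed`; sub-seeds for paired
equilibrium/gradient runs are drawn from a seeded generator so one seed
reproduces the pair. Batch-means standard errors use non-overlapping equal
time batches (`ddof = 1`). Event selection is by bisection on per-state
cumulative rate tables precomputed once per run.

## Known limitations

* The state space treats reservoirs as structureless sources/sinks; there
  is no finite-bath depletion and no tracer accumulation on the right.
* Lifetime censoring at the horizon slightly truncates the longest
  episodes.
* `P_f` is defined per unit activity *difference*; comparisons across
  gradients assume the near-linear response regime (the exact flux is
  checked to be increasing in the gradient near equilibrium, not linear
  globally).
* The CLI caps enumeration at i = 64 purely to keep outputs sane; the
  mathematics imposes no bound.
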