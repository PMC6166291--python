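"""Stochastic kinetics of the single-file pore: knock-on collisions and
Brownian hops, simulated exactly (Gillespie) and solved exactly (master
equation) for small pores.

Mechanisms
----------
The pore exchanges molecules with two reservoirs whose water activities
``a_L`` (entrance side) and ``a_R`` (exit side) scale the collision and
entry rates linearly.  An osmotic gradient is ``a_L > a_R``.  Events:

* **Knock-on collision** (rate ``k_coll * a_side``): a reservoir molecule
  strikes the column.  On a *full* pore the momentum is transmitted through
  the contiguous column and ejects the far-end molecule, leaving a vacancy
  at the far end; the striker does not enter.  If the pore already holds a
  vacancy anywhere except the struck end, the collision instead advances the
  single molecule on the striker's side of the vacancy into it, stepping the
  vacancy one slot toward the striker.
* **Brownian hop** (rate ``k_hop`` per eligible molecule): a molecule
  adjacent to the in-pore vacancy jumps into it, either direction.
* **Brownian escape** (rate ``k_exit`` per end): an end-slot molecule of a
  *full* pore leaves into the adjacent reservoir (disabled otherwise, which
  is the minimal rule preserving the at-most-one-vacancy constraint).
  The barrier ordering ``k_exit < k_hop`` is enforced: escaping the pore is
  harder than moving into an internal vacancy.
* **Entry** (rate ``k_enter * a_side``): a reservoir molecule fills a vacant
  end slot.  Entrants from the left are tracers with probability
  ``tracer_fraction_L`` (when no tracer is already inside); the right
  reservoir is tracer-free, matching the tracer thought-experiment where
  labelled water is added on the entrance side only.

Fluxes are counted at the exit-side (right) boundary: ``n_water_LR`` is the
number of molecules leaving to the right reservoir, ``n_water_RL`` the
number entering from it; in steady state the expected net flux is the same
at either boundary.  A tracer leaving to the right is a completed
left-to-right translocation (tracers only ever enter from the left).

The estimators follow the standard tracer-flux construction:
``P_d = (tracer L→R rate) / tracer_fraction_L`` from an equilibrium run and
``P_f = (net water flux) / (a_L - a_R)`` from a gradient run, both in
molecules per unit time, so their ratio is dimensionless and directly
comparable with the occupancy-state prediction N_p.  Standard errors come
from non-overlapping batch means (>= 20 batches).

For ``i <= 6`` the continuous-time Markov generator over all
``i**2 + i + 1`` occupancy states is built explicitly and its stationary
distribution solved by linear algebra, yielding exact fluxes that serve as
the oracle for the simulator.
"""

from __future__ import annotations

import enum
import math
import random
from bisect import bisect_left
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
from scipy.sparse.csgraph import connected_components

from .states import (
    Occupant,
    PoreConfiguration,
    enumerate_configurations,
    format_configuration,
)

__all__ = [
    "KineticParams",
    "EventKind",
    "Event",
    "TrajectoryStats",
    "PermeabilityEstimates",
    "StationarySolution",
    "VacancyLifetimeSummary",
    "DegenerateSystemError",
    "ReducibleChainError",
    "event_set",
    "simulate",
    "estimate_permeabilities",
    "permeability_ratio",
    "build_generator",
    "solve_stationary",
    "vacancy_lifetime_summary",
]

MAX_ORACLE_I = 6


class DegenerateSystemError(RuntimeError):
    """No event can fire from the current configuration (all rates zero)."""


class ReducibleChainError(RuntimeError):
    """The generator has more than one recurrent class."""

    def __init__(self, message: str, unreachable: list[str]):
        super().__init__(message)
        self.unreachable = unreachable


@dataclass(frozen=True)
class KineticParams:
    """Rates and run settings for the pore simulator.

    Time is dimensionless — the rates set the scale.  Defaults put all
    order-one processes at rate 1 and encode the barrier ordering
    ``k_exit < k_hop`` (leaving a full pore costs more than filling an
    internal vacancy).

    Parameters
    ----------
    i : pore length in slots.
    k_coll : base knock-on collision attempt rate per side; the effective
        rate is ``k_coll * a_side``.
    k_hop : Brownian hop rate of a molecule into an adjacent vacancy.
    k_exit : Brownian escape rate of an end-slot molecule from a full pore.
    k_enter : entry rate into a vacant end slot, per side, scaled by that
        side's activity.
    a_L, a_R : dimensionless reservoir water activities (left/right).
    tracer_fraction_L : probability that a left entrant is a tracer.
    t_max, burn_in : simulation horizon and discarded initial interval.
    n_batches : non-overlapping batches for standard errors.
    seed : RNG seed for the Gillespie realisation.
    """

    i: int
    k_coll: float = 1.0
    k_hop: float = 1.0
    k_exit: float = 0.1
    k_enter: float = 1.0
    a_L: float = 1.0
    a_R: float = 1.0
    tracer_fraction_L: float = 0.1
    t_max: float = 100000.0
    burn_in: float = 1000.0
    n_batches: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if self.i < 1:
            raise ValueError(f"pore length i must be >= 1, got {self.i}")
        for name in ("k_coll", "k_hop", "k_exit", "k_enter"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.a_L <= 0 or self.a_R <= 0:
            raise ValueError("reservoir activities must be > 0")
        if not 0.0 <= self.tracer_fraction_L <= 1.0:
            raise ValueError("tracer_fraction_L must lie in [0, 1]")
        if self.k_exit >= self.k_hop and not (self.k_exit == self.k_hop == 0.0):
            raise ValueError(
                "barrier ordering requires k_exit < k_hop "
                f"(got k_exit={self.k_exit}, k_hop={self.k_hop})"
            )
        if self.n_batches < 2:
            raise ValueError("n_batches must be >= 2")

    def replace(self, **changes) -> "KineticParams":
        return replace(self, **changes)


class EventKind(enum.Enum):
    KNOCK_ON_L = "knock_on_L"
    KNOCK_ON_R = "knock_on_R"
    HOP_TOWARD_EXIT = "hop_toward_exit"
    HOP_TOWARD_ENTRANCE = "hop_toward_entrance"
    EXIT_L = "exit_L"
    EXIT_R = "exit_R"
    ENTER_L = "enter_L"
    ENTER_R = "enter_R"


@dataclass(frozen=True)
class Event:
    """One enabled transition from a configuration.

    ``out_right``/``out_left`` mark a molecule crossing a boundary outward
    (``ejected`` says which occupant left); ``in_right``/``in_left`` mark an
    entry (``entrant`` says what came in).  ``tracer_LR`` flags a completed
    left-to-right tracer translocation (tracer leaves to the right; tracers
    only enter from the left).
    """

    kind: EventKind
    rate: float
    target: PoreConfiguration
    ejected: Occupant | None = None
    entrant: Occupant | None = None
    out_right: bool = False
    out_left: bool = False
    in_right: bool = False
    in_left: bool = False

    @property
    def tracer_LR(self) -> bool:
        return self.out_right and self.ejected is Occupant.TRACER


def event_set(config: PoreConfiguration, params: KineticParams) -> list[Event]:
    """All simultaneously enabled events from ``config`` with their rates.

    Zero-rate events are omitted.  Every target satisfies the occupancy
    invariants (at most one tracer, at most one vacancy).
    """
    i = config.i
    events: list[Event] = []
    rate_coll_L = params.k_coll * params.a_L
    rate_coll_R = params.k_coll * params.a_R

    if config.is_full:
        exit_occ = config.slots[-1]
        entrance_occ = config.slots[0]
        vac_at_exit = config.replace(i, Occupant.VACANCY)
        vac_at_entrance = config.replace(1, Occupant.VACANCY)
        if rate_coll_L > 0:
            events.append(
                Event(EventKind.KNOCK_ON_L, rate_coll_L, vac_at_exit,
                      ejected=exit_occ, out_right=True)
            )
        if rate_coll_R > 0:
            events.append(
                Event(EventKind.KNOCK_ON_R, rate_coll_R, vac_at_entrance,
                      ejected=entrance_occ, out_left=True)
            )
        if params.k_exit > 0:
            events.append(
                Event(EventKind.EXIT_R, params.k_exit, vac_at_exit,
                      ejected=exit_occ, out_right=True)
            )
            events.append(
                Event(EventKind.EXIT_L, params.k_exit, vac_at_entrance,
                      ejected=entrance_occ, out_left=True)
            )
    else:
        v = config.vacancy_slot
        assert v is not None
        # knock-on with a vacancy: the collision advances the one molecule
        # on the striker's side of the vacancy, stepping the vacancy toward
        # the striker; disabled when the struck end slot itself is vacant.
        if v > 1:
            s = list(config.slots)
            s[v - 1], s[v - 2] = s[v - 2], Occupant.VACANCY
            target = PoreConfiguration(tuple(s))
            if rate_coll_L > 0:
                events.append(Event(EventKind.KNOCK_ON_L, rate_coll_L, target))
            if params.k_hop > 0:
                events.append(Event(EventKind.HOP_TOWARD_EXIT, params.k_hop, target))
        if v < i:
            s = list(config.slots)
            s[v - 1], s[v] = s[v], Occupant.VACANCY
            target = PoreConfiguration(tuple(s))
            if rate_coll_R > 0:
                events.append(Event(EventKind.KNOCK_ON_R, rate_coll_R, target))
            if params.k_hop > 0:
                events.append(Event(EventKind.HOP_TOWARD_ENTRANCE, params.k_hop, target))
        # entry into a vacant end slot
        if v == 1 and params.k_enter > 0:
            rate = params.k_enter * params.a_L
            f = params.tracer_fraction_L if not config.has_tracer else 0.0
            if f < 1.0:
                events.append(
                    Event(EventKind.ENTER_L, rate * (1.0 - f),
                          config.replace(1, Occupant.WATER),
                          entrant=Occupant.WATER, in_left=True)
                )
            if f > 0.0:
                events.append(
                    Event(EventKind.ENTER_L, rate * f,
                          config.replace(1, Occupant.TRACER),
                          entrant=Occupant.TRACER, in_left=True)
                )
        if v == i and params.k_enter > 0:
            # the right reservoir holds no tracer
            events.append(
                Event(EventKind.ENTER_R, params.k_enter * params.a_R,
                      config.replace(i, Occupant.WATER),
                      entrant=Occupant.WATER, in_right=True)
            )
    return events


# ---------------------------------------------------------------------------
# trajectory statistics


@dataclass
class TrajectoryStats:
    """Post-burn-in counts and time fractions from one simulated run.

    ``n_water_LR``/``n_water_RL`` are molecule crossings of the exit-side
    boundary (outward/inward); ``n_tracer_LR``/``n_tracer_RL`` count
    completed tracer translocations.  ``vacancy_lifetimes`` holds one
    duration per vacancy episode: from the creation of a vacancy out of a
    full pore to the restoration of the full pore.  The ``batch_*`` arrays
    split the observation window into ``n_batches`` equal time slices for
    batch-means standard errors.
    """

    i: int
    sim_time: float
    n_tracer_LR: int
    n_tracer_RL: int
    n_water_LR: int
    n_water_RL: int
    vacancy_lifetimes: list[float]
    full_pore_fraction: float
    batch_duration: np.ndarray
    batch_net_water: np.ndarray
    batch_tracer_LR: np.ndarray
    batch_full_time: np.ndarray
    n_events: int = 0


def simulate(
    params: KineticParams,
    trace: Callable[[float, str, str], None] | None = None,
) -> TrajectoryStats:
    """Exact stochastic (Gillespie) realisation of the pore kinetics.

    Starting from a full all-water pore, events are drawn with exponential
    waiting times and probability proportional to their rates, using the
    transition table precomputed over the complete occupancy-state space.
    Statistics are collected only after ``params.burn_in``; the run is fully
    reproducible from ``params.seed``.

    ``trace``, if given, is called as ``trace(time, event_kind, config)``
    for every event (after burn-in filtering is *not* applied: all events
    are traced).
    """
    if params.t_max <= params.burn_in or params.burn_in < 0:
        raise ValueError("require t_max > burn_in >= 0")

    configs = enumerate_configurations(params.i)
    index = {c.slots: k for k, c in enumerate(configs)}
    full_state = [c.is_full for c in configs]
    labels = [format_configuration(c) for c in configs]

    # transition table: per state, cumulative rates, targets and count deltas
    cum_rates: list[list[float]] = []
    totals: list[float] = []
    targets: list[list[int]] = []
    deltas: list[list[tuple[int, int, int]]] = []  # (d_out_r, d_in_r, d_tracer_lr)
    kinds: list[list[str]] = []
    for c in configs:
        evs = event_set(c, params)
        acc = 0.0
        cum, tg, dl, kd = [], [], [], []
        for e in evs:
            acc += e.rate
            cum.append(acc)
            tg.append(index[e.target.slots])
            dl.append((int(e.out_right), int(e.in_right), int(e.tracer_LR)))
            kd.append(e.kind.value)
        cum_rates.append(cum)
        totals.append(acc)
        targets.append(tg)
        deltas.append(dl)
        kinds.append(kd)

    if max(totals) <= 0.0:
        raise DegenerateSystemError("all event rates are zero")

    rng = random.Random(params.seed)
    burn_in, t_max, nb = params.burn_in, params.t_max, params.n_batches
    obs_time = t_max - burn_in
    batch_w = obs_time / nb

    batch_duration = np.full(nb, batch_w)
    batch_net = np.zeros(nb)
    batch_tracer = np.zeros(nb, dtype=np.int64)
    batch_full = np.zeros(nb)
    counts = {"out_r": 0, "in_r": 0, "tracer_lr": 0}
    lifetimes: list[float] = []
    vac_created_at: float | None = None

    def add_full_time(a: float, b: float) -> None:
        # attribute the dwell interval [a, b) of a full-pore state to batches
        a = max(a, burn_in)
        b = min(b, t_max)
        if b <= a:
            return
        k0 = min(int((a - burn_in) / batch_w), nb - 1)
        k1 = min(int((b - burn_in) / batch_w), nb - 1)
        for k in range(k0, k1 + 1):
            lo = burn_in + k * batch_w
            hi = lo + batch_w
            batch_full[k] += min(b, hi) - max(a, lo)

    t = 0.0
    s = index[tuple([Occupant.WATER] * params.i)]
    n_events = 0
    while True:
        total = totals[s]
        if total <= 0.0:
            raise DegenerateSystemError(
                f"configuration {labels[s]} has no enabled events"
            )
        u = rng.random()
        dt = -math.log(1.0 - u) / total
        t_next = t + dt
        if full_state[s]:
            add_full_time(t, min(t_next, t_max))
        if t_next >= t_max:
            break
        k = bisect_left(cum_rates[s], rng.random() * total)
        k = min(k, len(cum_rates[s]) - 1)
        s_next = targets[s][k]
        n_events += 1
        if trace is not None:
            trace(t_next, kinds[s][k], labels[s_next])
        if t_next >= burn_in:
            b = min(int((t_next - burn_in) / batch_w), nb - 1)
            d_out, d_in, d_tr = deltas[s][k]
            counts["out_r"] += d_out
            counts["in_r"] += d_in
            counts["tracer_lr"] += d_tr
            batch_net[b] += d_out - d_in
            batch_tracer[b] += d_tr
        # vacancy episode bookkeeping
        if full_state[s] and not full_state[s_next]:
            vac_created_at = t_next
        elif not full_state[s] and full_state[s_next]:
            if vac_created_at is not None and vac_created_at >= burn_in:
                lifetimes.append(t_next - vac_created_at)
            vac_created_at = None
        s = s_next
        t = t_next

    return TrajectoryStats(
        i=params.i,
        sim_time=obs_time,
        n_tracer_LR=counts["tracer_lr"],
        n_tracer_RL=0,
        n_water_LR=counts["out_r"],
        n_water_RL=counts["in_r"],
        vacancy_lifetimes=lifetimes,
        full_pore_fraction=float(batch_full.sum() / obs_time),
        batch_duration=batch_duration,
        batch_net_water=batch_net,
        batch_tracer_LR=batch_tracer,
        batch_full_time=batch_full,
        n_events=n_events,
    )


# ---------------------------------------------------------------------------
# permeability estimators


@dataclass(frozen=True)
class PermeabilityEstimates:
    """P_d, P_f and their ratio with batch-means standard errors.

    ``p_d`` comes from an equilibrium run (tracer flux normalised by the
    tracer fraction), ``p_f`` from a gradient run (net flux normalised by
    the activity difference); the ratio standard error propagates both.
    ``low_precision`` is set when fewer than 100 tracer translocations
    were observed.
    """

    p_d: float
    p_d_se: float
    p_f: float | None = None
    p_f_se: float | None = None
    ratio: float | None = None
    ratio_se: float | None = None
    n_tracer_translocations: int = 0
    low_precision: bool = False


def _batch_se(values: np.ndarray) -> float:
    values = np.asarray(values, dtype=float)
    return float(values.std(ddof=1) / math.sqrt(len(values)))


def estimate_permeabilities(
    stats: TrajectoryStats,
    params: KineticParams,
    gradient_stats: TrajectoryStats | None = None,
    gradient_params: KineticParams | None = None,
) -> PermeabilityEstimates:
    """Turn trajectory statistics into permeability estimates.

    ``stats``/``params`` must be an equilibrium run (``a_L == a_R``) with a
    tracer source; it yields P_d.  If a gradient run is also supplied, P_f
    and the ratio P_f/P_d are estimated as well.
    """
    if params.a_L != params.a_R:
        raise ValueError("P_d requires an equilibrium run (a_L == a_R)")
    if params.tracer_fraction_L <= 0:
        raise ValueError("P_d requires tracer_fraction_L > 0")
    f = params.tracer_fraction_L
    p_d = (stats.n_tracer_LR / stats.sim_time) / f
    pd_batches = stats.batch_tracer_LR / stats.batch_duration / f
    p_d_se = _batch_se(pd_batches)
    low = stats.n_tracer_LR < 100

    p_f = p_f_se = ratio_val = ratio_se = None
    if gradient_stats is not None:
        if gradient_params is None:
            raise ValueError("gradient_stats requires gradient_params")
        da = gradient_params.a_L - gradient_params.a_R
        if da == 0:
            raise ValueError("P_f requires a_L != a_R in the gradient run")
        p_f = (gradient_stats.n_water_LR - gradient_stats.n_water_RL) / gradient_stats.sim_time / da
        pf_batches = gradient_stats.batch_net_water / gradient_stats.batch_duration / da
        p_f_se = _batch_se(pf_batches)
        if p_d > 0:
            ratio_val = p_f / p_d
            ratio_se = abs(ratio_val) * math.sqrt(
                (p_d_se / p_d) ** 2 + (p_f_se / p_f) ** 2 if p_f else (p_d_se / p_d) ** 2
            )
    return PermeabilityEstimates(
        p_d=p_d,
        p_d_se=p_d_se,
        p_f=p_f,
        p_f_se=p_f_se,
        ratio=ratio_val,
        ratio_se=ratio_se,
        n_tracer_translocations=stats.n_tracer_LR,
        low_precision=low,
    )


def permeability_ratio(params: KineticParams, gradient_a_L: float | None = None) -> PermeabilityEstimates:
    """Estimate P_f/P_d from one equilibrium and one gradient run.

    ``params`` defines the common rates; the equilibrium run uses
    ``a_L = a_R`` and the gradient run sets ``a_L`` to ``gradient_a_L``
    (default ``2 * a_R``).  Sub-seeds for the two runs are derived from
    ``params.seed``.
    """
    seeder = random.Random(params.seed)
    eq_seed = seeder.randrange(2**31)
    grad_seed = seeder.randrange(2**31)
    if gradient_a_L is None:
        gradient_a_L = 2.0 * params.a_R
    eq_params = params.replace(a_L=params.a_R, seed=eq_seed)
    grad_params = params.replace(a_L=gradient_a_L, seed=grad_seed)
    eq_stats = simulate(eq_params)
    grad_stats = simulate(grad_params)
    return estimate_permeabilities(eq_stats, eq_params, grad_stats, grad_params)


# ---------------------------------------------------------------------------
# exact master-equation oracle


@dataclass(frozen=True)
class StationarySolution:
    """Exact stationary distribution and boundary fluxes of the generator."""

    configs: tuple[PoreConfiguration, ...]
    pi: np.ndarray
    net_water_flux: float  # expected (out_right - in_right) per unit time
    tracer_rate_LR: float  # expected completed tracer translocations per unit time
    full_pore_fraction: float


def build_generator(
    i: int, params: KineticParams
) -> tuple[np.ndarray, list[PoreConfiguration]]:
    """Continuous-time Markov generator over the full occupancy-state space.

    Off-diagonal entries are the event rates from :func:`event_set` applied
    to every enumerated configuration; rows sum to zero.  Restricted to
    ``i <= 6`` — the exact solve is an oracle for small pores, where the
    state space has ``i**2 + i + 1`` states.
    """
    if i > MAX_ORACLE_I:
        raise ValueError(f"exact generator restricted to i <= {MAX_ORACLE_I}, got {i}")
    if params.i != i:
        params = params.replace(i=i)
    configs = enumerate_configurations(i)
    index = {c.slots: k for k, c in enumerate(configs)}
    n = len(configs)
    Q = np.zeros((n, n))
    for s, c in enumerate(configs):
        for e in event_set(c, params):
            t = index[e.target.slots]
            if t != s:  # every event changes the configuration, but be safe
                Q[s, t] += e.rate
    Q[np.arange(n), np.arange(n)] = -Q.sum(axis=1)
    return Q, configs


def solve_stationary(
    Q: np.ndarray,
    configs: Sequence[PoreConfiguration],
    params: KineticParams,
) -> StationarySolution:
    """Solve ``pi Q = 0`` with ``sum(pi) = 1`` and derive exact fluxes.

    Raises :class:`ReducibleChainError` when the chain has more than one
    recurrent class (the diagnostic lists the states outside the main one).
    The returned fluxes are the oracle values for :func:`simulate`:
    expected net molecule flux through the exit-side boundary, expected
    completed tracer translocation rate, and the stationary probability of
    the full (no-vacancy) pore.
    """
    n = Q.shape[0]
    adjacency = (Q > 0).astype(int)
    np.fill_diagonal(adjacency, 0)
    n_comp, comp = connected_components(adjacency, directed=True, connection="strong")
    # recurrent classes = strongly connected components with no exit edge
    recurrent = []
    for c in range(n_comp):
        members = np.flatnonzero(comp == c)
        outside = np.setdiff1d(np.arange(n), members)
        if not adjacency[np.ix_(members, outside)].any():
            recurrent.append(members)
    if len(recurrent) != 1:
        outside_main = sorted(set(range(n)) - set(map(int, recurrent[0]))) if recurrent else list(range(n))
        labels = [format_configuration(configs[s]) for s in outside_main]
        raise ReducibleChainError(
            f"generator has {len(recurrent)} recurrent classes; "
            f"states outside the first: {labels}",
            unreachable=labels,
        )

    A = Q.T.copy()
    A[-1, :] = 1.0
    b = np.zeros(n)
    b[-1] = 1.0
    pi = np.linalg.solve(A, b)
    pi = np.clip(pi, 0.0, None)
    pi = pi / pi.sum()

    if params.i != configs[0].i:
        params = params.replace(i=configs[0].i)
    net = 0.0
    tracer_rate = 0.0
    for s, c in enumerate(configs):
        for e in event_set(c, params):
            net += pi[s] * e.rate * (int(e.out_right) - int(e.in_right))
            tracer_rate += pi[s] * e.rate * int(e.tracer_LR)
    full_frac = float(sum(pi[s] for s, c in enumerate(configs) if c.is_full))
    return StationarySolution(
        configs=tuple(configs),
        pi=pi,
        net_water_flux=float(net),
        tracer_rate_LR=float(tracer_rate),
        full_pore_fraction=full_frac,
    )


# ---------------------------------------------------------------------------
# vacancy lifetimes


@dataclass(frozen=True)
class VacancyLifetimeSummary:
    """Mean/median/count of vacancy lifetimes T_v (creation to refill)."""

    count: int
    mean: float
    median: float

    @property
    def is_empty(self) -> bool:
        return self.count == 0


def vacancy_lifetime_summary(stats: TrajectoryStats) -> VacancyLifetimeSummary:
    """Summarise the vacancy-lifetime samples of a run.

    A lifetime runs from the moment a vacancy appears in a full pore (by
    knock-on ejection or Brownian escape) until an entry event restores the
    full pore.  With zero samples an empty sentinel (count 0, NaN moments)
    is returned.
    """
    samples = stats.vacancy_lifetimes
    if not samples:
        return VacancyLifetimeSummary(count=0, mean=math.nan, median=math.nan)
    arr = np.asarray(samples, dtype=float)
    return VacancyLifetimeSummary(
        count=len(samples), mean=float(arr.mean()), median=float(np.median(arr))
    )
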