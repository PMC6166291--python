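"""Enumeration and classification of single-file pore occupancy states.

A single-file water pore of length ``i`` is modelled as ``i`` ordered slots,
each one water-molecule diameter (d_w) wide, so the pore length is
``i * d_w``.  Slot 1 (index 0 internally) faces the entrance (left) solution
and slot ``i`` faces the exit (right) solution.  Each slot holds exactly one
of three objects: an ordinary water molecule ``O``, the isotopically
labelled tracer ``*O*`` (physically identical to water, but countable), or a
vacancy ``[]`` (an empty slot).  At most one tracer and at most one vacancy
may be present at any time; water molecules are indistinguishable, so only
the positions of the tracer and the vacancy matter.

Under these rules a pore of length ``i`` has exactly ``i**2 + i + 1``
distinct occupancy states: 1 with neither tracer nor vacancy (the null,
full-water state), ``i`` with only a tracer, ``i`` with only a vacancy, and
``i*(i-1)`` with one of each.  :func:`census` obtains these counts by
enumerating and classifying every configuration; :func:`closed_form_census`
evaluates the closed forms, and the two are cross-checked in the test suite.

Four occupancy-state classes drive the permeability argument (see
:mod:`porestates.ratios`):

* diffusion tracer states — any state containing the tracer (``i**2``);
* diffusion tracer *exit* states — tracer in the exit slot (``i``);
* osmotic tracer states — tracer present and the pore full, i.e. no
  vacancy (``i``);
* osmotic tracer *exit* states — full pore with the tracer in the exit
  slot (always 1).
"""

from __future__ import annotations

import enum
import itertools
from dataclasses import dataclass
from typing import Iterable, Iterator, Sequence

__all__ = [
    "Occupant",
    "PoreConfiguration",
    "StateClass",
    "StateCensus",
    "enumerate_configurations",
    "classify_configuration",
    "census",
    "closed_form_census",
    "format_configuration",
    "parse_configuration",
]


class Occupant(enum.IntEnum):
    """One of the three objects that can occupy a pore slot.

    The integer values fix the lexicographic enumeration order
    (WATER < TRACER < VACANCY).
    """

    WATER = 0
    TRACER = 1
    VACANCY = 2

    @property
    def glyph(self) -> str:
        return _GLYPHS[self]


_GLYPHS = {Occupant.WATER: "O", Occupant.TRACER: "*O*", Occupant.VACANCY: "[]"}


@dataclass(frozen=True)
class PoreConfiguration:
    """Ordered occupancy of a single-file pore.

    ``slots[0]`` is the entrance (left) slot; ``slots[-1]`` is the exit
    (right) slot.  Invariants (validated on construction): length >= 1,
    at most one tracer, at most one vacancy.
    """

    slots: tuple[Occupant, ...]

    def __post_init__(self) -> None:
        if len(self.slots) < 1:
            raise ValueError("a pore must have at least one slot")
        slots = tuple(Occupant(s) for s in self.slots)
        object.__setattr__(self, "slots", slots)
        if slots.count(Occupant.TRACER) > 1:
            raise ValueError("at most one tracer is allowed in the pore")
        if slots.count(Occupant.VACANCY) > 1:
            raise ValueError("at most one vacancy is allowed in the pore")

    # -- geometry -----------------------------------------------------
    @property
    def i(self) -> int:
        """Number of slots (= N_p when the pore is full)."""
        return len(self.slots)

    @property
    def pore_length(self) -> float:
        """Pore length in units of the water diameter d_w."""
        return float(self.i)

    # -- occupancy queries --------------------------------------------
    @property
    def has_tracer(self) -> bool:
        return Occupant.TRACER in self.slots

    @property
    def has_vacancy(self) -> bool:
        return Occupant.VACANCY in self.slots

    @property
    def is_full(self) -> bool:
        """True when every slot holds a molecule (no vacancy)."""
        return not self.has_vacancy

    @property
    def tracer_slot(self) -> int | None:
        """1-based slot of the tracer, or None."""
        try:
            return self.slots.index(Occupant.TRACER) + 1
        except ValueError:
            return None

    @property
    def vacancy_slot(self) -> int | None:
        """1-based slot of the vacancy, or None."""
        try:
            return self.slots.index(Occupant.VACANCY) + 1
        except ValueError:
            return None

    def replace(self, slot: int, occupant: Occupant) -> "PoreConfiguration":
        """Return a copy with 1-based ``slot`` set to ``occupant``."""
        s = list(self.slots)
        s[slot - 1] = occupant
        return PoreConfiguration(tuple(s))

    def mirrored(self) -> "PoreConfiguration":
        """Left-right mirror image (entrance and exit swapped)."""
        return PoreConfiguration(tuple(reversed(self.slots)))

    def __str__(self) -> str:
        return format_configuration(self)


@dataclass(frozen=True)
class StateClass:
    """Classification flags for one pore configuration."""

    is_null: bool
    has_tracer: bool
    has_vacancy: bool
    is_diffusion_tracer_state: bool
    is_diffusion_tracer_exit_state: bool
    is_osmotic_tracer_state: bool
    is_osmotic_tracer_exit_state: bool


@dataclass(frozen=True)
class StateCensus:
    """Counts of all occupancy-state classes for a pore of length ``i``."""

    i: int
    n_total: int
    n_null: int
    n_tracer_only: int
    n_vacancy_only: int
    n_tracer_and_vacancy: int
    n_d: int  # diffusion tracer states
    n_dex: int  # diffusion tracer exit states
    n_f: int  # osmotic (full-pore) tracer states
    n_fex: int  # osmotic tracer exit states

    FIELDS = (
        "i",
        "n_total",
        "n_null",
        "n_tracer_only",
        "n_vacancy_only",
        "n_tracer_and_vacancy",
        "n_d",
        "n_dex",
        "n_f",
        "n_fex",
    )

    def as_dict(self) -> dict[str, int]:
        return {name: getattr(self, name) for name in self.FIELDS}


def _check_i(i: int) -> int:
    if not isinstance(i, (int,)) or isinstance(i, bool):
        raise TypeError(f"pore length i must be an integer, got {i!r}")
    if i < 1:
        raise ValueError(f"pore length i must be >= 1, got {i}")
    return i


def enumerate_configurations(i: int) -> list[PoreConfiguration]:
    """Every distinct occupancy state of an ``i``-slot pore, exactly once.

    The constraints (at most one tracer, at most one vacancy,
    indistinguishable water) leave only the tracer and vacancy positions
    free, so states are built directly: the null state, ``i`` tracer-only
    states, ``i`` vacancy-only states, and ``i*(i-1)`` states with both.
    The result is sorted lexicographically over the slots with
    WATER < TRACER < VACANCY, giving a deterministic, reproducible order.
    """
    _check_i(i)
    water = [Occupant.WATER] * i
    configs = [PoreConfiguration(tuple(water))]
    for t in range(i):
        s = water.copy()
        s[t] = Occupant.TRACER
        configs.append(PoreConfiguration(tuple(s)))
    for v in range(i):
        s = water.copy()
        s[v] = Occupant.VACANCY
        configs.append(PoreConfiguration(tuple(s)))
    for v in range(i):
        for t in range(i):
            if t == v:
                continue
            s = water.copy()
            s[v] = Occupant.VACANCY
            s[t] = Occupant.TRACER
            configs.append(PoreConfiguration(tuple(s)))
    configs.sort(key=lambda c: c.slots)
    return configs


def classify_configuration(config: PoreConfiguration) -> StateClass:
    """Assign a configuration to the occupancy-state classes.

    The exit slot is slot ``i`` (the right end).  A configuration is a
    diffusion tracer state iff it contains the tracer; an osmotic tracer
    state additionally requires a full pore (no vacancy); the exit variants
    require the tracer in the exit slot.
    """
    has_tracer = config.has_tracer
    has_vacancy = config.has_vacancy
    tracer_at_exit = config.tracer_slot == config.i
    return StateClass(
        is_null=not has_tracer and not has_vacancy,
        has_tracer=has_tracer,
        has_vacancy=has_vacancy,
        is_diffusion_tracer_state=has_tracer,
        is_diffusion_tracer_exit_state=tracer_at_exit,
        is_osmotic_tracer_state=has_tracer and not has_vacancy,
        is_osmotic_tracer_exit_state=tracer_at_exit and not has_vacancy,
    )


def census(i: int) -> StateCensus:
    """Count every state class by enumerating and classifying all states."""
    _check_i(i)
    counts = dict.fromkeys(StateCensus.FIELDS[1:], 0)
    for config in enumerate_configurations(i):
        cls = classify_configuration(config)
        counts["n_total"] += 1
        if cls.is_null:
            counts["n_null"] += 1
        elif cls.has_tracer and cls.has_vacancy:
            counts["n_tracer_and_vacancy"] += 1
        elif cls.has_tracer:
            counts["n_tracer_only"] += 1
        else:
            counts["n_vacancy_only"] += 1
        counts["n_d"] += cls.is_diffusion_tracer_state
        counts["n_dex"] += cls.is_diffusion_tracer_exit_state
        counts["n_f"] += cls.is_osmotic_tracer_state
        counts["n_fex"] += cls.is_osmotic_tracer_exit_state
    return StateCensus(i=i, **counts)


def closed_form_census(i: int) -> StateCensus:
    """The closed-form counts: total ``i**2 + i + 1``, ``n_d = i**2``, etc."""
    _check_i(i)
    return StateCensus(
        i=i,
        n_total=i * i + i + 1,
        n_null=1,
        n_tracer_only=i,
        n_vacancy_only=i,
        n_tracer_and_vacancy=i * (i - 1),
        n_d=i * i,
        n_dex=i,
        n_f=i,
        n_fex=1,
    )


def format_configuration(config: PoreConfiguration) -> str:
    """Render a configuration with the field's glyphs, e.g. ``*O*[]O``."""
    return "".join(s.glyph for s in config.slots)


def parse_configuration(text: str) -> PoreConfiguration:
    """Inverse of :func:`format_configuration`.

    Accepts strings over the glyphs ``O``, ``*O*`` and ``[]``
    (whitespace ignored), e.g. ``"*O*[]O"`` or ``"O O *O*"``.
    """
    text = "".join(text.split())
    slots: list[Occupant] = []
    pos = 0
    while pos < len(text):
        if text.startswith("*O*", pos):
            slots.append(Occupant.TRACER)
            pos += 3
        elif text.startswith("[]", pos):
            slots.append(Occupant.VACANCY)
            pos += 2
        elif text.startswith("O", pos):
            slots.append(Occupant.WATER)
            pos += 1
        else:
            raise ValueError(f"unrecognised glyph at position {pos} in {text!r}")
    if not slots:
        raise ValueError("empty configuration string")
    return PoreConfiguration(tuple(slots))
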