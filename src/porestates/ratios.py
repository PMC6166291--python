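"""Theoretical predictions for the osmotic/diffusive permeability ratio.

For a single-file pore the ratio of the osmotic permeability P_f to the
diffusion (tracer) permeability P_d has been predicted by several competing
expressions in terms of the number of pore water molecules N_p = i:

==================  ===========================  =====================
label               expression                   origin
==================  ===========================  =====================
TRACER_STATES       (1/n_f) / (1/n_d) = i        occupancy-state counts
TRACER_EXIT_STATES  (1/n_fex) / (1/n_dex) = i    exit-state counts
NP_MINUS_1          i - 1                        literature
NP_PLUS_1           i + 1                        literature
NP2P1_OVER_NPP1     (i**2 + 1) / (i + 1)         literature
MEAN_OCC_PLUS_1     <n> + 1 with <n> = i - 1     mean-occupancy models
==================  ===========================  =====================

The first two are computed here from the :class:`~porestates.states.StateCensus`
counts, never from hard-coded closed forms, so the ratio is traceable to the
enumeration: n_d = i**2 diffusion tracer states versus n_f = i full-pore
tracer states (or their exit-state counterparts n_dex = i versus n_fex = 1)
give P_f/P_d = i = N_p either way.  MEAN_OCC_PLUS_1 uses the mean occupancy
of a pore allowed a single vacancy, <n> = i - 1, and therefore also equals i.

All values are exact :class:`fractions.Fraction` objects; display rounding
(2 decimals, half-up, trailing zeros trimmed) happens only in
:func:`format_value` / :func:`model_table`.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from fractions import Fraction
from typing import Iterable, Sequence

import pandas as pd

from .states import StateCensus, census

__all__ = [
    "RatioModel",
    "RatioPrediction",
    "ratio",
    "model_table",
    "asymptotic_gap",
    "format_value",
    "RATIO_TABLE_COLUMNS",
]


class RatioModel(enum.Enum):
    """The competing theoretical expressions for P_f / P_d."""

    TRACER_STATES = "tracer_states"
    TRACER_EXIT_STATES = "tracer_exit_states"
    NP_MINUS_1 = "np_minus_1"
    NP_PLUS_1 = "np_plus_1"
    NP2P1_OVER_NPP1 = "np2p1_over_npp1"
    MEAN_OCC_PLUS_1 = "mean_occ_plus_1"


@dataclass(frozen=True)
class RatioPrediction:
    """P_f/P_d predicted by one model at pore length ``i``.

    ``value`` is exact; ``mean_occupancy`` is set only for MEAN_OCC_PLUS_1.
    """

    i: int
    model: RatioModel
    value: Fraction
    mean_occupancy: Fraction | None = None

    def __float__(self) -> float:
        return float(self.value)


def ratio(i: int, model: RatioModel, counts: StateCensus | None = None) -> RatioPrediction:
    """Evaluate one P_f/P_d expression at pore length ``i``.

    For the two occupancy-state models the value is formed from the
    enumerated counts (``counts`` defaults to ``census(i)``): the osmotic
    route has 1/n_f (or 1/n_fex) of the relevant states available while the
    diffusive route has 1/n_d (1/n_dex), so the ratio is n_d/n_f
    (n_dex/n_fex).
    """
    model = RatioModel(model)
    if not isinstance(i, int) or isinstance(i, bool):
        raise TypeError(f"pore length i must be an integer, got {i!r}")
    if i < 1:
        raise ValueError(f"pore length i must be >= 1, got {i}")

    mean_occ: Fraction | None = None
    if model in (RatioModel.TRACER_STATES, RatioModel.TRACER_EXIT_STATES):
        c = counts if counts is not None else census(i)
        if c.i != i:
            raise ValueError(f"census is for i={c.i}, expected i={i}")
        if model is RatioModel.TRACER_STATES:
            value = Fraction(1, c.n_f) / Fraction(1, c.n_d)
        else:
            value = Fraction(1, c.n_fex) / Fraction(1, c.n_dex)
    elif model is RatioModel.NP_MINUS_1:
        value = Fraction(i - 1)
    elif model is RatioModel.NP_PLUS_1:
        value = Fraction(i + 1)
    elif model is RatioModel.NP2P1_OVER_NPP1:
        value = Fraction(i * i + 1, i + 1)
    elif model is RatioModel.MEAN_OCC_PLUS_1:
        # mean occupancy of a pore allowed at most one vacancy
        mean_occ = Fraction(i - 1)
        value = mean_occ + 1
    else:  # pragma: no cover
        raise AssertionError(model)
    return RatioPrediction(i=i, model=model, value=value, mean_occupancy=mean_occ)


#: Column order of the comparison table: the occupancy-state model first,
#: then the literature expressions.
RATIO_TABLE_COLUMNS = ("i", "tracer_state_model", "np_minus_1", "np2p1_over_npp1", "np_plus_1")

_TABLE_MODELS = {
    "tracer_state_model": RatioModel.TRACER_STATES,
    "np_minus_1": RatioModel.NP_MINUS_1,
    "np2p1_over_npp1": RatioModel.NP2P1_OVER_NPP1,
    "np_plus_1": RatioModel.NP_PLUS_1,
}


def model_table(i_values: Sequence[int], display: bool = False) -> pd.DataFrame:
    """Compare the P_f/P_d expressions across pore lengths.

    One row per ``i``, one column per expression.  With ``display=False``
    values are exact floats; with ``display=True`` they are the rounded
    display strings (2 decimals, half-up, trailing zeros trimmed, so e.g.
    50/8 renders as ``6.25`` and 46/5 as ``9.2``).
    """
    rows = []
    for i in i_values:
        row: dict[str, object] = {"i": i}
        for col, model in _TABLE_MODELS.items():
            value = ratio(i, model).value
            row[col] = format_value(value) if display else float(value)
        rows.append(row)
    return pd.DataFrame(rows, columns=list(RATIO_TABLE_COLUMNS))


def asymptotic_gap(i: int) -> Fraction:
    """Gap ``i - (i**2 + 1)/(i + 1)``, which equals ``(i - 1)/(i + 1)``.

    Zero at i = 1 and approaching 1 from below as the pore lengthens, so
    the quotient expression approaches (but never reaches) the
    occupancy-state prediction i.
    """
    if i < 1:
        raise ValueError(f"pore length i must be >= 1, got {i}")
    return Fraction(i) - Fraction(i * i + 1, i + 1)


def format_value(value: Fraction | float) -> str:
    """Display formatting: round half-up to 2 decimals, trim zeros."""
    if isinstance(value, Fraction):
        dec = Decimal(value.numerator) / Decimal(value.denominator)
    else:
        dec = Decimal(repr(float(value)))
    quantized = dec.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP)
    text = format(quantized.normalize(), "f")
    return text
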