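import itertools

import pytest

from porestates.states import Occupant, PoreConfiguration


def brute_force_configurations(i: int) -> set[tuple[Occupant, ...]]:
    """Independent oracle: filter the full 3**i product by the occupancy
    constraints (at most one tracer, at most one vacancy)."""
    out = set()
    for combo in itertools.product(list(Occupant), repeat=i):
        if combo.count(Occupant.TRACER) <= 1 and combo.count(Occupant.VACANCY) <= 1:
            out.add(combo)
    return out


@pytest.fixture(scope="session")
def brute_force():
    return brute_force_configurations
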