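"""Event rules, Gillespie simulator and exact stationary oracle."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from porestates.kinetics import (
    DegenerateSystemError,
    EventKind,
    KineticParams,
    ReducibleChainError,
    build_generator,
    estimate_permeabilities,
    event_set,
    permeability_ratio,
    simulate,
    solve_stationary,
    vacancy_lifetime_summary,
)
from porestates.states import (
    Occupant,
    PoreConfiguration,
    enumerate_configurations,
    parse_configuration,
)

W, T, V = Occupant.WATER, Occupant.TRACER, Occupant.VACANCY


def params(**kw):
    return KineticParams(**{"i": 3, **kw})


class TestParams:
    def test_barrier_ordering_enforced(self):
        with pytest.raises(ValueError, match="k_exit < k_hop"):
            params(k_exit=1.0, k_hop=0.5)

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            params(k_coll=-1.0)

    def test_activity_and_fraction_bounds(self):
        with pytest.raises(ValueError):
            params(a_L=0.0)
        with pytest.raises(ValueError):
            params(tracer_fraction_L=1.5)


class TestEventRules:
    def test_knock_on_full_pore_ejects_exit_molecule(self):
        """A collision on a full pore ejects the far-end molecule; the
        striker stays outside, leaving a vacancy at the exit slot."""
        config = parse_configuration("*O*OO")
        p = params()
        knock = [e for e in event_set(config, p) if e.kind is EventKind.KNOCK_ON_L]
        assert len(knock) == 1
        e = knock[0]
        assert str(e.target) == "*O*O[]"
        assert e.out_right and e.ejected is W and not e.tracer_LR
        assert e.rate == p.k_coll * p.a_L

    def test_knock_on_with_vacancy_advances_one_molecule(self):
        config = parse_configuration("*O*O[]")
        e = next(e for e in event_set(config, params())
                 if e.kind is EventKind.KNOCK_ON_L)
        assert str(e.target) == "*O*[]O"
        assert not e.out_right and not e.out_left

    def test_knock_on_moves_tracer_into_adjacent_vacancy(self):
        config = parse_configuration("*O*[]O")
        e = next(e for e in event_set(config, params())
                 if e.kind is EventKind.KNOCK_ON_L)
        assert str(e.target) == "[]*O*O"

    def test_tracer_ejection_is_counted_as_translocation(self):
        config = parse_configuration("OO*O*")
        ejections = [e for e in event_set(config, params())
                     if e.out_right]
        assert {e.kind for e in ejections} == {EventKind.KNOCK_ON_L, EventKind.EXIT_R}
        assert all(e.ejected is T and e.tracer_LR for e in ejections)

    def test_central_vacancy_has_two_equal_rate_hops(self):
        p = params()
        hops = [e for e in event_set(parse_configuration("O[]O"), p)
                if e.kind in (EventKind.HOP_TOWARD_EXIT, EventKind.HOP_TOWARD_ENTRANCE)]
        assert len(hops) == 2
        assert all(e.rate == p.k_hop for e in hops)
        assert {str(e.target) for e in hops} == {"[]OO", "OO[]"}

    def test_brownian_exit_only_on_full_pore(self):
        full_kinds = {e.kind for e in event_set(parse_configuration("OOO"), params())}
        assert EventKind.EXIT_L in full_kinds and EventKind.EXIT_R in full_kinds
        vac_kinds = {e.kind for e in event_set(parse_configuration("O[]O"), params())}
        assert EventKind.EXIT_L not in vac_kinds and EventKind.EXIT_R not in vac_kinds

    def test_entry_splits_water_and_tracer_by_fraction(self):
        p = params(tracer_fraction_L=0.25)
        entries = [e for e in event_set(parse_configuration("[]OO"), p)
                   if e.kind is EventKind.ENTER_L]
        rates = {e.entrant: e.rate for e in entries}
        assert rates[W] == pytest.approx(0.75 * p.k_enter * p.a_L)
        assert rates[T] == pytest.approx(0.25 * p.k_enter * p.a_L)

    def test_no_second_tracer_can_enter(self):
        entries = [e for e in event_set(parse_configuration("[]O*O*"), params())
                   if e.kind is EventKind.ENTER_L]
        assert len(entries) == 1 and entries[0].entrant is W

    def test_right_reservoir_is_tracer_free(self):
        entries = [e for e in event_set(parse_configuration("OO[]"), params())
                   if e.kind is EventKind.ENTER_R]
        assert len(entries) == 1 and entries[0].entrant is W

    def test_single_slot_pore_events(self):
        p = params(i=1)
        kinds = {e.kind for e in event_set(parse_configuration("O"), p)}
        assert kinds == {EventKind.KNOCK_ON_L, EventKind.KNOCK_ON_R,
                         EventKind.EXIT_L, EventKind.EXIT_R}
        vac_kinds = {e.kind for e in event_set(parse_configuration("[]"), p)}
        assert vac_kinds == {EventKind.ENTER_L, EventKind.ENTER_R}

    @settings(max_examples=80, deadline=None, derandomize=True)
    @given(
        i=st.integers(min_value=1, max_value=5),
        idx=st.integers(min_value=0, max_value=10**6),
        f=st.floats(min_value=0.0, max_value=1.0),
        a_L=st.floats(min_value=0.1, max_value=5.0),
    )
    def test_every_event_preserves_invariants(self, i, idx, f, a_L):
        """Targets stay valid (<=1 tracer, <=1 vacancy, same length) and
        occupancy changes only through boundary events."""
        configs = enumerate_configurations(i)
        config = configs[idx % len(configs)]
        p = KineticParams(i=i, tracer_fraction_L=f, a_L=a_L)
        for e in event_set(config, p):
            assert e.rate > 0
            assert e.target.i == i
            n_before = sum(s is not V for s in config.slots)
            n_after = sum(s is not V for s in e.target.slots)
            if e.out_right or e.out_left:
                assert n_after == n_before - 1
            elif e.in_right or e.in_left:
                assert n_after == n_before + 1
            else:
                assert n_after == n_before


class TestGenerator:
    @pytest.mark.parametrize("i", [1, 2, 3, 4, 6])
    def test_rows_sum_to_zero_and_dimension(self, i):
        Q, configs = build_generator(i, params(i=i))
        assert Q.shape == (i * i + i + 1, i * i + i + 1)
        assert np.abs(Q.sum(axis=1)).max() < 1e-12

    def test_refuses_large_state_space(self):
        with pytest.raises(ValueError, match="i <= 6"):
            build_generator(7, params(i=7))

    def test_equilibrium_net_flux_is_zero(self):
        """Tracers are dynamically identical to water, so the label-blind
        dynamics is left-right symmetric at equal activities."""
        p = params(a_L=1.0, a_R=1.0, tracer_fraction_L=0.2)
        sol = solve_stationary(*build_generator(3, p), p)
        assert abs(sol.net_water_flux) < 1e-12

    def test_stationary_distribution_mirror_symmetric_without_tracer(self):
        p = params(tracer_fraction_L=0.0)
        Q, configs = build_generator(3, p)
        sol = solve_stationary(Q, configs, p)
        pi = {c.slots: x for c, x in zip(configs, sol.pi)}
        for c in configs:
            assert pi[c.slots] == pytest.approx(pi[c.mirrored().slots], abs=1e-12)

    def test_tracer_states_are_unvisited_without_tracer_source(self):
        p = params(tracer_fraction_L=0.0)
        Q, configs = build_generator(3, p)
        sol = solve_stationary(Q, configs, p)
        for c, x in zip(configs, sol.pi):
            if c.has_tracer:
                assert x == pytest.approx(0.0, abs=1e-12)

    def test_reducible_chain_is_diagnosed(self):
        """Without vacancy creation (k_coll = k_exit = 0) every full-pore
        state is absorbing, so there are multiple recurrent classes."""
        p = params(k_coll=0.0, k_exit=0.0)
        Q, configs = build_generator(3, p)
        with pytest.raises(ReducibleChainError) as err:
            solve_stationary(Q, configs, p)
        assert err.value.unreachable

    @pytest.mark.parametrize("i", [2, 3])
    def test_net_flux_increases_with_activity_gradient(self, i):
        fluxes = []
        for a_L in (1.0, 1.1, 1.2, 1.5):
            p = params(i=i, a_L=a_L)
            sol = solve_stationary(*build_generator(i, p), p)
            fluxes.append(sol.net_water_flux)
        assert all(b > a for a, b in zip(fluxes, fluxes[1:]))

    def test_tracer_rate_scales_with_tracer_fraction(self):
        rates = []
        for f in (0.05, 0.1, 0.2):
            p = params(tracer_fraction_L=f)
            sol = solve_stationary(*build_generator(3, p), p)
            rates.append(sol.tracer_rate_LR / f)
        # normalised rate is nearly constant at trace-level fractions
        assert max(rates) / min(rates) < 1.25


class TestSimulate:
    def test_reproducible_given_seed(self):
        p = params(seed=42, t_max=2000.0, burn_in=100.0)
        s1, s2 = simulate(p), simulate(p)
        assert (s1.n_water_LR, s1.n_water_RL, s1.n_tracer_LR) == \
            (s2.n_water_LR, s2.n_water_RL, s2.n_tracer_LR)
        assert s1.vacancy_lifetimes == s2.vacancy_lifetimes
        s3 = simulate(p.replace(seed=43))
        assert (s1.n_water_LR, s1.n_tracer_LR) != (s3.n_water_LR, s3.n_tracer_LR)

    def test_no_tracer_source_means_no_translocations(self):
        stats = simulate(params(tracer_fraction_L=0.0, t_max=2000.0, burn_in=100.0, seed=7))
        assert stats.n_tracer_LR == 0 and stats.n_tracer_RL == 0

    def test_equilibrium_net_flux_within_three_se(self):
        stats = simulate(params(seed=11, t_max=20000.0, burn_in=500.0))
        flux = (stats.n_water_LR - stats.n_water_RL) / stats.sim_time
        se = np.std(stats.batch_net_water / stats.batch_duration, ddof=1) / \
            math.sqrt(len(stats.batch_net_water))
        assert abs(flux) <= 3 * se

    def test_full_pore_fraction_is_a_time_fraction(self):
        stats = simulate(params(seed=3, t_max=2000.0, burn_in=100.0))
        assert 0.0 < stats.full_pore_fraction < 1.0
        assert stats.batch_full_time.sum() == pytest.approx(
            stats.full_pore_fraction * stats.sim_time)

    def test_degenerate_system_is_signalled(self):
        # full start pore with no collision or escape events enabled
        p = params(k_coll=0.0, k_exit=0.0)
        with pytest.raises(DegenerateSystemError):
            simulate(p)

    def test_bad_horizon_rejected(self):
        with pytest.raises(ValueError):
            simulate(params(t_max=10.0, burn_in=10.0))

    def test_trace_callback_sees_every_event(self):
        rows = []
        stats = simulate(params(seed=5, t_max=200.0, burn_in=10.0),
                         trace=lambda t, kind, cfg: rows.append((t, kind, cfg)))
        assert len(rows) == stats.n_events
        times = [r[0] for r in rows]
        assert times == sorted(times)
        parse_configuration(rows[0][2])  # configurations are well-formed


class TestVacancyLifetimes:
    def test_empty_summary_sentinel(self):
        stats = simulate(params(seed=1, t_max=200.0, burn_in=10.0,
                                k_coll=0.001, k_exit=0.0))
        summary = vacancy_lifetime_summary(stats)
        if summary.count == 0:
            assert summary.is_empty and math.isnan(summary.mean)
        else:  # a rare vacancy appeared: samples must still be positive
            assert all(x > 0 for x in stats.vacancy_lifetimes)

    def test_instant_refill_limit(self):
        """With k_enter 1000x the hop rate a vacancy refills essentially
        immediately: mean lifetime << 1/k_hop."""
        stats = simulate(params(seed=2, k_enter=1000.0, t_max=5000.0, burn_in=100.0))
        summary = vacancy_lifetime_summary(stats)
        assert summary.count > 0
        assert summary.mean < 0.05 / params().k_hop

    def test_lifetimes_positive_and_finite(self):
        stats = simulate(params(seed=9, t_max=5000.0, burn_in=100.0))
        assert stats.vacancy_lifetimes
        assert all(0 < x < math.inf for x in stats.vacancy_lifetimes)


class TestEstimators:
    def test_pd_requires_equilibrium(self):
        p = params(a_L=2.0)
        stats = simulate(p.replace(t_max=2000.0, burn_in=100.0))
        with pytest.raises(ValueError, match="equilibrium"):
            estimate_permeabilities(stats, p)

    def test_pd_requires_tracer_source(self):
        p = params(tracer_fraction_L=0.0, t_max=2000.0, burn_in=100.0)
        stats = simulate(p)
        with pytest.raises(ValueError, match="tracer_fraction_L"):
            estimate_permeabilities(stats, p)

    def test_low_precision_flag_on_short_run(self):
        p = params(t_max=1500.0, burn_in=100.0, seed=4)
        est = estimate_permeabilities(simulate(p), p)
        assert est.n_tracer_translocations < 100
        assert est.low_precision

    def test_ratio_combines_equilibrium_and_gradient_runs(self):
        est = permeability_ratio(params(seed=8, t_max=20000.0, burn_in=500.0),
                                 gradient_a_L=2.0)
        assert est.p_d > 0 and est.p_f > 0
        assert est.ratio == pytest.approx(est.p_f / est.p_d)
        assert est.ratio_se is not None and est.ratio_se > 0
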