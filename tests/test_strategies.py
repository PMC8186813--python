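"""Strategy updates, optimal amplification, lineage stationarity."""

import math

import numpy as np
import pytest

from srnaevol import (
    INSTANT,
    BwmaxTable,
    FitnessShape,
    LineageState,
    SRNAParams,
    b_wmax,
    custom_strategy,
    generate_scenario,
    germline_b_update,
    integrate_generation,
    lifetime_fitness,
    simulate_cycle,
    simulate_to_stationarity,
    soma_b_profile,
    strategy_a,
    strategy_b,
    strategy_c,
    strategy_d,
    strategy_e,
    strategy_f,
    transmit_srna,
)
from srnaevol.strategies import StrategyConfig


class TestFactories:
    def test_wildtype_has_no_machinery(self):
        a = strategy_a()
        assert (a.b0, a.r_germ, a.P_b) == (0.0, 0.0, 0.0)
        assert a.is_order_free

    def test_invalid_configurations_rejected(self):
        with pytest.raises(ValueError):
            strategy_b(0.0)
        with pytest.raises(ValueError):
            strategy_c(0.0)
        with pytest.raises(ValueError):
            custom_strategy(P_b=0.5)  # plasticity without a plastic tissue
        with pytest.raises(ValueError):
            custom_strategy(r_germ=1.5)
        with pytest.raises(ValueError):
            strategy_d(P_b=0.5, a=0.0)

    def test_plastic_flags(self):
        assert strategy_d(0.5).somatic_plastic
        assert not strategy_d(0.5).germline_plastic
        assert strategy_e(0.5).somatic_plastic and strategy_e(0.5).germline_plastic
        assert strategy_f(0.5).germline_plastic and not strategy_f(0.5).somatic_plastic


class TestBwmax:
    def test_stress_needs_more_amplification(self, opt_params, shape):
        """Grid oracle: the cached optimum beats every coarse grid point,
        and the stressful environment demands at least as much
        amplification as the benign one."""
        lo = b_wmax(0.1, opt_params, shape)
        hi = b_wmax(0.9, opt_params, shape)
        assert hi >= lo
        assert lo == 0.0  # wildtype already overshoots the benign optimum
        grid = np.concatenate(([0.0], np.geomspace(1e-3, 2.0, 30)))
        w_best = lifetime_fitness(
            integrate_generation(opt_params, 0.0, 20, b_profile=hi),
            0.9, 0.0, shape)
        for b in grid:
            w = lifetime_fitness(
                integrate_generation(opt_params, 0.0, 20, b_profile=float(b)),
                0.9, 0.0, shape)
            assert w <= w_best + 1e-12

    def test_slowed_dynamics_favor_amplification(self, mu_opt, shape):
        slow = SRNAParams(mu=mu_opt, speed=0.75)
        assert b_wmax(0.9, slow, shape) > 0.0

    def test_cache_returns_identical_values(self, opt_params, shape):
        assert b_wmax(0.9, opt_params, shape) == b_wmax(0.9, opt_params, shape)

    def test_table_matches_direct_optimization(self, opt_params, shape, rng):
        """PCHIP table vs fresh Brent optimization at off-node endowments."""
        table = BwmaxTable(0.9, opt_params, shape)
        for n0 in rng.uniform(0.3, 20.0, size=4):
            direct = b_wmax(0.9, opt_params, shape, n0=float(n0))
            assert table(float(n0)) == pytest.approx(direct, abs=2e-3)

    def test_target_shrinks_with_inherited_endowment(self, opt_params, shape):
        """A well-endowed zygote needs less amplification."""
        rich = b_wmax(0.9, opt_params, shape, n0=30.0)
        poor = b_wmax(0.9, opt_params, shape, n0=0.0)
        assert rich < poor


class TestUpdates:
    def test_non_plastic_soma_keeps_inherited_rate(self, params, shape):
        prof = soma_b_profile(0.07, strategy_b(0.07), 0.9, params, shape)
        assert prof(0.0) == prof(13.7) == 0.07
        assert prof.constant_value == 0.07

    def test_delayed_response_starts_at_inherited_rate(self, params, shape):
        prof = soma_b_profile(0.02, strategy_d(0.5, a=0.15), 0.9, params,
                              shape, target=1.0)
        assert prof(0.0) == pytest.approx(0.02)
        expected = 0.02 + 0.5 * (1.0 - 0.02) * -math.expm1(-0.15 * 10)
        assert prof(10.0) == pytest.approx(expected)

    def test_instant_response_jumps_to_fraction_of_target(self, params, shape):
        prof = soma_b_profile(0.0, strategy_d(0.8, a=INSTANT), 0.9, params,
                              shape, target=1.0)
        assert prof(10.0) == pytest.approx(0.8)
        assert prof.constant_value == pytest.approx(0.8)

    def test_germline_reset_for_somatic_only_plasticity(self, params, shape):
        assert germline_b_update(0.03, strategy_d(0.9), 0.9, params, shape,
                                 target=1.0) == 0.03

    def test_full_tracking_with_instant_full_plasticity(self, params, shape):
        out = germline_b_update(0.3, strategy_e(1.0, a=INSTANT), 0.9, params,
                                shape, target=0.77)
        assert out == pytest.approx(0.77)

    def test_delayed_germline_shift(self, params, shape):
        out = germline_b_update(0.0, strategy_f(0.5, a=0.15), 0.9, params,
                                shape, c=20, target=1.0)
        assert out == pytest.approx(0.5 * -math.expm1(-3.0))

    @pytest.mark.parametrize("r,n,expected", [
        (0.0, 58.78, 0.0), (1.0, 58.78, 58.78), (0.5, 58.78, 29.39),
    ])
    def test_transmission(self, r, n, expected):
        assert transmit_srna(n, r) == pytest.approx(expected)


class TestLineage:
    def test_wildtype_cycle_matches_product_oracle(self, opt_params, shape,
                                                   scenario_k9):
        """Every wildtype generation is identical; W_GEO equals a direct
        product over the closed-form trajectory."""
        from srnaevol import closed_form_b0, instantaneous_fitness

        res = simulate_to_stationarity(strategy_a(), opt_params, shape,
                                       scenario_k9)
        n = closed_form_b0(0.0, np.arange(21.0), opt_params.replace(b=0.0))
        logs = []
        for eps in scenario_k9.eps_seq:
            w = np.prod([instantaneous_fitness(float(v), eps, 0.0, shape)
                         for v in n]) ** (1 / 21)
            logs.append(math.log(w))
        assert res.W_GEO == pytest.approx(math.exp(np.mean(logs)), rel=1e-9)
        assert res.burn_in_cycles == 1
        firsts = res.records[0]
        assert all(r.n_initial == firsts.n_initial for r in res.records)

    @pytest.mark.parametrize("reduced,reference", [
        (StrategyConfig(id="B0", b0=0.0), strategy_a()),
        (StrategyConfig(id="C0", r_germ=0.0), strategy_a()),
        (StrategyConfig(id="D0", P_b=0.0, somatic_plastic=True), strategy_a()),
        (StrategyConfig(id="E0", P_b=0.0, somatic_plastic=True,
                        germline_plastic=True), strategy_a()),
        (StrategyConfig(id="F0", b0=0.04, P_b=0.0, germline_plastic=True),
         strategy_b(0.04)),
    ])
    def test_strategy_reductions(self, opt_params, shape, scenario_k9,
                                 reduced, reference):
        """Switching off a strategy's machinery reproduces the simpler
        strategy record-for-record."""
        a = simulate_to_stationarity(reduced, opt_params, shape, scenario_k9)
        b = simulate_to_stationarity(reference, opt_params, shape, scenario_k9)
        for ra, rb in zip(a.records, b.records):
            assert ra.n_initial == pytest.approx(rb.n_initial, abs=1e-10)
            assert ra.n_final == pytest.approx(rb.n_final, rel=1e-9)
            assert ra.b_germ_out == pytest.approx(rb.b_germ_out, abs=1e-12)
            assert ra.W_LIFE == pytest.approx(rb.W_LIFE, rel=1e-9)

    def test_fast_path_equals_generic_cycle_iteration(self, opt_params, shape,
                                                      scenario_k9):
        mut = custom_strategy(id="B+C", b0=0.02, r_germ=0.15)
        fast = simulate_to_stationarity(mut, opt_params, shape, scenario_k9)
        slow = simulate_to_stationarity(mut, opt_params, shape, scenario_k9,
                                        use_fast_path=False)
        assert fast.W_GEO == pytest.approx(slow.W_GEO, rel=1e-9)
        for ra, rb in zip(fast.records, slow.records):
            assert ra.n_initial == pytest.approx(rb.n_initial, abs=1e-7)
            assert ra.W_LIFE == pytest.approx(rb.W_LIFE, rel=1e-9)

    def test_transmission_fixed_point_matches_affine_map(self, opt_params,
                                                         shape, scenario_k9):
        """Without amplification the per-generation map is affine,
        n+ = r*(A + q*n) with A = (mu/d)(1 - e^{-dc}) and q = e^{-dc};
        the stationary zygotic amount solves it exactly."""
        r = 0.5
        res = simulate_to_stationarity(strategy_c(r), opt_params, shape,
                                       scenario_k9)
        d, mu = opt_params.d, opt_params.mu
        q = math.exp(-d * 20)
        A = mu / d * (1 - q)
        n_star = r * A / (1 - r * q)
        assert res.records[0].n_initial == pytest.approx(n_star, rel=1e-8)

    def test_stationary_state_is_cycle_fixed_point(self, opt_params, shape,
                                                   scenario_k2):
        strat = strategy_e(0.6)
        res = simulate_to_stationarity(strat, opt_params, shape, scenario_k2)
        state = LineageState(res.records[0].n_initial,
                             res.records[0].b_germ_in)
        _, state_out = simulate_cycle(strat, opt_params, shape, scenario_k2,
                                      state)
        assert state_out.n_initial == pytest.approx(state.n_initial, abs=1e-7)
        assert state_out.b_germ == pytest.approx(state.b_germ, abs=1e-7)

    def test_full_plasticity_keeps_soma_and_germline_equal(self, opt_params,
                                                           shape, scenario_k2):
        res = simulate_to_stationarity(strategy_e(0.7), opt_params, shape,
                                       scenario_k2)
        for rec in res.records:
            assert rec.b_soma_final == pytest.approx(rec.b_germ_out, abs=1e-12)

    def test_somatic_plasticity_never_touches_germline(self, opt_params,
                                                       shape, scenario_k2):
        res = simulate_to_stationarity(strategy_d(0.9), opt_params, shape,
                                       scenario_k2)
        assert all(rec.b_germ_in == 0.0 and rec.b_germ_out == 0.0
                   for rec in res.records)

    def test_order_sensitivity_split(self, opt_params, shape, scenario_k2,
                                     scenario_k17):
        """Reordering environments leaves A and B unchanged but shifts
        strategies with inherited plastic state."""
        for strat in (strategy_a(), strategy_b(0.05)):
            w2 = simulate_to_stationarity(strat, opt_params, shape,
                                          scenario_k2).W_GEO
            w17 = simulate_to_stationarity(strat, opt_params, shape,
                                           scenario_k17).W_GEO
            assert w2 == pytest.approx(w17, rel=1e-12)
        for strat in (strategy_e(0.6), strategy_f(0.6)):
            w2 = simulate_to_stationarity(strat, opt_params, shape,
                                          scenario_k2).W_GEO
            w17 = simulate_to_stationarity(strat, opt_params, shape,
                                           scenario_k17).W_GEO
            assert abs(w2 - w17) > 1e-6
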