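import copy
import math

import numpy as np
import pytest

from ephmap import (
    FiberTerminal,
    GradientSpec,
    ModelParams,
    adaptation_coefficient,
    apply_canonical_adaptation,
    apply_coadaptation,
    build_target_field,
    fiber_weight,
    guidance_potential,
    propose_and_move,
    resetting_force,
    simulate,
    terminal_footprint,
)
from ephmap.model import SimulationError
from ephmap.scenarios import Scenario

from helpers import make_terminal
from oracles import brute_force_potential, weighted_history_coefficient


class TestFootprint:
    def test_single_square_weight_one(self, uniform_ephrin_field,
                                      single_square_terminal):
        fp = terminal_footprint(single_square_terminal, uniform_ephrin_field)
        assert fp == {(10, 4): pytest.approx(1.0)}

    def test_covers_disc_of_seven_units(self, uniform_ephrin_field):
        # centered on a square: the widest row spans seven unit squares
        t = make_terminal(x=10.5, y=4.5)
        fp = terminal_footprint(t, uniform_ephrin_field)
        xs = [ix for ix, _ in fp]
        assert max(xs) - min(xs) + 1 == 7      # diameter about seven units
        assert all(w > 0 for w in fp.values())

    def test_symmetric_weights(self, uniform_ephrin_field):
        # center equidistant from two squares along x
        t = make_terminal(x=10.0, y=4.5)
        fp = terminal_footprint(t, uniform_ephrin_field)
        assert fp[(9, 4)] == pytest.approx(fp[(10, 4)])

    def test_off_field_is_empty(self, uniform_ephrin_field):
        t = make_terminal(x=-20.0, y=4.0)
        assert terminal_footprint(t, uniform_ephrin_field) == {}


class TestFiberWeight:
    def test_before_onset_zero(self):
        p = ModelParams(j_onset=1000, ramp_len=500)
        assert fiber_weight(999, p) == 0.0

    def test_after_ramp_full(self):
        p = ModelParams(j_onset=1000, ramp_len=500, C0=2.0)
        assert fiber_weight(1500, p) == 2.0
        assert fiber_weight(10 ** 6, p) == 2.0

    def test_ramp_midpoint(self):
        p = ModelParams(j_onset=1000, ramp_len=500, C0=2.0)
        assert fiber_weight(1250, p) == pytest.approx(1.0)

    def test_switched_off_is_constant(self):
        p = ModelParams(ramp=False, C0=1.0)
        for i in (0, 5, 50000):
            assert fiber_weight(i, p) == 1.0

    def test_negative_iteration_rejected(self):
        with pytest.raises(ValueError):
            fiber_weight(-1, ModelParams())


class TestGuidancePotential:
    def test_reduced_form_ln5(self, uniform_ephrin_field,
                              single_square_terminal):
        # L_T = 4, L_F = R_F = 1, single square, no neighbors:
        # D = |ln(1 / (L_T/L_F + 1))| = ln 5
        D = guidance_potential(single_square_terminal, uniform_ephrin_field)
        assert D == pytest.approx(math.log(5.0), abs=1e-12)

    def test_reduced_form_ln2(self):
        field = build_target_field(
            20, 8, GradientSpec("uniform", level=1.0), GradientSpec("none")
        )
        t = make_terminal(x=10.5, y=4.5, radius=0.6)   # L_T = L_F = 1
        assert guidance_potential(t, field) == pytest.approx(
            math.log(2.0), abs=1e-12)

    def test_balanced_inputs_give_zero(self):
        field = build_target_field(
            20, 8,
            GradientSpec("uniform", level=2.0),
            GradientSpec("uniform", level=2.0),
        )
        t = make_terminal(x=10.0, y=4.0, R=1.3, L=1.3)
        assert guidance_potential(t, field) == pytest.approx(0.0, abs=1e-12)

    def test_non_negative(self, counter_field):
        rng = np.random.default_rng(0)
        for _ in range(20):
            t = make_terminal(x=rng.uniform(1, 49), y=rng.uniform(1, 7),
                              R=rng.uniform(0.1, 5), L=rng.uniform(0.1, 5))
            assert guidance_potential(t, counter_field) >= 0.0

    def test_off_field_terminal_flagged_infinite(self, uniform_ephrin_field):
        t = make_terminal(x=-20.0, y=4.0)
        assert guidance_potential(t, uniform_ephrin_field) == math.inf

    def test_matches_brute_force_with_neighbors(self, counter_field):
        rng = np.random.default_rng(7)
        terms = [make_terminal(x=rng.uniform(5, 45), y=rng.uniform(1, 7),
                               R=rng.uniform(0.3, 3), L=rng.uniform(0.3, 3))
                 for _ in range(4)]
        for t in terms:
            D = guidance_potential(t, counter_field, terms, C=1.5)
            Dref = brute_force_potential(t, counter_field, terms, C=1.5)
            assert D == pytest.approx(Dref, abs=1e-10)


class TestAdaptationCoefficient:
    def test_zero_history(self):
        assert adaptation_coefficient([], ModelParams()) == 1.0
        assert adaptation_coefficient([0.0] * 10, ModelParams()) == 1.0

    def test_constant_history_closed_form(self):
        p = ModelParams()
        d = 1.7
        a = adaptation_coefficient([d] * p.h, p)
        assert a == pytest.approx(1.0 + math.log(1.0 + p.mu * d), rel=1e-12)

    def test_single_recent_value_hand_computed(self):
        # h=10, mu=0.006, history (0,...,0,2): weighted mean = 20/55
        p = ModelParams()
        a = adaptation_coefficient([0.0] * 9 + [2.0], p)
        assert a == pytest.approx(1.0 + math.log(1.0 + 0.006 * 20.0 / 55.0),
                                  rel=1e-12)
        assert a == pytest.approx(1.0021794, abs=1e-7)

    def test_matches_oracle_on_short_history(self):
        p = ModelParams()
        hist = [0.3, 1.2, 0.7]
        assert adaptation_coefficient(hist, p) == pytest.approx(
            weighted_history_coefficient(hist, p.mu, p.h), rel=1e-12)

    def test_negative_history_aborts(self):
        with pytest.raises(SimulationError):
            adaptation_coefficient([-0.1], ModelParams())

    def test_overlong_history_rejected(self):
        with pytest.raises(ValueError):
            adaptation_coefficient([0.0] * 11, ModelParams())


class TestResettingForce:
    def test_no_deflection(self):
        assert resetting_force(1.0, 1.0, ModelParams()) == 0.0

    def test_direct_product(self):
        f = resetting_force(2.0, 1.0, ModelParams())
        assert f == pytest.approx(-0.0045)

    def test_zero_gain(self):
        assert resetting_force(5.0, 1.0, ModelParams(lam=0.0)) == 0.0


class TestCoadaptation:
    def test_fixed_point_of_unperturbed_system(self):
        t = make_terminal()
        apply_coadaptation(t, 1.0, ModelParams())
        assert t.R_F == pytest.approx(t.R_F0)
        assert t.L_F == pytest.approx(t.L_F0)

    def test_constant_a_converges_to_closed_form(self):
        p = ModelParams()
        a = 1.003                     # a - 1 < lambda
        t = make_terminal()
        for _ in range(10 ** 4):
            apply_coadaptation(t, a, p)
        S_star = p.lam * t.R_F0 / (p.lam + 1.0 - a)
        assert t.R_F == pytest.approx(S_star, abs=1e-6)
        assert t.L_F == pytest.approx(S_star, abs=1e-6)

    def test_ratio_invariant(self):
        p = ModelParams()
        t = make_terminal(R=2.0, L=0.5)
        ratio0 = t.R_F / t.L_F
        rng = np.random.default_rng(3)
        for _ in range(1000):
            apply_coadaptation(t, 1.0 + rng.uniform(0, 0.004), p)
        assert t.R_F / t.L_F == pytest.approx(ratio0, rel=1e-12)

    def test_rejects_a_below_one(self):
        with pytest.raises(ValueError):
            apply_coadaptation(make_terminal(), 0.9, ModelParams())


class TestCanonicalAdaptation:
    def test_matched_no_change(self):
        t = make_terminal(R=2.0, L=3.0)
        apply_canonical_adaptation(t, 2.0, 3.0, ModelParams())
        assert (t.R_F, t.L_F) == (2.0, 3.0)

    def test_full_relaxation(self):
        t = make_terminal(R=1.0, L=1.0)
        apply_canonical_adaptation(t, 2.0, 0.5, ModelParams(kappa=1.0))
        assert t.R_F == pytest.approx(2.0)
        assert t.L_F == pytest.approx(0.5)

    def test_small_step(self):
        t = make_terminal(R=1.0, L=1.0)
        apply_canonical_adaptation(t, 2.0, 1.0, ModelParams(kappa=0.01))
        assert t.R_F == pytest.approx(1.01)


class TestProposeAndMove:
    def test_uniform_when_unbiased(self, uniform_ephrin_field):
        # interior of a homogeneous field, beta = 0: all directions equal
        p = ModelParams(beta=0.0, q_x=0.25)
        rng = np.random.default_rng(0)
        counts = {d: 0 for d in [(1, 0), (-1, 0), (0, 1), (0, -1)]}
        for _ in range(1200):
            t = make_terminal(x=10.0, y=4.0)
            nx, ny = propose_and_move(t, uniform_ephrin_field, [], 0.0, p, rng)
            counts[(round(nx - 10.0), round(ny - 4.0))] += 1
        for c in counts.values():
            assert abs(c / 1200 - 0.25) < 3 * math.sqrt(0.25 * 0.75 / 1200)

    def test_cue_free_forward_bias(self, zero_field):
        p = ModelParams(beta=0.0, q_x=0.37)
        rng = np.random.default_rng(1)
        n_draws = 1200
        fwd = 0
        for _ in range(n_draws):
            t = make_terminal(x=10.0, y=4.0)
            nx, _ = propose_and_move(t, zero_field, [], 0.0, p, rng)
            fwd += nx > 10.0
        se = math.sqrt(0.37 * 0.63 / n_draws)
        assert abs(fwd / n_draws - 0.37) < 3 * se

    def test_large_beta_descends(self, counter_field):
        # nasal terminal far anterior: potential decreases toward +x
        p = ModelParams(beta=200.0)
        rng = np.random.default_rng(2)
        for _ in range(10):
            t = make_terminal(x=10.0, y=4.0, u=0.0, R=0.3, L=3.0)
            nx, _ = propose_and_move(t, counter_field, [], 0.0, p, rng)
            assert nx == 11.0

    def test_walls_reject_moves(self, uniform_ephrin_field):
        p = ModelParams(beta=0.0, q_x=0.25)
        rng = np.random.default_rng(3)
        for _ in range(50):
            t = make_terminal(x=0.5, y=0.5)
            nx, ny = propose_and_move(t, uniform_ephrin_field, [], 0.0, p, rng)
            assert nx >= 0.5 and ny >= 0.5  # -x/-y would leave the field

    def test_immobile_terminal_stays(self, uniform_ephrin_field):
        t = make_terminal(mobile=False)
        rng = np.random.default_rng(4)
        assert propose_and_move(t, uniform_ephrin_field, [], 0.0,
                                ModelParams(), rng) == t.center


def _mini_scenario(field, terminals, **overrides):
    overrides.setdefault("n_terminals", len(terminals))
    return Scenario(field=field, terminals=terminals,
                    params_overrides=overrides, tag="mini")


class TestSimulate:
    def test_unbiased_walk_on_zero_field(self, zero_field):
        terms = [make_terminal(x=10.0, y=4.0) for _ in range(30)]
        scn = _mini_scenario(zero_field, terms, n_iterations=200,
                             adaptation_mode="none", seed=5,
                             q_x=0.25, beta=0.0, C0=0.0, ramp=False)
        res = simulate(scn)
        mean_dx = np.mean(res.final_x - 10.0)
        assert abs(mean_dx) < 1.5

    def test_single_terminal_on_ephrin_adapts(self, uniform_ephrin_field):
        t = make_terminal(x=10.0, y=4.0)
        scn = _mini_scenario(uniform_ephrin_field, [t], n_iterations=800,
                             seed=6, C0=0.0, ramp=False, record_stride=1)
        res = simulate(scn)
        # sensors rise above baseline, potential declines toward a plateau
        assert res.sensors[-1, 0, 1] > 1.5
        early = res.potentials[:50, 0].mean()
        late = res.potentials[-50:, 0].mean()
        assert late < early

    def test_determinism_bit_identical(self, counter_field):
        def run():
            terms = [make_terminal(x=5.0 + i, y=4.0, u=i / 10.0)
                     for i in range(8)]
            scn = _mini_scenario(counter_field, terms, n_iterations=300,
                                 seed=42, record_stride=10)
            return simulate(scn)

        a, b = run(), run()
        assert np.array_equal(a.positions, b.positions)
        assert np.array_equal(a.sensors, b.sensors)
        assert np.array_equal(a.potentials, b.potentials)

    def test_off_field_terminal_aborts(self, uniform_ephrin_field):
        t = make_terminal(x=-30.0, y=4.0)
        scn = _mini_scenario(uniform_ephrin_field, [t], n_iterations=10)
        with pytest.raises(SimulationError):
            simulate(scn)

    def test_immobile_terminals_do_not_move_or_adapt(self,
                                                     uniform_ephrin_field):
        res_t = make_terminal(x=5.0, y=4.0, mobile=False)
        mob_t = make_terminal(x=15.0, y=4.0)
        scn = _mini_scenario(uniform_ephrin_field, [res_t, mob_t],
                             n_iterations=200, seed=7, ramp=False, C0=1.0)
        res = simulate(scn)
        assert tuple(res.final_positions[0]) == (5.0, 4.0)
        assert res.sensors[-1, 0, 0] == pytest.approx(1.0)
        assert res.sensors[-1, 1, 1] > 1.0    # the mobile one adapted
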