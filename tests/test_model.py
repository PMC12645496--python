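import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gcthybrid import (ModelConfig, StateLayout, cytokine_production,
                       homeostatic_trail_production, immune_equilibrium,
                       infection_hazard, pd_effect, phagocyte_recruitment,
                       rhs, trail_equilibrium)
from gcthybrid.simulate import initial_state

from conftest import random_states
from oracle_rhs import oracle_rhs


class TestPdEffect:
    def test_no_drug_no_effect(self, params, config):
        assert pd_effect(0.0, 0.0, params, config) == 0.0

    def test_half_effect_at_ec50(self, params, config):
        # a Hill term evaluated at its EC50 gives Emax/2
        assert pd_effect(1176.7, 0.0, params, config) == pytest.approx(
            0.8764 / 2, abs=1e-12)

    def test_saturation_limit(self, params, config):
        sat = pd_effect(1e6 * params.EC50_PAC, 1e6 * params.EC50_TRAIL,
                        params, config)
        expected = 0.8764 + 0.438 + 0.8 * 0.8764 * 0.438
        assert sat == pytest.approx(expected, abs=1e-3)
        # hard upper bound
        assert sat <= expected

    def test_negative_concentration_rejected(self, params, config):
        with pytest.raises(ValueError):
            pd_effect(-1.0, 0.0, params, config)
        with pytest.raises(ValueError):
            pd_effect(0.0, -1.0, params, config)

    def test_combination_variants(self, params):
        ep = pd_effect(500.0, 0.0, params, ModelConfig())
        et = pd_effect(0.0, 3.0, params, ModelConfig())
        bliss = pd_effect(500.0, 3.0, params,
                          ModelConfig(pd_combination="bliss"))
        assert bliss == pytest.approx(ep + et - ep * et, rel=1e-12)
        pac = pd_effect(500.0, 3.0, params,
                        ModelConfig(pd_combination="pac_only"))
        assert pac == pytest.approx(ep, rel=1e-12)


class TestSaturatingRates:
    def test_infection_hazard_anchor_points(self, params):
        assert infection_hazard(0.0, params) == 0.0
        assert infection_hazard(0.51, params) == pytest.approx(0.027)
        assert infection_hazard(1e6 * 0.51, params) == pytest.approx(
            0.054, rel=1e-5)
        with pytest.raises(ValueError):
            infection_hazard(-0.1, params)

    def test_cytokine_production_anchor_points(self, params):
        assert cytokine_production(0.0, params) == pytest.approx(3.9863e-4)
        assert cytokine_production(1e6 * params.psi_half, params) == \
            pytest.approx(1.429, abs=1e-4)
        assert cytokine_production(params.psi_half, params) == \
            pytest.approx((3.9863e-4 + 1.429) / 2, rel=1e-12)

    def test_phagocyte_recruitment_anchor_points(self, params):
        assert phagocyte_recruitment(0.0, params) == 0.0
        assert phagocyte_recruitment(0.739, params) == pytest.approx(
            4.6754 / 2)
        assert phagocyte_recruitment(1e9, params) == pytest.approx(
            4.6754, rel=1e-6)

    @pytest.mark.parametrize("fn,arg_max", [
        (infection_hazard, 10.0),
        (cytokine_production, 0.01),
        (phagocyte_recruitment, 50.0),
    ])
    def test_monotone_nondecreasing(self, params, fn, arg_max):
        grid = np.linspace(0.0, arg_max, 100)
        vals = fn(grid, params)
        assert np.all(np.diff(vals) >= 0)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(c1=st.floats(0, 1e5), c2=st.floats(0, 1e5),
           d1=st.floats(0, 100), d2=st.floats(0, 100))
    def test_pd_effect_monotone_in_each_argument(self, c1, c2, d1, d2):
        from gcthybrid import default_parameters
        p = default_parameters()
        cfg = ModelConfig()
        assert pd_effect(c1 + d1, c2, p, cfg) >= pd_effect(c1, c2, p, cfg) - 1e-12
        assert pd_effect(c1, c2 + d2, p, cfg) >= pd_effect(c1, c2, p, cfg) - 1e-12


class TestEquilibria:
    def test_trail_production_closed_form(self, params):
        assert homeostatic_trail_production(params) == pytest.approx(
            4.6027, abs=2e-4)

    def test_trail_production_no_binding_limit(self, params):
        # kon -> 0 reduces Tprod to plain elimination kel * T_star
        p = params.replace(kon=1e-12)
        assert homeostatic_trail_production(p) == pytest.approx(
            45 * 0.08090, rel=1e-9)

    def test_immune_equilibrium_values(self, params):
        c_star, p_star = immune_equilibrium(params)
        assert c_star == pytest.approx(3.9863e-4 / 0.16139, rel=1e-12)
        assert c_star == pytest.approx(2.470e-3, abs=1e-5)
        assert p_star == pytest.approx(4.450e-2, abs=1e-4)

    def test_elimination_dominates(self, params):
        c_hi, _ = immune_equilibrium(params.replace(k_elim=1e9))
        assert c_hi < 1e-10

    def test_rhs_vanishes_at_joint_equilibrium(self, params, config, layout):
        y = initial_state(0.0, "all_quiescent", params, config)
        dy = rhs(0.0, y, params, config)
        assert np.max(np.abs(dy)) < 1e-10


class TestRhs:
    def test_zero_state_sources_only(self, params, config, layout):
        dy = rhs(0.0, layout.zeros(), params, config)
        expected = layout.zeros()
        expected[layout.index["C"]] = 3.9863e-4
        expected[layout.index["T"]] = homeostatic_trail_production(params)
        assert np.allclose(dy, expected, atol=1e-12)

    def test_matches_independent_oracle(self, params, config, layout):
        states = random_states(layout, 200, seed=42)
        pd = params.to_dict()
        dy = rhs(0.0, states, params, config)
        for k in range(states.shape[0]):
            y = states[k]
            sd = {"Q": y[0], "G1": y[1], "A": list(y[layout.slice_A]),
                  **{n: y[layout.index[n]] for n in
                     ("I", "V", "C", "P", "PA", "PPAC", "Pe", "T", "TP",
                      "TA")}}
            od = oracle_rhs(sd, pd)
            expect = np.concatenate([[od["Q"], od["G1"]], od["A"],
                                     [od[n] for n in
                                      ("I", "V", "C", "P", "PA", "PPAC",
                                       "Pe", "T", "TP", "TA")]])
            np.testing.assert_allclose(dy[k], expect, rtol=1e-12, atol=1e-300)

    def test_nonnegativity_preserving_field(self, params, config, layout):
        # any coordinate at zero has nonnegative derivative under the
        # corrected variants
        rng = np.random.default_rng(1)
        for _ in range(100):
            y = random_states(layout, 1, seed=rng.integers(2**31))[0]
            i = rng.integers(layout.n_state)
            y[i] = 0.0
            dy = rhs(0.0, y, params, config)
            assert dy[i] >= -1e-12

    def test_literal_minus_variant_changes_infection_sign(self, params, layout):
        cfg_lit = ModelConfig(variant_infection_sign="literal_minus",
                              clip_negative=False)
        cfg_cor = ModelConfig(clip_negative=False)
        y = layout.zeros()
        y[layout.index["G1"]] = 0.01
        y[layout.slice_A] = 0.05  # N = 0.3 > G1 -> literal target negative
        y[layout.index["V"]] = 1.0
        d_lit = rhs(0.0, y, params, cfg_lit)
        d_cor = rhs(0.0, y, params, cfg_cor)
        assert d_lit[layout.index["I"]] < 0 < d_cor[layout.index["I"]]

    def test_ode_eq5_variant_tracks_algebraic_sum(self, params):
        # integrating the redundant N equation stays close to sum(A_i)
        from gcthybrid.simulate import DoseSchedule, simulate
        cfg5 = ModelConfig(variant_active_total="ode_eq5")
        lay5 = StateLayout.for_config(params, cfg5)
        y0 = initial_state(1e9, "residence_time", params, cfg5)
        traj = simulate(params, cfg5, y0, DoseSchedule(events=(), horizon=5),
                        [0, 2.5, 5])
        n_int = traj.value("N")
        n_alg = traj.states[..., lay5.slice_A].sum(axis=-1)
        assert np.allclose(n_int, n_alg, rtol=1e-3)

    def test_nonfinite_state_rejected(self, params, config, layout):
        y = layout.zeros()
        y[0] = np.nan
        with pytest.raises(FloatingPointError):
            rhs(0.0, y, params, config)

    def test_tumor_only_subsystem_grows(self, params, layout):
        # no virus, drugs, immune kill: total burden derivative positive
        cfg = ModelConfig()
        p = params.replace(kp=1e-300, d2=params.d2, d3=params.d3)
        y = initial_state(1e9, "residence_time", p, cfg)
        dy = rhs(0.0, y, p, cfg)
        total_dot = dy[0] + dy[1] + dy[layout.slice_A].sum()
        assert total_dot > 0
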