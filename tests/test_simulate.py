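import numpy as np
import pytest

from gcthybrid import (DoseEvent, DoseSchedule, ModelConfig, SolverOptions,
                       build_schedule, initial_state, simulate,
                       simulate_batch, tumor_burden)
from gcthybrid.sensitivity import BaselineProtocol


@pytest.fixture(scope="module")
def protocol_schedule(params):
    return build_schedule(375, 21, 0.03, 1e9, params, horizon=21)


class TestBuildSchedule:
    def test_reference_protocol(self, params, protocol_schedule):
        sched = protocol_schedule
        oral = [e for e in sched.events if e.target == "PA_oral"]
        viral = [e for e in sched.events if e.target == "V_inoculum"]
        assert len(oral) == 21
        assert all(e.amount == 3.75e8 for e in oral)
        assert [e.time for e in oral] == list(map(float, range(21)))
        assert len(viral) == 1 and viral[0].time == 0.0
        # 0.03 x 1e9 virions = 3e7 = 0.003 scaled units at 1e10 cells/unit
        assert viral[0].amount == pytest.approx(0.003)

    def test_zero_dose_schedule(self, params):
        sched = build_schedule(0, 21, 0, 1e9, params)
        assert all(e.amount == 0 for e in sched.events)

    def test_single_day_course(self, params):
        sched = build_schedule(375, 1, 0.03, 1e9, params)
        oral = [e for e in sched.events if e.target == "PA_oral"]
        assert len(oral) == 1 and oral[0].time == 0.0

    def test_negative_inputs_rejected(self, params):
        with pytest.raises(ValueError):
            build_schedule(-1, 21, 0.03, 1e9, params)
        with pytest.raises(ValueError):
            DoseEvent(0.0, "PA_oral", -5.0)
        with pytest.raises(ValueError):
            DoseEvent(0.0, "IV", 5.0)


class TestInitialState:
    def test_all_quiescent(self, params, config, layout):
        y = initial_state(1e9, "all_quiescent", params, config)
        assert y[layout.index["Q"]] == pytest.approx(0.1)
        assert y[layout.index["G1"]] == 0
        assert np.all(y[layout.slice_A] == 0)

    def test_residence_time_weights(self, params, config, layout):
        y = initial_state(1e9, "residence_time", params, config)
        total = layout.total_tumor(y)
        assert total == pytest.approx(0.1, rel=1e-12)
        w_q, w_g1, w_a = (1 / params.a1, 1 / (params.a2 + params.d2),
                          1 / params.ktr)
        norm = w_q + w_g1 + params.j * w_a
        assert y[layout.index["Q"]] == pytest.approx(0.1 * w_q / norm)
        assert y[layout.index["G1"]] == pytest.approx(0.1 * w_g1 / norm)
        assert np.allclose(y[layout.slice_A], 0.1 * w_a / norm)

    def test_zero_tumor_at_equilibrium(self, params, config, layout):
        from gcthybrid import immune_equilibrium, trail_equilibrium
        y = initial_state(0, "residence_time", params, config)
        c_star, p_star = immune_equilibrium(params)
        eq = trail_equilibrium(params)
        assert y[layout.index["C"]] == pytest.approx(c_star)
        assert y[layout.index["P"]] == pytest.approx(p_star)
        assert y[layout.index["T"]] == eq["T"]
        assert layout.total_tumor(y) == 0

    def test_unknown_mode_rejected(self, params, config):
        with pytest.raises(ValueError):
            initial_state(1e9, "uniform", params, config)


class TestSimulate:
    def test_zero_tumor_stays_zero(self, params, config, layout,
                                   protocol_schedule):
        y0 = initial_state(0, "residence_time", params, config)
        traj = simulate(params, config, y0, protocol_schedule,
                        np.linspace(0, 21, 8))
        assert traj.success
        assert np.all(traj.total_tumor() == 0)
        assert np.all(traj.value("I") == 0)

    def test_oral_depot_first_order_decay(self, params, config, layout):
        # the gut depot is autonomous: PA(t) = D exp(-ka t)
        sched = DoseSchedule(events=(DoseEvent(0.0, "PA_oral", 3.75e8),),
                             horizon=2.0)
        y0 = initial_state(0, "residence_time", params, config)
        t = np.linspace(0, 2, 41)
        traj = simulate(params, config, y0, sched, t,
                        SolverOptions(rtol=1e-10, atol=1e-8))
        expected = 3.75e8 * np.exp(-params.ka * t)
        np.testing.assert_allclose(traj.value("PA"), expected, rtol=1e-6)

    def test_pk_two_dose_superposition(self, params, config, layout):
        # PAC-1 subsystem is linear: doses at t=0 and t=1 superpose
        y0 = initial_state(0, "residence_time", params, config)
        t = np.linspace(0, 3, 31)
        opts = SolverOptions(rtol=1e-10, atol=1e-12)
        def run(events):
            sched = DoseSchedule(events=tuple(events), horizon=3.0)
            return simulate(params, config, y0, sched, t, opts)
        both = run([DoseEvent(0.0, "PA_oral", 1e8),
                    DoseEvent(1.0, "PA_oral", 2e8)])
        d1 = run([DoseEvent(0.0, "PA_oral", 1e8)])
        d2 = run([DoseEvent(1.0, "PA_oral", 2e8)])
        baseline = run([])
        for var in ("PA", "PPAC", "Pe"):
            sup = d1.value(var) + d2.value(var) - baseline.value(var)
            np.testing.assert_allclose(both.value(var), sup,
                                       rtol=1e-6, atol=1e-8)

    def test_therapy_never_increases_burden(self, params, config,
                                            protocol_schedule):
        y0 = initial_state(1e9, "residence_time", params, config)
        treated = simulate(params, config, y0, protocol_schedule, [0, 21])
        untreated = simulate(params, config, y0,
                             DoseSchedule(events=(), horizon=21), [0, 21])
        assert treated.total_tumor()[-1] <= untreated.total_tumor()[-1]

    def test_sampling_refinement_consistency(self, params, config,
                                             protocol_schedule):
        y0 = initial_state(1e9, "residence_time", params, config)
        coarse = simulate(params, config, y0, protocol_schedule, [0, 7, 21])
        fine = simulate(params, config, y0, protocol_schedule,
                        [0, 3.5, 7, 10.5, 14, 21])
        for tc, row in zip(coarse.times, coarse.states):
            i = list(fine.times).index(tc)
            np.testing.assert_allclose(row, fine.states[i], rtol=1e-4,
                                       atol=1e-12)

    def test_tolerance_convergence(self, params, config, protocol_schedule):
        y0 = initial_state(1e9, "residence_time", params, config)
        b = [simulate(params, config, y0, protocol_schedule, [0, 21],
                      SolverOptions(rtol=r, atol=a)).total_tumor()[-1]
             for r, a in [(1e-6, 1e-9), (5e-7, 5e-10)]]
        assert abs(b[1] - b[0]) / b[0] < 1e-3

    def test_first_state_is_initial_condition(self, params, config):
        y0 = initial_state(1e9, "residence_time", params, config)
        traj = simulate(params, config, y0,
                        DoseSchedule(events=(), horizon=5), [0, 5])
        np.testing.assert_array_equal(traj.states[0], y0)

    def test_nonnegativity_of_trajectories(self, params, config, layout,
                                           protocol_schedule):
        rng = np.random.default_rng(5)
        y0s = []
        for _ in range(20):
            y = initial_state(float(rng.uniform(1e8, 5e9)), "residence_time",
                              params, config)
            y[layout.index["V"]] = rng.uniform(0, 0.01)
            y0s.append(y)
        traj = simulate_batch(params, config, np.stack(y0s),
                              protocol_schedule, np.linspace(0, 21, 8))
        assert traj.success
        assert traj.states.min() >= -1e-9


class TestBatchAndRk4:
    def test_batch_matches_single(self, params, config, protocol_schedule):
        y0s = np.stack([initial_state(v, "residence_time", params, config)
                        for v in (5e8, 1e9, 4e9)])
        batch = simulate_batch(params, config, y0s, protocol_schedule,
                               [0, 10, 21])
        for k in range(3):
            single = simulate(params, config, y0s[k], protocol_schedule,
                              [0, 10, 21])
            np.testing.assert_allclose(batch.states[:, k, :], single.states,
                                       rtol=1e-6, atol=1e-12)

    def test_per_patient_parameters(self, params, config):
        y0s = np.stack([initial_state(1e9, "residence_time", params, config)]
                       * 2)
        p2 = params.replace(a1=params.a1 * 1.5)
        sched = DoseSchedule(events=(), horizon=7)
        batch = simulate_batch([params, p2], config, y0s, sched, [0, 7])
        s1 = simulate(params, config, y0s[0], sched, [0, 7])
        s2 = simulate(p2, config, y0s[1], sched, [0, 7])
        np.testing.assert_allclose(batch.states[:, 0], s1.states, rtol=1e-4,
                                   atol=1e-10)
        np.testing.assert_allclose(batch.states[:, 1], s2.states, rtol=1e-4,
                                   atol=1e-10)

    def test_rk4_agrees_with_adaptive_on_short_course(self, params, config):
        y0 = initial_state(1e9, "residence_time", params, config)
        sched = build_schedule(375, 2, 0.03, 1e9, params, horizon=2)
        ad = simulate(params, config, y0, sched, [0, 1, 2])
        fx = simulate(params, config, y0, sched, [0, 1, 2],
                      SolverOptions(method="RK4", fixed_dt=5e-4))
        np.testing.assert_allclose(fx.total_tumor(), ad.total_tumor(),
                                   rtol=1e-4)


class TestTumorBurden:
    def test_scale_conventions(self, params, layout):
        y = layout.zeros()
        y[layout.index["Q"]] = 0.1
        cells, cc = tumor_burden(y, params)
        assert cells == pytest.approx(1e9) and cc == pytest.approx(1.0)

    def test_additivity(self, params, layout):
        y = layout.zeros()
        y[layout.index["Q"]] = 0.05
        y[layout.index["G1"]] = 0.03
        y[layout.slice_A] = 0.02 / params.j
        cells, cc = tumor_burden(y, params)
        assert cells == pytest.approx(1e9) and cc == pytest.approx(1.0)

    def test_zero_state(self, params, layout):
        assert tumor_burden(layout.zeros(), params) == (0.0, 0.0)


def test_trajectory_export_roundtrip(tmp_path, params, config):
    y0 = initial_state(1e9, "residence_time", params, config)
    traj = simulate(params, config, y0, DoseSchedule(events=(), horizon=2),
                    [0, 1, 2])
    df = traj.to_frame()
    assert list(df.columns[:3]) == ["time", "Q", "G1"]
    path = tmp_path / "traj.csv"
    traj.to_tidy_csv(path)
    import pandas as pd
    tidy = pd.read_csv(path)
    assert set(tidy.columns) == {"time", "variable", "value"}
    assert len(tidy) == 3 * traj.layout.n_state
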