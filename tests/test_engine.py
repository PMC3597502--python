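import numpy as np
import pytest

from phagedyn.core import DelayBuffer, DomainError, ModelParams
from phagedyn.engine import (
    EventRecord,
    Simulation,
    SimulationControl,
    StepSizeError,
    TransferSchedule,
    bim_event_probability,
    cem_event_probability,
    draw_events,
    serial_transfer,
)
from conftest import BASE_KW, make_scenario


class TestEventProbabilities:
    def test_bim_zero_acquisition(self):
        assert bim_event_probability(0.0, 1e9, 1e-3, 1.0) == 0.0

    def test_bim_arithmetic(self):
        p = bim_event_probability(1e-6, 3.2e5, 1e-3, 1.0)
        assert p == pytest.approx(3.2e-4)

    def test_bim_cap_rule(self):
        with pytest.raises(StepSizeError):
            bim_event_probability(1e-6, 3.2e5, 10.0, 1.0, mode="unit")
        # poisson mode accepts expectations above 1
        assert bim_event_probability(1e-6, 3.2e5, 10.0, 1.0, mode="poisson") == pytest.approx(3.2)

    def test_cem_zero_mutation(self):
        assert cem_event_probability(0.0, 1e9, 80.0, 1e-3, 1.0) == 0.0

    def test_cem_arithmetic(self):
        p = cem_event_probability(1e-6, 1e5, 80.0, 1e-3, 1.0)
        assert p == pytest.approx(7.9e-3)

    def test_volume_scales_probability(self):
        p1 = bim_event_probability(1e-6, 3.2e5, 1e-3, 1.0)
        p2 = bim_event_probability(1e-6, 3.2e5, 1e-3, 2.0)
        assert p2 == pytest.approx(2 * p1)


class TestDrawEvents:
    def test_unit_threshold_behaviour(self):
        class FixedRng:
            def __init__(self, u):
                self.u = u

            def random(self, n):
                return np.full(n, self.u)

        assert draw_events([0.3], FixedRng(0.5), "unit")[0] == 0
        assert draw_events([0.3], FixedRng(0.1), "unit")[0] == 1

    def test_unit_rejects_p_at_least_one(self):
        with pytest.raises(StepSizeError):
            draw_events([1.0], np.random.default_rng(0), "unit")

    def test_malformed_probability_rejected(self):
        with pytest.raises(DomainError):
            draw_events([-0.1], np.random.default_rng(0), "unit")
        with pytest.raises(DomainError):
            draw_events([np.nan], np.random.default_rng(0), "poisson")

    def test_long_run_rate_matches_binomial(self):
        rng = np.random.default_rng(7)
        n, p = 100_000, 0.01
        total = sum(int(draw_events([p] * 10, rng, "unit").sum()) for _ in range(n // 10))
        sigma = np.sqrt(n * p * (1 - p))
        assert abs(total - n * p) < 3 * sigma

    def test_poisson_mode_counts(self):
        rng = np.random.default_rng(3)
        counts = draw_events(np.full(50_000, 0.02), rng, "poisson")
        assert abs(counts.mean() - 0.02) < 3 * np.sqrt(0.02 / 50_000)


class TestDeterminism:
    def _scen(self, seed):
        params = ModelParams(**BASE_KW, m=1e-6, mu=1e-6, n_orders=2)
        return make_scenario(
            params, B=[2e6, 0], P=[2e6, 0], duration=2.0, seed=seed,
            event_mode="poisson", output_every=0.1,
        )

    def test_same_seed_identical(self):
        a = Simulation(self._scen(42)).run()
        b = Simulation(self._scen(42)).run()
        np.testing.assert_array_equal(a.values, b.values)
        assert a.events == b.events

    def test_no_stochastic_channels_seed_independent(self, base_params):
        a = Simulation(make_scenario(base_params, [2e6], [2e6], duration=2.0, seed=1)).run()
        b = Simulation(make_scenario(base_params, [2e6], [2e6], duration=2.0, seed=2)).run()
        np.testing.assert_array_equal(a.values, b.values)

    def test_different_seed_different_events(self):
        a = Simulation(self._scen(1)).run()
        b = Simulation(self._scen(2)).run()
        assert a.events != b.events


class TestStep:
    def test_phage_free_resource_exhaustion_closed_form(self, base_params):
        scen = make_scenario(base_params, B=[2e6], P=[0.0], dt=1e-3, duration=24.0,
                             output_every=1.0)
        ts = Simulation(scen).run()
        final = ts.column("B0")[-1]
        assert final == pytest.approx(2e6 + 350 / 5e-7, rel=0.01)

    def test_unit_mode_cap_aborts(self):
        # huge acquisition probability forces p >= 1 once bursts begin
        params = ModelParams(**BASE_KW, m=1.0, mu=0.0, n_orders=2)
        scen = make_scenario(params, B=[2e8, 0], P=[1e8, 0], duration=2.0, dt=1e-3)
        with pytest.raises(StepSizeError):
            Simulation(scen).run()

    def test_step_size_convergence_first_order(self, base_params):
        finals = []
        for dt in (2e-3, 1e-3, 5e-4):
            scen = make_scenario(base_params, B=[2e6], P=[2e6], dt=dt, duration=6.0,
                                 output_every=1.0)
            ts = Simulation(scen).run()
            finals.append(ts.column("P0")[-1])
        d1 = abs(finals[1] - finals[0])
        d2 = abs(finals[2] - finals[1])
        assert d2 < 2 * d1 if d1 > 0 else d2 == 0

    def test_event_log_records_transitions(self):
        params = ModelParams(**BASE_KW, m=1e-4, mu=0.0, n_orders=2)
        scen = make_scenario(
            params, B=[2e6, 0.0], P=[2e6, 0.0], duration=4.0, event_mode="poisson"
        )
        ts = Simulation(scen).run()
        assert len(ts.events) > 0
        for ev in ts.events:
            assert ev.kind == "BIM-creation"
            assert ev.destination_order == ev.source_order + 1


class TestExpectedEventCounts:
    def test_mean_events_match_analytic_sum(self):
        params = ModelParams(**BASE_KW, m=3e-5, mu=0.0, n_orders=2)
        counts = []
        expected = None
        for seed in range(100):
            scen = make_scenario(
                params, B=[2e6, 0], P=[2e6, 0], duration=1.0, dt=2e-3,
                seed=seed, output_every=1.0,
            )
            ts = Simulation(scen).run()
            counts.append(len(ts.events))
            expected = sum(ts.meta["expected_events"].values())
        mean = np.mean(counts)
        sigma = np.sqrt(expected / 100)  # ~Poisson across 100 seeds
        assert abs(mean - expected) < 4 * max(sigma, 1e-3)

    def test_unit_and_poisson_agree_at_small_expectations(self):
        params = ModelParams(**BASE_KW, m=3e-5, mu=0.0, n_orders=2)
        means = {}
        for mode in ("unit", "poisson"):
            counts = [
                len(
                    Simulation(
                        make_scenario(
                            params, B=[2e6, 0], P=[2e6, 0], duration=1.0, dt=2e-3,
                            seed=seed, event_mode=mode, output_every=1.0,
                        )
                    ).run().events
                )
                for seed in range(100)
            ]
            means[mode] = np.mean(counts)
        # both Monte Carlo means estimate the same analytic expectation
        pooled_sigma = np.sqrt((means["unit"] + means["poisson"]) / 100)
        assert abs(means["unit"] - means["poisson"]) < 4 * max(pooled_sigma, 1e-3)


class TestSerialTransfer:
    def _state(self, params, B, P):
        from phagedyn.core import CommunityState

        return CommunityState(
            0.0, 0.3, np.asarray(B, float), np.asarray(P, float),
            np.zeros(len(params.replicative_pairs())),
        )

    def test_dilution_arithmetic(self, base_params):
        state = self._state(base_params, [5e8], [1e9])
        serial_transfer(state, TransferSchedule(dilution=100, resource=350))
        assert state.B[0] == pytest.approx(5e6)
        assert state.P[0] == pytest.approx(1e7)
        assert state.r == 350.0

    def test_resource_reset(self, base_params):
        state = self._state(base_params, [1e6], [0])
        serial_transfer(state, TransferSchedule(dilution=100, resource=350))
        assert state.r == 350.0

    def test_buffer_diluted_with_cells(self, base_params):
        buf = DelayBuffer(dt=1e-3, lam=0.4, n_pairs=1)
        buf.push(np.array([1000.0]))
        state = self._state(base_params, [1e6], [1e6])
        state.M = buf.totals()
        serial_transfer(state, TransferSchedule(dilution=100), buffer=buf)
        np.testing.assert_allclose(buf.totals(), state.M)
        assert state.M[0] == pytest.approx(1000.0 * 1e-3 / 100)

    def test_identity_transfer(self, base_params):
        state = self._state(base_params, [5e8], [1e9])
        before_B, before_P = state.B.copy(), state.P.copy()
        serial_transfer(state, TransferSchedule(dilution=1.0, resource=0.3))
        np.testing.assert_array_equal(state.B, before_B)
        np.testing.assert_array_equal(state.P, before_P)
        assert state.r == 0.3

    def test_stochastic_rounding_survival_probability(self, base_params):
        rng = np.random.default_rng(11)
        survived = 0
        trials = 2000
        for _ in range(trials):
            state = self._state(base_params, [50.0], [0.0])
            serial_transfer(
                state,
                TransferSchedule(dilution=100, stochastic_rounding=True),
                rng=rng,
            )
            assert state.B[0] * 1.0 == int(state.B[0])  # integer individuals
            if state.B[0] >= 1:
                survived += 1
        expect = 1 - 0.99**50  # ~0.395
        sigma = np.sqrt(expect * (1 - expect) / trials)
        assert abs(survived / trials - expect) < 4 * sigma

    def test_large_populations_not_resampled(self, base_params):
        rng = np.random.default_rng(0)
        state = self._state(base_params, [5e8], [0.0])
        serial_transfer(
            state, TransferSchedule(dilution=100, stochastic_rounding=True), rng=rng
        )
        assert state.B[0] == pytest.approx(5e6)


class TestEventRecord:
    def test_destination_must_increment(self):
        with pytest.raises(DomainError):
            EventRecord(1.0, "BIM-creation", 0, 2)


class TestControlValidation:
    def test_lam_dt_integrality_enforced(self, base_params):
        scen = make_scenario(base_params, [1e6], [0], dt=0.003)
        with pytest.raises(DomainError):
            Simulation(scen)

    @pytest.mark.parametrize("bad", [dict(dt=0), dict(duration=-1), dict(event_mode="x"),
                                     dict(volume=0), dict(output_every=0)])
    def test_bad_control_rejected(self, bad):
        with pytest.raises(DomainError):
            SimulationControl(**bad)
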