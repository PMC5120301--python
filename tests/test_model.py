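"""Core ODE system and RK4 integrator."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from thalcort import (
    DEFAULT_INITIAL_STATE,
    IntegrationError,
    ModelParameters,
    SimulationConfig,
    StimulusEvent,
    StimulusProtocol,
    linear_activation,
    model_rhs,
    sigmoid_activation,
    simulate,
)
from thalcort.continuation import find_equilibrium


class TestActivations:
    @pytest.mark.parametrize(
        "x, expected",
        [
            (0.0, 0.5),  # symmetry at the origin
            (0.1, 0.7760721550006662),  # frozen from an independent
            # log-domain evaluation exp(-log1p(nu**-x))
            (50.0, 1.0),
            (-50.0, 0.0),
        ],
    )
    def test_sigmoid_values(self, x, expected):
        assert sigmoid_activation(x, 2.5e5) == pytest.approx(expected, abs=1e-12)

    def test_sigmoid_saturates_within_unit_interval(self):
        assert 0.0 < sigmoid_activation(-1e4, 2.5e5) < sigmoid_activation(1e4, 2.5e5) <= 1.0

    @settings(max_examples=50, deadline=None)
    @given(
        x=st.floats(-1, 1),
        dx=st.floats(0.01, 1.0),
        nu=st.floats(1.5, 1e4),
    )
    def test_sigmoid_strictly_increasing(self, x, dx, nu):
        # ranges chosen so both values stay away from double-precision
        # saturation, where strict inequality is unobservable
        assert sigmoid_activation(x + dx, nu) > sigmoid_activation(x, nu)

    def test_sigmoid_rejects_bad_input(self):
        with pytest.raises(ValueError):
            sigmoid_activation(np.nan, 2.5e5)
        with pytest.raises(ValueError):
            sigmoid_activation(0.0, 1.0)

    @pytest.mark.parametrize(
        "x, expected",
        [(0.0, 0.5), (1.0, 3.3), (-0.0818, 2.8 * -0.0818 + 0.5)],
    )
    def test_linear_activation(self, x, expected):
        assert linear_activation(x) == pytest.approx(expected, rel=0, abs=0)


def _reference_rhs(y, p):
    """Independent scalar reimplementation of the vector field."""
    f = lambda x: 1.0 / (1.0 + p.nu ** (-x))
    s = lambda x: p.alpha * x + p.beta
    py, in1, in2, tc, re = y
    return np.array(
        [
            p.tau1 * (p.eps1 - py + p.k1 * f(py) - p.k2 * f(in1)
                      - p.k3 * f(in2) + p.k4 * f(tc)),
            p.tau2 * (p.eps2 - in1 + p.k5 * f(py) - p.k6 * f(in2)),
            p.tau3 * (p.eps3 - in2 + p.k7 * f(py) - p.k8 * f(in1)),
            p.tau4 * (p.eps4 - tc - p.k9 * s(re) + p.k10 * f(py)),
            p.tau5 * (p.eps5 - re - p.k11 * s(re) + p.k12 * s(tc) + p.k13 * f(py)),
        ]
    )


class TestRHS:
    def test_matches_independent_implementation(self, params, rng):
        for _ in range(20):
            y = rng.uniform(-2, 2, size=5)
            np.testing.assert_allclose(
                model_rhs(y, params), _reference_rhs(y, params), rtol=1e-12
            )

    def test_decoupled_limit_relaxes_to_inputs(self, params, rng):
        p0 = params.replace(**{f"k{i}": 0.0 for i in range(1, 14)})
        y = rng.uniform(-2, 2, size=5)
        eps = np.array([p0.eps1, p0.eps2, p0.eps3, p0.eps4, p0.eps5])
        tau = np.array([p0.tau1, p0.tau2, p0.tau3, p0.tau4, p0.tau5])
        # with all couplings removed each population relaxes linearly
        # toward its input constant
        np.testing.assert_allclose(model_rhs(y, p0), tau * (eps - y), rtol=1e-12)

    def test_vanishes_at_equilibrium(self, params):
        eq = find_equilibrium(params)
        assert np.max(np.abs(model_rhs(eq, params))) < 1e-10

    def test_rejects_bad_state(self, params):
        with pytest.raises(ValueError):
            model_rhs([0.1, 0.2, 0.3], params)
        with pytest.raises(ValueError):
            model_rhs([np.inf, 0, 0, 0, 0], params)

    def test_parameter_vector_arity(self):
        with pytest.raises(ValueError):
            ModelParameters.from_vector(np.zeros(7))

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            ModelParameters(k4=-0.5)
        with pytest.raises(ValueError):
            ModelParameters(tau3=0.0)
        with pytest.raises(ValueError):
            ModelParameters().replace(nonsense=1.0)


class TestIntegrator:
    def test_agrees_with_adaptive_reference_integrator(self, params):
        """Cross-check the fixed-step RK4 against scipy's adaptive RK45 at
        tight tolerances over an active transient."""
        from scipy.integrate import solve_ivp

        cfg = SimulationConfig(duration=2.0, transient_discard=0.5)
        mine = simulate(params, cfg).final_state()
        ref = solve_ivp(
            lambda t, y: model_rhs(y, params),
            (0.0, 2.0),
            DEFAULT_INITIAL_STATE,
            method="RK45",
            rtol=1e-10,
            atol=1e-12,
        )
        np.testing.assert_allclose(mine, ref.y[:, -1], atol=5e-8)

    def test_rk4_global_order(self, params):
        """Halving dt reduces the endpoint error ~16x (4th order)."""

        def end(dt):
            cfg = SimulationConfig(dt=dt, duration=0.5, transient_discard=0.1)
            return simulate(params, cfg).final_state()

        e_coarse = np.max(np.abs(end(1e-3) - end(5e-4)))
        e_fine = np.max(np.abs(end(5e-4) - end(2.5e-4)))
        assert 8.0 < e_coarse / e_fine < 32.0

    def test_started_at_equilibrium_stays_there(self, params):
        eq = find_equilibrium(params)
        traj = simulate(params, SimulationConfig(duration=20.0, initial_state=eq))
        assert np.max(np.abs(traj.states - eq)) < 1e-8

    def test_zero_magnitude_event_is_identity(self, params, short_config):
        ref = simulate(params, short_config)
        nil = StimulusProtocol.single(1.0, 0.0)
        out = simulate(params, short_config, nil)
        assert np.array_equal(ref.states, out.states)

    def test_cortical_mean_is_py_in1_average(self, params, short_config):
        traj = simulate(params, short_config)
        np.testing.assert_array_equal(
            traj.cortical_mean, 0.5 * (traj.states[:, 0] + traj.states[:, 1])
        )

    def test_jump_event_displaces_both_targets(self, params):
        cfg = SimulationConfig(duration=1.0, transient_discard=0.1)
        ref = simulate(params, cfg)
        jump = simulate(params, cfg, StimulusProtocol.single(0.5, 0.3))
        i = 501  # first grid point after the event
        delta = jump.states[i] - ref.states[i]
        # the displacement is -0.3 on both targets plus one RK4 step of the
        # (fast) cortical dynamics reacting to it
        assert delta[0] == pytest.approx(-0.3, abs=0.05)
        assert delta[1] == pytest.approx(-0.3, abs=0.15)
        assert abs(delta[2]) < 1e-3  # IN2 is slow and never stimulated directly

    def test_pulse_mode_differs_from_jump(self, params, short_config):
        jump = simulate(
            params, short_config, StimulusProtocol.single(1.0, 0.3, mode="jump")
        )
        pulse = simulate(
            params,
            short_config,
            StimulusProtocol.single(1.0, 0.3, mode="pulse", duration=0.05),
        )
        assert not np.array_equal(jump.states, pulse.states)

    def test_event_outside_window_rejected(self, params, short_config):
        with pytest.raises(ValueError):
            simulate(params, short_config, StimulusProtocol.single(10.0, 0.3))


class TestTrajectoryIO:
    def test_csv_round_trip(self, params, short_config, tmp_path):
        traj = simulate(params, short_config)
        path = tmp_path / "traj.csv"
        traj.write_csv(path)
        back = traj.read_csv(path)
        np.testing.assert_array_equal(back.states, traj.states)
        np.testing.assert_array_equal(back.time, traj.time)
        header = path.read_text().splitlines()[0]
        assert header == "t,PY,IN1,IN2,TC,RE,mean"

    def test_reader_rejects_wrong_schema(self, tmp_path):
        bad = tmp_path / "bad.csv"
        bad.write_text("a,b\n1,2\n")
        from thalcort import Trajectory

        with pytest.raises(ValueError):
            Trajectory.read_csv(bad)


class TestProtocol:
    def test_events_sorted_by_time(self):
        proto = StimulusProtocol(
            (StimulusEvent(5.0, 0.1), StimulusEvent(1.0, 0.2))
        )
        assert [e.time for e in proto.events] == [1.0, 5.0]

    def test_validation(self):
        with pytest.raises(ValueError):
            StimulusEvent(1.0, -0.1)
        with pytest.raises(ValueError):
            StimulusEvent(1.0, 0.1, mode="sawtooth")
        with pytest.raises(ValueError):
            StimulusEvent(1.0, 0.1, targets=("TC",))
        with pytest.raises(ValueError):
            StimulusProtocol.double(0.3, 0.2, t_initiation=5.0, t_termination=5.0)

    def test_periodic_expansion_alternates(self):
        proto = StimulusProtocol.periodic(
            period=20.0, initiation=0.3, termination=0.2,
            t_first=20.0, termination_offset=15.0, until=80.0,
        )
        times = [e.time for e in proto.events]
        mags = [e.magnitude for e in proto.events]
        assert times == [20.0, 35.0, 40.0, 55.0, 60.0, 75.0]
        assert mags == [0.3, 0.2] * 3

    def test_recurrent_seizures_under_periodic_stimulation(self, params):
        """Periodic initiation/termination pulses alternate seizure and
        background epochs."""
        proto = StimulusProtocol.periodic(
            period=30.0, initiation=0.3, termination=0.2,
            t_first=20.0, termination_offset=15.0, until=80.0,
        )
        traj = simulate(params, SimulationConfig(duration=100.0), proto)
        # seizure epochs: after initiation, before termination
        assert np.ptp(traj.window(28.0, 35.0)) > 0.2
        assert np.ptp(traj.window(58.0, 65.0)) > 0.2
        # background epochs: after termination, before the next initiation
        assert np.ptp(traj.window(45.0, 50.0)) < 1e-3
        assert np.ptp(traj.window(75.0, 80.0)) < 1e-3
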