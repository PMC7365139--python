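"""Circuit composition, co-culture dynamics, and AHL wire calibration."""

import numpy as np
import pytest

from csmux.circuit import (
    AhlParams,
    CircuitNode,
    CircuitSpec,
    Phase,
    Protocol,
    activation_time,
    estimate_ahl_rate,
    simulate_dynamics,
    steady_state,
)
from csmux.gates import HillParams, not_response, sensor_response
from csmux.reference import (
    build_channel_selector,
    build_mux_circuit,
    signal_path_layers,
)

GP = HillParams(100.0, 20000.0, 2000.0, 2.0)


def _linear_sensor(name: str, value: float) -> HillParams:
    """Near-constant 'sensor' used to inject a fixed MEFL level."""
    return HillParams(value, value + 1e-6, 1.0, 1.0, mode="activation")


def two_gate_cascade() -> CircuitSpec:
    nodes = (
        CircuitNode("drive", "sensor", ("x",), HillParams(1.0, 1e5, 10.0, 1.0, mode="activation")),
        CircuitNode("g1", "not_gate", ("drive",), GP),
        CircuitNode("g2", "not_gate", ("g1",), GP),
    )
    return CircuitSpec(nodes)


class TestSteadyState:
    def test_mux_routes_selected_input(self):
        mux = build_mux_circuit(with_sensors=True, with_ahl=False)
        hi = {"aTc": 20.0, "IPTG": 0.3, "DAPG": 100.0}
        # SELECT low (DAPG present -> NOT4 low): OUT_MUX tracks IN1 = NOT(aTc)
        out_atc0 = steady_state(mux, {"aTc": 0.0, "IPTG": 0.0, "DAPG": 100.0})["NOR3"]
        out_atc1 = steady_state(mux, {"aTc": 20.0, "IPTG": 0.0, "DAPG": 100.0})["NOR3"]
        assert out_atc0 > 10 * out_atc1  # aTc toggles the output
        # IPTG must not matter when SELECT is low
        out_iptg = steady_state(mux, {"aTc": 0.0, "IPTG": 0.3, "DAPG": 100.0})["NOR3"]
        assert out_iptg == pytest.approx(out_atc0, rel=0.05)
        # SELECT high (DAPG absent): OUT_MUX tracks IN2 = NOT(IPTG)
        out2_0 = steady_state(mux, {"aTc": 0.0, "IPTG": 0.0, "DAPG": 0.0})["NOR3"]
        out2_1 = steady_state(mux, {"aTc": 0.0, "IPTG": 0.3, "DAPG": 0.0})["NOR3"]
        assert out2_0 > 10 * out2_1

    def test_constitutive_node_outputs_ymax(self):
        const = CircuitSpec(
            (CircuitNode("c", "sensor", ("x",), HillParams(9999.0, 9999.0 + 1e-9, 1.0, 1.0, mode="activation")),)
        )
        for x in (0.0, 5.0, 100.0):
            assert steady_state(const, {"x": x})["c"] == pytest.approx(9999.0, rel=1e-6)

    def test_cascade_equals_nested_closed_form(self, rng):
        c = two_gate_cascade()
        for x in rng.uniform(0, 50, size=50):
            ss = steady_state(c, {"x": x})
            drive = sensor_response(x, c.node("drive").params)
            expected = not_response(not_response(drive, GP), GP)
            assert ss["g2"] == pytest.approx(expected, rel=1e-12)

    def test_unknown_inducer_raises(self):
        with pytest.raises(KeyError):
            steady_state(two_gate_cascade(), {})

    def test_mux_symmetry_under_channel_swap(self):
        """Swapping IN1/IN2 and exchanging the select rails mirrors the map.

        Built with explicit complementary select rails so the swap is an
        exact graph automorphism of the circuit.
        """
        inj = HillParams(1.0, 30000.0, 1.0, 1.0, mode="activation")
        nodes = (
            CircuitNode("IN1", "sensor", ("in1",), inj),
            CircuitNode("IN2", "sensor", ("in2",), inj),
            CircuitNode("SEL", "sensor", ("sel",), inj),
            CircuitNode("SELC", "sensor", ("selc",), inj),
            CircuitNode("NOR_A", "nor_gate", ("IN1", "SEL"), GP),
            CircuitNode("NOR_B", "nor_gate", ("IN2", "SELC"), GP),
            CircuitNode("OUT", "nor_gate", ("NOR_A", "NOR_B"), GP),
        )
        mux = CircuitSpec(nodes)
        for a, b, s in [(0.0, 80.0, 0.0), (80.0, 0.0, 30.0), (25.0, 60.0, 80.0)]:
            fwd = steady_state(mux, {"in1": a, "in2": b, "sel": s, "selc": 80 - s})
            rev = steady_state(mux, {"in1": b, "in2": a, "sel": 80 - s, "selc": s})
            assert fwd["OUT"] == pytest.approx(rev["OUT"], rel=1e-12)


class TestDynamics:
    def test_zero_production_decays_exponentially(self):
        # induce the drive so the gate's target drops to ~0: X(t) = X0 exp(-lam t)
        lam = 0.7
        nodes = (
            CircuitNode("drive", "sensor", ("x",), HillParams(0.0, 1e6, 1.0, 2.0, mode="activation")),
            CircuitNode("g", "not_gate", ("drive",), HillParams(0.0, 5000.0, 10.0, 2.0)),
        )
        c = CircuitSpec(nodes)
        proto = Protocol(
            phases=(Phase(3.0, {"x": 100.0}),),
            initial_od={"strain": 0.1},
            growth_rate={"strain": lam},
        )
        traj = simulate_dynamics(c, proto)
        assert traj.outputs["g"][0] == pytest.approx(5000.0)  # uninduced start
        expected = 5000.0 * np.exp(-lam * traj.times)
        assert np.allclose(traj.outputs["g"], expected, rtol=2e-3, atol=1e-3)

    def test_constant_production_reaches_p_over_lambda(self):
        # receiver switched on by exogenous AHL rises first-order to its target
        lam = 0.9
        rp = HillParams(0.0, 7000.0, 3.0, 1.5, mode="activation")
        c = CircuitSpec((CircuitNode("R", "ahl_receiver", ("AHL",), rp),))
        proto = Protocol(
            phases=(Phase(12.0 / lam, {"AHL": 1e6}),),
            growth_rate={"strain": lam},
            initial_od={"strain": 0.05},
        )
        traj = simulate_dynamics(c, proto)
        target = 7000.0  # P/lambda of the equivalent production-decay form
        assert traj.outputs["R"][0] == pytest.approx(0.0, abs=1e-6)
        assert traj.outputs["R"][-1] == pytest.approx(target, rel=1e-3)
        # and the closed-form transient
        expected = target * (1 - np.exp(-lam * traj.times))
        assert np.allclose(traj.outputs["R"], expected, rtol=2e-3, atol=1.0)

    def test_ahl_accumulates_linearly_at_published_rate(self):
        # constant OD = 0.2 and LuxI = 1000 MEFL: A(t) = 0.089 * 0.2 * 1000 * t
        nodes = (
            CircuitNode("drive", "sensor", ("x",), _linear_sensor("d", 1000.0)),
            CircuitNode("S", "ahl_sender", ("drive",), AhlParams(k_prod=0.089)),
        )
        c = CircuitSpec(nodes)
        proto = Protocol(
            phases=(Phase(2.0, {"x": 0.0}),),
            initial_od={"strain": 0.2},
            growth_rate={"strain": 0.0},
        )
        traj = simulate_dynamics(c, proto)
        expected = 0.089 * 0.2 * 1000.0 * traj.times
        assert np.allclose(traj.ahl, expected, rtol=1e-6, atol=1e-9)

    def test_steady_state_is_long_time_limit(self, rng):
        """Random 3-gate circuits: ODE limit matches the topological pass within 1%.

        The protocol induces the sensor, so the system relaxes from its
        uninduced state toward the induced steady state.
        """
        for trial in range(5):
            k1, k2, k3 = rng.uniform(200, 5000, size=3)
            n1, n2, n3 = rng.uniform(1.0, 3.0, size=3)
            x_level = float(rng.uniform(1.0, 50.0))
            nodes = (
                CircuitNode(
                    "drive", "sensor", ("x",),
                    HillParams(50.0, 8000.0, 5.0, 1.5, mode="activation"),
                ),
                CircuitNode("g1", "not_gate", ("drive",), HillParams(80, 15000, k1, n1)),
                CircuitNode("g2", "not_gate", ("g1",), HillParams(120, 22000, k2, n2)),
                CircuitNode("g3", "nor_gate", ("g1", "g2"), HillParams(90, 18000, k3, n3)),
            )
            c = CircuitSpec(nodes)
            lam = 0.8
            proto = Protocol(
                phases=(Phase(14.0 / lam, {"x": x_level}),),
                growth_rate={"strain": lam},
                initial_od={"strain": 0.05},
            )
            traj = simulate_dynamics(c, proto)
            ss = steady_state(c, {"x": x_level})
            for node in ("g1", "g2", "g3"):
                assert traj.outputs[node][-1] == pytest.approx(ss[node], rel=0.01)

    def test_full_retention_dilution_is_noop(self):
        c = two_gate_cascade()
        base = Protocol(
            phases=(Phase(3.0, {"x": 10.0}),),
            growth_rate={"strain": 0.5},
            initial_od={"strain": 0.05},
        )
        with_events = Protocol(
            phases=(Phase(3.0, {"x": 10.0}, dilution_period_h=1.0, retained_fraction=1.0),),
            growth_rate={"strain": 0.5},
            initial_od={"strain": 0.05},
        )
        t1 = simulate_dynamics(c, base)
        t2 = simulate_dynamics(c, with_events)
        # integrator restarts at event boundaries leave only tolerance-level drift
        assert t1.outputs["g2"][-1] == pytest.approx(t2.outputs["g2"][-1], rel=1e-4)
        assert t2.od["strain"][-1] == pytest.approx(t1.od["strain"][-1], rel=1e-4)

    def test_dilution_scales_od_and_ahl(self):
        nodes = (
            CircuitNode("drive", "sensor", ("x",), _linear_sensor("d", 1000.0)),
            CircuitNode("S", "ahl_sender", ("drive",), AhlParams(k_prod=0.1)),
        )
        c = CircuitSpec(nodes)
        proto = Protocol(
            phases=(Phase(2.0, {"x": 0.0}, dilution_period_h=1.0, retained_fraction=0.5),),
            initial_od={"strain": 0.2},
            growth_rate={"strain": 0.0},
        )
        traj = simulate_dynamics(c, proto)
        i = int(np.searchsorted(traj.times, 1.0, side="right"))
        assert traj.od["strain"][i] == pytest.approx(0.1, rel=1e-6)

    def test_trajectory_nonnegative(self):
        cs = build_channel_selector()
        proto = Protocol(
            phases=(Phase(4.0, {"DAPG": 100.0}, dilution_period_h=1.5, retained_fraction=0.28),),
            initial_od={"sender": 0.06, "receiver": 0.006},
            growth_rate={"sender": 0.85, "receiver": 0.85},
        )
        traj = simulate_dynamics(cs, proto)
        assert np.all(traj.ahl >= 0)
        for series in traj.outputs.values():
            assert np.all(series >= 0)
        assert np.all(np.diff(traj.times) > 0)


class TestAhlRate:
    def test_recovers_generating_rate_within_two_percent(self):
        k_true = 0.1
        t = np.linspace(0.0, 2.5, 6)
        od = 0.0129 * np.exp(0.8 * t)
        lux = np.full_like(t, 15000.0)
        exposure = np.concatenate(
            [[0.0], np.cumsum(0.5 * (od[1:] * lux[1:] + od[:-1] * lux[:-1]) * np.diff(t))]
        )
        rp = HillParams(80.0, 9000.0, 3.0, 1.5, mode="activation")
        readout = sensor_response(k_true * exposure, rp)
        k_est = estimate_ahl_rate(t, od, lux, readout, rp)
        assert k_est == pytest.approx(k_true, rel=0.02)

    def test_zero_luxi_gives_zero_rate(self):
        t = np.linspace(0, 2.5, 6)
        od = np.full_like(t, 0.2)
        lux = np.zeros_like(t)
        rp = HillParams(80.0, 9000.0, 3.0, 1.5, mode="activation")
        readout = np.full_like(t, 80.0)  # receiver at its floor
        assert estimate_ahl_rate(t, od, lux, readout, rp) == 0.0

    def test_saturated_readouts_excluded_with_warning(self):
        t = np.linspace(0, 2.0, 5)
        od = np.full_like(t, 0.2)
        lux = np.full_like(t, 1000.0)
        rp = HillParams(80.0, 9000.0, 3.0, 1.5, mode="activation")
        readout = np.array([80.0, 500.0, 2000.0, 9000.0, 9500.0])  # last two invalid
        with pytest.warns(UserWarning, match="excluded"):
            estimate_ahl_rate(t, od, lux, readout, rp)


class TestActivationTime:
    def test_first_order_rise_crosses_at_ln2_over_lambda(self):
        lam = 0.9
        rp = HillParams(0.0, 5000.0, 3.0, 1.5, mode="activation")
        c = CircuitSpec((CircuitNode("R", "ahl_receiver", ("AHL",), rp),))
        proto = Protocol(
            phases=(Phase(10.0 / lam, {"AHL": 1e6}),),
            growth_rate={"strain": lam},
            initial_od={"strain": 0.05},
        )
        traj = simulate_dynamics(c, proto)
        t_half = activation_time(traj, "R", 0.5)
        assert t_half == pytest.approx(np.log(2) / lam, rel=0.02)

    def test_never_crossing_returns_none(self):
        lam = 0.5
        c = two_gate_cascade()
        proto = Protocol(
            phases=(Phase(2.0, {"x": 0.0}),),
            growth_rate={"strain": lam},
            initial_od={"strain": 0.05},
        )
        traj = simulate_dynamics(c, proto)
        assert activation_time(traj, "g2", 0.5, lo=0.0, hi=1e9) is None

    def test_missing_node_raises(self):
        c = two_gate_cascade()
        proto = Protocol(phases=(Phase(1.0, {"x": 0.0}),))
        traj = simulate_dynamics(c, proto)
        with pytest.raises(KeyError):
            activation_time(traj, "nope", 0.5)


def test_cs_longest_path_is_eight_layers():
    assert signal_path_layers(build_channel_selector()) == 8
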