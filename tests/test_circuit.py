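import math

import numpy as np
import pytest

from rcaxon import SolutionState, build_axon_circuit, extract_features, simulate_transient
from rcaxon.circuit import CircuitModel, ProbeLoad, PulseSpec, Trace


def _shunt_ladder(sections, source_resistance, probe_node=0):
    """Ladder with a grounded termination: the last section shunts to ground."""
    r, c = zip(*sections)
    return CircuitModel(
        section_resistances=r,
        section_capacitances=c,
        source_resistance=source_resistance,
        source_inductance=0.0,
        termination_resistance=0.0,
        probe_node=probe_node,
        probe_load=None,
    )


STEP = PulseSpec(period=2e-6, high_level=1.0, low_level=0.0, high_fraction=0.9995)


class TestTransientAgainstClosedForms:
    def test_one_section_rc_step_response(self):
        """Single shunt r||c behind Rs: analytic exponential with tau=(Rs||r)c."""
        Rs, r, c = 100.0, 250.0, 1e-9
        circ = _shunt_ladder([(r, c)], Rs)
        tr = simulate_transient(circ, STEP, duration=2e-6, dt=1e-9, settle=False)
        mask = tr.times <= STEP.period * STEP.high_fraction
        tau = (Rs * r / (Rs + r)) * c
        analytic = (r / (Rs + r)) * (1.0 - np.exp(-tr.times[mask] / tau))
        assert np.abs(tr.voltages[mask] - analytic).max() < 1e-9

    def test_two_section_eigendecomposition_oracle(self):
        """Two-state ladder vs an independently hand-derived modal solution."""
        r1, c1, r2, c2, Rs = 300.0, 2e-9, 500.0, 1e-9, 150.0
        circ = _shunt_ladder([(r1, c1), (r2, c2)], Rs, probe_node=1)
        tr = simulate_transient(circ, STEP, duration=2e-6, dt=1e-9, settle=False)
        # KCL, x = [v0, v1]: M x' = -G x + b u
        M = np.array([[c1, -c1], [-c1, c1 + c2]])
        G = np.array([[1 / Rs + 1 / r1, -1 / r1], [-1 / r1, 1 / r1 + 1 / r2]])
        A = -np.linalg.solve(M, G)
        b = np.linalg.solve(M, np.array([1 / Rs, 0.0]))
        w, V = np.linalg.eig(A)
        x_inf = -np.linalg.solve(A, b * STEP.high_level)
        coef = np.linalg.solve(V, -x_inf)
        mask = tr.times <= STEP.period * STEP.high_fraction
        t = tr.times[mask]
        x = x_inf[:, None] + V @ (coef[:, None] * np.exp(w[:, None] * t[None, :]))
        assert np.abs(x[1].real - tr.voltages[mask]).max() < 1e-9

    def test_ode_path_agrees_with_exact_propagation(self):
        circ = build_axon_circuit(SolutionState(1e-4))
        exact = simulate_transient(circ, method="expm")
        ode = simulate_transient(circ, method="ode")
        assert np.abs(exact.voltages - ode.voltages).max() < 1e-4


class TestLTIProperties:
    def test_zero_amplitude_drive_gives_zero_trace(self):
        circ = build_axon_circuit(SolutionState(1e-4))
        tr = simulate_transient(circ, PulseSpec(high_level=0.0, low_level=0.0))
        assert np.abs(tr.voltages).max() == 0.0

    def test_superposition(self):
        circ = build_axon_circuit(SolutionState(1e-4))
        p1 = PulseSpec(high_level=3.0, low_level=-3.0)
        p2 = PulseSpec(high_level=1.0, low_level=0.5)
        p_sum = PulseSpec(high_level=4.0, low_level=-2.5)
        v1 = simulate_transient(circ, p1).voltages
        v2 = simulate_transient(circ, p2).voltages
        v12 = simulate_transient(circ, p_sum).voltages
        assert np.abs(v1 + v2 - v12).max() < 1e-9 * np.abs(v12).max()

    @pytest.mark.parametrize("c_mM", [0.0, 0.1, 1.0, 20.0])
    def test_passivity(self, c_mM):
        """Probe amplitude never exceeds the drive amplitude."""
        circ = build_axon_circuit(SolutionState(c_mM * 1e-3))
        tr = simulate_transient(circ)
        assert np.abs(tr.voltages).max() <= 3.0

    def test_grid_refinement_stability(self):
        circ = build_axon_circuit(SolutionState(1e-4))
        coarse = simulate_transient(circ, dt=2.5e-9)
        fine = simulate_transient(circ, dt=1.25e-9)
        diff = np.abs(coarse.voltages - fine.voltages[::2]).max()
        assert diff < 1e-6 * np.abs(coarse.voltages).max()

    def test_steady_periodic_initial_state(self):
        """Two consecutive periods of the settled response are identical."""
        circ = build_axon_circuit(SolutionState(1e-4))
        tr = simulate_transient(circ, duration=4e-6)
        n = 800
        assert np.abs(tr.voltages[:n] - tr.voltages[n : 2 * n]).max() < 1e-9


class TestBuildAxonCircuit:
    def test_uniform_solution_gives_identical_sections(self, geometry):
        circ = build_axon_circuit(SolutionState(0.020, background_conductivity=0.0), geometry)
        assert len(set(circ.section_resistances)) == 1
        assert len(set(circ.section_capacitances)) == 1
        # kappa = 0.614 S/m -> r = d/(kappa A) ~ 543 ohm
        assert circ.section_resistances[0] == pytest.approx(543, rel=1e-2)

    def test_doubling_conductivity_halves_r_keeps_c(self, geometry):
        c1 = build_axon_circuit(SolutionState(0.001, background_conductivity=0.0), geometry)
        c2 = build_axon_circuit(SolutionState(0.002, background_conductivity=0.0), geometry)
        assert c2.section_resistances[0] == pytest.approx(c1.section_resistances[0] / 2, rel=1e-12)
        assert c2.section_capacitances[0] == c1.section_capacitances[0]

    def test_floating_capacitor_network_diagnosed(self):
        with pytest.raises(ValueError, match="capacitance matrix|ground"):
            circ = CircuitModel(
                section_resistances=(1e3,),
                section_capacitances=(1e-12,),
                source_resistance=1.0,
                source_inductance=0.0,
                termination_resistance=650.0,
                probe_node=0,
                probe_load=None,
            )
            simulate_transient(circ)


class TestExtractFeatures:
    def _trace(self, volts, dt=1e-9):
        t = np.arange(len(volts)) * dt
        return Trace(times=t, voltages=np.asarray(volts, float), dt=dt)

    def test_ratio_arithmetic(self):
        """Max +0.30, min -0.25 about a zero baseline -> ratio 1.2."""
        v = np.zeros(100)
        v[10] = 0.30
        v[20] = -0.25
        f = extract_features(self._trace(v))
        assert f.baseline == 0.0
        assert f.ratio == pytest.approx(1.2, rel=1e-12)

    def test_symmetric_response_ratio_one(self):
        t = np.arange(200)
        v = 0.5 * np.sin(2 * np.pi * t / 50)
        f = extract_features(self._trace(v))
        assert f.ratio == pytest.approx(1.0, rel=1e-6)

    def test_degenerate_b_flagged_not_divided(self):
        v = np.zeros(100)
        v[10] = 0.3
        f = extract_features(self._trace(v))
        assert f.degenerate and math.isinf(f.ratio)

    def test_rise_and_fall_times_of_known_edge(self):
        # linear ramp up over 100 ns, down over 200 ns: 10-90% widths are 80/160 ns
        up = np.linspace(0, 1, 101)
        down = np.linspace(1, 0, 201)
        v = np.concatenate([np.zeros(300), up, down[1:], np.zeros(300)])
        f = extract_features(self._trace(v))
        assert f.rise_time == pytest.approx(80e-9, rel=1e-6)
        assert f.fall_time == pytest.approx(160e-9, rel=1e-6)

    def test_ratio_monotone_across_low_concentration_sweep(self, trace_source):
        """a/b increases across the 0.025-0.5 mM trace family."""
        ratios = [
            extract_features(trace_source(c * 1e-3)).ratio
            for c in (0.025, 0.1, 0.25, 0.5)
        ]
        assert all(r2 > r1 for r1, r2 in zip(ratios, ratios[1:]))

    def test_ratio_nondecreasing_full_operating_range(self, trace_source):
        """a/b non-decreasing in conductivity over 0-20 mM; the undershoot
        vanishes at the high-conductivity end, where the ratio is degenerate
        (unbounded) rather than finite."""
        feats = [
            extract_features(trace_source(c * 1e-3))
            for c in (0.0, 0.025, 0.1, 0.5, 1.0, 5.0, 20.0)
        ]
        finite = [f.ratio for f in feats if not f.degenerate]
        assert all(r2 >= r1 for r1, r2 in zip(finite, finite[1:]))
        # degenerate entries only ever follow the finite ones
        flags = [f.degenerate for f in feats]
        assert flags == sorted(flags)
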