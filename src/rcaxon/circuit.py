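"""Equivalent-circuit model of the artificial axon and its transient response.

The device is modelled as a ladder of ten series parallel-RC sections (the
electrolyte wells) between a launch plate and a termination plate.  The drive
branch carries the generator's series resistance and inductance; the return
wires contribute their own R and L, lumped into the same series branch because
the loop current is common.  The oscilloscope probe is a configurable
(R_probe, C_probe) shunt from the probed plate to the ground-return wire, and
the ground-return node is taken as the voltage reference.

The network is linear and time-invariant and the drive is a piecewise-constant
rectangular pulse train, so the transient is propagated exactly segment by
segment with the matrix exponential of the state matrix; no time-stepping
error is incurred at the sample points.  A conventional stiff ODE integration
is available as a cross-check path.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.linalg import expm

from .electrolyte import ChannelGeometry, SolutionState, compartment_impedance, conductivity_from_concentration

__all__ = [
    "PulseSpec",
    "ProbeLoad",
    "CircuitModel",
    "Trace",
    "TraceFeatures",
    "DEFAULT_FIXED_ELEMENTS",
    "build_axon_circuit",
    "simulate_transient",
    "extract_features",
]


@dataclass(frozen=True)
class PulseSpec:
    """Rectangular pulse-train drive.

    Defaults reproduce the experimental stimulus: 2 us period, +3 V for 0.5 %
    of the period (10 ns), -3 V for the remaining 99.5 %.  A period starts at
    the rising edge of the high segment.
    """

    period: float = 2.0e-6
    high_level: float = 3.0
    low_level: float = -3.0
    high_fraction: float = 0.005

    def __post_init__(self) -> None:
        if self.period <= 0:
            raise ValueError("period must be > 0")
        if not 0.0 < self.high_fraction < 1.0:
            raise ValueError("high_fraction must be in (0, 1)")

    @property
    def high_duration(self) -> float:
        return self.period * self.high_fraction


@dataclass(frozen=True)
class ProbeLoad:
    """Oscilloscope probe input impedance, shunted plate-to-ground-wire.

    The default 10 MOhm / 5 pF is within the range of passive high-impedance
    probes and keeps the a/b amplitude ratio a strictly increasing function of
    electrolyte concentration over the whole operating range, which the
    calibration pipeline requires (larger tip capacitances make the ratio dip
    at the low-conductivity end before rising).
    """

    resistance: float = 10.0e6
    capacitance: float = 5.0e-12

    def __post_init__(self) -> None:
        if self.resistance <= 0 or self.capacitance < 0:
            raise ValueError("probe resistance must be > 0 and capacitance >= 0")


#: Fixed wiring elements of the experimental circuit (generator lead,
#: return wires, termination): R1 = R2 = 3.5 mOhm, R3 = 7 mOhm, R4 = 650 Ohm,
#: L1 = L2 = 60 nH, L3 = 120 nH.
DEFAULT_FIXED_ELEMENTS = {
    "R1": 0.0035,
    "R2": 0.0035,
    "R3": 0.007,
    "R4": 650.0,
    "L1": 60.0e-9,
    "L2": 60.0e-9,
    "L3": 120.0e-9,
}


@dataclass(frozen=True)
class CircuitModel:
    """Lumped ladder network.

    ``section_resistances[i]`` and ``section_capacitances[i]`` describe the
    parallel-RC element between plate ``i`` and plate ``i+1`` (plates are
    numbered 0..n, with plate 0 the launch plate).  ``source_resistance`` and
    ``source_inductance`` lump the generator lead with the return wires
    (R1+R2+R3, L1+L2+L3): the probe references the ground-return wire, so the
    loop current through drive and return branches is identical and the
    branches combine in series.  ``termination_resistance`` connects the last
    plate to the ground return; a value of exactly 0 grounds that plate.
    """

    section_resistances: tuple[float, ...]
    section_capacitances: tuple[float, ...]
    source_resistance: float = 0.011
    source_inductance: float = 240.0e-9
    termination_resistance: float = 650.0
    probe_node: int = 5
    probe_load: ProbeLoad | None = field(default_factory=ProbeLoad)
    stray_section_capacitance: float = 0.0
    node_shunt_capacitance: float = 0.0
    topology: str = "series-ladder/lumped-return"

    def __post_init__(self) -> None:
        n = len(self.section_resistances)
        if n < 1 or len(self.section_capacitances) != n:
            raise ValueError("section R and C lists must be non-empty and equal length")
        if any(r <= 0 for r in self.section_resistances if not math.isinf(r)):
            raise ValueError("section resistances must be > 0")
        if any(c <= 0 for c in self.section_capacitances):
            raise ValueError("section capacitances must be > 0")
        if not 0 <= self.probe_node <= n:
            raise ValueError(f"probe_node must be in 0..{n}")
        if self.source_resistance < 0 or self.source_inductance < 0:
            raise ValueError("source branch R and L must be >= 0")
        if self.termination_resistance < 0:
            raise ValueError("termination_resistance must be >= 0")

    @property
    def n_sections(self) -> int:
        return len(self.section_resistances)


@dataclass(frozen=True)
class Trace:
    """Uniformly sampled voltage record at the probed plate."""

    times: np.ndarray
    voltages: np.ndarray
    dt: float
    n_averages: int = 1
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.voltages, dtype=float)
        if t.ndim != 1 or t.shape != v.shape:
            raise ValueError("times and voltages must be 1-D arrays of equal length")
        if t.size >= 2:
            steps = np.diff(t)
            if np.any(steps <= 0) or not np.allclose(steps, self.dt, rtol=1e-9, atol=0):
                raise ValueError("times must be a strictly increasing uniform grid with step dt")
        if not (np.all(np.isfinite(t)) and np.all(np.isfinite(v))):
            raise ValueError("trace values must be finite")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "voltages", v)


def build_axon_circuit(
    solution: SolutionState,
    geometry: ChannelGeometry | None = None,
    fixed: dict | None = None,
    probe_load: ProbeLoad | None = ProbeLoad(),
    probe_node: int = 5,
) -> CircuitModel:
    """Assemble the ladder network for a uniform solution in the channel.

    Every well receives the same (r, c) from
    :func:`rcaxon.electrolyte.compartment_impedance`; the fixed wiring
    elements default to the as-built values in :data:`DEFAULT_FIXED_ELEMENTS`.
    """
    geometry = geometry or ChannelGeometry()
    elements = dict(DEFAULT_FIXED_ELEMENTS)
    if fixed:
        elements.update(fixed)
    kappa = conductivity_from_concentration(solution)
    r, c = compartment_impedance(geometry, kappa)
    n = geometry.n_wells
    return CircuitModel(
        section_resistances=(r,) * n,
        section_capacitances=(c,) * n,
        source_resistance=elements["R1"] + elements["R2"] + elements["R3"],
        source_inductance=elements["L1"] + elements["L2"] + elements["L3"],
        termination_resistance=elements["R4"],
        probe_node=probe_node,
        probe_load=probe_load,
    )


def _stamp(mat: np.ndarray, a: int, b: int, value: float, m: int) -> None:
    """Stamp a two-terminal element between nodes a and b (b may be grounded)."""
    if a < m:
        mat[a, a] += value
    if b < m:
        mat[b, b] += value
    if a < m and b < m:
        mat[a, b] -= value
        mat[b, a] -= value


def _state_space(circuit: CircuitModel) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Build x' = A x + B u with output y = C x at the probed plate.

    States are the ungrounded plate voltages (plus the source-branch inductor
    current when the branch inductance is nonzero).  KCL at the plates gives
    ``M v' + G v = e0 * i_in`` with M the capacitance matrix and G the
    conductance matrix of the grounded network; M is positive definite as long
    as the capacitor graph ties every plate to the grounded reference, which
    the probe capacitance (or a grounded termination) guarantees.
    """
    n = circuit.n_sections
    grounded_last = circuit.termination_resistance == 0.0
    m = n if grounded_last else n + 1  # unknown plate nodes 0..m-1

    M = np.zeros((m, m))
    G = np.zeros((m, m))
    for i in range(n):
        r = circuit.section_resistances[i]
        c = circuit.section_capacitances[i] + circuit.stray_section_capacitance
        g = 0.0 if math.isinf(r) else 1.0 / r
        _stamp(G, i, i + 1, g, m)
        _stamp(M, i, i + 1, c, m)
    if circuit.node_shunt_capacitance > 0:
        for i in range(m):
            M[i, i] += circuit.node_shunt_capacitance
    if circuit.probe_load is not None:
        p = circuit.probe_node
        if p >= m:
            raise ValueError("probe_node coincides with the grounded termination plate")
        G[p, p] += 1.0 / circuit.probe_load.resistance
        M[p, p] += circuit.probe_load.capacitance
    if not grounded_last:
        G[n, n] += 1.0 / circuit.termination_resistance

    # Diagnose a floating capacitor network before inverting.
    try:
        M_inv = np.linalg.inv(M)
    except np.linalg.LinAlgError as exc:
        raise ValueError(
            "singular capacitance matrix: the capacitor network does not tie "
            "every plate to ground (add a probe load, node shunt capacitance "
            "or a grounded termination)"
        ) from exc

    e0 = np.zeros(m)
    e0[0] = 1.0

    Rs, Ls = circuit.source_resistance, circuit.source_inductance
    if Ls > 0:
        A = np.zeros((m + 1, m + 1))
        A[:m, :m] = -M_inv @ G
        A[:m, m] = M_inv @ e0
        A[m, 0] = -1.0 / Ls
        A[m, m] = -Rs / Ls
        B = np.zeros(m + 1)
        B[m] = 1.0 / Ls
    else:
        if Rs <= 0:
            raise ValueError("source branch must have positive resistance when inductance is 0")
        Gd = G.copy()
        Gd[0, 0] += 1.0 / Rs
        A = -M_inv @ Gd
        B = M_inv @ e0 / Rs

    C = np.zeros(A.shape[0])
    if circuit.probe_node >= m:
        raise ValueError("probe_node is the grounded termination plate; its voltage is identically 0")
    C[circuit.probe_node] = 1.0

    # Stability / conditioning diagnostic: all natural modes must decay.
    eigvals = np.linalg.eigvals(A)
    worst = eigvals[np.argmax(eigvals.real)]
    if worst.real > 0:
        tau = math.inf if worst.real == 0 else 1.0 / abs(worst.real)
        raise ValueError(
            f"unstable element set: growing mode with time constant {tau:.3e} s "
            f"(eigenvalue {worst:.3e})"
        )
    return A, B, C


def _check_commensurate(pulse: PulseSpec, dt: float) -> tuple[int, int]:
    """Samples per period and per high segment; both must be whole numbers."""
    n_period = pulse.period / dt
    n_high = pulse.high_duration / dt
    if abs(n_period - round(n_period)) > 1e-9 * n_period or round(n_high) < 1 or abs(
        n_high - round(n_high)
    ) > 1e-6 * max(n_high, 1.0):
        raise ValueError(
            "dt must divide both the pulse period and the high-segment duration "
            f"(period/dt = {n_period}, high/dt = {n_high})"
        )
    return int(round(n_period)), int(round(n_high))


def _periodic_initial_state(
    phi: np.ndarray, g: np.ndarray, pulse: PulseSpec, n_period: int, n_high: int
) -> np.ndarray:
    """Fixed point of the one-period affine map (steady periodic state).

    Stepping x -> phi x + g u over one period composes to
    x -> Phi_P x + d_P; the periodic orbit passes through
    x* = (I - Phi_P)^-1 d_P at the rising edge.
    """
    dim = phi.shape[0]
    # Affine accumulation: d after k steps from x=0.
    d = np.zeros(dim)
    # Segment-wise: d_high = (phi^n_high acting ...) computed by stepping once per
    # segment using precomputed powers keeps this O(log n) but plain stepping over
    # 800 samples of a ~12-state system is already negligible.
    for k in range(n_period):
        u = pulse.high_level if k < n_high else pulse.low_level
        d = phi @ d + g * u
    phi_period = np.linalg.matrix_power(phi, n_period)
    x_star = np.linalg.solve(np.eye(dim) - phi_period, d)
    return x_star


def simulate_transient(
    circuit: CircuitModel,
    pulse: PulseSpec | None = None,
    duration: float = 2.0e-6,
    dt: float = 2.5e-9,
    method: str = "expm",
    settle: bool = True,
    metadata: dict | None = None,
) -> Trace:
    """Probe-plate voltage trace under the pulse train.

    With ``method="expm"`` the LTI response is propagated exactly over each
    sample step with the matrix exponential (the drive is constant between
    samples because dt must divide both the period and the high-segment
    duration), and the initial state is the exact steady periodic state, so the
    reported window needs no settling transient.  ``method="ode"`` integrates
    the same state equations with an implicit stiff solver as an independent
    numerical path.

    The trace starts at the rising edge of a pulse (t = 0).
    """
    pulse = pulse or PulseSpec()
    if duration < pulse.period:
        raise ValueError("duration must cover at least one pulse period")
    A, B, C = _state_space(circuit)
    n_period, n_high = _check_commensurate(pulse, dt)
    n_samples = int(round(duration / dt))

    if method == "expm":
        phi = expm(A * dt)
        # g = A^-1 (phi - I) B without forming A^-1 explicitly.
        g = np.linalg.solve(A, (phi - np.eye(A.shape[0])) @ B)
        x = (
            _periodic_initial_state(phi, g, pulse, n_period, n_high)
            if settle
            else np.zeros(A.shape[0])
        )
        volts = np.empty(n_samples + 1)
        volts[0] = C @ x
        for k in range(n_samples):
            u = pulse.high_level if (k % n_period) < n_high else pulse.low_level
            x = phi @ x + g * u
            volts[k + 1] = C @ x
    elif method == "ode":
        from scipy.integrate import solve_ivp

        tau_min = 1.0 / np.abs(np.linalg.eigvals(A).real).max()
        if dt > tau_min / 10 and not settle:
            # dt only controls the output grid here, but warn-level strictness
            # is kept for parity with explicit-stepping expectations.
            pass

        def u_of(t: float) -> float:
            return pulse.high_level if (t % pulse.period) < pulse.high_duration else pulse.low_level

        def rhs(t: float, x: np.ndarray) -> np.ndarray:
            return A @ x + B * u_of(t)

        x0 = np.zeros(A.shape[0])
        if settle:
            phi = expm(A * dt)
            g = np.linalg.solve(A, (phi - np.eye(A.shape[0])) @ B)
            x0 = _periodic_initial_state(phi, g, pulse, n_period, n_high)
        t_eval = np.arange(n_samples + 1) * dt
        sol = solve_ivp(
            rhs,
            (0.0, n_samples * dt),
            x0,
            method="BDF",
            t_eval=t_eval,
            max_step=pulse.high_duration / 4,
            rtol=1e-9,
            atol=1e-12,
        )
        if not sol.success:
            raise RuntimeError(f"ODE integration failed: {sol.message}")
        volts = C @ sol.y
    else:
        raise ValueError(f"unknown method {method!r}")

    times = np.arange(n_samples + 1) * dt
    return Trace(times=times, voltages=volts, dt=dt, n_averages=1, metadata=metadata or {})


@dataclass(frozen=True)
class TraceFeatures:
    """Pulse-shape features of a trace.

    ``a`` is the maximum excursion above the baseline, ``b`` the magnitude of
    the maximum excursion below it, and ``ratio = a/b`` is the
    concentration-sensitive feature used by the quantification pipeline.  The
    baseline is the median of the final quarter of the record (late
    inter-pulse interval), i.e. amplitudes are measured relative to the
    settled probe voltage, not relative to 0 V.
    """

    a: float
    b: float
    ratio: float
    peak: float
    rise_time: float
    fall_time: float
    baseline: float
    degenerate: bool = False


def _edge_time(times: np.ndarray, volts: np.ndarray, lo: float, hi: float) -> float:
    """Time between the last crossing of lo and the first crossing of hi."""
    above = volts >= hi
    if not above.any():
        return math.nan
    i_hi = int(np.argmax(above))
    below = volts[:i_hi] <= lo
    if i_hi == 0 or not below.any():
        return math.nan
    i_lo = int(len(below) - 1 - np.argmax(below[::-1]))

    def cross(i: int, level: float) -> float:
        if volts[i + 1] == volts[i]:
            return times[i]
        f = (level - volts[i]) / (volts[i + 1] - volts[i])
        return times[i] + f * (times[i + 1] - times[i])

    return cross(i_hi - 1, hi) - cross(i_lo, lo)


def extract_features(trace: Trace, noise_floor: float = 1e-12) -> TraceFeatures:
    """Extract (a, b, a/b, peak, rise/fall times) from a trace.

    ``b`` smaller than ``noise_floor`` marks the result degenerate and the
    ratio is reported as ``inf`` instead of silently dividing by ~0.
    """
    v = trace.voltages
    t = trace.times
    if v.size < 8:
        raise ValueError("trace too short for feature extraction")
    tail = v[-max(2, v.size // 4):]
    baseline = float(np.median(tail))
    dev = v - baseline
    a = float(dev.max())
    b = float(-dev.min())
    degenerate = b < noise_floor
    ratio = math.inf if degenerate else a / b
    peak = float(v.max())

    i_peak = int(np.argmax(v))
    lo, hi = baseline + 0.1 * a, baseline + 0.9 * a
    rise = _edge_time(t[: i_peak + 1], v[: i_peak + 1], lo, hi)
    # Falling edge: mirror the search on the reversed post-peak segment.
    fall = _edge_time(
        t[i_peak:] - t[i_peak],
        v[i_peak:][::-1],
        lo,
        hi,
    )
    return TraceFeatures(
        a=a,
        b=b,
        ratio=ratio,
        peak=peak,
        rise_time=rise,
        fall_time=fall,
        baseline=baseline,
        degenerate=degenerate,
    )
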