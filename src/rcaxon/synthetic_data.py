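"""Synthetic experiments: noisy averaged oscilloscope traces with ground truth.

Emulates a complete measurement session on the artificial axon: at each
sampling time the vesicle kinetics set the external K2SO4 concentration, the
circuit model turns it into a probe-plate transient, and the instrument model
adds per-acquisition Gaussian noise, 8-bit quantisation and 16-acquisition
averaging.  A vesicle-free blank and a Triton-lysis endpoint (full release)
are generated alongside, together with a ground-truth table, so every stage of
the quantification pipeline can be exercised and scored without measured data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .circuit import CircuitModel, ProbeLoad, PulseSpec, Trace, build_axon_circuit, simulate_transient
from .electrolyte import ChannelGeometry, SolutionState
from .vesicle_kinetics import (
    DEFAULT_KINETICS,
    DEFAULT_PREP,
    KineticsParams,
    VesiclePrep,
    efflux_fraction,
    external_concentration,
)

__all__ = [
    "NoiseModel",
    "NOISE_FREE",
    "ExperimentSchedule",
    "SyntheticExperiment",
    "default_schedule",
    "generate_trace",
    "simulate_experiment",
]


@dataclass(frozen=True)
class NoiseModel:
    """Oscilloscope acquisition model.

    Each acquisition is the clean transient plus white Gaussian noise of SD
    ``additive_sigma``, digitised to ``quantization_bits`` over a full-scale
    span of ``full_scale`` volts centred on the clean-trace median (as a scope
    is offset to keep the waveform on screen); the displayed record averages
    ``n_averages`` acquisitions, reducing the noise SD by sqrt(n).
    Quantisation happens per acquisition, before averaging, so acquisition
    noise dithers the quantiser exactly as in the instrument.
    ``quantization_bits=None`` disables quantisation.  All randomness flows
    from ``seed``.
    """

    additive_sigma: float = 5.0e-3
    quantization_bits: int | None = 8
    full_scale: float = 2.0
    n_averages: int = 16
    seed: int = 0

    def __post_init__(self) -> None:
        if self.additive_sigma < 0:
            raise ValueError("additive_sigma must be >= 0")
        if self.n_averages < 1:
            raise ValueError("n_averages must be >= 1")
        if self.quantization_bits is not None and self.quantization_bits < 2:
            raise ValueError("quantization_bits must be >= 2 (or None)")
        if self.full_scale <= 0:
            raise ValueError("full_scale must be > 0")


#: Ideal instrument: no noise, no quantisation, single acquisition.
NOISE_FREE = NoiseModel(additive_sigma=0.0, quantization_bits=None, n_averages=1, seed=0)


def generate_trace(
    circuit: CircuitModel,
    pulse: PulseSpec | None = None,
    noise: NoiseModel | None = None,
    duration: float = 2.0e-6,
    dt: float = 2.5e-9,
    rng: np.random.Generator | None = None,
    metadata: dict | None = None,
) -> Trace:
    """Noisy averaged oscilloscope record of the probe-plate transient.

    Deterministic given the noise model's seed; pass ``rng`` to draw from an
    external generator instead (used by :func:`simulate_experiment` so one
    recorded seed covers a whole session).
    """
    pulse = pulse or PulseSpec()
    noise = noise or NoiseModel()
    clean = simulate_transient(circuit, pulse, duration=duration, dt=dt)
    v = clean.voltages
    if noise.additive_sigma == 0.0 and noise.quantization_bits is None:
        return Trace(clean.times, v, dt, n_averages=noise.n_averages, metadata=metadata or {})

    if rng is None:
        rng = np.random.default_rng(noise.seed)
    acq = v[None, :] + rng.normal(0.0, noise.additive_sigma, size=(noise.n_averages, v.size))
    if noise.quantization_bits is not None:
        offset = float(np.median(v))
        q = noise.full_scale / (2**noise.quantization_bits)
        half = noise.full_scale / 2.0
        acq = np.clip(acq - offset, -half, half - q)
        acq = np.round(acq / q) * q + offset
    averaged = acq.mean(axis=0)
    return Trace(clean.times, averaged, dt, n_averages=noise.n_averages, metadata=metadata or {})


@dataclass(frozen=True)
class ExperimentSchedule:
    """Protocol of one synthetic experiment.

    Sampling times are minutes from the start of the session and must lie in
    [0, 38] (the longest protocol: 7 min valinomycin preincubation followed by
    30 min of exposure, sampled to 38 min).  The Triton endpoint, when
    included, is recorded after the last sampling time.
    """

    condition: str
    prep: VesiclePrep = DEFAULT_PREP
    kinetics: KineticsParams | None = None
    sampling_times: tuple[float, ...] = (0.0, 5.0, 10.0, 15.0, 20.0, 25.0, 30.0)
    include_triton_endpoint: bool = True
    dt: float = 2.5e-9
    duration: float = 2.0e-6
    label: str = ""

    def __post_init__(self) -> None:
        t = np.asarray(self.sampling_times, dtype=float)
        if t.size == 0 or np.any(np.diff(t) <= 0):
            raise ValueError("sampling_times must be non-empty and strictly increasing")
        if t[0] < 0 or t[-1] > 38.0:
            raise ValueError("sampling_times must lie within [0, 38] min")

    def resolved_kinetics(self) -> KineticsParams:
        return self.kinetics if self.kinetics is not None else DEFAULT_KINETICS[self.condition]


def default_schedule(condition: str, **overrides) -> ExperimentSchedule:
    """Shipped sampling schedules.

    ``sham``, ``emf`` and ``val`` use a 5-min grid to 30 min; ``val_emf``
    follows the combined protocol (valinomycin at 0, field on at 7 min,
    sampled through 38 min; the stated time points 7, 8, 9, 15, 20, 23, 28 and
    38 min appear on the grid).
    """
    if condition == "val_emf":
        times = (0.0, 7.0, 8.0, 9.0, 15.0, 20.0, 23.0, 28.0, 38.0)
    else:
        times = (0.0, 5.0, 10.0, 15.0, 20.0, 25.0, 30.0)
    return ExperimentSchedule(condition=condition, sampling_times=times, **overrides)


@dataclass(frozen=True)
class SyntheticExperiment:
    """Traces plus ground truth for one simulated session."""

    traces: tuple[Trace, ...]
    blank: Trace
    triton: Trace | None
    ground_truth: pd.DataFrame
    schedule: ExperimentSchedule
    noise: NoiseModel
    geometry: ChannelGeometry
    background: SolutionState


def simulate_experiment(
    schedule: ExperimentSchedule,
    geometry: ChannelGeometry | None = None,
    background: SolutionState | None = None,
    noise: NoiseModel | None = None,
    pulse: PulseSpec | None = None,
    probe_load: ProbeLoad | None = ProbeLoad(),
) -> SyntheticExperiment:
    """Generate a full synthetic session.

    For each sampling time t the released fraction f(t) sets the external
    K2SO4 concentration, a circuit is built for that solution and a noisy
    trace recorded.  A blank (vesicle-free background solution) and, when
    scheduled, a Triton endpoint at the full-release concentration are
    appended.  The ground-truth table columns are ``t_min``, ``fraction``,
    ``c_out`` (mol/L) and ``percent``.
    """
    geometry = geometry or ChannelGeometry()
    background = background or SolutionState(0.0)
    noise = noise or NoiseModel()
    pulse = pulse or PulseSpec()
    kinetics = schedule.resolved_kinetics()
    rng = np.random.default_rng(noise.seed)

    def trace_at(c_k2so4: float, meta: dict) -> Trace:
        solution = replace(background, c_k2so4=c_k2so4)
        circuit = build_axon_circuit(solution, geometry, probe_load=probe_load)
        return generate_trace(
            circuit,
            pulse,
            noise,
            duration=schedule.duration,
            dt=schedule.dt,
            rng=rng,
            metadata=meta,
        )

    blank = trace_at(0.0, {"condition": schedule.condition, "kind": "blank"})
    rows, traces = [], []
    for t_min in schedule.sampling_times:
        frac = efflux_fraction(kinetics, t_min)
        c_out = external_concentration(schedule.prep, frac)
        traces.append(
            trace_at(
                c_out,
                {
                    "condition": schedule.condition,
                    "kind": "sample",
                    "t_min": float(t_min),
                    "c_true": float(c_out),
                },
            )
        )
        rows.append(
            {
                "t_min": float(t_min),
                "fraction": float(frac),
                "c_out": float(c_out),
                "percent": 100.0 * float(frac),
            }
        )

    triton = None
    if schedule.include_triton_endpoint:
        c_full = schedule.prep.full_release_k2so4
        triton = trace_at(
            c_full,
            {"condition": schedule.condition, "kind": "triton", "c_true": float(c_full)},
        )

    return SyntheticExperiment(
        traces=tuple(traces),
        blank=blank,
        triton=triton,
        ground_truth=pd.DataFrame(rows),
        schedule=schedule,
        noise=noise,
        geometry=geometry,
        background=background,
    )
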