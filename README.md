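# rcaxon

Modelling and quantification toolkit for an **artificial axon**: a
Plexiglas channel partitioned by copper plates into ten electrolyte-filled
wells, forming a lumped-element RC transmission line that mimics passive
signal propagation along a nerve fibre. Lipid vesicles loaded with K2SO4 sit
in the channel; millimetre-wave exposure (53.37 GHz) and/or the K+-ionophore
valinomycin release potassium into the external medium, raising its
conductivity and thereby changing the shape of the electrical pulse recorded
at a probed plate. The package is aimed at membrane-biophysics and
bioelectromagnetics groups who want to simulate such experiments, size their
dosimetry, and run the complete concentration-recovery pipeline on synthetic
or recorded traces.

## What it computes

- **Electrolyte → circuit** (`rcaxon.electrolyte`, `rcaxon.circuit`):
  bulk conductivity from limiting molar ionic conductivities,
  κ = c·(2λ°(K⁺) + λ°(SO4²⁻)) + κ_bg; per-well lumped elements
  R = d/(κA), C = ε0·εr·A/d; and the exact transient of the resulting ladder
  network under a rectangular pulse train (2 µs period, +3 V for 0.5 % of the
  period, −3 V otherwise), propagated segment-by-segment with the matrix
  exponential of the state matrix — no time-stepping error at the 2.5 ns
  sample points.
- **Dosimetry** (`rcaxon.em_dosimetry`): for ε_c = ε′ − jε″ the effective
  conductivity σ = 2πf·ε0·ε″, in-medium wavelength λ0/Re√ε_c, field
  penetration depth δ = λ0/(2π|Im√ε_c|), the SAR depth profile
  SAR(z) = ½(σ/ρ)|E0|²e^(−2z/δ), and the adiabatic temperature bound
  SAR·t/c_p.
- **Efflux kinetics** (`rcaxon.vesicle_kinetics`): saturating first-order
  release f(t) = p·(1 − e^(−k·(t−lag))) per condition (sham, field,
  valinomycin, valinomycin+field), the external K2SO4 concentration
  c(t) = f(t)·c_full (with c_full = [K⁺]_internal/2 by dissociation
  stoichiometry), Nernst potentials, and deterministic least-squares
  parameter recovery.
- **Quantification** (`rcaxon.quantification`): the a/b amplitude-ratio
  feature, blank correction a = (a/b)_sample − (a/b)_blank, monotone
  calibration-curve construction and inversion, Triton X-100 normalisation to
  percent efflux, and Welch t-tests between condition means.
- **Synthetic data** (`rcaxon.synthetic_data`): complete simulated sessions —
  noisy, 8-bit-quantised, 16-acquisition-averaged oscilloscope traces whose
  concentration evolves according to the kinetics, plus blank and
  Triton-lysis endpoint traces and a ground-truth table.

## Worked example

```python
from rcaxon import SolutionState, build_axon_circuit, simulate_transient
from rcaxon.quantification import DEFAULT_CALIBRATION_GRID, build_calibration, quantify_experiment
from rcaxon.synthetic_data import NOISE_FREE, default_schedule, simulate_experiment

def trace_source(c):
    return simulate_transient(build_axon_circuit(SolutionState(c)))

calibration = build_calibration(DEFAULT_CALIBRATION_GRID, trace_source)
experiment = simulate_experiment(default_schedule("val_emf"), noise=NOISE_FREE)
result = quantify_experiment(experiment.traces, experiment.triton, calibration)
print(result.table[["t_min", "percent"]].to_string(index=False))
```

```
 t_min    percent
   0.0   0.000000
   7.0  14.171664
   8.0  15.299832
   9.0  16.282699
  15.0  19.934489
  20.0  21.327751
  23.0  21.806378
  28.0  22.261302
  38.0  22.605489
```

Each row is the percent of the encapsulated potassium recovered at that time
by the full pipeline (trace → a/b ratio → blank correction → calibration
inversion → Triton normalisation). On noise-free traces the recovered values
track the kinetic ground truth to well within half a percentage point —
e.g. 21.81 % at 23 min for the valinomycin+field condition, whose kinetics
plateau at 22.7 %.

The `examples/` directory holds narrative scripts, one per capability:
`circuit_response.py`, `dosimetry_report.py`, `efflux_kinetics.py`,
`full_experiment_pipeline.py`. Each builds a small input, runs the method and
prints annotated numbers.

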