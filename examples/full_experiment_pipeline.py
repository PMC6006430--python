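"""End-to-end synthetic experiment: generate, calibrate, quantify, compare.

Simulates noisy oscilloscope sessions (5 mV noise per acquisition, 8-bit
digitisation, 16-acquisition averaging) for the EMF-only and
valinomycin+EMF conditions, builds a calibration curve from noise-free
simulator traces at known concentrations, and recovers percent potassium
efflux per time point via the a/b-ratio pipeline.  Replicate sessions are
then compared with a two-tailed Welch t-test, mirroring the statistical
treatment of the measured data.
"""

import numpy as np

from rcaxon import SolutionState, build_axon_circuit, simulate_transient
from rcaxon.quantification import (
    DEFAULT_CALIBRATION_GRID,
    build_calibration,
    compare_conditions,
    quantify_experiment,
)
from rcaxon.synthetic_data import NoiseModel, default_schedule, simulate_experiment

cache = {}


def trace_source(c):
    if c not in cache:
        cache[c] = simulate_transient(build_axon_circuit(SolutionState(c)))
    return cache[c]


calibration = build_calibration(DEFAULT_CALIBRATION_GRID, trace_source)
print(f"calibration: {len(calibration.concentrations)} knots, blank a/b = {calibration.blank_ratio:.3f}")

groups = {}
for condition, n_reps in (("emf", 6), ("val_emf", 6)):
    at_20min = []
    for rep in range(n_reps):
        exp = simulate_experiment(
            default_schedule(condition), noise=NoiseModel(seed=100 * rep + 7)
        )
        res = quantify_experiment(exp.traces, exp.triton, calibration, clamp=True)
        at_20min.append(float(res.table.loc[res.table.t_min == 20.0, "percent"].iloc[0]))
        if rep == 0:
            truth = exp.ground_truth
            print(f"\n{condition}, replicate 0 (truth vs recovered, %):")
            merged = res.table.merge(truth, on="t_min", suffixes=("_rec", "_true"))
            for _, r in merged.iterrows():
                print(f"  t = {r.t_min:4.0f} min   {r.percent_true:6.2f}   {r.percent_rec:6.2f}")
    groups[condition] = at_20min

cmp = compare_conditions(groups["emf"], groups["val_emf"])
print(
    f"\nefflux at 20 min: emf {cmp.mean_a:.1f} +/- {cmp.sd_a:.1f} % vs "
    f"val_emf {cmp.mean_b:.1f} +/- {cmp.sd_b:.1f} % "
    f"(Welch t = {cmp.t_statistic:.2f}, p = {cmp.p_two_tailed:.4f})"
)
print(
    "The combined condition releases significantly more potassium than the "
    "field alone,\nas in the measured experiments."
)
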