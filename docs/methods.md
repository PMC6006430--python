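# Methods

This note records the models implemented in `rcaxon`, their assumptions, the
defaults that matter, and the choices made where the design was genuinely
open.

## Electrolyte model

Bulk conductivity of the K2SO4 solution is the infinite-dilution form
κ = c·(2λ°(K⁺) + λ°(SO4²⁻)) + κ_bg with λ°(K⁺) = 73.5 and
λ°(SO4²⁻) = 160 S·cm²/mol (25 °C limiting values). No Kohlrausch √c
correction is applied: over the 0–20 mM working range the infinite-dilution
estimate already matches the measured endpoint (6140 µS/cm at 20 mM) within
2 %, and a concentration-dependent Λ would add a parameter the data cannot
constrain. The glycine/sucrose background is carried as a single measured
constant, κ_bg = 0.33 µS/cm; it is not derivable from the stated composition
(5 µM glycine contributes far less) and is treated as an instrument-level
input. Activity coefficients and the temperature dependence of Λ are out of
scope.

Each well between adjacent plates is a parallel-plate element:
R = d/(κA), C = ε0εr·A/d with d = 1 cm spacing and A = 1 cm × 3 mm submerged
area, giving capacitances of ~2 pF and R from ~500 Ω (20 mM) to ~10 MΩ
(salt-free). εr = 80 is the static water value, appropriate for the MHz-scale
pulse spectrum; the 53.37 GHz permittivity lives in the dosimetry module
because water is strongly dispersive between those bands.

The back-calculation σ = L/(RA) defaults to a 9 cm conduction path (nine
well-to-well gaps between launch and termination plates). The printed
end-to-end resistance (92 kΩ), the geometry and the quoted 0.03 S/m are
mutually consistent only to ~20 %, and the effective path length is not
stated; 9 cm reproduces 0.03 S/m at one significant figure.

## Circuit model and transient solver

The device is a ladder: drive branch → launch plate → ten series (r‖c)
sections → termination plate → 650 Ω to the ground return. The generator lead
(R1, L1) and the two return wires (R2/L2, R3/L3) carry the same loop current
— the probe references the ground-return wire and no other branch reaches the
reference — so they are lumped into one series branch (R = R1+R2+R3 = 11 mΩ,
L = L1+L2+L3 = 240 nH). This lumping is exact for the implemented topology,
which also makes the unresolvable question of whether the return elements sit
before or after the termination plate immaterial. The single largest
modelling choice is the probe: a configurable (R_probe ‖ C_probe) shunt from
the probed plate (default: plate 5) to the ground return.

**Probe default.** 10 MΩ ‖ 5 pF. The resistance is the standard passive
high-impedance probe value. The tip capacitance was chosen inside the
realistic 2–15 pF range as the value for which the a/b amplitude ratio is a
strictly increasing function of electrolyte concentration over the whole
0–20 mM operating range; at ≥10 pF the ratio dips between 0 and ~0.04 mM
before rising, which would make the calibration non-invertible exactly where
the efflux experiments operate. Plate-to-plate stray capacitance and
node-to-ground shunts default to zero but are configurable; they reshape the
low-concentration waveform (e.g. double peaks) without being required for any
quantitative result. Absolute trace amplitudes are topology-dependent and are
treated as order-of-magnitude quantities only; monotonicity and ratio
features are the load-bearing outputs.

**Solver.** The network is linear and time-invariant and the drive is
piecewise constant, so the state (plate voltages plus the branch inductor
current) is propagated exactly: x(t+dt) = e^{A·dt}x(t) + A⁻¹(e^{A·dt}−I)B·u.
dt must divide both the pulse period and the high-segment duration (true for
the native 2.5 ns / 2 µs / 10 ns grid), making the drive constant between
samples; the reported window then has no discretisation error at the sample
points, and refining dt only adds samples. The initial state is the exact
steady periodic orbit, obtained by solving the fixed point of the one-period
affine map — no settling periods are simulated. The capacitance matrix is the
grounded Laplacian of the capacitor graph and must be non-singular (every
plate tied to ground through capacitors); a floating network or a growing
mode raises a diagnostic naming the offending configuration. An implicit
(BDF) ODE integration of the same equations is available as an independent
numerical path and agrees with the exact propagation to ~1e-6 of the signal.

**Features.** The baseline is the median of the final quarter of the record
(the late inter-pulse interval), i.e. amplitudes are measured relative to the
settled probe voltage, not to 0 V — the drive's −3 V DC divider level would
otherwise dominate both a and b. a is the maximum excursion above baseline, b
the magnitude of the maximum excursion below it, rise/fall times are 10–90 %
crossings around the main peak. When b falls below a configurable noise floor
the ratio is flagged degenerate and reported as inf rather than silently
divided; this happens at high conductivity, where the inter-pulse undershoot
vanishes.

## Dosimetry

A 1-D normal-incidence plane-wave model of the lossy half-space replaces
full-wave simulation of horn, Plexiglas and wells. From ε_c = 11.76 − j24 at
53.37 GHz: σ = 2πf·ε0·ε″ = 71.3 S/m, δ = λ0/(2π|Im√ε_c|) = 0.327 mm (field
e-folding convention; power decays twice as fast), λ_med = λ0/Re√ε_c =
1.281 mm. The value quoted elsewhere for the in-medium wavelength (1.39 mm)
is not reproduced by any standard convention we identified (1.28 mm is what
the formula gives); the implementation reports the standard-formula value.
SAR(z) = ½(σ/ρ)|E0|²e^(−2z/δ) integrates exactly to the transmitted Poynting
flux — the energy-conservation identity the tests verify. The surface field
requires an antenna gain (not printed for the horn); absolute SAR is
therefore an order-of-magnitude quantity here, while σ, δ and the profile
shape are exact for the stated permittivity. The lumped thermal model
dT/dt = SAR/c_p − loss·T gives the adiabatic bound SAR·t/c_p at zero loss
(0.47 K for 1.1 W/kg over 30 min), an upper bound on any measured rise.

## Efflux kinetics

The condition time courses are described by the minimal model matching both
the observed rise and the plateau: f(t) = p·(1 − e^(−k·max(0, t−lag))). No
mechanistic flux equation is attempted — the field effect is phenomenological
(condition-specific k and p), SO4²⁻ is treated as impermeant with implicit
H⁺ counter-transport, and membrane-potential feedback on the flux, vesicle
size distributions and per-vesicle stochasticity are out of scope.

Shipped defaults are calibrated so the curves pass through the measured
condition means, using the closed-form and Brent-solved anchor inversions
exposed as `rate_from_anchor` and `params_from_two_anchors`:

| condition | anchors (t min, f) | k (1/min) | plateau |
|---|---|---|---|
| sham | no detectable leak | 0 | 0 |
| emf | (25, 0.102); plateau set to 0.105 | 0.14221 | 0.105 |
| val | (15, 0.137), (25, 0.148) | 0.15940 | 0.15080 |
| val_emf | (23, 0.218), (38, 0.226) | 0.13978 | 0.22712 |

For the field-only arm a single anchor is stated with saturation reported
soon after, so the plateau is set slightly above the 25-min value (0.105) and
k solved from the anchor. The combined condition is fitted as a single curve
with lag 0 even though the field switches on at 7 min: the two stated
anchors at 23 and 38 min reflect the combined history, and a two-phase model
would be unidentifiable from them. Vesicle stoichiometry: a preparation with
0.48 mM suspension-equivalent internal K⁺ releases at most 0.24 mM K2SO4
(complete dissociation, 2 K⁺ per formula unit). The quoted valinomycin
"final concentration of 15 mM" is inconsistent with the stated volumes
(5 µL × 10 mg/mL in ~3 mL ≈ 15 µM) and is read as a units typo; the value is
not used by the model.

`fit_kinetics` is deterministic multi-start least squares (fixed grid of rate
initialisations, trust-region refinement); a numerically zero series returns
plateau 0 with the rate flagged unidentifiable instead of a spurious fit.

## Quantification

a = (a/b)_sample − (a/b)_blank is compared against a calibration curve built
from traces at known concentrations. The curve is monotone piecewise-linear
**in concentration**, with an implicit (0, 0) knot (the blank defines zero
signal at zero analyte): the simulated response is close to linear in c over
the 0–0.5 mM working range, and interpolating in log10(c) instead (kept as a
selectable variant) mis-inverts mid-interval points of a linear response by
several percent at factor-of-two knot spacing. The default knot grid is 11
log-spaced concentrations from 0.005 to 0.5 mM — dense enough that
interpolation error contributes ≪0.1 absolute percentage point to recovered
efflux. Non-monotone calibration points are rejected with diagnostics, and
inversion outside the calibrated range raises (or clamps, on request) rather
than extrapolating into the flat low-signal regime. Percent efflux is
100·c(t)/c(Triton), both concentrations estimated through the same calibration
so that interpolation bias largely cancels. Condition comparison uses the
Welch (unequal-variance) two-tailed t-test by default, with pooled-variance
selectable; groups with zero variance fall back to an exact-equality report.

## Synthetic instrument

Each acquisition is the exact transient plus white Gaussian noise (default
5 mV SD — plausible for a 500 MHz 8-bit instrument at these vertical scales),
digitised at 8 bits over a ±1 V span centred on the clean-trace median (the
scope is assumed offset to keep the waveform on screen; the simulated
excursions stay within ±0.85 V of the median over the calibrated range), and
16 such acquisitions are averaged. Quantisation is applied per acquisition,
before averaging, as the instrument does; the acquisition noise then dithers
the quantiser and the average recovers sub-LSB resolution, which is why noisy
pipeline runs show no systematic quantisation bias. All randomness flows from
a single recorded seed; reruns are bit-identical. Drift, mains pickup,
trigger jitter and the instrument transfer function are not emulated — real
traces will violate the whiteness and stationarity assumptions, so passing
the noisy-recovery tests bounds estimator behaviour under idealised noise
only, not under instrument systematics.

The default schedules sample on a 5-min grid to 30 min (sham, field-only,
valinomycin-only) and on a reconstructed grid containing the stated 7, 8, 9,
15, 20, 23, 28 and 38 min points for the combined protocol; the exact
experimental sampling times are only partially stated, and the grids are
labelled as reconstructions.

## Problem sizes

Each trace is one 2 µs period at 2.5 ns (801 samples) of a ~13-state system;
a full synthetic session is 9–11 traces and a calibration 12, so the complete
pipeline runs in seconds and the test suite (including 400-replicate noise
statistics and 20-replicate recovery checks) in well under a minute.

## Known limitations

- Absolute trace voltages depend on unrecovered topology details (probe
  placement, strays, end effects); only trends and ratio features are
  quantitative.
- The dosimetry is 1-D: no standing waves in the Plexiglas, no well-edge SAR
  enhancement, no spatial maps.
- Kinetics are phenomenological; the parameters summarise, not explain, the
  condition differences.
- The p-values of condition comparisons on synthetic data reflect the shipped
  noise model, not measurement reality.
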