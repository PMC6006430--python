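"""Amplitude-ratio quantification of external K2SO4 concentration.

The measurement pipeline mirrors the experimental protocol:

1. On each oscilloscope trace compute the ratio a/b between the maximum and
   minimum amplitude deviations (:func:`rcaxon.circuit.extract_features`).
2. Subtract the same ratio measured on an analyte-free blank:
   ``a = (a/b)_sample - (a/b)_blank``.
3. Convert ``a`` to concentration through a monotone calibration curve built
   from traces at known K2SO4 concentrations.
4. Normalise to percent efflux against the concentration measured after
   Triton X-100 lysis, which releases all encapsulated potassium and defines
   100 %.
5. Compare condition means with a two-tailed two-sample t-test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .circuit import Trace, extract_features

__all__ = [
    "CalibrationError",
    "CalibrationCurve",
    "EffluxResult",
    "ConditionComparison",
    "DEFAULT_CALIBRATION_GRID",
    "blank_corrected_a",
    "build_calibration",
    "invert_calibration",
    "percent_efflux",
    "compare_conditions",
    "quantify_experiment",
]

#: Default calibration concentrations, mol/L: log-spaced knots spanning the
#: working range of the low-concentration regime (5e-3 to 0.5 mM), dense
#: enough that piecewise-linear interpolation error is negligible against the
#: percent-efflux scale.
DEFAULT_CALIBRATION_GRID = tuple(
    float(c) * 1e-3
    for c in (0.005, 0.01, 0.02, 0.03, 0.05, 0.08, 0.12, 0.18, 0.25, 0.35, 0.5)
)


class CalibrationError(ValueError):
    """Raised when a calibration is non-monotone or an inversion is out of range."""


def blank_corrected_a(sample_ratio: float, blank_ratio: float) -> float:
    """Blank-corrected amplitude feature ``a = (a/b)_sample - (a/b)_blank``."""
    if not (math.isfinite(sample_ratio) and math.isfinite(blank_ratio)):
        raise ValueError("sample and blank ratios must be finite")
    if sample_ratio <= 0 or blank_ratio <= 0:
        raise ValueError("amplitude ratios must be positive")
    return sample_ratio - blank_ratio


@dataclass(frozen=True)
class CalibrationCurve:
    """Monotone map between K2SO4 concentration and blank-corrected a.

    Knots must have strictly increasing concentrations and strictly increasing
    ``a`` values.  Interpolation is monotone piecewise-linear, by default
    directly in concentration (the response is close to linear in c over the
    working range, and an implicit (0, 0) knot anchors the toe — the blank
    defines a = 0 at c = 0 by construction).  ``log_space=True`` interpolates
    in log10(concentration) above the first positive knot instead, for
    responses closer to linear in log c.
    """

    concentrations: np.ndarray
    a_values: np.ndarray
    blank_ratio: float = math.nan
    log_space: bool = False
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        c = np.asarray(self.concentrations, dtype=float)
        a = np.asarray(self.a_values, dtype=float)
        if c.ndim != 1 or c.size < 2 or c.shape != a.shape:
            raise CalibrationError("need >= 2 calibration points of matching shape")
        if np.any(np.diff(c) <= 0) or c[0] < 0:
            raise CalibrationError("concentrations must be non-negative and strictly increasing")
        if np.any(np.diff(a) <= 0):
            bad = int(np.argmin(np.diff(a)))
            raise CalibrationError(
                "calibration rejected: a-values not strictly increasing between "
                f"c = {c[bad]:.3e} and c = {c[bad + 1]:.3e} mol/L "
                f"(a = {a[bad]:.6g} -> {a[bad + 1]:.6g})"
            )
        object.__setattr__(self, "concentrations", c)
        object.__setattr__(self, "a_values", a)

    @property
    def _knots(self) -> tuple[np.ndarray, np.ndarray]:
        """(c, a) including an implicit (0, 0) knot when absent."""
        c, a = self.concentrations, self.a_values
        if c[0] > 0:
            c = np.concatenate(([0.0], c))
            a = np.concatenate(([0.0], a))
        return c, a

    def a_of(self, concentration: float) -> float:
        """Interpolated blank-corrected a at a concentration inside the range."""
        c, a = self._knots
        if not c[0] <= concentration <= c[-1]:
            raise CalibrationError(
                f"concentration {concentration:.3e} outside calibrated range "
                f"[{c[0]:.3e}, {c[-1]:.3e}] mol/L"
            )
        if not self.log_space:
            return float(np.interp(concentration, c, a))
        # Toe segment: linear in c between the zero knot and the first
        # positive knot; log-linear above it.
        i_pos = int(np.argmax(c > 0))
        if concentration <= c[i_pos]:
            return float(np.interp(concentration, c[: i_pos + 1], a[: i_pos + 1]))
        return float(np.interp(np.log10(concentration), np.log10(c[i_pos:]), a[i_pos:]))

    def invert(self, a_value: float, clamp: bool = False) -> float:
        """Concentration whose calibrated a equals ``a_value`` (unique, monotone).

        Out-of-range values raise :class:`CalibrationError` unless ``clamp``
        is set, in which case the nearest range endpoint is returned.
        """
        c, a = self._knots
        if not a[0] <= a_value <= a[-1]:
            if clamp:
                return float(c[0] if a_value < a[0] else c[-1])
            raise CalibrationError(
                f"a = {a_value:.6g} outside calibrated range [{a[0]:.6g}, {a[-1]:.6g}]"
            )
        if not self.log_space:
            return float(np.interp(a_value, a, c))
        i_pos = int(np.argmax(c > 0))
        if a_value <= a[i_pos]:
            return float(np.interp(a_value, a[: i_pos + 1], c[: i_pos + 1]))
        logc = np.interp(a_value, a[i_pos:], np.log10(c[i_pos:]))
        return float(10.0**logc)


def build_calibration(
    concentrations: Sequence[float],
    trace_source: Callable[[float], Trace],
    blank_concentration: float = 0.0,
    log_space: bool = False,
) -> CalibrationCurve:
    """Build a calibration curve from traces at known concentrations.

    ``trace_source`` maps a K2SO4 concentration (mol/L) to a
    :class:`~rcaxon.circuit.Trace` — typically a closure over the circuit
    simulator, or a reader of recorded trace files.  The blank ratio is
    measured at ``blank_concentration`` and subtracted from every point.
    """
    conc = np.asarray(sorted(concentrations), dtype=float)
    if conc.size < 2:
        raise CalibrationError("need at least 2 calibration concentrations")
    blank = extract_features(trace_source(blank_concentration))
    if blank.degenerate:
        raise CalibrationError("blank trace has a degenerate a/b ratio")
    a_vals = []
    for c in conc:
        feats = extract_features(trace_source(float(c)))
        if feats.degenerate:
            raise CalibrationError(f"degenerate a/b ratio at calibration point c = {c:.3e} mol/L")
        a_vals.append(blank_corrected_a(feats.ratio, blank.ratio))
    return CalibrationCurve(
        concentrations=conc,
        a_values=np.asarray(a_vals),
        blank_ratio=blank.ratio,
        log_space=log_space,
        diagnostics={"blank_concentration": blank_concentration},
    )


def invert_calibration(curve: CalibrationCurve, a_value: float, clamp: bool = False) -> float:
    """Functional wrapper around :meth:`CalibrationCurve.invert`."""
    return curve.invert(a_value, clamp=clamp)


def percent_efflux(c_t: float, c_triton: float) -> float:
    """Percent efflux: 100 * c(t) / c(Triton), the full-lysis normalisation."""
    if c_triton <= 0:
        raise ValueError("c_triton must be > 0")
    return 100.0 * c_t / c_triton


@dataclass(frozen=True)
class ConditionComparison:
    """Two-sample comparison of percent-efflux groups."""

    t_statistic: float
    p_two_tailed: float
    mean_a: float
    sd_a: float
    mean_b: float
    sd_b: float
    n_a: int
    n_b: int
    welch: bool
    degenerate: bool = False


def compare_conditions(
    group_a: Sequence[float],
    group_b: Sequence[float],
    welch: bool = True,
) -> ConditionComparison:
    """Two-tailed two-sample t-test between condition means (Welch by default).

    Groups with (numerically) zero pooled variance cannot support a t-test;
    the result is flagged degenerate and reports exact equality (p = 1 when
    the means coincide, p = 0 otherwise) instead of dividing by zero.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs n >= 2")
    stats_kw = dict(equal_var=not welch)
    if a.std(ddof=1) == 0.0 and b.std(ddof=1) == 0.0:
        equal = a.mean() == b.mean()
        return ConditionComparison(
            t_statistic=0.0 if equal else math.inf,
            p_two_tailed=1.0 if equal else 0.0,
            mean_a=a.mean(), sd_a=0.0, mean_b=b.mean(), sd_b=0.0,
            n_a=a.size, n_b=b.size, welch=welch, degenerate=True,
        )
    t, p = stats.ttest_ind(a, b, **stats_kw)
    return ConditionComparison(
        t_statistic=float(t),
        p_two_tailed=float(p),
        mean_a=float(a.mean()),
        sd_a=float(a.std(ddof=1)),
        mean_b=float(b.mean()),
        sd_b=float(b.std(ddof=1)),
        n_a=a.size,
        n_b=b.size,
        welch=welch,
    )


@dataclass(frozen=True)
class EffluxResult:
    """Per-timepoint quantified efflux for one experiment.

    ``table`` columns: t_min, ratio, a_value, c_estimate (mol/L), percent.
    """

    table: pd.DataFrame
    triton_concentration: float
    condition: str = ""
    replicate_id: int | None = None

    def __post_init__(self) -> None:
        if self.triton_concentration <= 0:
            raise ValueError("triton_concentration must be > 0")


def quantify_experiment(
    traces: Sequence[Trace],
    triton_trace: Trace,
    calibration: CalibrationCurve,
    blank_trace: Trace | None = None,
    clamp: bool = False,
    condition: str = "",
    replicate_id: int | None = None,
) -> EffluxResult:
    """Run the full quantification pipeline on a sequence of sample traces.

    Each trace must carry ``t_min`` in its metadata.  The blank ratio defaults
    to the one stored in the calibration; pass ``blank_trace`` to re-measure
    it (e.g. when quantifying with a calibration built on another session).
    """
    if blank_trace is not None:
        blank_ratio = extract_features(blank_trace).ratio
    else:
        blank_ratio = calibration.blank_ratio
    if not math.isfinite(blank_ratio):
        raise ValueError("no blank ratio available: pass blank_trace or a calibration that stores one")

    def concentration_of(trace: Trace) -> tuple[float, float]:
        feats = extract_features(trace)
        a = blank_corrected_a(feats.ratio, blank_ratio)
        # Sample ratios can fall marginally below the blank's; a tiny negative
        # a is indistinguishable from zero analyte.
        a = max(a, 0.0)
        return feats.ratio, calibration.invert(a, clamp=clamp)

    triton_ratio, c_triton = concentration_of(triton_trace)
    rows = []
    for trace in traces:
        t_min = trace.metadata.get("t_min")
        if t_min is None:
            raise ValueError("each sample trace needs 't_min' metadata")
        ratio, c_est = concentration_of(trace)
        rows.append(
            {
                "t_min": float(t_min),
                "ratio": ratio,
                "a_value": ratio - blank_ratio,
                "c_estimate": c_est,
                "percent": percent_efflux(c_est, c_triton),
            }
        )
    table = pd.DataFrame(rows).sort_values("t_min", ignore_index=True)
    return EffluxResult(
        table=table,
        triton_concentration=c_triton,
        condition=condition,
        replicate_id=replicate_id,
    )
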