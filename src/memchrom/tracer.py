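"""Residence-time-distribution analysis of tracer pulse experiments.

Non-binding tracer pulses (dextran / pullulan standards) probe the fluid
dynamics of a membrane module.  From the first two moments of the outlet
curve one obtains the total voidage

    eps = (t_mean - t_instrument) * Vdot / Vm

and, from the normalised variance sigma^2 / t_mean^2, the axial dispersion
coefficient of a zone of characteristic length ``l`` and velocity ``v``
under either closed-vessel

    sigma^2/t^2 = 2 x - 2 x^2 (1 - exp(-1/x)),      x = Dax / (v l)

or open-vessel Danckwerts assumptions

    sigma^2/t^2 = 2 x + 8 x^2.

The Bodenstein number Bo = v l / Dax classifies the flow regime: below a
critical value of 5 dispersion dominates and the zone behaves like a stirred
tank, above it like a plug-flow pipe.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "TracerCurve",
    "MomentResult",
    "moments",
    "voidage",
    "closed_vessel_variance",
    "open_vessel_variance",
    "dax_from_variance_closed",
    "dax_from_variance_open",
    "bodenstein",
    "classify_regime",
    "BODENSTEIN_CRITICAL",
]

#: transition between stirred-tank and plug-flow behaviour.
BODENSTEIN_CRITICAL = 5.0


@dataclass(frozen=True)
class TracerCurve:
    """A detector trace from a tracer pulse experiment."""

    time: np.ndarray  # min
    signal: np.ndarray  # arbitrary detector units
    volumetric_flow: float  # mL/min
    tracer_molecular_weight: float | None = None  # Da

    def __post_init__(self) -> None:
        object.__setattr__(self, "time", np.asarray(self.time, dtype=float))
        object.__setattr__(self, "signal", np.asarray(self.signal, dtype=float))
        if self.time.ndim != 1 or self.time.shape != self.signal.shape:
            raise ValueError("time and signal must be 1-D arrays of equal length")
        if len(self.time) >= 2 and np.any(np.diff(self.time) <= 0):
            raise ValueError("tracer time grid must be strictly increasing")


@dataclass(frozen=True)
class MomentResult:
    mean_residence_time: float  # min
    variance: float  # min^2

    @property
    def normalized_variance(self) -> float:
        return self.variance / self.mean_residence_time**2


def moments(curve: TracerCurve, baseline_fraction: float = 0.05) -> MomentResult:
    """First and second central moment of a tracer curve.

    The signal is baseline-corrected by subtracting the smaller of the
    medians of the first and last ``baseline_fraction`` of points (robust
    when the peak reaches into either window), clipped at zero, then
    integrated by trapezoidal quadrature on the given grid.
    """
    t, s = curve.time, curve.signal
    if len(t) == 1:
        # degenerate Dirac-like spike
        return MomentResult(mean_residence_time=float(t[0]), variance=0.0)
    n_base = max(1, int(len(s) * baseline_fraction))
    baseline = min(np.median(s[:n_base]), np.median(s[-n_base:]))
    s = np.clip(s - baseline, 0.0, None)
    area = np.trapezoid(s, t)
    if area <= 0:
        raise ValueError("tracer curve has zero signal area after baseline correction")
    t_mean = float(np.trapezoid(t * s, t) / area)
    var = float(np.trapezoid((t - t_mean) ** 2 * s, t) / area)
    return MomentResult(mean_residence_time=t_mean, variance=var)


def voidage(t_mean: float, t_instrument: float, flow: float, vm: float) -> float:
    """Total voidage from mean residence time (dead time subtracted)."""
    if flow <= 0 or vm <= 0:
        raise ValueError("flow and module volume must be > 0")
    if t_mean < t_instrument:
        raise ValueError(
            f"mean residence time ({t_mean}) below instrument dead time "
            f"({t_instrument}); check blank-run assignment"
        )
    return (t_mean - t_instrument) * flow / vm


def closed_vessel_variance(x: float) -> float:
    """Normalised variance of a closed vessel at dispersion number x = Dax/(v l)."""
    x = np.asarray(x, dtype=float)
    return 2.0 * x - 2.0 * x**2 * (1.0 - np.exp(-1.0 / np.maximum(x, 1e-300)))


def open_vessel_variance(x: float) -> float:
    """Normalised variance of an open vessel at dispersion number x = Dax/(v l)."""
    x = np.asarray(x, dtype=float)
    return 2.0 * x + 8.0 * x**2


def dax_from_variance_closed(norm_variance: float, v: float, l: float) -> float:
    """Invert the closed-vessel variance relation for Dax (units of v*l).

    The relation is monotone in x = Dax/(v l) and saturates at 1 (perfectly
    mixed vessel), so only ``0 < sigma^2/t^2 < 1`` is attainable.  The root is
    bracketed on a log grid to tolerate dispersion numbers spanning many
    orders of magnitude.
    """
    if v <= 0 or l <= 0:
        raise ValueError("velocity and length must be > 0")
    if not 0 < norm_variance < 1:
        raise ValueError(
            f"closed-vessel normalised variance must lie in (0, 1), got {norm_variance}"
        )

    def f(log_x: float) -> float:
        return closed_vessel_variance(10.0**log_x) - norm_variance

    lo, hi = -12.0, 6.0
    if f(lo) > 0 or f(hi) < 0:
        raise ValueError(
            f"normalised variance {norm_variance} outside the attainable closed-vessel "
            "range for the bracket Dax/(v*l) in (1e-12, 1e6)"
        )
    log_x = brentq(f, lo, hi, xtol=1e-14, rtol=1e-15)
    return float(10.0**log_x * v * l)


def dax_from_variance_open(norm_variance: float, v: float, l: float) -> float:
    """Invert the open-vessel variance relation for Dax (closed form).

    Positive root of 8 x^2 + 2 x - y = 0: x = (-2 + sqrt(4 + 32 y)) / 16.
    """
    if v <= 0 or l <= 0:
        raise ValueError("velocity and length must be > 0")
    if norm_variance <= 0:
        raise ValueError(f"normalised variance must be > 0, got {norm_variance}")
    x = (-2.0 + np.sqrt(4.0 + 32.0 * norm_variance)) / 16.0
    return float(x * v * l)


def bodenstein(u: float, l: float, dax: float) -> float:
    """Bodenstein number Bo = u l / Dax."""
    if u <= 0 or l <= 0 or dax <= 0:
        raise ValueError("u, l and Dax must all be > 0")
    return u * l / dax


def classify_regime(bo: float, critical: float = BODENSTEIN_CRITICAL) -> str:
    """Classify a Bodenstein number as ``"plug_flow"`` or ``"stirred_tank"``."""
    return "plug_flow" if bo >= critical else "stirred_tank"
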