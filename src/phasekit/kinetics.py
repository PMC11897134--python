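"""Kinetic and thermodynamic readouts of condensate droplets.

Fitters for:

* FRAP recovery — single-exponential (reaction-dominant) model giving the
  recovery time constant tau, half-time tau ln 2, and the mobile fraction.
* Droplet coalescence — the relaxation time of two fusing droplets scales
  with their mean radius, tau = l * (eta/gamma); the slope through the
  origin is the inverse capillary velocity eta/gamma (s/um).  Only the
  ratio of viscosity to interfacial tension is identifiable.
* Reaction kinetics — ordinary least-squares slope of a (normalized)
  fluorescence trace gives an apparent rate constant; the ratio of two such
  constants is the fold enhancement by the condensed phase.
* Pseudo-first-order conversion — f(t) = 1 - exp(-k t), calibrated in
  closed form from one (t, fraction) point or by least squares on several.
* Turbidity — per-cycle amplitudes and reversibility ratios of phase
  cycling, and thresholding of a (pH, salt) turbidity grid into a boolean
  phase-separation map.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
from scipy import optimize, stats

from .errors import ArgumentError, DataError, FitError


@dataclass
class FrapTrace:
    """Normalized FRAP time series (pre-bleach mean = 1)."""

    times: np.ndarray  # s
    intensity: np.ndarray
    bleach_index: int  # index of the first post-bleach sample

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.times.shape != self.intensity.shape:
            raise ArgumentError("times and intensity must have equal length")
        if not (np.diff(self.times) > 0).all():
            raise DataError("times must be strictly increasing")
        if (self.intensity < 0).any():
            raise DataError("intensity must be non-negative")
        if not 0 <= self.bleach_index < len(self.times):
            raise ArgumentError("bleach_index out of range")


@dataclass
class FrapFit:
    """Fitted exponential recovery parameters."""

    i0: float  # post-bleach intercept
    plateau: float
    tau: float  # s
    t_half: float  # s, = tau ln 2
    mobile_fraction: float  # (plateau - i0) / (1 - i0), clipped to [0, 1]
    rss: float


@dataclass
class CoalescenceEvent:
    """One droplet fusion: relaxation time tau (s) at mean radius l (um)."""

    tau: float
    l: float


@dataclass
class CapillaryFit:
    """Inverse capillary velocity eta/gamma from coalescence events."""

    eta_over_gamma: float  # s / um
    stderr: float | None
    n_events: int
    # free-intercept diagnostic (not used for eta/gamma)
    slope_with_intercept: float | None = None
    intercept: float | None = None


@dataclass
class KineticTrace:
    """A reaction-progress time series."""

    times: np.ndarray
    signal: np.ndarray
    model_hint: str = "linear"  # linear | first_order

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.times.shape != self.signal.shape:
            raise ArgumentError("times and signal must have equal length")
        if not (np.diff(self.times) > 0).all():
            raise DataError("times must be strictly increasing")


@dataclass
class RateFit:
    """Apparent rate constant from an OLS fit of signal vs time."""

    k: float
    stderr: float
    window: tuple[float, float]
    r_squared: float
    raw_slope: float | None = None  # unnormalized slope, when normalization used


@dataclass
class FirstOrderFit:
    """Pseudo-first-order model f(t) = 1 - exp(-k t)."""

    k: float

    def predict(self, t):
        return 1.0 - np.exp(-self.k * np.asarray(t, dtype=float))


@dataclass
class CycleMetrics:
    """Per-cycle turbidity amplitudes and reversibility ratios."""

    amplitudes: list[float]
    reversibility: list[float]  # amplitude_i / amplitude_1


@dataclass
class TurbidityCurve:
    """Absorbance (600 nm) time series over phase cycles."""

    times: np.ndarray
    absorbance: np.ndarray
    cycle_boundaries: list[tuple[int, int]] | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        if self.times.shape != self.absorbance.shape:
            raise ArgumentError("times and absorbance must have equal length")
        if (self.absorbance < 0).any():
            raise DataError("absorbance must be non-negative")


@dataclass
class PhaseDiagram:
    """Turbidity over a rectangular (pH, NaCl) grid, plus a boolean phase map."""

    ph_values: np.ndarray  # (n,)
    nacl_values: np.ndarray  # (m,) mM
    turbidity: np.ndarray  # (n, m)
    phase_separated: np.ndarray | None = None  # (n, m) bool
    threshold: float | None = None

    def __post_init__(self) -> None:
        self.ph_values = np.asarray(self.ph_values, dtype=float)
        self.nacl_values = np.asarray(self.nacl_values, dtype=float)
        self.turbidity = np.asarray(self.turbidity, dtype=float)
        if self.turbidity.shape != (len(self.ph_values), len(self.nacl_values)):
            raise ArgumentError("turbidity grid must be (n_ph, n_nacl)")


class FoldEnhancement(NamedTuple):
    fold: float
    fold_rounded: int


def fit_frap(trace: FrapTrace) -> FrapFit:
    """Nonlinear least squares of the single-exponential recovery model.

    I(t) = plateau - (plateau - i0) exp(-(t - t_bleach)/tau) on the
    post-bleach samples.  Initialization: i0 = first post-bleach value,
    plateau = last value, tau = time to close half the gap.
    """
    t = trace.times[trace.bleach_index:]
    y = trace.intensity[trace.bleach_index:]
    if len(t) < 5:
        raise ArgumentError("need at least 5 post-bleach samples")
    tb = t[0]
    i0_init = float(y[0])
    plateau_init = float(y[-1])
    half = (i0_init + plateau_init) / 2.0
    crossing = np.nonzero(y >= half)[0] if plateau_init >= i0_init else np.nonzero(y <= half)[0]
    tau_init = float(t[crossing[0]] - tb) if len(crossing) and t[crossing[0]] > tb else float((t[-1] - tb) / 3.0)
    tau_init = max(tau_init, 1e-6)
    init = (i0_init, plateau_init, tau_init)

    def model(tt, i0, plateau, tau):
        return plateau - (plateau - i0) * np.exp(-(tt - tb) / tau)

    try:
        popt, _ = optimize.curve_fit(
            model, t, y, p0=init,
            bounds=([-np.inf, -np.inf, 1e-12], [np.inf, np.inf, np.inf]),
            xtol=1e-8, ftol=1e-8, maxfev=20000,
        )
    except (RuntimeError, optimize.OptimizeWarning) as exc:
        rss = float(((model(t, *init) - y) ** 2).sum())
        raise FitError(f"FRAP fit failed to converge: {exc}", init=init, rss=rss) from exc
    i0, plateau, tau = (float(v) for v in popt)
    rss = float(((model(t, *popt) - y) ** 2).sum())
    denom = 1.0 - i0
    mobile = float(np.clip((plateau - i0) / denom, 0.0, 1.0)) if abs(denom) > 1e-12 else 1.0
    return FrapFit(
        i0=i0, plateau=plateau, tau=tau,
        t_half=tau * math.log(2.0), mobile_fraction=mobile, rss=rss,
    )


def fit_coalescence(events: list[CoalescenceEvent]) -> CapillaryFit:
    """Least-squares slope of tau on l through the origin.

    eta/gamma = sum(tau l) / sum(l^2); the standard error comes from the
    residuals (undefined for a single event).  A free-intercept fit is
    reported as a diagnostic only.
    """
    if len(events) < 1:
        raise ArgumentError("need at least one coalescence event")
    tau = np.array([e.tau for e in events], dtype=float)
    l = np.array([e.l for e in events], dtype=float)
    if (tau <= 0).any() or (l <= 0).any():
        raise DataError("all relaxation times and radii must be positive")
    slope = float((tau * l).sum() / (l * l).sum())
    n = len(events)
    if n > 1:
        resid = tau - slope * l
        stderr = float(np.sqrt((resid**2).sum() / (n - 1) / (l * l).sum()))
        lr = stats.linregress(l, tau)
        diag_slope, diag_int = float(lr.slope), float(lr.intercept)
    else:
        stderr = None
        diag_slope = diag_int = None
    return CapillaryFit(
        eta_over_gamma=slope, stderr=stderr, n_events=n,
        slope_with_intercept=diag_slope, intercept=diag_int,
    )


def fit_linear_rate(
    trace: KineticTrace,
    window: tuple[float, float] | None = None,
    normalize_to: float | None = None,
) -> RateFit:
    """Apparent rate constant: OLS slope of signal vs time in a window.

    With ``normalize_to`` the signal is divided by that plateau value first
    (making the slope a per-time rate of a dimensionless progress variable)
    and the raw slope is reported alongside.
    """
    t, y = trace.times, trace.signal
    if window is None:
        window = (float(t[0]), float(t[-1]))
    lo, hi = window
    if not hi > lo:
        raise ArgumentError("degenerate window: requires hi > lo")
    if lo < t[0] or hi > t[-1]:
        raise ArgumentError("window outside trace support")
    sel = (t >= lo) & (t <= hi)
    if sel.sum() < 3:
        raise ArgumentError("need at least 3 samples in the window")
    ts, ys = t[sel], y[sel]
    raw = None
    if normalize_to is not None:
        if normalize_to <= 0:
            raise ArgumentError("normalize_to must be positive")
        lr_raw = stats.linregress(ts, ys)
        raw = float(lr_raw.slope)
        ys = ys / normalize_to
    if np.ptp(ys) == 0:
        # constant signal: zero slope, zero error
        return RateFit(k=0.0, stderr=0.0, window=(lo, hi), r_squared=0.0, raw_slope=raw)
    lr = stats.linregress(ts, ys)
    return RateFit(
        k=float(lr.slope), stderr=float(lr.stderr),
        window=(lo, hi), r_squared=float(lr.rvalue**2), raw_slope=raw,
    )


def rate_enhancement(k_with: float, k_without: float) -> FoldEnhancement:
    """Fold increase in apparent rate due to the condensed phase."""
    if k_without <= 0:
        raise ArgumentError("k_without must be positive")
    if k_with < 0:
        raise ArgumentError("k_with must be non-negative")
    fold = k_with / k_without
    return FoldEnhancement(fold=fold, fold_rounded=int(round(fold)))


def fit_first_order_fraction(points: list[tuple[float, float]]) -> FirstOrderFit:
    """Calibrate f(t) = 1 - exp(-k t) from (time, converted-fraction) points.

    One point: closed form k = -ln(1 - f)/t.  Several: least squares of
    -ln(1 - f) on t through the origin.
    """
    if len(points) < 1:
        raise ArgumentError("need at least one (time, fraction) point")
    t = np.array([p[0] for p in points], dtype=float)
    f = np.array([p[1] for p in points], dtype=float)
    if (f < 0).any() or (f >= 1).any():
        raise ArgumentError("fractions must be in [0, 1)")
    if (t <= 0).any():
        raise ArgumentError("times must be positive")
    y = -np.log1p(-f)
    if len(t) == 1:
        k = float(y[0] / t[0])
    else:
        k = float((t * y).sum() / (t * t).sum())
    return FirstOrderFit(k=k)


def turbidity_cycle_metrics(
    curve: TurbidityCurve,
    cycle_boundaries: list[tuple[int, int]] | None = None,
) -> CycleMetrics:
    """Amplitude and reversibility per phase cycle.

    Each cycle spans one high (condensed) and one low (dissolved) plateau;
    plateau levels use the middle 50% of samples in each half-cycle to
    avoid transition edges.  Reversibility is each amplitude relative to
    the first cycle's.
    """
    bounds = cycle_boundaries if cycle_boundaries is not None else curve.cycle_boundaries
    if not bounds:
        raise ArgumentError("cycle boundaries required")
    n = len(curve.absorbance)
    prev_end = 0
    amplitudes = []
    for start, end in bounds:
        if not (0 <= start < end <= n):
            raise ArgumentError(f"cycle boundary ({start}, {end}) outside curve")
        if start < prev_end:
            raise ArgumentError("cycle boundaries must be ordered and non-overlapping")
        prev_end = end
        seg = curve.absorbance[start:end]
        half = len(seg) // 2
        if half < 2:
            raise ArgumentError("cycle too short to estimate plateaus")
        a = _plateau(seg[:half])
        b = _plateau(seg[half:])
        amplitudes.append(abs(a - b))
    first = amplitudes[0]
    if first == 0:
        raise DataError("first cycle has zero amplitude; reversibility undefined")
    return CycleMetrics(
        amplitudes=amplitudes,
        reversibility=[a / first for a in amplitudes],
    )


def _plateau(segment: np.ndarray) -> float:
    m = len(segment)
    lo, hi = m // 4, m - m // 4
    return float(segment[lo:hi].mean())


def build_phase_map(
    grid: PhaseDiagram,
    blank_mean: float,
    blank_sd: float,
    k_sd: float = 3.0,
) -> PhaseDiagram:
    """Threshold a turbidity grid into a boolean phase-separation map.

    A cell is phase-separated iff its turbidity strictly exceeds
    blank_mean + k_sd * blank_sd (a blank-well detection limit).
    """
    if blank_sd < 0:
        raise ArgumentError("blank_sd must be >= 0")
    turb = grid.turbidity
    if np.isnan(turb).any():
        where = np.argwhere(np.isnan(turb))
        coords = [
            (float(grid.ph_values[i]), float(grid.nacl_values[j])) for i, j in where
        ]
        raise DataError(f"missing turbidity cells at (pH, NaCl): {coords}")
    threshold = blank_mean + k_sd * blank_sd
    return PhaseDiagram(
        ph_values=grid.ph_values,
        nacl_values=grid.nacl_values,
        turbidity=turb,
        phase_separated=turb > threshold,
        threshold=threshold,
    )
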