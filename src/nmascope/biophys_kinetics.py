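"""Single-exponential kinetic fits and melt-curve Tm extraction.

Polymerization/depolymerization fluorescence traces are fitted with a
single exponential; the apparent half-time is ln2/k from the fitted rate.
Thermal-shift melt curves yield a melting temperature from the peak of the
first derivative of the (smoothed) melting function.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np
from scipy.optimize import curve_fit
from scipy.signal import peak_prominences, savgol_filter

__all__ = [
    "KineticTrace",
    "ExponentialFit",
    "MeltCurve",
    "MeltResult",
    "FitError",
    "FitRejectedError",
    "fit_half_time",
    "fit_rate",
    "threshold_half_time",
    "melt_tm",
]

LN2 = float(np.log(2.0))

#: residual RMS above this fraction of |amplitude| flags a poor
#: single-exponential description (e.g. multi-phase kinetics)
HIGH_RESIDUAL_FRACTION = 0.05


class FitError(RuntimeError):
    """The nonlinear fit failed to converge."""


class FitRejectedError(ValueError):
    """The fitted parameters are physically inadmissible (e.g. k <= 0,
    zero amplitude)."""


@dataclass
class KineticTrace:
    """Fluorescence vs time. ``mode`` is ``polymerization`` (rising) or
    ``depolymerization`` (falling)."""

    time: np.ndarray
    signal: np.ndarray
    mode: str = "polymerization"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.mode not in ("polymerization", "depolymerization"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if len(self.time) < 8:
            raise ValueError("kinetic trace needs at least 8 points")
        if len(self.time) != len(self.signal):
            raise ValueError("time and signal lengths differ")
        if not (np.all(np.isfinite(self.time)) and np.all(np.isfinite(self.signal))):
            raise ValueError("trace contains non-finite values")
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing")

    @property
    def rising(self) -> bool:
        return self.mode == "polymerization"


@dataclass
class ExponentialFit:
    """Parameters of F(t) = F0 + A*(1 - exp(-k t)) (rising) or
    F0 + A*exp(-k t) (falling)."""

    amplitude: float
    rate: float
    offset: float
    residual_rms: float
    mode: str
    window: Tuple[float, float]
    high_residual: bool = False

    def __post_init__(self):
        if self.rate <= 0:
            raise FitRejectedError(f"rate must be positive, got {self.rate}")

    @property
    def half_time(self) -> float:
        return LN2 / self.rate

    def to_dict(self) -> dict:
        return {
            "amplitude": self.amplitude,
            "rate": self.rate,
            "offset": self.offset,
            "half_time": self.half_time,
            "residual_rms": self.residual_rms,
            "mode": self.mode,
            "window_start": self.window[0],
            "window_end": self.window[1],
            "high_residual": self.high_residual,
        }


def _rising(t, f0, a, k):
    return f0 + a * (1.0 - np.exp(-k * t))


def _falling(t, f0, a, k):
    return f0 + a * np.exp(-k * t)


def _initial_guesses(t: np.ndarray, y: np.ndarray, rising: bool):
    """F0 from the first-quartile signal, A from the signal range, k from a
    log-linear regression of the normalized approach to plateau."""
    span = float(y.max() - y.min())
    if rising:
        f0 = float(np.quantile(y, 0.25))
        plateau = float(y.max())
        resid = plateau - y
    else:
        f0 = float(np.quantile(y, 0.25))
        plateau = float(y.min())
        resid = y - plateau
    a = span if span > 0 else 1.0
    # log-linear slope on the decaying residual; clip to keep logs finite
    pos = resid > 0.01 * max(span, np.finfo(float).tiny)
    if pos.sum() >= 3:
        slope = np.polyfit(t[pos], np.log(resid[pos]), 1)[0]
        k0 = -slope if slope < 0 else 1.0 / max(t[-1] - t[0], 1e-12)
    else:
        k0 = 1.0 / max(t[-1] - t[0], 1e-12)
    return f0, a, max(k0, 1e-9)


def fit_half_time(
    trace: KineticTrace,
    window: Optional[Tuple[float, float]] = None,
) -> ExponentialFit:
    """Nonlinear least-squares single-exponential fit of a kinetic trace.

    ``window`` optionally restricts the fit to a time interval (e.g. to
    skip a nucleation lag); the default is the full trace. Raises
    :class:`FitRejectedError` for zero-amplitude traces or non-positive
    fitted rates and :class:`FitError` on non-convergence.
    """
    t_all, y_all = trace.time, trace.signal
    if window is None:
        window = (float(t_all[0]), float(t_all[-1]))
    mask = (t_all >= window[0]) & (t_all <= window[1])
    if mask.sum() < 4:
        raise ValueError("fit window contains fewer than 4 points")
    t = t_all[mask] - t_all[mask][0]
    y = y_all[mask]

    span = float(y.max() - y.min())
    scale = max(abs(y).max(), 1.0)
    if span <= 1e-12 * scale:
        raise FitRejectedError("constant signal: zero amplitude")

    model = _rising if trace.rising else _falling
    p0 = _initial_guesses(t, y, trace.rising)
    try:
        popt, _ = curve_fit(
            model,
            t,
            y,
            p0=p0,
            bounds=([-np.inf, -np.inf, 1e-12], [np.inf, np.inf, np.inf]),
            maxfev=20000,
        )
    except (RuntimeError, ValueError) as exc:
        raise FitError(f"single-exponential fit failed: {exc}") from exc
    f0, a, k = (float(x) for x in popt)
    if k <= 0:
        raise FitRejectedError(f"fitted rate {k} <= 0")
    if abs(a) <= 1e-9 * scale:
        raise FitRejectedError("fitted amplitude is zero")
    resid = y - model(t, *popt)
    rms = float(np.sqrt(np.mean(resid**2)))
    return ExponentialFit(
        amplitude=a,
        rate=k,
        offset=f0,
        residual_rms=rms,
        mode=trace.mode,
        window=window,
        high_residual=rms > HIGH_RESIDUAL_FRACTION * abs(a),
    )


def fit_rate(trace: KineticTrace, **kwargs) -> float:
    """Fitted exponential rate k (s^-1); see :func:`fit_half_time`."""
    return fit_half_time(trace, **kwargs).rate


def threshold_half_time(trace: KineticTrace) -> float:
    """Non-parametric half-time: time at which the signal crosses the
    midpoint between its initial and plateau levels (linear interpolation).
    Provided as a sensitivity check against the parametric route."""
    t, y = trace.time, trace.signal
    start, end = y[0], y[-1]
    if abs(end - start) <= 1e-12 * max(abs(y).max(), 1.0):
        raise FitRejectedError("constant signal: half-time undefined")
    mid = (start + end) / 2.0
    crossing = (y - mid) * (start - mid) <= 0
    idx = int(np.argmax(crossing))
    if idx == 0:
        return float(t[0])
    t0, t1 = t[idx - 1], t[idx]
    y0, y1 = y[idx - 1], y[idx]
    if y1 == y0:
        return float(t0) - float(t[0])
    return float(t0 + (mid - y0) * (t1 - t0) / (y1 - y0) - t[0])


@dataclass
class MeltCurve:
    """Fluorescence vs temperature on a monotone grid."""

    temperature: np.ndarray
    signal: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.temperature = np.asarray(self.temperature, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if len(self.temperature) < 10:
            raise ValueError("melt curve needs at least 10 points")
        if len(self.temperature) != len(self.signal):
            raise ValueError("temperature and signal lengths differ")
        if np.any(np.diff(self.temperature) <= 0):
            raise ValueError("temperature grid must be strictly increasing")
        if not np.all(np.isfinite(self.signal)):
            raise ValueError("melt curve contains non-finite values")


@dataclass
class MeltResult:
    tm: float
    derivative: np.ndarray = field(repr=False)
    temperature: np.ndarray = field(repr=False)
    prominence: float = 0.0
    reliable: bool = True
    note: str = ""

    def to_dict(self) -> dict:
        return {
            "tm": self.tm,
            "prominence": self.prominence,
            "reliable": self.reliable,
            "note": self.note,
        }


def melt_tm(
    curve: MeltCurve,
    smooth_window: int = 5,
    smooth_order: int = 2,
) -> MeltResult:
    """Tm from the peak of the first derivative of the melting function.

    The signal is smoothed with a centered moving polynomial
    (Savitzky-Golay) window before differentiation on the temperature
    grid. Ties are broken toward the lower temperature. A derivative
    maximum at the grid boundary yields a result flagged unreliable.
    """
    temp, y = curve.temperature, curve.signal
    if smooth_window > 1:
        w = min(smooth_window, len(y) if len(y) % 2 else len(y) - 1)
        if w > smooth_order:
            y = savgol_filter(y, w, smooth_order)
    deriv = np.gradient(y, temp)
    # ties (within float jitter) break toward the lower temperature
    dmax = deriv.max()
    tol = 1e-9 * max(abs(dmax), 1.0)
    idx = int(np.flatnonzero(deriv >= dmax - tol)[0])
    tm = float(temp[idx])
    boundary = idx == 0 or idx == len(temp) - 1
    prom = 0.0
    if not boundary:
        prom = float(peak_prominences(deriv, [idx])[0][0])
    else:
        warnings.warn(
            "derivative maximum at grid boundary; Tm unreliable", stacklevel=2
        )
    return MeltResult(
        tm=tm,
        derivative=deriv,
        temperature=temp,
        prominence=prom,
        reliable=not boundary,
        note="" if not boundary else "derivative peak at grid boundary",
    )
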