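"""Derived quantities of Kv11.1 voltage-clamp experiments.

Implements the measurement side of the pipeline: mono- and bi-exponential
relaxation fits, peak-tail extraction, the activation Boltzmann curve, the
fully-activated I-V with its linear conductance fit, the rectification
factor R = I / (G * n * (V - E_rev)) with its inactivation Boltzmann, the
inactivation-onset time-constant table, the deactivation component tables
and the steady-state I-V.

All fits are nonlinear least squares via :func:`scipy.optimize.curve_fit`
with log-linearized initial guesses.  Fit failures are flagged on the
result objects (or as NaN rows in tables), never silently swallowed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .protocols import TraceSet

__all__ = [
    "DegenerateFitError",
    "UnidentifiableError",
    "ExpFitResult",
    "BoltzmannFitResult",
    "FullyActivatedIV",
    "RectificationResult",
    "fit_monoexp",
    "fit_biexp",
    "measure_peak_tail",
    "tail_amplitude_hook_fit",
    "peak_tail_table",
    "activation_tau_table",
    "activation_curve",
    "fully_activated_iv",
    "rectification_curve",
    "inactivation_onset_taus",
    "deactivation_tables",
    "steady_state_iv",
]

MAXFEV = 10_000
_REL_TOL = 1e-8


class DegenerateFitError(ValueError):
    """Raised when the data cannot constrain the requested fit (e.g. flat)."""


class UnidentifiableError(ValueError):
    """Raised when the data do not span the transition being fitted."""


@dataclass(frozen=True)
class ExpFitResult:
    """Result of a mono- or bi-exponential fit I(t) = sum A_i exp(-t/tau_i) + C."""

    amplitudes: Tuple[float, ...]   # uA, ordered with taus
    taus: Tuple[float, ...]         # ms, ascending
    offset: float                   # uA
    window: Tuple[float, float]     # ms, on the segment's local time base
    residual_norm: float
    converged: bool
    flags: Tuple[str, ...] = ()

    @property
    def tau(self) -> float:
        return self.taus[0]

    @property
    def tau_fast(self) -> float:
        return self.taus[0]

    @property
    def tau_slow(self) -> float:
        return self.taus[-1]

    @property
    def weight_fast(self) -> float:
        """|A_fast| / (|A_fast| + |A_slow|) for bi-exponential fits."""
        if len(self.amplitudes) < 2:
            return 1.0
        a = np.abs(self.amplitudes)
        return float(a[0] / a.sum())


@dataclass(frozen=True)
class BoltzmannFitResult:
    v_half: float        # mV
    k: float             # mV
    amplitude: float     # normalization constant
    residual_norm: float
    increasing: bool     # True for activation-type curves

    def __call__(self, v):
        v = np.asarray(v, dtype=float)
        sign = -1.0 if self.increasing else 1.0
        return self.amplitude / (1.0 + np.exp(sign * (v - self.v_half) / self.k))


@dataclass(frozen=True)
class FullyActivatedIV:
    voltages: np.ndarray     # mV
    tail_peaks: np.ndarray   # uA, signed
    g: float                 # uS
    e_rev: float             # mV (zero crossing of the linear fit)
    fit_window: Tuple[float, float]  # mV


@dataclass(frozen=True)
class RectificationResult:
    voltages: np.ndarray          # mV, after exclusions
    r: np.ndarray                 # dimensionless
    excluded_voltages: np.ndarray
    boltzmann: BoltzmannFitResult


def _window_slice(time: np.ndarray, window: Tuple[float, float]) -> np.ndarray:
    t0, t1 = window
    return (time >= t0 - 1e-9) & (time <= t1 + 1e-9)


def _tau_guess(t: np.ndarray, y: np.ndarray, c: float, a: float) -> float:
    """Log-linearized slope of |y - c| where the decay is well resolved."""
    resid = (y - c) / a if a != 0 else np.zeros_like(y)
    ok = resid > 0.05
    if ok.sum() < 3:
        return max(t[-1] - t[0], 1.0) / 3.0
    slope = np.polyfit(t[ok], np.log(resid[ok]), 1)[0]
    if slope >= 0:
        return max(t[-1] - t[0], 1.0)
    return float(np.clip(-1.0 / slope, 1e-3, 100.0 * (t[-1] - t[0])))


def fit_monoexp(time: np.ndarray, current: np.ndarray,
                window: Optional[Tuple[float, float]] = None) -> ExpFitResult:
    """Least-squares fit of A*exp(-t/tau) + C to a sweep segment.

    ``time`` is local to the segment (ms).  Raises
    :class:`DegenerateFitError` on flat traces; non-convergence is flagged
    on the result, never silent.
    """
    time = np.asarray(time, dtype=float)
    current = np.asarray(current, dtype=float)
    if window is None:
        window = (float(time[0]), float(time[-1]))
    m = _window_slice(time, window)
    t, y = time[m], current[m]
    if t.size < 10:
        raise ValueError("fit window must contain at least 10 samples")
    t = t - t[0]
    span = float(np.ptp(y))
    if span < 1e-12 or span < 1e-9 * max(1.0, np.abs(y).max()):
        raise DegenerateFitError("trace is constant over the fit window")
    c0 = float(np.mean(y[-max(3, t.size // 10):]))
    a0 = float(y[0] - c0)
    if abs(a0) < 1e-6 * span:
        a0 = span if y[0] > c0 else -span
    tau0 = _tau_guess(t, y, c0, a0)

    def model(tt, a, tau, c):
        return a * np.exp(-tt / tau) + c

    converged = True
    try:
        popt, _ = curve_fit(model, t, y, p0=(a0, tau0, c0), maxfev=MAXFEV,
                            xtol=_REL_TOL, bounds=([-np.inf, 1e-6, -np.inf],
                                                   [np.inf, np.inf, np.inf]))
    except RuntimeError:
        popt, converged = (a0, tau0, c0), False
    resid = float(np.linalg.norm(y - model(t, *popt)))
    return ExpFitResult(
        amplitudes=(float(popt[0]),), taus=(float(popt[1]),), offset=float(popt[2]),
        window=window, residual_norm=resid, converged=converged,
        flags=() if converged else ("non_convergent",),
    )


def fit_biexp(time: np.ndarray, current: np.ndarray,
              window: Optional[Tuple[float, float]] = None) -> ExpFitResult:
    """Two-component exponential fit with components ordered tau_fast < tau_slow.

    Initial guesses are obtained by peeling: the slow component is
    log-linearized on the late half of the window, subtracted, and the fast
    component estimated from the early residual.  If the two fitted time
    constants differ by less than 1.5x the result is flagged
    ``effectively_monoexponential``.
    """
    time = np.asarray(time, dtype=float)
    current = np.asarray(current, dtype=float)
    if window is None:
        window = (float(time[0]), float(time[-1]))
    m = _window_slice(time, window)
    t, y = time[m], current[m]
    if t.size < 50:
        raise ValueError("bi-exponential fit needs at least 50 samples")
    t = t - t[0]
    span = float(np.ptp(y))
    if span < 1e-12:
        raise DegenerateFitError("trace is constant over the fit window")
    c0 = float(np.mean(y[-max(3, t.size // 20):]))
    sign = 1.0 if y[0] >= c0 else -1.0
    # peel: slow component from the late half
    late = t > 0.4 * t[-1]
    rl = sign * (y[late] - c0)
    okl = rl > 1e-4 * span
    if okl.sum() >= 3:
        slope_l, inter_l = np.polyfit(t[late][okl], np.log(rl[okl]), 1)
        tau_s0 = float(np.clip(-1.0 / min(slope_l, -1e-9), 1.0, 1e5))
        a_s0 = sign * float(np.exp(inter_l))
    else:
        tau_s0 = (t[-1]) / 2.0
        a_s0 = (y[0] - c0) / 2.0
    early = t < 0.25 * t[-1]
    re = sign * (y[early] - c0) - sign * a_s0 * np.exp(-t[early] / tau_s0)
    oke = re > 1e-4 * span
    if oke.sum() >= 3:
        slope_f, inter_f = np.polyfit(t[early][oke], np.log(re[oke]), 1)
        tau_f0 = float(np.clip(-1.0 / min(slope_f, -1e-9), 1e-2, tau_s0))
        a_f0 = sign * float(np.exp(inter_f))
    else:
        tau_f0, a_f0 = tau_s0 / 5.0, (y[0] - c0) / 2.0

    def model(tt, a1, tau1, a2, tau2, c):
        return a1 * np.exp(-tt / tau1) + a2 * np.exp(-tt / tau2) + c

    converged = True
    try:
        popt, _ = curve_fit(model, t, y, p0=(a_f0, tau_f0, a_s0, tau_s0, c0),
                            maxfev=MAXFEV, xtol=_REL_TOL,
                            bounds=([-np.inf, 1e-6, -np.inf, 1e-6, -np.inf],
                                    [np.inf, np.inf, np.inf, np.inf, np.inf]))
    except RuntimeError:
        popt, converged = (a_f0, tau_f0, a_s0, tau_s0, c0), False
    a1, tau1, a2, tau2, c = popt
    if tau1 > tau2:  # order fast first
        a1, tau1, a2, tau2 = a2, tau2, a1, tau1
    flags = [] if converged else ["non_convergent"]
    amps = np.abs([a1, a2])
    if tau2 / tau1 < 1.5 or amps.min() < 0.01 * amps.sum():
        flags.append("effectively_monoexponential")
    resid = float(np.linalg.norm(y - model(t, a1, tau1, a2, tau2, c)))
    return ExpFitResult(
        amplitudes=(float(a1), float(a2)), taus=(float(tau1), float(tau2)),
        offset=float(c), window=window, residual_norm=resid,
        converged=converged, flags=tuple(flags),
    )


def measure_peak_tail(time: np.ndarray, current: np.ndarray,
                      blank_ms: float = 2.0, smooth_ms: float = 0.0,
                      search_ms: Optional[float] = None) -> float:
    """Signed extremum of largest magnitude after a capacitive-settling blank.

    ``time`` is local to the tail epoch (starts near 0).  Picks the hook
    peak on rising-then-falling tails rather than the first sample.  For
    noisy sweeps a boxcar of ``smooth_ms`` suppresses the upward bias of
    picking a maximum over noise, and ``search_ms`` restricts the search
    to the start of the epoch where the physical peak occurs.
    """
    time = np.asarray(time, dtype=float)
    current = np.asarray(current, dtype=float)
    if smooth_ms > 0 and time.size > 1:
        dt = time[1] - time[0]
        width = max(1, int(round(smooth_ms / dt)))
        kernel = np.ones(width) / width
        current = np.convolve(current, kernel, mode="same")
    m = time >= blank_ms - 1e-9
    if search_ms is not None:
        m &= time <= blank_ms + search_ms
    if not m.any():
        raise ValueError("tail epoch shorter than the blank period")
    seg = current[m]
    return float(seg[np.argmax(np.abs(seg))])


def tail_amplitude_hook_fit(time: np.ndarray, current: np.ndarray,
                            blank_ms: float = 2.0, fit_ms: float = 400.0) -> float:
    """Tail amplitude from a regression of the full hook waveform.

    Fits C + A*exp(-t/tau_decay)*(1 - exp(-t/tau_recovery)) over the first
    ``fit_ms`` of the tail and returns the fitted curve's signed extremum.
    Being regression-only (no argmax over samples), the estimate is free of
    the upward bias that extremum-picking acquires on noisy sweeps; use it
    in place of :func:`measure_peak_tail` when sigma is appreciable.
    Falls back to the smoothed extremum if the regression fails.
    """
    time = np.asarray(time, dtype=float)
    current = np.asarray(current, dtype=float)
    m = (time >= blank_ms - 1e-9) & (time <= blank_ms + fit_ms + 1e-9)
    if m.sum() < 20:
        raise ValueError("tail epoch too short for the hook regression")
    tt, yy = time[m] - blank_ms, current[m]
    w = max(1, int(round(10.0 / max(time[1] - time[0], 1e-9))))
    ys = np.convolve(yy, np.ones(w) / w, mode="same")
    pk = float(ys[np.argmax(np.abs(ys))])
    c0 = float(yy[-max(3, yy.size // 10):].mean())

    def model(t, a, tau_d, tau_r, c):
        return c + a * np.exp(-t / tau_d) * (1.0 - np.exp(-t / tau_r))

    try:
        popt, _ = curve_fit(model, tt, yy, p0=(1.3 * (pk - c0), 250.0, 2.0, c0),
                            maxfev=20000,
                            bounds=([-np.inf, 1.0, 0.05, -np.inf],
                                    [np.inf, 1e5, 50.0, np.inf]))
    except RuntimeError:
        return pk
    a, tau_d, tau_r, c = popt
    t_star = tau_r * np.log(1.0 + tau_d / tau_r)
    return float(model(t_star, *popt))


def _tail_epoch_index(traces: TraceSet) -> int:
    """Epoch holding the tail: the one after the SWEEP epoch, else the SWEEP epoch."""
    proto = traces.protocol
    var = proto.variable_epoch_index
    if var >= 0 and var + 1 < len(proto.epochs):
        return var + 1
    if var >= 0:
        return var
    return len(proto.epochs) - 1


def peak_tail_table(traces: TraceSet, tail_epoch: Optional[int] = None,
                    blank_ms: float = 2.0, smooth_ms: float = 0.0,
                    search_ms: Optional[float] = None,
                    method: str = "peak") -> pd.DataFrame:
    """Peak tail current per sweep; columns voltage_mV, peak_uA.

    ``method='peak'`` takes the signed extremum (exact on clean sweeps);
    ``method='hook_fit'`` reads the amplitude off a hook-waveform
    regression, which stays unbiased under additive noise.
    """
    if tail_epoch is None:
        tail_epoch = _tail_epoch_index(traces)
    tloc, seg = traces.epoch_segment(tail_epoch)
    if method == "peak":
        peaks = [measure_peak_tail(tloc, seg[i], blank_ms=blank_ms,
                                   smooth_ms=smooth_ms, search_ms=search_ms)
                 for i in range(traces.n_sweeps)]
    elif method == "hook_fit":
        peaks = [tail_amplitude_hook_fit(tloc, seg[i], blank_ms=blank_ms)
                 for i in range(traces.n_sweeps)]
    else:
        raise ValueError(f"unknown tail method {method!r}")
    return pd.DataFrame({"voltage_mV": traces.sweep_voltages, "peak_uA": peaks})


def activation_tau_table(traces: TraceSet, v_range: Tuple[float, float] = (-20.0, 20.0),
                         window_ms: float = 500.0) -> pd.DataFrame:
    """Mono-exponential activation tau per test voltage.

    Restricted to test potentials in ``v_range`` (outside it the overlap
    with inactivation makes a single exponential a poor description); the
    fit window is the first ``window_ms`` of the variable epoch.
    """
    proto = traces.protocol
    var = proto.variable_epoch_index
    tloc, seg = traces.epoch_segment(var)
    rows = []
    for i, v in enumerate(traces.sweep_voltages):
        if not (v_range[0] - 1e-9 <= v <= v_range[1] + 1e-9):
            continue
        try:
            fit = fit_monoexp(tloc, seg[i], window=(0.0, window_ms))
            rows.append({"voltage_mV": v, "tau_ms": fit.tau,
                         "amplitude_uA": fit.amplitudes[0], "offset_uA": fit.offset,
                         "converged": fit.converged, "flags": ";".join(fit.flags)})
        except (DegenerateFitError, ValueError) as err:
            rows.append({"voltage_mV": v, "tau_ms": np.nan, "amplitude_uA": np.nan,
                         "offset_uA": np.nan, "converged": False, "flags": str(err)})
    return pd.DataFrame(rows)


def _fit_boltzmann(v: np.ndarray, y: np.ndarray, increasing: bool,
                   p0: Tuple[float, float, float]) -> BoltzmannFitResult:
    sign = -1.0 if increasing else 1.0

    def model(vv, a, vh, k):
        return a / (1.0 + np.exp(sign * (vv - vh) / k))

    popt, _ = curve_fit(model, v, y, p0=p0, maxfev=MAXFEV, xtol=_REL_TOL,
                        bounds=([0.0, -200.0, 0.1], [10.0, 200.0, 100.0]))
    resid = float(np.linalg.norm(y - model(v, *popt)))
    return BoltzmannFitResult(v_half=float(popt[1]), k=float(popt[2]),
                              amplitude=float(popt[0]), residual_norm=resid,
                              increasing=increasing)


def activation_curve(tails: pd.DataFrame) -> BoltzmannFitResult:
    """Boltzmann fit to peak tail currents normalized to maximal magnitude.

    ``tails`` as returned by :func:`peak_tail_table`.  Raises
    :class:`UnidentifiableError` when the tails do not span the activation
    transition.
    """
    v = np.asarray(tails["voltage_mV"], dtype=float)
    peaks = np.asarray(tails["peak_uA"], dtype=float)
    if v.size < 5:
        raise UnidentifiableError("need at least 5 test voltages")
    mag = np.abs(peaks)
    if mag.max() <= 0:
        raise UnidentifiableError("all tail currents are zero")
    y = mag / mag.max()
    if y.min() > 0.5 or y.max() - y.min() < 0.3:
        raise UnidentifiableError("tail currents do not span the activation range")
    vh0 = float(v[np.argmin(np.abs(y - 0.5))])
    return _fit_boltzmann(v, y, increasing=True, p0=(1.0, vh0, 8.0))


def fully_activated_iv(traces: TraceSet,
                       fit_window: Tuple[float, float] = (-120.0, -90.0),
                       blank_ms: float = 2.0, smooth_ms: float = 0.0,
                       search_ms: Optional[float] = None,
                       method: str = "peak") -> FullyActivatedIV:
    """Peak tails vs tail voltage with an Ohmic linear fit on ``fit_window``.

    The slope of the line is the maximal tail conductance G (uS) and its
    zero crossing the reversal potential.
    """
    table = peak_tail_table(traces, blank_ms=blank_ms, smooth_ms=smooth_ms,
                            search_ms=search_ms, method=method)
    v = np.asarray(table["voltage_mV"], dtype=float)
    peaks = np.asarray(table["peak_uA"], dtype=float)
    m = (v >= fit_window[0] - 1e-9) & (v <= fit_window[1] + 1e-9)
    if m.sum() < 2:
        raise ValueError("fewer than 2 tail voltages inside the linear-fit window")
    slope, intercept = np.polyfit(v[m], peaks[m], 1)
    if slope <= 0:
        raise ValueError("non-positive fitted conductance")
    return FullyActivatedIV(voltages=v, tail_peaks=peaks, g=float(slope * 1e3),
                            e_rev=float(-intercept / slope), fit_window=fit_window)


def rectification_curve(iv: FullyActivatedIV, n_at_plus40: float = 1.0,
                        exclusion_mv: float = 5.0) -> RectificationResult:
    """Rectification factor R(V) = I(V) / (G * n * (V - E_rev)), Boltzmann-fitted.

    Voltages within ``exclusion_mv`` of the reversal potential are excluded
    (vanishing driving force makes R there a 0/0).  ``n_at_plus40`` is the
    activation variable during the preceding +40 mV step (1.0 for a fully
    activated channel).
    """
    v = iv.voltages
    excl = np.abs(v - iv.e_rev) < exclusion_mv
    if excl.all():
        raise ValueError("all voltages excluded around the reversal potential")
    vv, ii = v[~excl], iv.tail_peaks[~excl]
    r = ii / (1e-3 * iv.g * n_at_plus40 * (vv - iv.e_rev))
    vh0 = float(vv[np.argmin(np.abs(r - 0.5))])
    boltz = _fit_boltzmann(vv, r, increasing=False, p0=(1.0, vh0, 20.0))
    return RectificationResult(voltages=vv, r=r, excluded_voltages=v[excl],
                               boltzmann=boltz)


def inactivation_onset_taus(traces: TraceSet, blank_ms: float = 1.0) -> pd.DataFrame:
    """Mono-exponential tau of inactivation onset per test voltage.

    A first-pass fit over the initial 20 ms sets the scale; the final fit
    window is ~3 time constants, long enough to capture 95% of the decay
    while keeping the much slower deactivation drift out of the window.
    Per-voltage failures become NaN rows.
    """
    proto = traces.protocol
    var = proto.variable_epoch_index
    if var < 2:
        raise ValueError("expected an activation step and a recovery epoch "
                         "before the variable test epoch")
    tloc, seg = traces.epoch_segment(var)
    t_end = float(tloc[-1])
    rows = []
    for i, v in enumerate(traces.sweep_voltages):
        try:
            first = fit_monoexp(tloc, seg[i], window=(blank_ms, min(20.0, t_end)))
            w_end = min(t_end, blank_ms + max(3.0 * first.tau, 10.0))
            fit = fit_monoexp(tloc, seg[i], window=(blank_ms, w_end))
            rows.append({"voltage_mV": v, "tau_ms": fit.tau,
                         "amplitude_uA": fit.amplitudes[0], "offset_uA": fit.offset,
                         "converged": fit.converged, "flags": ";".join(fit.flags)})
        except (DegenerateFitError, ValueError) as err:
            rows.append({"voltage_mV": v, "tau_ms": np.nan, "amplitude_uA": np.nan,
                         "offset_uA": np.nan, "converged": False, "flags": str(err)})
    return pd.DataFrame(rows)


def deactivation_tables(traces: TraceSet, blank_ms: float = 5.0) -> pd.DataFrame:
    """Bi-exponential deactivation components per hyperpolarizing voltage.

    Columns: voltage_mV, tau_fast_ms, tau_slow_ms, weight_fast, flags.
    """
    proto = traces.protocol
    var = proto.variable_epoch_index
    tloc, seg = traces.epoch_segment(var)
    rows = []
    for i, v in enumerate(traces.sweep_voltages):
        try:
            fit = fit_biexp(tloc, seg[i], window=(blank_ms, float(tloc[-1])))
            rows.append({"voltage_mV": v, "tau_fast_ms": fit.tau_fast,
                         "tau_slow_ms": fit.tau_slow, "weight_fast": fit.weight_fast,
                         "converged": fit.converged, "flags": ";".join(fit.flags)})
        except (DegenerateFitError, ValueError) as err:
            rows.append({"voltage_mV": v, "tau_fast_ms": np.nan, "tau_slow_ms": np.nan,
                         "weight_fast": np.nan, "converged": False, "flags": str(err)})
    return pd.DataFrame(rows)


def steady_state_iv(traces: TraceSet, window_ms: float = 100.0) -> pd.DataFrame:
    """Mean current over the last ``window_ms`` of the variable epoch."""
    proto = traces.protocol
    var = proto.variable_epoch_index
    tloc, seg = traces.epoch_segment(var)
    m = tloc >= tloc[-1] - window_ms + 1e-9
    return pd.DataFrame({
        "voltage_mV": traces.sweep_voltages,
        "current_uA": seg[:, m].mean(axis=1),
    })
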