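"""Concentration-response analysis of Kv11.1 block.

Simulates the repeated-depolarization protocol across a blocker
concentration series and fits the Hill dose-response model

    I_drug / I_control = 1 / (1 + (c / IC50)^h)

by nonlinear regression on log-transformed concentration.  The model is
the two-parameter reduction of a four-parameter logistic with top = 1 and
bottom = 0, which is exact for currents expressed as fractions of the
drug-free control.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .analysis import (MAXFEV, UnidentifiableError, _REL_TOL,
                       measure_peak_tail, tail_amplitude_hook_fit)
from .model import BlockParams, ChannelParams, NoiseSpec, simulate_protocol
from .protocols import pharmacology_protocol

__all__ = ["DoseResponse", "DEFAULT_CONCENTRATIONS", "run_block_series",
           "fit_dose_response"]

#: Standard terfenadine series (uM).
DEFAULT_CONCENTRATIONS: Tuple[float, ...] = (0.01, 0.03, 0.1, 0.3, 1.0, 3.0, 10.0)


@dataclass(frozen=True)
class DoseResponse:
    concentrations: Tuple[float, ...]   # uM, ascending
    fractions: Tuple[float, ...]        # I_drug / I_control
    ic50: float                         # uM
    hill: float
    ic50_stderr: float                  # asymptotic SE (NaN when hill fixed-free mix fails)
    residual_norm: float

    def __post_init__(self) -> None:
        c = np.asarray(self.concentrations)
        if np.any(c <= 0) or np.any(np.diff(c) <= 0):
            raise ValueError("concentrations must be positive and increasing")
        if self.ic50 <= 0:
            raise ValueError("ic50 must be > 0")

    def __call__(self, c):
        c = np.asarray(c, dtype=float)
        return 1.0 / (1.0 + (c / self.ic50) ** self.hill)


def run_block_series(
    params: ChannelParams,
    block: BlockParams,
    concentrations: Sequence[float] = DEFAULT_CONCENTRATIONS,
    noise: Optional[NoiseSpec] = None,
    steady_window_ms: float = 100.0,
    tail_blank_ms: float = 2.0,
    tail_method: str = "peak",
) -> pd.DataFrame:
    """Simulate the concentration series; fractional currents vs control.

    For each concentration (plus drug-free control) the repeated 0 mV
    depolarization protocol is simulated; block is read both from the
    steady-state current at the end of the 0 mV step and from the peak
    tail after repolarization to -80 mV.

    Returns a DataFrame with columns ``concentration_uM``,
    ``fraction_steady_state`` and ``fraction_tail``.  With
    ``tail_method='hook_fit'`` tail amplitudes come from the hook-waveform
    regression, which stays unbiased on noisy sweeps.
    """
    conc = [float(c) for c in concentrations]
    if any(c <= 0 for c in conc):
        raise ValueError("concentrations must be positive")
    proto = pharmacology_protocol(n_repeats=1)
    var_like = 0  # the 0 mV step epoch
    tail_epoch = 1

    def _measures(traces):
        tloc, seg = traces.epoch_segment(var_like)
        m = tloc >= tloc[-1] - steady_window_ms + 1e-9
        steady = float(seg[0, m].mean())
        ttail, tseg = traces.epoch_segment(tail_epoch)
        if tail_method == "hook_fit":
            tail = tail_amplitude_hook_fit(ttail, tseg[0], blank_ms=tail_blank_ms)
        else:
            tail = measure_peak_tail(ttail, tseg[0], blank_ms=tail_blank_ms)
        return steady, tail

    control = simulate_protocol(proto, params, noise=noise)
    s0, t0 = _measures(control)
    if s0 == 0 or t0 == 0:
        raise ValueError("control currents are zero; cannot form fractions")
    rows = []
    for i, c in enumerate(conc):
        n = noise
        if noise is not None and noise.seed is not None:
            n = NoiseSpec(sigma=noise.sigma, leak_conductance=noise.leak_conductance,
                          leak_reversal=noise.leak_reversal, seed=noise.seed + 1 + i)
        tr = simulate_protocol(proto, params, noise=n, block=(block, c))
        s, t = _measures(tr)
        rows.append({"concentration_uM": c, "fraction_steady_state": s / s0,
                     "fraction_tail": t / t0})
    return pd.DataFrame(rows).sort_values("concentration_uM", ignore_index=True)


def fit_dose_response(
    fractions: pd.DataFrame,
    column: str = "fraction_steady_state",
    fix_hill: Optional[float] = None,
) -> DoseResponse:
    """Fit the Hill model on log10(concentration); returns a :class:`DoseResponse`.

    ``fractions`` as returned by :func:`run_block_series` (or any frame
    with ``concentration_uM`` and the requested column).  With
    ``fix_hill`` the Hill coefficient is held fixed and only the IC50 is
    estimated.
    """
    c = np.asarray(fractions["concentration_uM"], dtype=float)
    y = np.asarray(fractions[column], dtype=float)
    if c.size < 4:
        raise UnidentifiableError("need at least 4 concentrations")
    if y.min() > 0.7:
        raise UnidentifiableError("series shows almost no block; IC50 not identifiable")
    if y.max() < 0.3:
        raise UnidentifiableError("series is fully blocked; IC50 not identifiable")
    x = np.log10(c)
    x50_0 = float(x[np.argmin(np.abs(y - 0.5))])

    if fix_hill is not None:
        def model(xx, x50):
            return 1.0 / (1.0 + 10.0 ** (fix_hill * (xx - x50)))
        popt, pcov = curve_fit(model, x, y, p0=(x50_0,), maxfev=MAXFEV, xtol=_REL_TOL)
        x50, hill = float(popt[0]), float(fix_hill)
        var_x50 = float(pcov[0, 0])
    else:
        def model(xx, x50, h):
            return 1.0 / (1.0 + 10.0 ** (h * (xx - x50)))
        popt, pcov = curve_fit(model, x, y, p0=(x50_0, 1.0), maxfev=MAXFEV,
                               xtol=_REL_TOL, bounds=([-10.0, 0.05], [10.0, 20.0]))
        x50, hill = float(popt[0]), float(popt[1])
        var_x50 = float(pcov[0, 0])
    ic50 = 10.0 ** x50
    # delta method: SE(ic50) = ln(10) * ic50 * SE(x50)
    se = float(np.log(10.0) * ic50 * np.sqrt(var_x50)) if np.isfinite(var_x50) else np.nan
    resid = float(np.linalg.norm(y - 1.0 / (1.0 + (c / ic50) ** hill)))
    return DoseResponse(concentrations=tuple(c), fractions=tuple(y), ic50=ic50,
                        hill=hill, ic50_stderr=se, residual_norm=resid)
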