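"""Synthetic right-ventricular wedge action potentials and APD analysis.

The wedge generator is phenomenological: each captured beat is a
sigmoidal upstroke followed by a plateau and a sigmoidal repolarization,
scaled so that the 90%-repolarization time equals a target APD90 given by
an exponential restitution curve

    APD90(BCL) = apd_max - a * exp(-BCL / tau_rest)

with an optional drug arm that multiplies APD90 by (1 + prolongation(BCL)),
largest at long cycle lengths (reverse rate dependence).  A stimulus fails
to capture when the interval since the previous upstroke is shorter than
the ongoing APD90 plus a refractory margin.

APD measurement is independent of the generator: upstrokes are detected
from the maximal dV/dt, and APD at a given repolarization level uses
per-beat peak and baseline.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .model import NoiseSpec

__all__ = ["APParams", "APRecording", "generate_ap_train", "measure_apd",
           "rate_dependence_table", "DEFAULT_BCLS"]

#: Pacing cycle lengths (ms) of the standard wedge experiment.
DEFAULT_BCLS = (4000.0, 2000.0, 1000.0, 500.0, 333.0, 250.0)


@dataclass(frozen=True)
class APParams:
    """Wedge action-potential generator parameters (ms / mV)."""

    v_rest: float = -85.0
    v_peak: float = 25.0
    upstroke_ms: float = 2.0
    apd_max: float = 480.0          # ms, asymptotic APD90 at slow pacing
    rest_amp: float = 400.0         # ms, restitution amplitude a
    tau_rest: float = 750.0         # ms, restitution constant
    # fractional APD90 increase under drug, by BCL; only the 2000 ms entry
    # is an experimentally reported value, the rest shape the reverse rate
    # dependence.
    drug_prolongation: Dict[float, float] = field(default_factory=lambda: {
        4000.0: 0.20, 2000.0: 0.17, 1000.0: 0.12, 500.0: 0.06, 333.0: 0.04})
    refractory_margin: float = 60.0  # ms
    repol_width: float = 12.0        # ms, repolarization sigmoid width
    sampling_rate: float = 2000.0    # Hz

    def __post_init__(self) -> None:
        if self.v_peak <= self.v_rest:
            raise ValueError("v_peak must exceed v_rest")
        if not (self.apd_max > self.rest_amp >= 0):
            raise ValueError("need apd_max > restitution amplitude >= 0")
        if any(f < 0 for f in self.drug_prolongation.values()):
            raise ValueError("prolongation fractions must be >= 0")

    def prolongation(self, bcl: float) -> float:
        """Fractional drug prolongation at a BCL (nearest tabulated BCL)."""
        if not self.drug_prolongation:
            return 0.0
        key = min(self.drug_prolongation, key=lambda b: abs(b - bcl))
        return self.drug_prolongation[key]

    def target_apd90(self, bcl: float, drug: bool = False) -> float:
        apd = self.apd_max - self.rest_amp * np.exp(-bcl / self.tau_rest)
        if drug:
            apd *= 1.0 + self.prolongation(bcl)
        return float(apd)


@dataclass
class APRecording:
    time: np.ndarray            # ms
    vm: np.ndarray              # mV
    bcl: float                  # ms
    stimulus_times: np.ndarray  # ms
    captured_flags: np.ndarray  # bool per stimulus
    metadata: dict = field(default_factory=dict)

    @property
    def captured(self) -> bool:
        """True when every stimulus elicited an action potential."""
        return bool(self.captured_flags.all())


def _beat_waveform(t_rel: np.ndarray, params: APParams, apd90: float) -> np.ndarray:
    """Voltage (above rest) of one beat, 90%-repolarizing at ``apd90``.

    The upstroke sigmoid is centered at upstroke_ms/2 (maximal slope =
    activation time); the repolarization sigmoid is placed so vm crosses
    the 10%-amplitude level exactly APD90 after the activation time.
    """
    amp = params.v_peak - params.v_rest
    t_mid = params.upstroke_ms / 2.0
    w_up = max(params.upstroke_ms / 6.0, 1e-3)
    w_r = params.repol_width
    t_c = t_mid + apd90 - w_r * np.log(9.0)
    up = expit((t_rel - t_mid) / w_up)
    rep = expit(-(t_rel - t_c) / w_r)
    return amp * up * rep


def generate_ap_train(
    params: APParams,
    bcl: float,
    n_beats: int = 8,
    drug: bool = False,
    noise: Optional[NoiseSpec] = None,
) -> APRecording:
    """Paced train of action potentials at one basic cycle length.

    Stimuli are delivered every ``bcl`` ms; a stimulus whose interval since
    the previous upstroke is below APD90 + refractory margin fails and
    produces no beat (2:1 block at short cycle lengths).
    """
    if bcl <= 0:
        raise ValueError("bcl must be > 0")
    if n_beats < 1:
        raise ValueError("n_beats must be >= 1")
    apd = params.target_apd90(bcl, drug=drug)
    dt = 1000.0 / params.sampling_rate
    total = n_beats * bcl + apd + 200.0
    t = np.arange(int(round(total / dt))) * dt
    vm = np.full(t.size, params.v_rest)
    stim_times = np.arange(n_beats) * bcl + 10.0
    captured = np.zeros(n_beats, dtype=bool)
    last_upstroke = -np.inf
    for j, ts in enumerate(stim_times):
        if ts - last_upstroke < apd + params.refractory_margin:
            continue
        captured[j] = True
        last_upstroke = ts + params.upstroke_ms / 2.0
        m = t >= ts
        vm[m] = params.v_rest + _beat_waveform(t[m] - ts, params, apd)
    if noise is not None and noise.sigma > 0:
        rng = np.random.default_rng(noise.seed)
        vm = vm + rng.normal(0.0, noise.sigma, size=vm.size)
    return APRecording(time=t, vm=vm, bcl=float(bcl), stimulus_times=stim_times,
                       captured_flags=captured,
                       metadata={"drug": drug, "target_apd90_ms": apd})


def measure_apd(recording: APRecording, level: float = 90.0) -> np.ndarray:
    """APD at ``level``% repolarization for every detected beat (ms).

    Beats are found from dV/dt maxima; for each beat the baseline is the
    potential just before the upstroke and the peak the maximum before the
    next beat, so drifting recordings are measured per beat.  Raises on
    recordings without any captured beat.
    """
    t, vm = recording.time, recording.vm
    dt = float(t[1] - t[0])
    dvdt = np.gradient(vm, dt)
    thresh = 0.3 * dvdt.max()
    if dvdt.max() <= 0 or thresh <= 0:
        raise ValueError("no upstroke found in recording")
    above = dvdt > thresh
    # group contiguous supra-threshold runs into upstrokes
    edges = np.flatnonzero(np.diff(above.astype(int)) == 1) + 1
    if above[0]:
        edges = np.r_[0, edges]
    ups = []
    for e in edges:
        run_end = e
        while run_end < above.size and above[run_end]:
            run_end += 1
        ups.append(e + int(np.argmax(dvdt[e:run_end])))
    if not ups:
        raise ValueError("no captured beats in recording")
    apds = []
    for b, idx in enumerate(ups):
        nxt = ups[b + 1] if b + 1 < len(ups) else vm.size
        base = vm[max(0, idx - int(5.0 / dt)):max(1, idx - 1)].min() \
            if idx > 1 else vm[0]
        seg = vm[idx:nxt]
        pk_rel = int(np.argmax(seg))
        peak = float(seg[pk_rel])
        target = peak - (level / 100.0) * (peak - base)
        below = np.flatnonzero(seg[pk_rel:] < target)
        if below.size == 0:
            apds.append(np.nan)  # repolarization not captured within window
            continue
        cross = idx + pk_rel + below[0]
        apds.append(float(t[cross] - t[idx]))
    return np.asarray(apds)


def rate_dependence_table(
    params: APParams,
    bcls: Sequence[float] = DEFAULT_BCLS,
    n_beats: int = 8,
    noise: Optional[NoiseSpec] = None,
) -> pd.DataFrame:
    """Control vs drug APD90 at each BCL with percent change and capture flags.

    APD90 is measured on the last captured beat.  Rows where either arm
    lost 1:1 capture keep their measured values but are flagged.
    """
    if not len(bcls):
        raise ValueError("empty BCL list")
    rows = []
    for bcl in bcls:
        rec_c = generate_ap_train(params, bcl, n_beats=n_beats, drug=False, noise=noise)
        rec_d = generate_ap_train(params, bcl, n_beats=n_beats, drug=True, noise=noise)
        apd_c = measure_apd(rec_c)[-1]
        apd_d = measure_apd(rec_d)[-1]
        rows.append({
            "bcl_ms": float(bcl),
            "apd90_control_ms": apd_c,
            "apd90_drug_ms": apd_d,
            "percent_change": 100.0 * (apd_d - apd_c) / apd_c,
            "captured_control": rec_c.captured,
            "captured_drug": rec_d.captured,
        })
    return pd.DataFrame(rows)
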