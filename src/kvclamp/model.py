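"""Forward model of a two-gate Kv11.1 (hERG)-like channel under voltage clamp.

The channel carries current

    I = b * g_max * n * r * (V - e_rev) / 1000        [uA]

with conductance in uS and voltages in mV, where ``n`` is the activation
gate, ``r`` the inactivation (availability) gate and ``b`` a fractional
block factor.  Both gates relax first-order toward voltage-dependent
Boltzmann steady states with bell-shaped voltage-dependent time constants;
within a constant-voltage epoch the relaxation is integrated in closed
form, so simulated sweeps are exact up to floating point.

Bi-exponential deactivation, a hallmark of Kv11.1 tails, is emulated with
an optional second activation-gate population that shares the steady state
but relaxes with a slower time constant: tau_slow(V) = tau_act(V) plus a
bell-shaped excess (``tau_act_slow_spec``) centered in the deactivation
voltage range, so both populations are kinetically identical at test
potentials and diverge only where deactivation is measured.  The observed
fast fraction is set by a voltage-dependent weight ``w_fast(V)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Tuple

import numpy as np
from scipy.special import expit

from .protocols import StepProtocol, TraceSet

__all__ = [
    "TauSpec",
    "WeightSpec",
    "ChannelParams",
    "BlockParams",
    "GateState",
    "NoiseSpec",
    "steady_state_activation",
    "steady_state_availability",
    "advance_gates",
    "simulate_protocol",
    "fractional_block",
    "apply_kcne2",
]

_V_CHECK = np.linspace(-140.0, 60.0, 201)


@dataclass(frozen=True)
class TauSpec:
    """Bell-shaped voltage dependence of a relaxation time constant (ms).

    tau(V) = tau_min + tau_amp / (exp((V - v_peak)/s_depol) + exp(-(V - v_peak)/s_hyper))

    ``s_depol`` sets how fast tau falls on the depolarized side of the
    peak, ``s_hyper`` on the hyperpolarized side.  All values in ms / mV.
    """

    tau_min: float
    tau_amp: float
    v_peak: float
    s_depol: float
    s_hyper: float

    def __post_init__(self) -> None:
        if self.tau_min <= 0 or self.tau_amp < 0:
            raise ValueError("tau_min must be > 0 and tau_amp >= 0")
        if self.s_depol <= 0 or self.s_hyper <= 0:
            raise ValueError("slope factors must be > 0")

    def __call__(self, v):
        x = (np.asarray(v, dtype=float) - self.v_peak)
        return self.tau_min + self.tau_amp / (
            np.exp(x / self.s_depol) + np.exp(-x / self.s_hyper)
        )

    def scaled(self, factor: float) -> "TauSpec":
        """Uniformly slow down (factor > 1) or speed up the relaxation."""
        return replace(self, tau_min=self.tau_min * factor, tau_amp=self.tau_amp * factor)


@dataclass(frozen=True)
class WeightSpec:
    """Voltage-dependent fast fraction of the two deactivation populations.

    w(V) = w_min + (w_max - w_min) / (1 + exp((V - v_half)/k)); decreasing
    with depolarization so the fast component dominates at hyperpolarized
    potentials.
    """

    w_min: float = 0.35
    w_max: float = 0.90
    v_half: float = -80.0
    k: float = 12.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.w_min <= self.w_max <= 1.0):
            raise ValueError("need 0 <= w_min <= w_max <= 1")
        if self.k <= 0:
            raise ValueError("k must be > 0")

    def __call__(self, v):
        v = np.asarray(v, dtype=float)
        return self.w_min + (self.w_max - self.w_min) / (
            1.0 + np.exp((v - self.v_half) / self.k)
        )


@dataclass(frozen=True)
class ChannelParams:
    """Full parameterization of a two-gate Kv11.1-like channel.

    Units: conductance uS, potentials mV, time constants ms.
    """

    g_max: float
    e_rev: float
    v_half_act: float
    k_act: float
    v_half_inact: float
    k_inact: float
    tau_act_spec: TauSpec
    tau_inact_spec: TauSpec
    tau_act_slow_spec: Optional[TauSpec] = None
    w_fast_spec: Optional[WeightSpec] = None
    label: str = ""

    def __post_init__(self) -> None:
        if not np.isfinite([self.g_max, self.e_rev, self.v_half_act, self.k_act,
                            self.v_half_inact, self.k_inact]).all():
            raise ValueError("channel parameters must be finite")
        if self.g_max <= 0:
            raise ValueError("g_max must be > 0")
        if self.k_act <= 0 or self.k_inact <= 0:
            raise ValueError("Boltzmann slope factors must be > 0")
        for spec in (self.tau_act_spec, self.tau_inact_spec, self.tau_act_slow_spec):
            if spec is not None and np.any(spec(_V_CHECK) <= 0):
                raise ValueError("time constants must be strictly positive on [-140, 60] mV")
        if self.tau_act_slow_spec is not None and self.w_fast_spec is None:
            object.__setattr__(self, "w_fast_spec", WeightSpec())

    @property
    def two_population(self) -> bool:
        return self.tau_act_slow_spec is not None

    def tau_act_slow(self, v):
        """Slow-population time constant: tau_act(V) + the bell-shaped excess."""
        return self.tau_act_spec(v) + self.tau_act_slow_spec(v)


@dataclass(frozen=True)
class BlockParams:
    """Hill-type concentration dependence of channel block."""

    ic50: float  # uM
    hill: float = 1.0

    def __post_init__(self) -> None:
        if self.ic50 <= 0:
            raise ValueError("ic50 must be > 0")
        if self.hill <= 0:
            raise ValueError("hill must be > 0")


@dataclass(frozen=True)
class GateState:
    """Gate variables; ``n_slow`` tracks the slow activation population."""

    n: float
    r: float
    n_slow: Optional[float] = None

    def __post_init__(self) -> None:
        vals = [self.n, self.r] + ([self.n_slow] if self.n_slow is not None else [])
        if any(v < -1e-12 or v > 1.0 + 1e-12 for v in vals):
            raise ValueError("gate variables must lie in [0, 1]")


@dataclass(frozen=True)
class NoiseSpec:
    """Additive measurement noise and linear background (leak) conductance."""

    sigma: float = 0.0           # uA
    leak_conductance: float = 0.0  # uS
    leak_reversal: float = 0.0   # mV
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.sigma < 0 or self.leak_conductance < 0:
            raise ValueError("sigma and leak_conductance must be >= 0")


def steady_state_activation(v, params: ChannelParams):
    """Boltzmann open fraction n_inf(V) = 1/(1 + exp((V1/2 - V)/k))."""
    v = np.asarray(v, dtype=float)
    out = expit((v - params.v_half_act) / params.k_act)
    return float(out) if out.ndim == 0 else out


def steady_state_availability(v, params: ChannelParams):
    """Boltzmann availability r_inf(V) = 1/(1 + exp((V - V1/2)/k)); decreasing."""
    v = np.asarray(v, dtype=float)
    out = expit(-(v - params.v_half_inact) / params.k_inact)
    return float(out) if out.ndim == 0 else out


def equilibrium_state(v: float, params: ChannelParams) -> GateState:
    """Gate state after an infinitely long hold at voltage ``v``."""
    n = steady_state_activation(v, params)
    r = steady_state_availability(v, params)
    return GateState(n=n, r=r, n_slow=n if params.two_population else None)


def advance_gates(state: GateState, v: float, dt: float, params: ChannelParams) -> GateState:
    """Relax each gate toward its steady state at ``v`` for ``dt`` ms (closed form)."""
    if dt < 0:
        raise ValueError("dt must be >= 0")
    n_inf = steady_state_activation(v, params)
    r_inf = steady_state_availability(v, params)
    n = n_inf + (state.n - n_inf) * np.exp(-dt / float(params.tau_act_spec(v)))
    r = r_inf + (state.r - r_inf) * np.exp(-dt / float(params.tau_inact_spec(v)))
    n_slow = None
    if params.two_population:
        ns0 = state.n_slow if state.n_slow is not None else state.n
        n_slow = n_inf + (ns0 - n_inf) * np.exp(-dt / float(params.tau_act_slow(v)))
    return GateState(n=float(n), r=float(r), n_slow=None if n_slow is None else float(n_slow))


def fractional_block(concentration: float, block: BlockParams) -> float:
    """Fraction of current remaining at a blocker concentration (Hill equation)."""
    if concentration < 0:
        raise ValueError("concentration must be >= 0")
    if concentration == 0:
        return 1.0
    return 1.0 / (1.0 + (concentration / block.ic50) ** block.hill)


def apply_kcne2(params: ChannelParams, reduction_fraction: float) -> ChannelParams:
    """Scale g_max by (1 - reduction_fraction); kinetics untouched.

    Models KCNE2 co-expression as a pure reduction of functional channel
    density, matching the observed current reduction with unchanged gating.
    """
    if not (0.0 <= reduction_fraction < 1.0):
        raise ValueError("reduction_fraction must lie in [0, 1)")
    label = params.label + "+KCNE2" if params.label else "+KCNE2"
    return replace(params, g_max=params.g_max * (1.0 - reduction_fraction), label=label)


def _conducting_n(v: float, n: np.ndarray, n_slow: Optional[np.ndarray],
                  params: ChannelParams) -> np.ndarray:
    if n_slow is None:
        return n
    w = float(params.w_fast_spec(v))
    return w * n + (1.0 - w) * n_slow


def simulate_protocol(
    protocol: StepProtocol,
    params: ChannelParams,
    noise: Optional[NoiseSpec] = None,
    block: Optional[Tuple[BlockParams, float]] = None,
) -> TraceSet:
    """Simulate every sweep of a step protocol; returns a :class:`TraceSet`.

    Gates start at equilibrium for the holding potential of each sweep (the
    default inter-sweep interval is long enough for re-equilibration).
    Within each constant-voltage epoch the gate trajectory is evaluated in
    closed form at every sample time.
    """
    if not protocol.epochs:
        raise ValueError("protocol has no epochs")
    b = 1.0
    conc = None
    if block is not None:
        blockp, conc = block
        b = fractional_block(conc, blockp)

    dt = 1000.0 / protocol.sampling_rate  # ms per sample
    total = protocol.total_duration
    n_samples = int(round(total / dt))
    t = np.arange(n_samples) * dt

    rng = None
    if noise is not None and noise.seed is not None:
        rng = np.random.default_rng(noise.seed)
    elif noise is not None and noise.sigma > 0:
        rng = np.random.default_rng()

    sweeps = np.empty((protocol.n_sweeps, n_samples))
    for i in range(protocol.n_sweeps):
        segs = protocol.resolve_sweep(i)
        state = equilibrium_state(protocol.holding, params)
        current = np.empty(n_samples)
        t0 = 0.0
        for v, dur in segs:
            mask = (t >= t0 - 1e-9) & (t < t0 + dur - 1e-9)
            tl = t[mask] - t0
            n_inf = steady_state_activation(v, params)
            r_inf = steady_state_availability(v, params)
            n_t = n_inf + (state.n - n_inf) * np.exp(-tl / float(params.tau_act_spec(v)))
            r_t = r_inf + (state.r - r_inf) * np.exp(-tl / float(params.tau_inact_spec(v)))
            ns_t = None
            if params.two_population:
                ns0 = state.n_slow if state.n_slow is not None else state.n
                ns_t = n_inf + (ns0 - n_inf) * np.exp(
                    -tl / float(params.tau_act_slow(v)))
            n_cond = _conducting_n(v, n_t, ns_t, params)
            i_chan = 1e-3 * b * params.g_max * n_cond * r_t * (v - params.e_rev)
            if noise is not None and noise.leak_conductance > 0:
                i_chan = i_chan + 1e-3 * noise.leak_conductance * (v - noise.leak_reversal)
            current[mask] = i_chan
            state = advance_gates(state, v, dur, params)
            t0 += dur
        if noise is not None and noise.sigma > 0:
            current = current + rng.normal(0.0, noise.sigma, size=n_samples)
        sweeps[i] = current

    meta = {"label": params.label}
    if noise is not None:
        meta.update(sigma=noise.sigma, leak_conductance=noise.leak_conductance,
                    seed=noise.seed)
    if conc is not None:
        meta["concentration_uM"] = conc
    return TraceSet(
        time=t,
        sweeps=sweeps,
        sweep_voltages=np.asarray(protocol.test_voltages, dtype=float),
        protocol=protocol,
        metadata=meta,
    )
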