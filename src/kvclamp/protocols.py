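"""Step-protocol and trace containers plus the standard Kv11.1 clamp protocols.

A :class:`StepProtocol` is a piecewise-constant voltage command: a holding
potential followed by an ordered list of epochs.  Exactly one epoch may be
the sweep-variable epoch (marked ``SWEEP``) whose voltage is taken from
``sweep_voltages``; protocols without a variable epoch have a single sweep.

The five canonical protocols used to characterize Kv11.1 gating are
provided as builders: activation (tail at -120 mV), fully-activated I-V,
inactivation onset, deactivation and the repeated-depolarization
pharmacology protocol.  Epoch durations are defaults chosen so quasi
steady state is reached within each epoch (>=5 relaxation times at the
relevant voltages); they are not experimental values and are adjustable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Sequence, Tuple, Union

import numpy as np

__all__ = [
    "SWEEP",
    "StepProtocol",
    "TraceSet",
    "activation_protocol",
    "fully_activated_iv_protocol",
    "inactivation_onset_protocol",
    "deactivation_protocol",
    "pharmacology_protocol",
]

SWEEP = "SWEEP"
EpochVoltage = Union[float, str]


@dataclass(frozen=True)
class StepProtocol:
    holding: float                       # mV
    epochs: Tuple[Tuple[EpochVoltage, float], ...]  # (voltage mV | SWEEP, duration ms)
    sweep_voltages: Tuple[float, ...] = ()
    sampling_rate: float = 2000.0        # Hz
    inter_sweep_interval: float = 10000.0  # ms at holding between sweeps
    name: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "epochs", tuple((v, float(d)) for v, d in self.epochs))
        object.__setattr__(self, "sweep_voltages",
                           tuple(float(v) for v in self.sweep_voltages))
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be > 0")
        if any(d <= 0 for _, d in self.epochs):
            raise ValueError("epoch durations must be > 0")
        n_var = sum(1 for v, _ in self.epochs if isinstance(v, str))
        if any(isinstance(v, str) and v != SWEEP for v, _ in self.epochs):
            raise ValueError("symbolic epoch voltage must be 'SWEEP'")
        if self.sweep_voltages:
            if n_var != 1:
                raise ValueError("exactly one SWEEP epoch required with sweep_voltages")
        elif n_var:
            raise ValueError("SWEEP epoch requires non-empty sweep_voltages")

    @property
    def n_sweeps(self) -> int:
        return max(1, len(self.sweep_voltages))

    @property
    def variable_epoch_index(self) -> int:
        """Index of the SWEEP epoch, or -1 if the protocol has none."""
        for i, (v, _) in enumerate(self.epochs):
            if isinstance(v, str):
                return i
        return -1

    @property
    def test_voltages(self) -> Tuple[float, ...]:
        """Per-sweep voltage of the variable epoch (holding if none)."""
        if self.sweep_voltages:
            return self.sweep_voltages
        return (self.holding,)

    @property
    def total_duration(self) -> float:
        return float(sum(d for _, d in self.epochs))

    def resolve_sweep(self, sweep: int) -> List[Tuple[float, float]]:
        """Concrete (voltage, duration) list for one sweep."""
        out = []
        for v, d in self.epochs:
            if isinstance(v, str):
                v = self.sweep_voltages[sweep]
            out.append((float(v), d))
        return out

    def epoch_bounds(self, epoch_index: int) -> Tuple[float, float]:
        """(start ms, end ms) of an epoch on the sweep time base."""
        start = sum(d for _, d in self.epochs[:epoch_index])
        return float(start), float(start + self.epochs[epoch_index][1])

    def epoch_sample_slice(self, epoch_index: int) -> slice:
        """Slice of the sample grid covered by an epoch."""
        dt = 1000.0 / self.sampling_rate
        start, end = self.epoch_bounds(epoch_index)
        n_total = int(round(self.total_duration / dt))
        return slice(int(np.ceil(start / dt - 1e-9)),
                     min(n_total, int(np.ceil(end / dt - 1e-9))))

    # --- plain-text serialization (one epoch per line) ------------------
    def to_text(self) -> str:
        lines = [
            "# kvclamp step protocol",
            f"name: {self.name}",
            f"holding_mV: {self.holding:g}",
            f"sampling_rate_Hz: {self.sampling_rate:g}",
            f"inter_sweep_interval_ms: {self.inter_sweep_interval:g}",
        ]
        if self.sweep_voltages:
            lines.append("sweep_voltages_mV: "
                         + " ".join(f"{v:g}" for v in self.sweep_voltages))
        for v, d in self.epochs:
            vtxt = SWEEP if isinstance(v, str) else f"{v:g}"
            lines.append(f"epoch: {vtxt} {d:g}")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_text(cls, text: str) -> "StepProtocol":
        kw = {"name": "", "sweep_voltages": ()}
        epochs = []
        for raw in text.splitlines():
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            key, _, val = line.partition(":")
            key, val = key.strip(), val.strip()
            if key == "name":
                kw["name"] = val
            elif key == "holding_mV":
                kw["holding"] = float(val)
            elif key == "sampling_rate_Hz":
                kw["sampling_rate"] = float(val)
            elif key == "inter_sweep_interval_ms":
                kw["inter_sweep_interval"] = float(val)
            elif key == "sweep_voltages_mV":
                kw["sweep_voltages"] = tuple(float(x) for x in val.split())
            elif key == "epoch":
                vtxt, dtxt = val.split()
                v = SWEEP if vtxt == SWEEP else float(vtxt)
                epochs.append((v, float(dtxt)))
            else:
                raise ValueError(f"unknown protocol key: {key!r}")
        if "holding" not in kw:
            raise ValueError("protocol text missing holding_mV")
        if not epochs:
            raise ValueError("protocol text has no epochs")
        return cls(epochs=tuple(epochs), **kw)


@dataclass
class TraceSet:
    """A family of current sweeps sharing one protocol and time base.

    ``time`` in ms, ``sweeps`` shaped (n_sweeps, n_samples) in uA.
    """

    time: np.ndarray
    sweeps: np.ndarray
    sweep_voltages: np.ndarray
    protocol: StepProtocol
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.sweeps = np.atleast_2d(np.asarray(self.sweeps, dtype=float))
        self.sweep_voltages = np.asarray(self.sweep_voltages, dtype=float)
        if self.sweeps.shape[1] != self.time.size:
            raise ValueError("sweeps and time base disagree in sample count")
        if self.sweeps.shape[0] != self.sweep_voltages.size:
            raise ValueError("one test voltage per sweep required")

    @property
    def n_sweeps(self) -> int:
        return self.sweeps.shape[0]

    def epoch_segment(self, epoch_index: int) -> Tuple[np.ndarray, np.ndarray]:
        """(local time ms from epoch start, currents (n_sweeps, n)) of an epoch."""
        sl = self.protocol.epoch_sample_slice(epoch_index)
        start, _ = self.protocol.epoch_bounds(epoch_index)
        return self.time[sl] - start, self.sweeps[:, sl]


def _steps(v_min: float, v_max: float, step: float) -> Tuple[float, ...]:
    n = int(round((v_max - v_min) / step)) + 1
    return tuple(v_min + i * step for i in range(n))


def activation_protocol(v_min: float = -60.0, v_max: float = 40.0, step: float = 10.0,
                        step_duration: float = 4000.0, tail_duration: float = 2000.0,
                        sampling_rate: float = 2000.0) -> StepProtocol:
    """Depolarizing family from -80 mV holding with a -120 mV tail.

    Peak tail currents at -120 mV report channel activation at the
    preceding test potential; steps below -60 mV evoke no time-dependent
    current, hence the default range -60..+40 mV.
    """
    if v_min >= v_max:
        raise ValueError("v_min must be < v_max")
    if step <= 0:
        raise ValueError("step must be > 0")
    return StepProtocol(
        holding=-80.0,
        epochs=((SWEEP, step_duration), (-120.0, tail_duration)),
        sweep_voltages=_steps(v_min, v_max, step),
        sampling_rate=sampling_rate,
        name="activation",
    )


def fully_activated_iv_protocol(step_duration: float = 2000.0,
                                tail_duration: float = 1000.0,
                                sampling_rate: float = 2000.0) -> StepProtocol:
    """+40 mV activating step, then tails spanning -120..+40 mV."""
    return StepProtocol(
        holding=-80.0,
        epochs=((40.0, step_duration), (SWEEP, tail_duration)),
        sweep_voltages=_steps(-120.0, 40.0, 10.0),
        sampling_rate=sampling_rate,
        name="fully_activated_iv",
    )


def inactivation_onset_protocol(recovery_duration: float = 20.0,
                                test_duration: float = 500.0,
                                sampling_rate: float = 2000.0) -> StepProtocol:
    """+20 mV activation, brief -120 mV step to release inactivation,
    then test steps -20..+40 mV over which inactivation re-develops.

    The -120 mV epoch is kept much shorter than the deactivation time
    constant so the activation gate stays essentially open.
    """
    return StepProtocol(
        holding=-80.0,
        epochs=((20.0, 2000.0), (-120.0, recovery_duration), (SWEEP, test_duration)),
        sweep_voltages=_steps(-20.0, 40.0, 10.0),
        sampling_rate=sampling_rate,
        name="inactivation_onset",
    )


def deactivation_protocol(tail_duration: float = 8000.0,
                          sampling_rate: float = 2000.0) -> StepProtocol:
    """+20 mV activation followed by hyperpolarizing steps -100..-70 mV."""
    return StepProtocol(
        holding=-80.0,
        epochs=((20.0, 2000.0), (SWEEP, tail_duration)),
        sweep_voltages=_steps(-100.0, -70.0, 10.0),
        sampling_rate=sampling_rate,
        name="deactivation",
    )


def pharmacology_protocol(n_repeats: int = 1, step_duration: float = 4000.0,
                          tail_duration: float = 2000.0,
                          sampling_rate: float = 2000.0) -> StepProtocol:
    """Repeated 0 mV depolarizations from -80 mV; tail measured at -80 mV."""
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    epochs = []
    for _ in range(n_repeats):
        epochs += [(0.0, step_duration), (-80.0, tail_duration)]
    return StepProtocol(
        holding=-80.0,
        epochs=tuple(epochs),
        sampling_rate=sampling_rate,
        name="pharmacology",
    )
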