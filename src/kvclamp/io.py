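"""File I/O, replicate statistics and the end-to-end analysis pipeline.

Trace files use either a tab-delimited ATF-dialect (the text trace format
of common acquisition software: a two-line signature, quoted header
records, column titles, then the numeric body) or an equivalent CSV with
``# key=value`` comment lines.  Both embed the full step protocol so a
file round-trips to an identical :class:`~kvclamp.protocols.TraceSet`.

Replicate aggregation follows the outlier convention of the source
experiments: at most one value farther than three standard deviations
from the mean (computed on the full set) is removed, and quantities are
reported as mean +/- SEM.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
import yaml

from . import analysis, pharm, wedge
from .model import ChannelParams, NoiseSpec, apply_kcne2, simulate_protocol
from .presets import load_block, load_params
from .protocols import (SWEEP, StepProtocol, TraceSet, activation_protocol,
                        deactivation_protocol, fully_activated_iv_protocol,
                        inactivation_onset_protocol)

__all__ = ["write_traceset", "read_traceset", "write_protocol", "read_protocol",
           "ReplicateSummary", "summarize_replicates", "RunConfig", "run_pipeline"]

log = logging.getLogger("kvclamp")

_ATF_SIGNATURE = "ATF\t1.0"
_UNITS = "ms,uA"


# --------------------------------------------------------------------------
# trace files
# --------------------------------------------------------------------------

def _header_records(traces: TraceSet) -> List[str]:
    proto = traces.protocol
    rec = [
        "Signature=kvclamp TraceSet",
        f"Name={proto.name}",
        f"Holding_mV={proto.holding:g}",
        f"SamplingRate_Hz={proto.sampling_rate:g}",
        f"InterSweepInterval_ms={proto.inter_sweep_interval:g}",
        f"Units={_UNITS}",
    ]
    if proto.sweep_voltages:
        rec.append("SweepVoltages_mV=" + ",".join(f"{v:g}" for v in proto.sweep_voltages))
    for v, d in proto.epochs:
        vtxt = SWEEP if isinstance(v, str) else f"{v:g}"
        rec.append(f"Epoch={vtxt} {d:g}")
    if traces.metadata:
        rec.append("Meta=" + json.dumps(traces.metadata, sort_keys=True, default=str))
    return rec


def _protocol_from_records(records: dict) -> Tuple[StepProtocol, dict]:
    if records.get("Units") != _UNITS:
        raise ValueError(f"unit mismatch: expected {_UNITS!r}, file says "
                         f"{records.get('Units')!r}")
    epochs = []
    for e in records["Epoch"]:
        vtxt, dtxt = e.split()
        epochs.append((SWEEP if vtxt == SWEEP else float(vtxt), float(dtxt)))
    sweep_v = ()
    if "SweepVoltages_mV" in records:
        sweep_v = tuple(float(x) for x in records["SweepVoltages_mV"][0].split(","))
    proto = StepProtocol(
        holding=float(records["Holding_mV"][0]),
        epochs=tuple(epochs),
        sweep_voltages=sweep_v,
        sampling_rate=float(records["SamplingRate_Hz"][0]),
        inter_sweep_interval=float(records["InterSweepInterval_ms"][0]),
        name=records.get("Name", [""])[0],
    )
    meta = json.loads(records["Meta"][0]) if "Meta" in records else {}
    return proto, meta


def write_traceset(traces: TraceSet, path: Union[str, Path],
                   fmt: Optional[str] = None) -> Path:
    """Write a TraceSet as ATF-dialect (.atf) or CSV (.csv) text."""
    path = Path(path)
    fmt = fmt or path.suffix.lstrip(".").lower()
    cols = [f"Sweep {i + 1:02d} {v:g} mV"
            for i, v in enumerate(traces.sweep_voltages)]
    body = pd.DataFrame(traces.sweeps.T, columns=cols)
    body.insert(0, "Time (ms)", traces.time)
    records = _header_records(traces)
    if fmt == "atf":
        lines = [_ATF_SIGNATURE, f"{len(records)}\t{body.shape[1]}"]
        lines += [f'"{r}"' for r in records]
        lines.append("\t".join(f'"{c}"' for c in body.columns))
        data = body.to_csv(sep="\t", index=False, header=False,
                           float_format="%.17g")
        path.write_text("\n".join(lines) + "\n" + data)
    elif fmt == "csv":
        lines = [f"# {r}" for r in records]
        data = body.to_csv(index=False, float_format="%.17g")
        path.write_text("\n".join(lines) + "\n" + data)
    else:
        raise ValueError(f"unknown trace format {fmt!r} (use 'atf' or 'csv')")
    return path


def _collect_records(raw: Sequence[str]) -> dict:
    rec: dict = {}
    for r in raw:
        key, sep, val = r.partition("=")
        if not sep:
            raise ValueError(f"malformed header record {r!r}")
        if key == "Units":
            rec[key] = val
        else:
            rec.setdefault(key, []).append(val)
    return rec


def read_traceset(path: Union[str, Path], fmt: Optional[str] = None) -> TraceSet:
    """Read an ATF-dialect or CSV trace file back into a TraceSet."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = fmt or path.suffix.lstrip(".").lower()
    text = path.read_text()
    lines = text.splitlines()
    if fmt == "atf":
        if not lines or lines[0] != _ATF_SIGNATURE:
            raise ValueError("not an ATF file: missing 'ATF\\t1.0' signature line")
        try:
            n_rec, n_cols = (int(x) for x in lines[1].split("\t"))
        except Exception as err:
            raise ValueError("malformed ATF dimension line") from err
        raw = [ln.strip().strip('"') for ln in lines[2:2 + n_rec]]
        records = _collect_records(raw)
        titles = [c.strip('"') for c in lines[2 + n_rec].split("\t")]
        if len(titles) != n_cols:
            raise ValueError(f"column count mismatch: header says {n_cols}, "
                             f"title row has {len(titles)}")
        body = pd.read_csv(path, sep="\t", skiprows=3 + n_rec, header=None,
                           names=titles, float_precision="round_trip")
    elif fmt == "csv":
        raw = []
        for ln in lines:
            if ln.startswith("# "):
                raw.append(ln[2:])
            else:
                break
        records = _collect_records(raw)
        body = pd.read_csv(path, comment="#", float_precision="round_trip")
        titles = list(body.columns)
    else:
        raise ValueError(f"unknown trace format {fmt!r}")
    if "Time (ms)" not in titles:
        raise ValueError("missing column 'Time (ms)'")
    if body.isna().any().any():
        raise ValueError("ragged or non-numeric data body")
    proto, meta = _protocol_from_records(records)
    sweep_cols = [c for c in titles if c != "Time (ms)"]
    expected = proto.n_sweeps
    if len(sweep_cols) != expected:
        raise ValueError(f"missing sweep column: expected {expected} sweeps, "
                         f"found {len(sweep_cols)}")
    voltages = proto.test_voltages
    return TraceSet(
        time=body["Time (ms)"].to_numpy(),
        sweeps=body[sweep_cols].to_numpy().T,
        sweep_voltages=np.asarray(voltages, dtype=float),
        protocol=proto,
        metadata=meta,
    )


def write_protocol(protocol: StepProtocol, path: Union[str, Path]) -> Path:
    path = Path(path)
    path.write_text(protocol.to_text())
    return path


def read_protocol(path: Union[str, Path]) -> StepProtocol:
    return StepProtocol.from_text(Path(path).read_text())


# --------------------------------------------------------------------------
# replicate statistics
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ReplicateSummary:
    mean: float
    sem: float
    n: int
    n_removed: int
    removed: Tuple[float, ...] = ()


def summarize_replicates(values: Sequence[float]) -> ReplicateSummary:
    """Mean +/- SEM after removing at most one >3 SD outlier.

    The outlier criterion uses the mean and SD of the full set (sample SD,
    including the candidate itself); only the single most extreme value can
    be removed.
    """
    vals = np.asarray(list(values), dtype=float)
    if vals.size < 2:
        raise ValueError("need at least 2 replicate values")
    mean_all = vals.mean()
    sd_all = vals.std(ddof=1)
    removed: Tuple[float, ...] = ()
    keep = vals
    if sd_all > 0:
        idx = int(np.argmax(np.abs(vals - mean_all)))
        if np.abs(vals[idx] - mean_all) > 3.0 * sd_all:
            removed = (float(vals[idx]),)
            keep = np.delete(vals, idx)
    sem = keep.std(ddof=1) / np.sqrt(keep.size) if keep.size > 1 else 0.0
    return ReplicateSummary(mean=float(keep.mean()), sem=float(sem),
                            n=int(keep.size), n_removed=len(removed),
                            removed=removed)


# --------------------------------------------------------------------------
# pipeline
# --------------------------------------------------------------------------

_CONFIG_KEYS = {"param_set", "seed", "replicates", "sigma", "leak_conductance",
                "outdir", "kcne2_reduction", "n_beats"}


@dataclass(frozen=True)
class RunConfig:
    param_set: str = "equine"
    seed: int = 0
    replicates: int = 1
    sigma: float = 0.0              # uA additive noise; 0 = noiseless
    leak_conductance: float = 0.0   # uS
    outdir: str = "kvclamp_out"
    kcne2_reduction: float = 0.423
    n_beats: int = 8

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValueError("replicate count must be >= 1")

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(d) - _CONFIG_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def _noise(cfg: RunConfig, rep: int) -> Optional[NoiseSpec]:
    if cfg.sigma == 0 and cfg.leak_conductance == 0:
        return None
    return NoiseSpec(sigma=cfg.sigma, leak_conductance=cfg.leak_conductance,
                     seed=cfg.seed + 1000 * rep)


def run_pipeline(config: RunConfig) -> dict:
    """Simulate, analyze and aggregate the full experiment suite.

    Writes tidy CSV tables and a machine-readable ``summary.json`` (recovered
    parameters vs simulator ground truth, per-stage seeds, config hash) to
    ``config.outdir`` and returns the summary as a dict.  Any stage failure
    aborts with a stage-named error.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    params = load_params(config.param_set)
    scalars: dict = {k: [] for k in
                     ("v_half_act", "k_act", "g_max", "e_rev", "v_half_inact",
                      "ic50_steady", "ic50_tail")}
    act_taus, onset_taus, deact_rows, ssiv_frames = [], [], [], []

    def stage(name, fn, *a, **kw):
        try:
            res = fn(*a, **kw)
        except Exception as err:
            raise RuntimeError(f"pipeline stage {name!r} failed: {err}") from err
        log.info("stage=%s param_set=%s seed=%s done", name, config.param_set,
                 config.seed)
        return res

    # extremum peaks are exact on clean sweeps; under noise the
    # hook-regression amplitude avoids extremum-selection bias
    tail_method = "hook_fit" if config.sigma > 0 else "peak"
    for rep in range(config.replicates):
        noise = _noise(config, rep)
        tr_act = stage("simulate_activation", simulate_protocol,
                       activation_protocol(), params, noise)
        boltz = stage("activation_curve", analysis.activation_curve,
                      analysis.peak_tail_table(tr_act, method=tail_method))
        scalars["v_half_act"].append(boltz.v_half)
        scalars["k_act"].append(boltz.k)
        act_taus.append(stage("activation_taus", analysis.activation_tau_table, tr_act))
        ssiv_frames.append(stage("steady_state_iv", analysis.steady_state_iv, tr_act))

        tr_iv = stage("simulate_fully_activated_iv", simulate_protocol,
                      fully_activated_iv_protocol(), params, noise)
        iv = stage("fully_activated_iv", analysis.fully_activated_iv, tr_iv,
                   method=tail_method)
        scalars["g_max"].append(iv.g)
        scalars["e_rev"].append(iv.e_rev)
        rect = stage("rectification", analysis.rectification_curve, iv)
        scalars["v_half_inact"].append(rect.boltzmann.v_half)

        tr_on = stage("simulate_inactivation_onset", simulate_protocol,
                      inactivation_onset_protocol(), params, noise)
        onset_taus.append(stage("onset_taus", analysis.inactivation_onset_taus, tr_on))

        tr_de = stage("simulate_deactivation", simulate_protocol,
                      deactivation_protocol(), params, noise)
        deact_rows.append(stage("deactivation", analysis.deactivation_tables, tr_de))

        dr = stage("dose_response", pharm.run_block_series, params,
                   load_block("terfenadine_steady"), pharm.DEFAULT_CONCENTRATIONS,
                   noise, tail_method=tail_method)
        scalars["ic50_steady"].append(
            stage("fit_dose_steady", pharm.fit_dose_response, dr,
                  "fraction_steady_state").ic50)
        dr_tail = stage("dose_response_tail", pharm.run_block_series, params,
                        load_block("terfenadine_tail"), pharm.DEFAULT_CONCENTRATIONS,
                        noise, tail_method=tail_method)
        scalars["ic50_tail"].append(
            stage("fit_dose_tail", pharm.fit_dose_response, dr_tail,
                  "fraction_tail").ic50)

    # KCNE2 comparison on the last replicate's noise settings (noiseless default)
    params_k = apply_kcne2(params, config.kcne2_reduction)
    ss_ctrl = analysis.steady_state_iv(simulate_protocol(activation_protocol(), params))
    ss_k = analysis.steady_state_iv(simulate_protocol(activation_protocol(), params_k))
    kcne2 = pd.DataFrame({
        "voltage_mV": ss_ctrl["voltage_mV"],
        "current_control_uA": ss_ctrl["current_uA"],
        "current_kcne2_uA": ss_k["current_uA"],
        "percent_reduction": 100.0 * (1.0 - ss_k["current_uA"] / ss_ctrl["current_uA"]),
    })

    wtab = stage("wedge", wedge.rate_dependence_table, wedge.APParams(),
                 wedge.DEFAULT_BCLS, config.n_beats)

    # aggregate & write
    def agg(vals):
        if len(vals) == 1:
            return {"mean": float(vals[0]), "sem": 0.0, "n": 1, "n_removed": 0}
        s = summarize_replicates(vals)
        return {"mean": s.mean, "sem": s.sem, "n": s.n, "n_removed": s.n_removed}

    truth = {"v_half_act": params.v_half_act, "k_act": params.k_act,
             "g_max": params.g_max, "e_rev": params.e_rev,
             "v_half_inact": params.v_half_inact,
             "ic50_steady": load_block("terfenadine_steady").ic50,
             "ic50_tail": load_block("terfenadine_tail").ic50}
    summary = {
        "param_set": config.param_set,
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "replicates": config.replicates,
        "recovered": {k: agg(v) for k, v in scalars.items()},
        "ground_truth": truth,
    }

    def mean_table(frames):
        cat = pd.concat(frames)
        num = cat.select_dtypes("number")
        return num.groupby(cat["voltage_mV"].values).mean().reset_index(drop=True)

    mean_table(act_taus).to_csv(out / "activation_taus.csv", index=False)
    mean_table(onset_taus).to_csv(out / "inactivation_onset_taus.csv", index=False)
    mean_table(deact_rows).to_csv(out / "deactivation.csv", index=False)
    mean_table(ssiv_frames).to_csv(out / "steady_state_iv.csv", index=False)
    kcne2.to_csv(out / "kcne2.csv", index=False)
    dr.merge(dr_tail, on="concentration_uM", suffixes=("_steady", "_tail")) \
        .to_csv(out / "dose_response.csv", index=False)
    wtab.to_csv(out / "wedge.csv", index=False)
    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    log.info("pipeline complete outdir=%s hash=%s", out, summary["config_hash"])
    return summary
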