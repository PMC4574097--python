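import numpy as np
import pytest

import kvclamp as kv


@pytest.fixture(scope="session")
def equine():
    return kv.load_params("equine")


@pytest.fixture(scope="session")
def human():
    return kv.load_params("human")


@pytest.fixture(scope="session")
def tr_act_equine(equine):
    """Noiseless activation-protocol sweeps, equine parameter set."""
    return kv.simulate_protocol(kv.activation_protocol(), equine)


@pytest.fixture(scope="session")
def tr_act_human(human):
    return kv.simulate_protocol(kv.activation_protocol(), human)


@pytest.fixture(scope="session")
def tr_iv_equine(equine):
    """Noiseless fully-activated I-V sweeps, equine parameter set."""
    return kv.simulate_protocol(kv.fully_activated_iv_protocol(), equine)


@pytest.fixture(scope="session")
def tr_onset_equine(equine):
    return kv.simulate_protocol(kv.inactivation_onset_protocol(), equine)


@pytest.fixture(scope="session")
def tr_deact_equine(equine):
    return kv.simulate_protocol(kv.deactivation_protocol(), equine)


@pytest.fixture()
def simple_params():
    """Single-population channel with flat, well-separated kinetics."""
    return kv.ChannelParams(
        g_max=100.0, e_rev=-100.0, v_half_act=-20.0, k_act=8.0,
        v_half_inact=-55.0, k_inact=25.0,
        tau_act_spec=kv.TauSpec(tau_min=50.0, tau_amp=400.0, v_peak=-40.0,
                                s_depol=25.0, s_hyper=40.0),
        tau_inact_spec=kv.TauSpec(tau_min=1.0, tau_amp=10.0, v_peak=0.0,
                                  s_depol=30.0, s_hyper=30.0),
        label="simple",
    )


def euler_gate_oracle(protocol, params, sweep, n_fine=1000):
    """Explicit-Euler integration of the gate ODEs at an n_fine-times finer
    step; returns gate values at the protocol's sample times.

    Independent of the closed-form path: steps dx = dt*(x_inf - x)/tau(V).
    """
    dt = 1000.0 / protocol.sampling_rate
    h = dt / n_fine
    segs = protocol.resolve_sweep(sweep)
    n = kv.steady_state_activation(protocol.holding, params)
    r = kv.steady_state_availability(protocol.holding, params)
    ns = n
    t_samples, out = [], []
    t = 0.0
    next_sample = 0.0
    for v, dur in segs:
        n_inf = kv.steady_state_activation(v, params)
        r_inf = kv.steady_state_availability(v, params)
        tau_n = float(params.tau_act_spec(v))
        tau_r = float(params.tau_inact_spec(v))
        tau_ns = float(params.tau_act_slow(v)) if params.two_population else None
        steps = int(round(dur / h))
        for _ in range(steps):
            if t >= next_sample - 1e-9:
                t_samples.append(t)
                out.append((n, ns, r, v))
                next_sample += dt
            n += h * (n_inf - n) / tau_n
            r += h * (r_inf - r) / tau_r
            if tau_ns is not None:
                ns += h * (n_inf - ns) / tau_ns
            t += h
    return np.array(t_samples), out
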