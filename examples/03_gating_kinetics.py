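"""Activation, inactivation-onset and deactivation kinetics.

Runs the three kinetic protocols on the equine set and prints the fitted
time constants: mono-exponential activation (first 500 ms, -20..+20 mV
only), mono-exponential inactivation onset (-20..+40 mV after a brief
release step) and bi-exponential deactivation (-100..-70 mV).
"""

import kvclamp as kv

params = kv.load_params("equine")

act = kv.activation_tau_table(
    kv.simulate_protocol(kv.activation_protocol(), params))
print("Activation tau (ms) vs voltage (reflects activation overlapping with")
print("inactivation, which is why the analysis stops at +20 mV):")
print(act[["voltage_mV", "tau_ms"]].round(1).to_string(index=False))

onset = kv.inactivation_onset_taus(
    kv.simulate_protocol(kv.inactivation_onset_protocol(), params))
print("\nInactivation onset tau (ms): a few milliseconds, faster with")
print("depolarization -- two orders of magnitude faster than activation:")
print(onset[["voltage_mV", "tau_ms"]].round(2).to_string(index=False))

deact = kv.deactivation_tables(
    kv.simulate_protocol(kv.deactivation_protocol(), params))
print("\nBi-exponential deactivation: fast/slow tau (ms) and fast weight;")
print("the fast component dominates at more hyperpolarized potentials:")
print(deact[["voltage_mV", "tau_fast_ms", "tau_slow_ms", "weight_fast"]]
      .round(2).to_string(index=False))
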