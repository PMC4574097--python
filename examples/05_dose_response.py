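"""Terfenadine block: simulated concentration series and Hill fit.

Simulates the repeated 0 mV depolarization protocol at seven terfenadine
concentrations, forms fractional currents I_drug/I_control from the
steady-state current and from the peak tail, and fits the Hill
dose-response model on log-transformed concentration to obtain the IC50.
"""

import kvclamp as kv

params = kv.load_params("equine")

for label, block_name, column in (
        ("steady-state", "terfenadine_steady", "fraction_steady_state"),
        ("peak tail", "terfenadine_tail", "fraction_tail")):
    series = kv.run_block_series(params, kv.load_block(block_name))
    fit = kv.fit_dose_response(series, column)
    print(f"{label} readout:")
    print(series.round(4).to_string(index=False))
    print(f"  IC50 = {fit.ic50:.3g} uM, Hill coefficient = {fit.hill:.3g}\n")

print("IC50 is the concentration that halves the current.  Sub-micromolar")
print("block of Kv11.1 by an antihistamine is the classic mechanism of")
print("drug-acquired long QT syndrome.")
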