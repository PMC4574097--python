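# Hill block parameter sets for terfenadine on equine Kv11.1.
# Two entries because the half-blocking concentration differs slightly
# depending on whether block is read from the steady-state current at the
# end of the 0 mV step or from the peak tail at -80 mV.
terfenadine_steady:
  ic50: 0.42   # uM
  hill: 1.0
terfenadine_tail:
  ic50: 0.37   # uM
  hill: 1.0
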