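# Equine Kv11.1 co-expressed with the KCNE2 beta-subunit: identical gating,
# steady-state current reduced by 42.3% (pure conductance scaling).
base: equine
kcne2_reduction: 0.423
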