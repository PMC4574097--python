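# Equine Kv11.1 parameter set.
# g_max, e_rev, v_half_act, k_act come from fitted two-electrode voltage-clamp
# measurements of the equine channel; everything else (inactivation Boltzmann,
# time-constant surfaces, deactivation populations) is a phenomenological
# calibration of the simulator -- see docs/methods.md.
label: equine
g_max: 159.0          # uS, maximal tail conductance
e_rev: -103.0         # mV, reversal potential
v_half_act: -17.3     # mV, activation midpoint
k_act: 8.1            # mV, activation slope
v_half_inact: 3.5     # mV, availability midpoint (not-from-experiment)
k_inact: 20.0         # mV, availability slope (not-from-experiment)
tau_act:              # ms; fast activation/deactivation population (not-from-experiment)
  tau_min: 35.0
  tau_amp: 1600.0
  v_peak: -30.0       # mV
  s_depol: 18.0       # mV
  s_hyper: 45.0       # mV
tau_act_slow:         # ms; excess slowing of the slow deactivation population (not-from-experiment)
  tau_min: 15.0
  tau_amp: 4800.0
  v_peak: -85.0
  s_depol: 15.0
  s_hyper: 30.0
w_fast:               # fast-population weight vs voltage (not-from-experiment)
  w_min: 0.35
  w_max: 0.90
  v_half: -80.0       # mV
  k: 12.0             # mV
tau_inact:            # ms; inactivation onset/recovery, 1.5x slower than human
  tau_min: 0.6
  tau_amp: 14.0
  v_peak: -26.0
  s_depol: 25.0
  s_hyper: 12.0
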