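# Human Kv11.1 parameter set.
# g_max, e_rev, v_half_act, k_act come from fitted two-electrode voltage-clamp
# measurements of the human channel; activation kinetics are shared with the
# equine set (no measurable difference), inactivation onset is 1.5x faster.
label: human
g_max: 234.0          # uS
e_rev: -104.0         # mV
v_half_act: -14.2     # mV
k_act: 9.6            # mV
v_half_inact: 3.5     # mV (not-from-experiment)
k_inact: 20.0         # mV (not-from-experiment)
tau_act:
  tau_min: 35.0
  tau_amp: 1600.0
  v_peak: -30.0
  s_depol: 18.0
  s_hyper: 45.0
tau_act_slow:
  tau_min: 15.0
  tau_amp: 4800.0
  v_peak: -85.0
  s_depol: 15.0
  s_hyper: 30.0
w_fast:
  w_min: 0.35
  w_max: 0.90
  v_half: -80.0
  k: 12.0
tau_inact:            # ms; equine values / 1.5
  tau_min: 0.4
  tau_amp: 9.3333
  v_peak: -26.0
  s_depol: 25.0
  s_hyper: 12.0
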