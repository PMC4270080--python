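channels:
  H:
    e_rev: -30.0
    gates:
      l:
        exponent: 1
        k: 8.0
        kind: hyperpolarization_activated
        tau_amp: 40.0
        tau_k: 12.0
        tau_min: 20.0
        tau_vhalf: -75.0
        vhalf: -82.0
  KA:
    e_rev: -90.0
    gates:
      a:
        exponent: 1
        k: 11.5
        kind: activation
        tau_amp: 1.0
        tau_k: 10.0
        tau_min: 0.5
        tau_vhalf: -30.0
        vhalf: 11.0
      b:
        exponent: 1
        k: 8.0
        kind: inactivation
        tau_amp: 18.0
        tau_k: -8.0
        tau_min: 6.0
        tau_vhalf: -60.0
        vhalf: -56.0
  Kdr:
    e_rev: -90.0
    gates:
      n:
        exponent: 1
        k: 10.0
        kind: activation
        tau_amp: 3.0
        tau_k: 12.0
        tau_min: 1.0
        tau_vhalf: -30.0
        vhalf: -5.0
  Na:
    e_rev: 55.0
    gates:
      h:
        exponent: 1
        k: 4.0
        kind: inactivation
        tau_amp: 12.0
        tau_k: 6.0
        tau_min: 1.0
        tau_vhalf: -55.0
        vhalf: -47.0
      m:
        exponent: 3
        k: 6.0
        kind: activation
        tau_amp: 0.25
        tau_k: 10.0
        tau_min: 0.08
        tau_vhalf: -30.0
        vhalf: -38.0
version: 1
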