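# Versioned parameter presets for the thalamocortical SWD model.
version: 1
presets:
  taylor2016-default:
    model:
      eps1: -0.35
      eps2: -3.4
      eps3: -4.4
      eps4: -2.0
      eps5: -5.0
      tau1: 26.0
      tau2: 32.5        # 26 * 1.25
      tau3: 0.13        # 26 * 0.005  (slow GABA_B-like population IN2)
      tau4: 2.6         # 26 * 0.1
      tau5: 2.6         # 26 * 0.1
      k1: 1.8           # PY -> PY
      k2: 1.5           # IN1 -> PY
      k3: 0.03          # IN2 -> PY
      k4: 1.0           # TC -> PY
      k5: 4.0           # PY -> IN1
      k6: 0.03          # IN2 -> IN1
      k7: 3.0           # PY -> IN2
      k8: 1.5           # IN1 -> IN2
      k9: 0.6           # RE -> TC
      k10: 3.0          # PY -> TC
      k11: 0.2          # RE -> RE
      k12: 10.5         # TC -> RE
      k13: 3.0          # PY -> RE
      nu: 2.5e+5
      alpha: 2.8
      beta: 0.5
    simulation:
      dt: 0.001
      duration: 20.0
      transient_discard: 5.0
      initial_state: [0.1724, 0.1787, 0.1803, -0.0818, 0.2775]
    stimulus:
      mode: jump
      direction: -1.0
      initiation_magnitude: 0.3
      termination_magnitude: 0.2
      t_initiation: 20.0
      t_termination: 35.0
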