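axial_resistivity: 100.0
compartments:
  HH:
    params:
      A: 0.01
      Ca: 0.05
      Cm: 10.0
      V: -60.0
    channels:
      Kd:
        type: Kd
        params:
          E: -80.0
          gbar: 300.0
          m: 0.017252877733533435
      Leak:
        type: Leak
        params:
          E: -50.0
          gbar: 1.0
      NaV:
        type: NaV
        params:
          E: 50.0
          gbar: 1000.0
          h: 0.8949994149797352
          m: 0.001468947445920677
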