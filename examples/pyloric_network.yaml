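axial_resistivity: 100.0
compartments:
  AB:
    params:
      A: 0.0628
      Ca: 0.05
      Cm: 10.0
      V: -60.0
    channels:
      A:
        type: A
        params:
          E: -80.0
          gbar: 500.0
          h: 0.6530907921413984
          m: 0.022530107995424174
      CaS:
        type: CaS
        params:
          E: 30.0
          gbar: 60.0
          h: 0.5
          m: 0.03444519566621117
      CaT:
        type: CaT
        params:
          E: 30.0
          gbar: 25.0
          h: 0.9937737000858555
          m: 0.010257410848182862
      H:
        type: H
        params:
          E: -20.0
          gbar: 0.1
          m: 0.0613831074034922
      KCa:
        type: KCa
        params:
          E: -80.0
          gbar: 50.0
          m: 0.0012254571656942156
      Kd:
        type: Kd
        params:
          E: -80.0
          gbar: 1000.0
          m: 0.017252877733533435
      Leak:
        type: Leak
        params:
          E: -50.0
          gbar: 0.0
      NaV:
        type: NaV
        params:
          E: 50.0
          gbar: 1000.0
          h: 0.8949994149797352
          m: 0.001468947445920677
    mechanisms:
    - type: CalciumMech
      params:
        Ca_0: 0.05
        Ca_out: 3000.0
        T: 11.0
        f: 14.96
        tau_Ca: 200.0
  LP:
    params:
      A: 0.0628
      Ca: 0.05
      Cm: 10.0
      V: -60.0
    channels:
      A:
        type: A
        params:
          E: -80.0
          gbar: 200.0
          h: 0.6530907921413984
          m: 0.022530107995424174
      CaS:
        type: CaS
        params:
          E: 30.0
          gbar: 40.0
          h: 0.5
          m: 0.03444519566621117
      H:
        type: H
        params:
          E: -20.0
          gbar: 0.5
          m: 0.0613831074034922
      KCa:
        type: KCa
        params:
          E: -80.0
          gbar: 0.0
          m: 0.0012254571656942156
      Kd:
        type: Kd
        params:
          E: -80.0
          gbar: 250.0
          m: 0.017252877733533435
      Leak:
        type: Leak
        params:
          E: -50.0
          gbar: 0.3
      NaV:
        type: NaV
        params:
          E: 50.0
          gbar: 1000.0
          h: 0.8949994149797352
          m: 0.001468947445920677
    mechanisms:
    - type: CalciumMech
      params:
        Ca_0: 0.05
        Ca_out: 3000.0
        T: 11.0
        f: 14.96
        tau_Ca: 200.0
  PY:
    params:
      A: 0.0628
      Ca: 0.05
      Cm: 10.0
      V: -60.0
    channels:
      A:
        type: A
        params:
          E: -80.0
          gbar: 500.0
          h: 0.6530907921413984
          m: 0.022530107995424174
      CaS:
        type: CaS
        params:
          E: 30.0
          gbar: 20.0
          h: 0.5
          m: 0.03444519566621117
      CaT:
        type: CaT
        params:
          E: 30.0
          gbar: 25.0
          h: 0.9937737000858555
          m: 0.010257410848182862
      H:
        type: H
        params:
          E: -20.0
          gbar: 0.5
          m: 0.0613831074034922
      Kd:
        type: Kd
        params:
          E: -80.0
          gbar: 1250.0
          m: 0.017252877733533435
      Leak:
        type: Leak
        params:
          E: -50.0
          gbar: 0.1
      NaV:
        type: NaV
        params:
          E: 50.0
          gbar: 1000.0
          h: 0.8949994149797352
          m: 0.001468947445920677
    mechanisms:
    - type: CalciumMech
      params:
        Ca_0: 0.05
        Ca_out: 3000.0
        T: 11.0
        f: 14.96
        tau_Ca: 200.0
synapses:
- type: Cholinergic
  pre: AB
  post: LP
  Delta: 5.0
  E_syn: -80.0
  V_half: -35.0
  gbar: 30.0
  k_minus: 0.01
  s: 0.0066928509242848554
- type: Glutamatergic
  pre: AB
  post: LP
  Delta: 5.0
  E_syn: -70.0
  V_half: -35.0
  gbar: 30.0
  k_minus: 0.025
  s: 0.0066928509242848554
- type: Cholinergic
  pre: AB
  post: PY
  Delta: 5.0
  E_syn: -80.0
  V_half: -35.0
  gbar: 10.0
  k_minus: 0.01
  s: 0.0066928509242848554
- type: Glutamatergic
  pre: AB
  post: PY
  Delta: 5.0
  E_syn: -70.0
  V_half: -35.0
  gbar: 30.0
  k_minus: 0.025
  s: 0.0066928509242848554
- type: Glutamatergic
  pre: LP
  post: AB
  Delta: 5.0
  E_syn: -70.0
  V_half: -35.0
  gbar: 3.0
  k_minus: 0.025
  s: 0.0066928509242848554
- type: Glutamatergic
  pre: LP
  post: PY
  Delta: 5.0
  E_syn: -70.0
  V_half: -35.0
  gbar: 5.0
  k_minus: 0.025
  s: 0.0066928509242848554
- type: Glutamatergic
  pre: PY
  post: LP
  Delta: 5.0
  E_syn: -70.0
  V_half: -35.0
  gbar: 10.0
  k_minus: 0.025
  s: 0.0066928509242848554
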