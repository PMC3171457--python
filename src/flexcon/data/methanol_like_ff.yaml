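cross:
- - theta5
  - phi5
  - 4.0
harmonic:
  b2:
    k: 300.0
    q0: 1.09
  b3:
    k: 300.0
    q0: 1.41
  b4:
    k: 300.0
    q0: 1.09
  b5:
    couplings:
      phi4: 0.01
    k: 300.0
    q0: 1.09
  b6:
    k: 300.0
    q0: 1.09
  phi5:
    couplings:
      phi4: 0.05
    k: 30.0
    q0: 2.0943951023931953
    wrap: true
  phi6:
    k: 30.0
    q0: -2.0943951023931953
    wrap: true
  theta3:
    k: 80.0
    q0: 1.911135530933791
  theta4:
    k: 80.0
    q0: 1.911135530933791
  theta5:
    couplings:
      phi4: 0.03
    k: 80.0
    q0: 1.911135530933791
  theta6:
    couplings:
      phi4: -0.02
    k: 80.0
    q0: 1.911135530933791
seed: 0
torsion:
  phi4:
  - gamma: 0.0
    n: 3
    v: 0.5
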