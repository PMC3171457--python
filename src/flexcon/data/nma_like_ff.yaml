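cross:
- - theta5
  - phi5
  - 3.0
- - b5
  - theta5
  - 2.0
harmonic:
  b10:
    k: 300.0
    q0: 1.09
  b11:
    k: 300.0
    q0: 1.09
  b12:
    k: 300.0
    q0: 1.09
  b2:
    k: 300.0
    q0: 1.09
  b3:
    k: 300.0
    q0: 1.52
  b4:
    k: 300.0
    q0: 1.23
  b5:
    couplings:
      phi4: 0.008
    k: 300.0
    q0: 1.34
  b6:
    k: 300.0
    q0: 1.01
  b7:
    k: 300.0
    q0: 1.45
  b8:
    k: 300.0
    q0: 1.09
  b9:
    k: 300.0
    q0: 1.09
  phi10:
    k: 30.0
    q0: -2.0943951023931953
    wrap: true
  phi11:
    k: 30.0
    q0: 2.0943951023931953
    wrap: true
  phi12:
    k: 30.0
    q0: -2.0943951023931953
    wrap: true
  phi5:
    couplings:
      phi4: 0.05
    k: 30.0
    q0: 3.141592653589793
    wrap: true
  phi7:
    couplings:
      phi6: -0.04
    k: 30.0
    q0: 3.141592653589793
    wrap: true
  phi9:
    couplings:
      phi8: 0.05
    k: 30.0
    q0: 2.0943951023931953
    wrap: true
  theta10:
    k: 80.0
    q0: 1.911135530933791
  theta11:
    couplings:
      phi4: -0.02
    k: 80.0
    q0: 1.911135530933791
  theta12:
    k: 80.0
    q0: 1.911135530933791
  theta3:
    k: 80.0
    q0: 1.911135530933791
  theta4:
    k: 80.0
    q0: 2.111848394913139
  theta5:
    couplings:
      phi4: 0.04
      phi6: 0.02
    k: 80.0
    q0: 2.007128639793479
  theta6:
    k: 80.0
    q0: 2.076941809873252
  theta7:
    couplings:
      phi6: 0.03
    k: 80.0
    q0: 2.111848394913139
  theta8:
    k: 80.0
    q0: 1.911135530933791
  theta9:
    couplings:
      phi8: 0.03
    k: 80.0
    q0: 1.911135530933791
seed: 0
torsion:
  phi4:
  - gamma: 0.0
    n: 3
    v: 0.4
  phi6:
  - gamma: 0.0
    n: 2
    v: 1.0
  phi8:
  - gamma: 0.0
    n: 3
    v: 0.4
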