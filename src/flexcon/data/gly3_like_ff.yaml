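cross:
- - theta9
  - phi9
  - 3.0
harmonic:
  b10:
    k: 300.0
    q0: 1.52
  b11:
    k: 300.0
    q0: 1.09
  b12:
    k: 300.0
    q0: 1.09
  b13:
    k: 300.0
    q0: 1.23
  b14:
    couplings:
      phi13: 0.006
    k: 300.0
    q0: 1.34
  b15:
    k: 300.0
    q0: 1.01
  b16:
    k: 300.0
    q0: 1.45
  b17:
    k: 300.0
    q0: 1.52
  b18:
    k: 300.0
    q0: 1.09
  b19:
    k: 300.0
    q0: 1.09
  b2:
    k: 300.0
    q0: 1.09
  b20:
    k: 300.0
    q0: 1.23
  b21:
    k: 300.0
    q0: 1.34
  b22:
    k: 300.0
    q0: 1.01
  b23:
    k: 300.0
    q0: 1.45
  b24:
    k: 300.0
    q0: 1.52
  b25:
    k: 300.0
    q0: 1.09
  b26:
    k: 300.0
    q0: 1.09
  b27:
    k: 300.0
    q0: 1.23
  b28:
    k: 300.0
    q0: 1.34
  b29:
    k: 300.0
    q0: 1.01
  b3:
    k: 300.0
    q0: 1.52
  b30:
    k: 300.0
    q0: 1.45
  b4:
    k: 300.0
    q0: 1.23
  b5:
    k: 300.0
    q0: 1.09
  b6:
    k: 300.0
    q0: 1.09
  b7:
    k: 300.0
    q0: 1.34
  b8:
    k: 300.0
    q0: 1.01
  b9:
    k: 300.0
    q0: 1.45
  phi11:
    k: 30.0
    q0: 2.0943951023931953
    wrap: true
  phi12:
    k: 30.0
    q0: -2.0943951023931953
    wrap: true
  phi14:
    couplings:
      phi13: 0.05
      phi17: -0.03
    k: 30.0
    q0: 3.141592653589793
    wrap: true
  phi15:
    couplings:
      phi17: 0.05
    k: 30.0
    q0: 0.0
    wrap: true
  phi16:
    k: 30.0
    q0: 3.141592653589793
    wrap: true
  phi18:
    k: 30.0
    q0: 2.0943951023931953
    wrap: true
  phi19:
    k: 30.0
    q0: -2.0943951023931953
    wrap: true
  phi21:
    k: 30.0
    q0: 3.141592653589793
    wrap: true
  phi22:
    couplings:
      phi24: 0.05
    k: 30.0
    q0: 0.0
    wrap: true
  phi23:
    k: 30.0
    q0: 3.141592653589793
    wrap: true
  phi25:
    k: 30.0
    q0: 2.0943951023931953
    wrap: true
  phi26:
    k: 30.0
    q0: -2.0943951023931953
    wrap: true
  phi28:
    couplings:
      phi27: 0.06
    k: 30.0
    q0: 3.141592653589793
    wrap: true
  phi29:
    k: 30.0
    q0: 0.0
    wrap: true
  phi30:
    k: 30.0
    q0: 3.141592653589793
    wrap: true
  phi5:
    k: 30.0
    q0: 2.0943951023931953
    wrap: true
  phi6:
    k: 30.0
    q0: -2.0943951023931953
    wrap: true
  phi7:
    k: 30.0
    q0: 3.141592653589793
    wrap: true
  phi8:
    couplings:
      phi10: 0.06
    k: 30.0
    q0: 0.0
    wrap: true
  phi9:
    k: 30.0
    q0: 3.141592653589793
    wrap: true
  theta10:
    k: 80.0
    q0: 1.9198621771937625
  theta11:
    k: 80.0
    q0: 1.911135530933791
  theta12:
    k: 80.0
    q0: 1.911135530933791
  theta13:
    k: 80.0
    q0: 2.111848394913139
  theta14:
    couplings:
      phi13: 0.04
    k: 80.0
    q0: 2.007128639793479
  theta15:
    k: 80.0
    q0: 2.076941809873252
  theta16:
    k: 80.0
    q0: 2.111848394913139
  theta17:
    k: 80.0
    q0: 1.9198621771937625
  theta18:
    k: 80.0
    q0: 1.911135530933791
  theta19:
    k: 80.0
    q0: 1.911135530933791
  theta20:
    k: 80.0
    q0: 2.111848394913139
  theta21:
    couplings:
      phi20: 0.04
    k: 80.0
    q0: 2.007128639793479
  theta22:
    k: 80.0
    q0: 2.076941809873252
  theta23:
    k: 80.0
    q0: 2.111848394913139
  theta24:
    k: 80.0
    q0: 1.9198621771937625
  theta25:
    k: 80.0
    q0: 1.911135530933791
  theta26:
    k: 80.0
    q0: 1.911135530933791
  theta27:
    k: 80.0
    q0: 2.111848394913139
  theta28:
    k: 80.0
    q0: 2.007128639793479
  theta29:
    k: 80.0
    q0: 2.076941809873252
  theta3:
    k: 80.0
    q0: 1.911135530933791
  theta30:
    k: 80.0
    q0: 2.111848394913139
  theta4:
    k: 80.0
    q0: 2.111848394913139
  theta5:
    k: 80.0
    q0: 1.911135530933791
  theta6:
    k: 80.0
    q0: 1.911135530933791
  theta7:
    couplings:
      phi4: 0.03
    k: 80.0
    q0: 2.007128639793479
  theta8:
    k: 80.0
    q0: 2.076941809873252
  theta9:
    k: 80.0
    q0: 2.111848394913139
seed: 0
torsion:
  phi10:
  - gamma: 0.0
    n: 2
    v: 0.8
  - gamma: 0.5
    n: 3
    v: 0.3
  phi13:
  - gamma: 0.0
    n: 2
    v: 0.8
  - gamma: 0.5
    n: 3
    v: 0.3
  phi17:
  - gamma: 0.0
    n: 2
    v: 0.8
  - gamma: 0.5
    n: 3
    v: 0.3
  phi20:
  - gamma: 0.0
    n: 2
    v: 0.8
  - gamma: 0.5
    n: 3
    v: 0.3
  phi24:
  - gamma: 0.0
    n: 2
    v: 0.8
  - gamma: 0.5
    n: 3
    v: 0.3
  phi27:
  - gamma: 0.0
    n: 2
    v: 0.8
  - gamma: 0.5
    n: 3
    v: 0.3
  phi4:
  - gamma: 0.0
    n: 3
    v: 0.4
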