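# nma_like fixture: synthetic emulation (idealized geometry, declared split)
H
C 1 1.0900000000
C 2 1.5200000000 1 109.5000000000
O 3 1.2300000000 2 121.0000000000 1 30.0000000000 principal
N 3 1.3400000000 2 115.0000000000 4 180.0000000000 phase
H 5 1.0100000000 3 119.0000000000 2 0.0000000000 principal
C 5 1.4500000000 3 121.0000000000 6 180.0000000000 phase
H 7 1.0900000000 5 109.5000000000 3 60.0000000000 principal
H 7 1.0900000000 5 109.5000000000 8 120.0000000000 phase
H 7 1.0900000000 5 109.5000000000 8 -120.0000000000 phase
H 2 1.0900000000 3 109.5000000000 1 120.0000000000 phase
H 2 1.0900000000 3 109.5000000000 1 -120.0000000000 phase
unconstrained: phi4 phi6 phi8
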