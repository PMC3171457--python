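# gly3_like fixture: synthetic emulation (idealized geometry, declared split)
H
C 1 1.0900000000
C 2 1.5200000000 1 109.5000000000
O 3 1.2300000000 2 121.0000000000 1 40.0000000000 principal
H 2 1.0900000000 3 109.5000000000 1 120.0000000000 phase
H 2 1.0900000000 3 109.5000000000 1 -120.0000000000 phase
N 3 1.3400000000 2 115.0000000000 4 180.0000000000 phase
H 7 1.0100000000 3 119.0000000000 2 0.0000000000 principal
C 7 1.4500000000 3 121.0000000000 8 180.0000000000 phase
C 9 1.5200000000 7 110.0000000000 3 -80.0000000000 principal
H 9 1.0900000000 7 109.5000000000 10 120.0000000000 phase
H 9 1.0900000000 7 109.5000000000 10 -120.0000000000 phase
O 10 1.2300000000 9 121.0000000000 7 -30.0000000000 principal
N 10 1.3400000000 9 115.0000000000 13 180.0000000000 phase
H 14 1.0100000000 10 119.0000000000 9 0.0000000000 principal
C 14 1.4500000000 10 121.0000000000 15 180.0000000000 phase
C 16 1.5200000000 14 110.0000000000 10 -80.0000000000 principal
H 16 1.0900000000 14 109.5000000000 17 120.0000000000 phase
H 16 1.0900000000 14 109.5000000000 17 -120.0000000000 phase
O 17 1.2300000000 16 121.0000000000 14 -30.0000000000 principal
N 17 1.3400000000 16 115.0000000000 20 180.0000000000 phase
H 21 1.0100000000 17 119.0000000000 16 0.0000000000 principal
C 21 1.4500000000 17 121.0000000000 22 180.0000000000 phase
C 23 1.5200000000 21 110.0000000000 17 -80.0000000000 principal
H 23 1.0900000000 21 109.5000000000 24 120.0000000000 phase
H 23 1.0900000000 21 109.5000000000 24 -120.0000000000 phase
O 24 1.2300000000 23 121.0000000000 21 -30.0000000000 principal
N 24 1.3400000000 23 115.0000000000 27 180.0000000000 phase
H 28 1.0100000000 24 119.0000000000 23 0.0000000000 principal
H 28 1.4500000000 24 121.0000000000 29 180.0000000000 phase
unconstrained: phi4 phi10 phi13 phi17 phi20 phi24 phi27
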