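# methanol_like fixture: synthetic emulation (idealized geometry, declared split)
H
C 1 1.0900000000
O 2 1.4100000000 1 109.5000000000
H 2 1.0900000000 3 109.5000000000 1 60.0000000000 principal
H 2 1.0900000000 3 109.5000000000 4 120.0000000000 phase
H 2 1.0900000000 3 109.5000000000 4 -120.0000000000 phase
unconstrained: phi4
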