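name ALA
net_charge 0
[atoms]
N  N 0
CA C 0
C  C 0
O  O 0
CB C 0
[bonds]
N CA
CA C
C O
CA CB
[chi]
[internal]
CB CA N C 1.530 110.5 -122.6
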