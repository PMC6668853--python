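name GLY
net_charge 0
[atoms]
N  N 0
CA C 0
C  C 0
O  O 0
[bonds]
N CA
CA C
C O
[chi]
[internal]
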