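name LYS
net_charge 1
[atoms]
N  N 0
CA C 0
C  C 0
O  O 0
CB C 0
CG C 0
CD C 0
CE C 0
NZ N 1
[bonds]
N CA
CA C
C O
CA CB
CB CG
CG CD
CD CE
CE NZ
[chi]
N CA CB CG
CA CB CG CD
CB CG CD CE
CG CD CE NZ
[internal]
CB CA N C   1.530 110.5 -122.6
CG CB CA N  1.520 114.0 chi1
CD CG CB CA 1.520 111.5 chi2
CE CD CG CB 1.520 111.5 chi3
NZ CE CD CG 1.470 111.5 chi4
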