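# beta-methylamino-L-alanine, protonated secondary amine (+1 on NG)
name BMAA
net_charge 1
[atoms]
N  N 0
CA C 0
C  C 0
O  O 0
CB C 0
NG N 1
CG C 0
[bonds]
N CA
CA C
C O
CA CB
CB NG
NG CG
[chi]
N CA CB NG
CA CB NG CG
[internal]
CB CA N C   1.530 110.5 -122.6
NG CB CA N  1.470 109.5 chi1
CG NG CB CA 1.470 112.0 chi2
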