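e0: 2.5
r: 0.56
s0: 6.0
He1: 5.6
Hs1: 3.8
Hf1: 173.1
ae1: 110.0
as1: 40.0
af1: 790.0
Cpe1: 65.0
Cpf1: 19.5
Cps1: 19.5
Cep1: 52.0
Cfp1: 52.0
Cfs1: 6.5
Csp1: 19.5
Csf1: 6.5
m1: 0.0
var1: 60.0
He2: 5.2
Hs2: 4.5
Hf2: 57.1
ae2: 85.0
as2: 30.0
af2: 350.0
Cpe2: 80.0
Cpf2: 24.0
Cps2: 24.0
Cep2: 64.0
Cfp2: 64.0
Cfs2: 8.0
Csp2: 24.0
Csf2: 8.0
m2: 0.0
var2: 60.0
He5: 2.7
Hs5: 3.2
Hf5: 39.0
ae5: 40.0
as5: 20.0
af5: 300.0
Cpe5: 59.0
Cpf5: 17.7
Cps5: 17.7
Cep5: 47.2
Cfp5: 47.2
Cfs5: 5.9
Csp5: 17.7
Csf5: 5.9
m5: 0.0
var5: 60.0
k21: 0.0
k51: 0.0
k52: 0.0
k12: 0.0
k15: 0.0
k25: 0.0
T: 0.01
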