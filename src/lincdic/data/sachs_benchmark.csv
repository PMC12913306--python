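,Raf,Mek,Plcg,PIP2,PIP3,Erk,Akt,PKA,PKC,P38,Jnk
Raf,0,1,0,0,0,0,0,0,0,0,0
Mek,0,0,0,0,0,1,0,0,0,0,0
Plcg,0,0,0,1,1,0,0,0,1,0,0
PIP2,0,0,0,0,0,0,0,0,1,0,0
PIP3,0,0,0,1,0,0,1,0,0,0,0
Erk,0,0,0,0,0,0,1,0,0,0,0
Akt,0,0,0,0,0,0,0,0,0,0,0
PKA,1,1,0,0,0,1,1,0,0,1,1
PKC,1,1,0,0,0,0,0,1,0,1,1
P38,0,0,0,0,0,0,0,0,0,0,0
Jnk,0,0,0,0,0,0,0,0,0,0,0
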