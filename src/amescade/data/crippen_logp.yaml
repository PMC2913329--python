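# Atom-type contributions for the additive logP estimate (ALOGP).
# Values are the published Wildman-Crippen atom-contribution table;
# patterns are tried in order, first match (on the first mapped atom) wins.
types:
  - {name: C1,  smarts: ['[CH4]', '[CH3]C', '[CH2](C)C'], logp: 0.1441}
  - {name: C2,  smarts: ['[CH](C)(C)C', '[C](C)(C)(C)C'], logp: 0.0}
  - {name: C8,  smarts: ['[CH3]c'], logp: 0.08452}
  - {name: C9,  smarts: ['[CH3]a'], logp: -0.1444}
  - {name: C10, smarts: ['[CH2X4]a'], logp: -0.0516}
  - {name: C11, smarts: ['[CHX4]a'], logp: 0.1193}
  - {name: C12, smarts: ['[CH0X4]a'], logp: -0.0967}
  - {name: C3,  smarts: ['[CH3][N,O,P,S,F,Cl,Br,I]', '[CH2X4][N,O,P,S,F,Cl,Br,I]'], logp: -0.2035}
  - {name: C4,  smarts: ['[CH1X4][N,O,P,S,F,Cl,Br,I]', '[CH0X4][N,O,P,S,F,Cl,Br,I]'], logp: -0.2051}
  - {name: C5,  smarts: ['[C]=[!C;A;!#1]'], logp: -0.2783}
  - {name: C6,  smarts: ['[CH2]=C', '[CH1](=C)[A;!#1]', '[CH0](=C)([A;!#1])[A;!#1]', '[C](=C)=C'], logp: 0.1551}
  - {name: C7,  smarts: ['[CX2]#[A;!#1]'], logp: 0.0017}
  - {name: C13, smarts: ['[cH0]-[A;!C;!N;!O;!S;!F;!Cl;!Br;!I;!#1;!#15]'], logp: -0.5443}
  - {name: C14, smarts: ['[c][#9]'], logp: 0.0}
  - {name: C15, smarts: ['[c][#17]'], logp: 0.245}
  - {name: C16, smarts: ['[c][#35]'], logp: 0.198}
  - {name: C17, smarts: ['[c][#53]'], logp: 0.0}
  - {name: C18, smarts: ['[cH]'], logp: 0.1581}
  - {name: C19, smarts: ['[c](:a)(:a):a'], logp: 0.2955}
  - {name: C20, smarts: ['[c](:a)(:a)-a'], logp: 0.2713}
  - {name: C21, smarts: ['[c](:a)(:a)-C'], logp: 0.136}
  - {name: C22, smarts: ['[c](:a)(:a)-N'], logp: 0.4619}
  - {name: C23, smarts: ['[c](:a)(:a)-O'], logp: 0.5437}
  - {name: C24, smarts: ['[c](:a)(:a)-S'], logp: 0.1893}
  - {name: C25, smarts: ['[c](:a)(:a)=[C,N,O]'], logp: -0.8186}
  - {name: C26, smarts: ['[C](=C)(a)[A;!#1]', '[C](=C)(c)a', '[CH1](=C)a', '[C]=c'], logp: 0.264}
  - {name: C27, smarts: ['[CX4][A;!C;!N;!O;!P;!S;!F;!Cl;!Br;!I;!#1]'], logp: 0.2148}
  - {name: CS,  smarts: ['[#6]'], logp: 0.08129}
  - {name: H1,  smarts: ['[#1][#6,#1]'], logp: 0.123}
  - {name: H2,  smarts: ['[#1]O[CX4,c]', '[#1]O[!#6;!#7;!#8;!#16]', '[#1][!#6;!#7;!#8]'], logp: -0.2677}
  - {name: H3,  smarts: ['[#1][#7]', '[#1]O[#7]'], logp: 0.2142}
  - {name: H4,  smarts: ['[#1]OC=[#6,#7,O,S]', '[#1]O[O,S]'], logp: 0.2980}
  - {name: HS,  smarts: ['[#1]'], logp: 0.1125}
  - {name: N1,  smarts: ['[NH2+0][A;!#1]'], logp: -1.019}
  - {name: N2,  smarts: ['[NH+0]([A;!#1])[A;!#1]'], logp: -0.7096}
  - {name: N3,  smarts: ['[NH2+0]a'], logp: -1.027}
  - {name: N4,  smarts: ['[NH1+0]([!#1;A,a])a'], logp: -0.5188}
  - {name: N5,  smarts: ['[NH+0]=[!#1;A,a]'], logp: 0.08387}
  - {name: N6,  smarts: ['[N+0](=[!#1;A,a])[!#1;A,a]'], logp: 0.1836}
  - {name: N7,  smarts: ['[N+0]([A;!#1])([A;!#1])[A;!#1]'], logp: -0.3187}
  - {name: N8,  smarts: ['[N+0](a)([!#1;A,a])[A;!#1]', '[N+0](a)(a)a'], logp: -0.4458}
  - {name: N9,  smarts: ['[N+0]#[A;!#1]'], logp: 0.01508}
  - {name: N10, smarts: ['[NH3,NH2,NH;+,+2,+3]'], logp: -1.95}
  - {name: N11, smarts: ['[n+0]'], logp: -0.3239}
  - {name: N12, smarts: ['[n;+,+2,+3]'], logp: -1.119}
  - {name: N13, smarts: ['[NH0;+,+2,+3]([A;!#1])([A;!#1])([A;!#1])[A;!#1]',
                         '[NH0;+,+2,+3](=[A;!#1])([A;!#1])[!#1;A,a]',
                         '[NH0;+,+2,+3](=[#6])=[#7]'], logp: -0.3396}
  - {name: N14, smarts: ['[N;+,+2,+3]=[N;-,-2,-3]', '[N;+,+2,+3]#[A;-,-2,-3]', '[N;-,-2,-3]'], logp: 0.2887}
  - {name: NS,  smarts: ['[#7]'], logp: -0.4806}
  - {name: O1,  smarts: ['[o]'], logp: 0.1552}
  - {name: O2,  smarts: ['[OH,OH2]'], logp: -0.2893}
  - {name: O3,  smarts: ['[O]([A;!#1])[A;!#1]'], logp: -0.0684}
  - {name: O4,  smarts: ['[O](a)[!#1;A,a]'], logp: -0.4195}
  - {name: O5,  smarts: ['[O]=[#7,#8]', '[OX1;-,-2,-3][#7]'], logp: 0.0335}
  - {name: O6,  smarts: ['[OX1;-,-2,-3][#16]', '[O;-0]=[#16;-0]'], logp: -0.3339}
  - {name: O12, smarts: ['[O-]C(=O)'], logp: -1.326}
  - {name: O7,  smarts: ['[OX1;-,-2,-3][!#1;!N;!S]'], logp: -1.189}
  - {name: O8,  smarts: ['[O]=c'], logp: 0.1788}
  - {name: O9,  smarts: ['[O]=[CH]C', '[O]=C(C)([A;!#1])', '[O]=[CH][N,O]', '[O]=[CH2]', '[O]=[CX2]=O'], logp: -0.1526}
  - {name: O10, smarts: ['[O]=[CH]c', '[O]=C([C,c])[a;!#1]', '[O]=C(c)[A;!#1]'], logp: 0.1129}
  - {name: O11, smarts: ['[O]=C([!#1;!#6])[!#1;!#6]'], logp: 0.4833}
  - {name: OS,  smarts: ['[#8]'], logp: -0.1188}
  - {name: F,   smarts: ['[#9-0]'], logp: 0.4202}
  - {name: Cl,  smarts: ['[#17-0]'], logp: 0.6895}
  - {name: Br,  smarts: ['[#35-0]'], logp: 0.8456}
  - {name: I,   smarts: ['[#53-0]'], logp: 0.8857}
  - {name: Hal, smarts: ['[#9,#17,#35,#53;-]', '[#53;+,+2,+3]', '[+;#3,#11,#19,#37,#55]'], logp: -2.996}
  - {name: P,   smarts: ['[#15]'], logp: 0.8612}
  - {name: S2,  smarts: ['[S;-,-2,-3,+,+2,+3,+4,+5]', '[S]=[OX1]', '[S]=[NX2]'], logp: -0.0024}
  - {name: S1,  smarts: ['[S;-0]'], logp: 0.6482}
  - {name: S3,  smarts: ['[s]'], logp: 0.6237}
  - {name: Me1, smarts: ['[#3,#11,#19,#37,#55]', '[#4,#12,#20,#38,#56]',
                         '[#5,#13,#31,#49,#81]', '[#14,#32,#50,#82]',
                         '[#33,#51,#83]', '[#34,#52,#84]'], logp: -0.3808}
  - {name: Me2, smarts: ['[#21,#22,#23,#24,#25,#26,#27,#28,#29,#30]',
                         '[#39,#40,#41,#42,#43,#44,#45,#46,#47,#48]',
                         '[#72,#73,#74,#75,#76,#77,#78,#79,#80]'], logp: -0.0025}
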