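# Default atom-type fragment table: 21 Kier-Hall style E-state atom types
# covering the common C/N/O/S/halogen bonding environments of small organic
# molecules.  Each heavy atom matches at most one type; the loader rejects
# tables whose predicates overlap.  The table is a runtime configuration --
# alternative fragment lists can be supplied in the same format.
types:
  - {name: sCH3,  description: "-CH3",                        smarts: '[CX4H3]'}
  - {name: ssCH2, description: "-CH2-",                       smarts: '[CX4H2]'}
  - {name: sssCH, description: ">CH-",                        smarts: '[CX4H1]'}
  - {name: ssssC, description: ">C<",                         smarts: '[CX4H0]'}
  - {name: dsCH,  description: "=CH-",                        smarts: '[CX3H1;+0]'}
  - {name: dssC,  description: "=C<",                         smarts: '[CX3H0;+0]'}
  - {name: aaCH,  description: "aromatic CH",                 smarts: '[cH1]'}
  - {name: aasC,  description: "aromatic C, substituted or fused", smarts: '[cH0]'}
  - {name: sNH2,  description: "-NH2",                        smarts: '[NX3H2;+0]'}
  - {name: ssNH,  description: "-NH-",                        smarts: '[NX3H1;+0]'}
  - {name: sssN,  description: ">N-",                         smarts: '[NX3H0;+0;!$([NX3](=[OX1])=[OX1])]'}
  - {name: aaN,   description: "aromatic N",                  smarts: '[n]'}
  - {name: ddsN,  description: "nitro N (either resonance form)", smarts: '[$([NX3;+0](=[OX1])=[OX1]),$([NX3+](=[OX1])[OX1-])]'}
  - {name: sOH,   description: "-OH",                         smarts: '[OX2H1]'}
  - {name: ssO,   description: "-O- (ether/ester)",           smarts: '[OX2H0;+0]'}
  - {name: dO,    description: "=O (incl. nitro O-)",         smarts: '[$([OX1;+0]),$([OX1-][NX3+](=[OX1]))]'}
  - {name: ssS,   description: "-S-",                         smarts: '[SX2H0;+0]'}
  - {name: sF,    description: "-F",                          smarts: '[F;+0]'}
  - {name: sCl,   description: "-Cl",                         smarts: '[Cl;+0]'}
  - {name: sBr,   description: "-Br",                         smarts: '[Br;+0]'}
  - {name: sI,    description: "-I",                          smarts: '[I;+0]'}
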