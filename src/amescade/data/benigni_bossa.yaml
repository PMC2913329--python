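# Mutagenicity structural-alert rulebase, Benigni/Bossa (Toxtree) lineage.
# Best-effort SMARTS transcription of the 30 published mutagenicity alerts;
# ids are descriptive, provenance notes point at the classical alert names.
# `literature_fp_rate_zero` marks alerts reported with a nominal 0% false
# positive rate in the source literature (used by the low-support safeguard
# during rule selection).
#
# The optional `partition:` block assigns alerts to the enhancing /
# suspicious checkpoints; without it all alerts load as `unused` until a
# rule-selection run (or an explicit partition) supplies the assignment.
alerts:
  - alert_id: acyl_halide
    name: acyl halide
    provenance: "SA1 acyl halides"
    literature_fp_rate_zero: true
    patterns: ['[CX3](=[OX1])[F,Cl,Br,I]']
  - alert_id: sulfonate_ester
    name: alkyl ester of sulfonic or phosphonic acid
    provenance: "SA2 alkyl esters of sulphonic/phosphonic acids"
    literature_fp_rate_zero: true
    patterns:
      - '[CX4;H2,H3][OX2][SX4](=[OX1])(=[OX1])'
      - '[CX4;H2,H3][OX2][PX4](=[OX1])'
  - alert_id: n_methylol
    name: N-methylol derivative
    provenance: "SA3 N-methylol derivatives"
    literature_fp_rate_zero: true
    patterns: ['[NX3][CX4H2][OX2H1]']
  - alert_id: haloalkene
    name: monohaloalkene
    provenance: "SA4 monohaloalkenes"
    patterns: ['[CX3]=[CX3][F,Cl,Br,I]']
  - alert_id: mustard
    name: nitrogen or sulfur mustard (beta-haloethyl)
    provenance: "SA5 S or N mustards"
    literature_fp_rate_zero: true
    patterns: ['[F,Cl,Br,I][CX4H2][CX4H2][NX3,SX2]']
  - alert_id: lactone_sultone
    name: propiolactone / propiosultone
    provenance: "SA6 propiolactones and propiosultones"
    literature_fp_rate_zero: true
    patterns:
      - 'O=C1OCC1'
      - 'O=S1(=O)OCCC1'
      - 'O=S1(=O)OCC1'
  - alert_id: epoxide_aziridine
    name: epoxide or aziridine
    provenance: "SA7 epoxides and aziridines"
    patterns: ['[CX4]1[OX2][CX4]1', '[CX4]1[NX3][CX4]1']
  - alert_id: aliphatic_halide
    name: aliphatic halide
    provenance: "SA8 aliphatic halogens"
    patterns: ['[CX4][Cl,Br,I]']
  - alert_id: alkyl_nitrite
    name: alkyl nitrite
    provenance: "SA9 alkyl nitrites"
    literature_fp_rate_zero: true
    patterns: ['[CX4][OX2][NX2]=[OX1]']
  - alert_id: ab_unsaturated_carbonyl
    name: alpha,beta-unsaturated carbonyl
    provenance: "SA10 alpha,beta-unsaturated carbonyls"
    patterns: ['[CX3]=[CX3][CX3]=[OX1]']
    exceptions: ['O=C1C=CC(=O)C=C1']  # quinones are a separate alert
  - alert_id: aldehyde
    name: simple aldehyde
    provenance: "SA11 simple aldehydes"
    patterns: ['[CX3H1](=[OX1])[#6]', '[CX3H2]=[OX1]']
  - alert_id: quinone
    name: quinone
    provenance: "SA12 quinones"
    patterns: ['O=C1C=CC(=O)C=C1', 'O=C1C(=O)C=CC=C1']
  - alert_id: hydrazine
    name: hydrazine
    provenance: "SA13 hydrazines"
    patterns: ['[NX3][NX3]']
  - alert_id: aliphatic_azo_azoxy
    name: aliphatic azo or azoxy
    provenance: "SA14 aliphatic azo and azoxy"
    patterns:
      - '[#6;A][NX2]=[NX2][#6;A]'
      - '[NX2]=[NX3+]([OX1-])'
      - '[NX2]=[NX3](=[OX1])'
  - alert_id: isocyanate
    name: isocyanate or isothiocyanate
    provenance: "SA15 isocyanate and isothiocyanate groups"
    patterns: ['[NX2]=C=[O,S]']
  - alert_id: alkyl_carbamate
    name: alkyl carbamate or thiocarbamate
    provenance: "SA16 alkyl carbamates and thiocarbamates"
    patterns: ['[NX3][CX3](=[OX1])[OX2][CX4]', '[NX3][CX3](=[SX1])[OX2,SX2][CX4]']
  - alert_id: polycyclic_aromatic
    name: polycyclic aromatic hydrocarbon (3+ fused rings)
    provenance: "SA18 polycyclic aromatic hydrocarbons"
    patterns:
      - 'c1ccc2cc3ccccc3cc2c1'
      - 'c1ccc2ccc3ccccc3c2c1'
      - 'c1cc2ccc3cccc4ccc(c1)c2c34'
  - alert_id: heterocyclic_pah
    name: heterocyclic polycyclic aromatic (aza-arene)
    provenance: "SA19 heterocyclic polycyclic aromatic hydrocarbons"
    patterns:
      - 'c1ccc2nc3ccccc3cc2c1'
      - 'c1ccc2c(c1)[nH]c1ccccc12'
      - 'c1ccc2ncc3ccccc3c2c1'
  - alert_id: nitrosamine
    name: N-nitroso (alkyl or aryl nitrosamine)
    provenance: "SA21 alkyl and aryl N-nitroso groups"
    literature_fp_rate_zero: true
    patterns: ['[NX3][NX2]=[OX1]']
  - alert_id: azide_triazene
    name: azide or triazene
    provenance: "SA22 azide and triazene groups"
    literature_fp_rate_zero: true
    patterns:
      - '[$([NX2]=[NX2+]=[NX1-]),$([NX2-][NX2+]#[NX1]),$([NX1-]=[NX2+]=[NX2])]'
      - '[NX3][NX2]=[NX2]'
  - alert_id: aliphatic_n_nitro
    name: aliphatic N-nitro
    provenance: "SA23 aliphatic N-nitro"
    literature_fp_rate_zero: true
    patterns: ['[NX3][$([NX3](=[OX1])=[OX1]),$([NX3+](=[OX1])[OX1-])]']
  - alert_id: enol_ether
    name: alpha,beta-unsaturated alkoxy (enol ether)
    provenance: "SA24 alpha,beta-unsaturated alkoxy groups"
    patterns: ['[CX3]=[CX3][OX2][CX4]']
    exceptions: ['[CX3](=[OX1])']  # enol esters / vinylogous acids excluded
  - alert_id: aromatic_nitroso
    name: aromatic nitroso
    provenance: "SA25 aromatic nitroso"
    literature_fp_rate_zero: true
    patterns: ['c[NX2]=[OX1]']
  - alert_id: aromatic_n_oxide
    name: aromatic ring N-oxide
    provenance: "SA26 aromatic N-oxides"
    patterns: ['[$([n+][OX1-]),$([nX3]=[OX1])]']
  - alert_id: aromatic_nitro
    name: aromatic nitro
    provenance: "SA27 nitroaromatic"
    patterns: ['c[$([NX3](=[OX1])=[OX1]),$([NX3+](=[OX1])[OX1-])]']
  - alert_id: aromatic_amine
    name: primary aromatic amine or hydroxylamine
    provenance: "SA28 primary aromatic amine, hydroxylamine and derived esters"
    patterns: ['c[NX3H2]', 'c[NX3H1][OX2]']
    exceptions: ['cS(=[OX1])(=[OX1])[OX2H1,OX1-]']  # ring sulfonic acids mitigate
  - alert_id: aromatic_alkylamine
    name: aromatic mono- or dialkylamine
    provenance: "SA28bis aromatic mono- and dialkylamines"
    patterns: ['c[NX3H1][CX4]', 'c[NX3]([CX4])[CX4]']
  - alert_id: aromatic_n_acylamine
    name: aromatic N-acylamine
    provenance: "SA28ter aromatic N-acyl amines"
    patterns: ['c[NX3H1][CX3]=[OX1]']
  - alert_id: aromatic_diazo
    name: aromatic diazo
    provenance: "SA29 aromatic diazo"
    patterns: ['c[NX2]=[NX2]']
  - alert_id: coumarin_furocoumarin
    name: coumarin or furocoumarin
    provenance: "SA30 coumarins and furocoumarins"
    patterns: ['O=c1ccc2ccccc2o1', 'O=c1ccc2cc3ccoc3cc2o1', 'O=c1ccc2c(o1)cc1occc1c2']

# Default partition: the outcome of this package's own rule-selection run on
# its synthetic fixture set (n=1000, alert/label correlation 0.9, decoy rate
# 0.1, seed 0).  It is a placeholder demonstrating the format; retraining on
# real data, or an explicit externally-derived assignment, should replace it.
partition:
  enhancing: [mustard, epoxide_aziridine, nitrosamine, azide_triazene, aromatic_amine]
  suspicious: [aliphatic_halide]
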