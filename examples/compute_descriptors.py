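"""Compute the 25-descriptor vector for a few molecules.

Four global descriptors (Gmin, idwbar, ALOGP, nrings) plus 21 atom-type
fragment counts; these are the features the statistical layer learns from.
"""

from amescade import compute_all, record_from_smiles

records = [
    record_from_smiles("propane", "CCC"),
    record_from_smiles("nitrobenzene", "c1ccccc1[N+](=O)[O-]"),
    record_from_smiles("aspirin", "CC(=O)Oc1ccccc1C(=O)O"),
]
table = compute_all(records)

for name in ("Gmin", "idwbar", "ALOGP", "nrings", "sCH3", "aaCH", "ddsN"):
    print(f"{name:>8}: " + "  ".join(f"{table.frame.loc[r.mol_id, name]:8.3f}" for r in records))

# Gmin is the least electron-rich atom's E-state (low for nitro oxygens);
# idwbar grows with topological spread; ALOGP is additive lipophilicity;
# sCH3/aaCH/ddsN count methyl, aromatic CH and nitro-N environments.
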