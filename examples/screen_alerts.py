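"""Screen molecules against the shipped mutagenicity structural alerts.

Each fired alert names a reactive substructure (toxicophore) associated
with a positive Ames test.
"""

from rdkit import Chem

from amescade import default_rulebase, screen

rulebase = default_rulebase()
print(f"rulebase: {len(rulebase.alerts)} alerts\n")

for name, smi in [
    ("nitrobenzene", "c1ccccc1[N+](=O)[O-]"),
    ("glycidol (epoxide)", "OCC1CO1"),
    ("N-nitrosodimethylamine", "CN(C)N=O"),
    ("cyclohexane", "C1CCCCC1"),
]:
    fired = screen(rulebase, Chem.MolFromSmiles(smi), "all")
    print(f"{name:25s} -> {fired or 'no alerts'}")

# Alert-free molecules like cyclohexane pass every checkpoint; alert
# bearers are candidates for recovery when the SVM calls them negative.
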