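"""Deterministic synthetic molecule sets with controlled alert/label
correlation.

The generator emulates the shape of a labelled Ames set: mutagens mostly
carry a reactive alert substructure (nitroaromatic, aromatic amine,
epoxide, alkyl halide, ...) grafted onto a benign scaffold; a decoy rate
puts the same substructures on some non-mutagens; alert-free mutagens
exist too.  This gives every cascade stage something to do: the SVM can
learn the alert-correlated descriptor signal, rule selection sees both
catchable false negatives and decoys, and the checkpoints have residual
mutagens to recover.

No chemical realism is claimed: labels are assigned by construction, not
by any mutagenicity model.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

from rdkit import Chem

from .records import AmesLabel, MoleculeRecord, record_from_smiles, standardize

#: benign scaffolds; [*:1] marks the attachment point
DEFAULT_SCAFFOLDS = (
    "CCCC[*:1]", "CCCCCC[*:1]", "CC(C)C[*:1]", "CCC(C)(C)[*:1]",
    "C1CCCCC1[*:1]", "C1CCCC1[*:1]", "c1ccccc1[*:1]", "Cc1ccccc1[*:1]",
    "CCc1ccc(cc1)[*:1]", "c1ccc2ccccc2c1[*:1]",
    "COCC[*:1]", "CCOCC[*:1]", "OCC(C)[*:1]", "OCCCC[*:1]",
    "CC(=O)OCC[*:1]", "CCOC(=O)C[*:1]", "CC(=O)NC[*:1]", "CC(C)(C)OC[*:1]",
    "C1CCOC1C[*:1]", "CC(O)CC[*:1]",
)

#: alert-bearing fragments; each must fire >=1 alert of the default rulebase
DEFAULT_ALERT_FRAGMENTS = (
    "[*:1]c1ccc(cc1)[N+](=O)[O-]",   # aromatic nitro
    "[*:1]c1ccc(N)cc1",              # primary aromatic amine
    "[*:1]CC1CO1",                   # epoxide
    "[*:1]CCCl",                     # aliphatic halide
    "[*:1]CCBr",                     # aliphatic halide
    "[*:1]CN(C)N=O",                 # nitrosamine
    "[*:1]CNN",                      # hydrazine
    "[*:1]CC=O",                     # aldehyde
    "[*:1]CN=[N+]=[N-]",             # azide
    "[*:1]N(CCCl)CCCl",              # nitrogen mustard
)

#: benign fragments for alert-free molecules
DEFAULT_BENIGN_FRAGMENTS = (
    "[*:1]C", "[*:1]CC", "[*:1]CCC", "[*:1]C(C)C", "[*:1]OC",
    "[*:1]O", "[*:1]CCOC", "[*:1]COC(C)=O",
)


@dataclass
class FixtureSpec:
    n: int = 1000
    frac_mutagen: float = 0.56        # class balance of the Bursi-style sets
    alert_bearing_mutagen_rate: float = 0.9
    alert_bearing_nonmutagen_rate: float = 0.1
    scaffold_pool: tuple = DEFAULT_SCAFFOLDS
    alert_fragments: tuple = DEFAULT_ALERT_FRAGMENTS
    benign_fragments: tuple = DEFAULT_BENIGN_FRAGMENTS
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 10:
            raise ValueError("n must be >= 10")
        for rate in (self.frac_mutagen, self.alert_bearing_mutagen_rate,
                     self.alert_bearing_nonmutagen_rate):
            if not 0.0 <= rate <= 1.0:
                raise ValueError("rates must lie in [0, 1]")
        if not self.scaffold_pool:
            raise ValueError("scaffold pool is empty")


def _join(scaffold_smiles: str, fragment_smiles: str) -> str:
    scaffold = Chem.MolFromSmiles(scaffold_smiles)
    fragment = Chem.MolFromSmiles(fragment_smiles)
    joined = Chem.molzip(Chem.CombineMols(scaffold, fragment))
    Chem.SanitizeMol(joined)
    return Chem.MolToSmiles(joined)


def generate(spec: FixtureSpec) -> list[MoleculeRecord]:
    """Generate ``spec.n`` labelled records, reproducible from ``spec.seed``."""
    rng = random.Random(spec.seed)
    records = []
    for i in range(spec.n):
        mutagen = rng.random() < spec.frac_mutagen
        rate = (spec.alert_bearing_mutagen_rate if mutagen
                else spec.alert_bearing_nonmutagen_rate)
        bearing = rng.random() < rate
        scaffold = rng.choice(spec.scaffold_pool)
        fragment = rng.choice(spec.alert_fragments if bearing else spec.benign_fragments)
        smiles = _join(scaffold, fragment)
        label = AmesLabel.MUTAGEN if mutagen else AmesLabel.NONMUTAGEN
        rec = standardize(record_from_smiles(f"syn{i:05d}", smiles, label))
        records.append(rec)
    return records
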