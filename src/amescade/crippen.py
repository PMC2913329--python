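"""Atom-additive octanol/water partition coefficient (the ALOGP descriptor).

The estimate is the sum over all atoms -- hydrogens included -- of a
published per-atom-type contribution (Wildman & Crippen's atom-typing
refinement of the Ghose-Crippen scheme).  Atom types are SMARTS patterns
tried in table order; the first pattern whose first mapped atom is the
query atom assigns the type.  An atom matched by no pattern makes the
descriptor fail for that molecule (never a silent zero).
"""

from __future__ import annotations

import functools
from dataclasses import dataclass
from pathlib import Path

import yaml
from rdkit import Chem


class UnclassifiableAtomError(ValueError):
    """An atom not covered by the contribution table."""


@dataclass(frozen=True)
class AtomTypeEntry:
    name: str
    patterns: tuple  # compiled query mols
    logp: float


_DATA = Path(__file__).parent / "data"


@functools.lru_cache(maxsize=4)
def load_contribution_table(path: str | None = None) -> tuple[AtomTypeEntry, ...]:
    """Load and compile the atom-type contribution table (ordered)."""
    src = Path(path) if path else _DATA / "crippen_logp.yaml"
    raw = yaml.safe_load(src.read_text())
    entries = []
    for item in raw["types"]:
        patterns = []
        for smarts in item["smarts"]:
            q = Chem.MolFromSmarts(smarts)
            if q is None:
                raise ValueError(f"bad SMARTS {smarts!r} in type {item['name']}")
            patterns.append(q)
        entries.append(AtomTypeEntry(item["name"], tuple(patterns), float(item["logp"])))
    return tuple(entries)


def atom_contributions(mol: Chem.Mol, table=None) -> list[tuple[str, float]]:
    """Per-atom (type name, logP contribution) for the hydrogen-added molecule."""
    if table is None:
        table = load_contribution_table()
    hmol = Chem.AddHs(mol)
    n = hmol.GetNumAtoms()
    assigned: list[tuple[str, float] | None] = [None] * n
    remaining = n
    for entry in table:
        if remaining == 0:
            break
        for patt in entry.patterns:
            for match in hmol.GetSubstructMatches(patt, uniquify=False, maxMatches=100000):
                i = match[0]
                if assigned[i] is None:
                    assigned[i] = (entry.name, entry.logp)
                    remaining -= 1
    for i, a in enumerate(assigned):
        if a is None:
            sym = hmol.GetAtomWithIdx(i).GetSymbol()
            raise UnclassifiableAtomError(f"atom {i} ({sym}) matches no contribution type")
    return assigned  # type: ignore[return-value]


def alogp(mol: Chem.Mol, table=None) -> float:
    """Additive logP over all atoms of the molecule (hydrogens included)."""
    return float(sum(c for _, c in atom_contributions(mol, table)))
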