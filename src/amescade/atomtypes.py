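"""E-state atom-type fragment counts (the 21 count descriptors).

Each descriptor counts the heavy atoms of one bonding-environment type,
e.g. ``sCH3`` counts -CH3 groups (propane has 2).  The type table is a
runtime configuration of disjoint SMARTS predicates; an atom matching two
types is a configuration error, an atom matching none simply goes
uncounted.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass
from pathlib import Path

import yaml
from rdkit import Chem


class TypeTableError(ValueError):
    """Malformed or overlapping atom-type table."""


@dataclass(frozen=True)
class AtomType:
    name: str
    description: str
    query: Chem.Mol


_DATA = Path(__file__).parent / "data"

# small diverse probe set used to reject overlapping predicates at load time
_PROBE_SMILES = (
    "CCC", "CC(C)(C)C", "c1ccccc1C", "c1ccncc1", "CCO", "CC(=O)OC",
    "c1ccccc1[N+](=O)[O-]", "CN(C)N=O", "Nc1ccccc1", "CNC", "CSC",
    "FC(Cl)(Br)I", "O=Cc1ccc(O)cc1", "CC(=O)N", "C=CC#N", "ON(=O)=O",
)


def _check_disjoint(types: list[AtomType]) -> None:
    for smi in _PROBE_SMILES:
        mol = Chem.MolFromSmiles(smi)
        hits: dict[int, str] = {}
        for t in types:
            for match in mol.GetSubstructMatches(t.query):
                i = match[0]
                if i in hits and hits[i] != t.name:
                    raise TypeTableError(
                        f"types {hits[i]!r} and {t.name!r} overlap on atom {i} of {smi}"
                    )
                hits[i] = t.name


@functools.lru_cache(maxsize=4)
def load_type_table(path: str | None = None) -> tuple[AtomType, ...]:
    """Load, compile and validate an atom-type table (YAML)."""
    src = Path(path) if path else _DATA / "estate_fragments.yaml"
    raw = yaml.safe_load(src.read_text())
    types, seen = [], set()
    for item in raw["types"]:
        name = item["name"]
        if name in seen:
            raise TypeTableError(f"duplicate atom type {name!r}")
        seen.add(name)
        q = Chem.MolFromSmarts(item["smarts"])
        if q is None:
            raise TypeTableError(f"bad SMARTS for atom type {name!r}: {item['smarts']!r}")
        types.append(AtomType(name, item.get("description", ""), q))
    _check_disjoint(types)
    return tuple(types)


def atom_type_counts(mol: Chem.Mol, table=None) -> dict[str, int]:
    """Count heavy atoms of each configured type.

    Raises ``TypeTableError`` if an atom matches more than one type.
    """
    if table is None:
        table = load_type_table()
    counts = {t.name: 0 for t in table}
    owner: dict[int, str] = {}
    for t in table:
        matched = {m[0] for m in mol.GetSubstructMatches(t.query)}
        for i in matched:
            if i in owner:
                raise TypeTableError(
                    f"atom {i} matches both {owner[i]!r} and {t.name!r}"
                )
            owner[i] = t.name
        counts[t.name] = len(matched)
    return counts
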