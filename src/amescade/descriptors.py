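"""The 25-descriptor set and its max-abs normalization.

Four global descriptors -- Gmin (minimum E-state), idwbar (mean distance
information content), ALOGP (additive logP) and nrings (cyclomatic
number) -- plus 21 atom-type fragment counts.  Columns are normalised by
dividing by the training-set maximum absolute value; prediction-time
matrices reuse the stored training factors, never their own.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import atomtypes, crippen, estate, topology
from .records import MoleculeRecord

GLOBAL_DESCRIPTORS = ("Gmin", "idwbar", "ALOGP", "nrings")


def descriptor_names(type_table=None) -> list[str]:
    if type_table is None:
        type_table = atomtypes.load_type_table()
    return list(GLOBAL_DESCRIPTORS) + [t.name for t in type_table]


@dataclass
class DescriptorVector:
    mol_id: str
    values: dict[str, float]
    computed_ok: bool = True
    errors: list[str] = field(default_factory=list)


@dataclass
class DescriptorTable:
    """Descriptor matrix plus per-row success flags."""

    frame: pd.DataFrame  # indexed by mol_id, one column per descriptor
    ok: pd.Series  # boolean, aligned with frame.index

    @property
    def names(self) -> list[str]:
        return list(self.frame.columns)

    def valid_matrix(self) -> pd.DataFrame:
        return self.frame.loc[self.ok]

    def to_csv(self, path: str | Path) -> None:
        out = self.frame.copy()
        out.insert(len(out.columns), "computed_ok", self.ok.astype(int))
        out.to_csv(path, index_label="mol_id")

    @classmethod
    def from_csv(cls, path: str | Path) -> "DescriptorTable":
        frame = pd.read_csv(path, index_col="mol_id")
        frame.index = frame.index.astype(str)
        if "computed_ok" in frame.columns:
            ok = frame.pop("computed_ok").astype(bool)
        else:
            ok = ~frame.isna().any(axis=1)
        return cls(frame, ok)


def compute_vector(record: MoleculeRecord, type_table=None, logp_table=None) -> DescriptorVector:
    """All 25 descriptors for one record; failures are recorded, not raised."""
    if type_table is None:
        type_table = atomtypes.load_type_table()
    names = descriptor_names(type_table)
    if not record.ok:
        return DescriptorVector(record.mol_id, dict.fromkeys(names, np.nan), False, ["parse_failed"])
    values: dict[str, float] = {}
    errors: list[str] = []
    mol = record.mol
    for name, fn in (
        ("Gmin", estate.gmin),
        ("idwbar", topology.idwbar),
        ("nrings", topology.nrings),
    ):
        try:
            values[name] = float(fn(mol))
        except Exception as exc:
            values[name] = np.nan
            errors.append(f"{name}: {exc}")
    try:
        values["ALOGP"] = crippen.alogp(mol, logp_table)
    except Exception as exc:
        values["ALOGP"] = np.nan
        errors.append(f"ALOGP: {exc}")
    try:
        values.update({k: float(v) for k, v in atomtypes.atom_type_counts(mol, type_table).items()})
    except Exception as exc:
        values.update({t.name: np.nan for t in type_table})
        errors.append(f"atom_type_counts: {exc}")
    values = {n: values[n] for n in names}
    return DescriptorVector(record.mol_id, values, not errors, errors)


def compute_all(
    records: Sequence[MoleculeRecord], type_table=None, logp_table=None
) -> DescriptorTable:
    """One descriptor vector per record, in input order.

    Per-record failures set ``computed_ok=False`` for that row only; such
    rows surface as "unpredicted" in the cascade.
    """
    vectors = [compute_vector(r, type_table, logp_table) for r in records]
    index = pd.Index([v.mol_id for v in vectors], name="mol_id")
    frame = pd.DataFrame([v.values for v in vectors], index=index)
    ok = pd.Series([v.computed_ok for v in vectors], index=index)
    return DescriptorTable(frame, ok)


# ---------------------------------------------------------------- scaling

@dataclass
class ScalingFactors:
    """Per-column maximum absolute value from a training matrix."""

    factors: pd.Series  # strictly positive

    def to_dict(self) -> dict[str, float]:
        return {k: float(v) for k, v in self.factors.items()}

    @classmethod
    def from_dict(cls, d: dict[str, float]) -> "ScalingFactors":
        return cls(pd.Series(d, dtype=float))


def fit_scaling(matrix: pd.DataFrame) -> ScalingFactors:
    """Column-wise max-abs factors; an all-zero column gets factor 1."""
    factors = matrix.abs().max(axis=0).astype(float)
    factors[~(factors > 0)] = 1.0
    return ScalingFactors(factors)


def apply_scaling(matrix: pd.DataFrame, scaling: ScalingFactors) -> pd.DataFrame:
    """Divide each column by its stored factor (column sets must agree)."""
    missing = set(matrix.columns) ^ set(scaling.factors.index)
    if missing:
        raise ValueError(f"column mismatch between matrix and scaling factors: {sorted(missing)}")
    return matrix / scaling.factors
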