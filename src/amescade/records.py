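"""Molecule records: reading, standardization and prediction output.

Input formats are SMILES lists, SDF (V2000) files and CSV tables with a
``mol_id,smiles,ames_label[,set_tag]`` header.  Records that fail to parse
are kept with a ``parse_failed`` flag rather than dropped, so that every
input row is accounted for downstream (such compounds surface as
"unpredicted" in the cascade output).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

from rdkit import Chem
from rdkit import RDLogger

RDLogger.DisableLog("rdApp.*")


class AmesLabel(str, Enum):
    MUTAGEN = "mutagen"
    NONMUTAGEN = "nonmutagen"
    UNKNOWN = "unknown"


class SetTag(str, Enum):
    TRAIN = "train"
    TEST = "test"
    NONE = "none"


#: accepted spellings for the experimental label (case-insensitive)
_POSITIVE_ALIASES = {"mutagen", "mutagenic", "1", "positive", "pos", "active"}
_NEGATIVE_ALIASES = {
    "nonmutagen",
    "non-mutagen",
    "nonmutagenic",
    "non-mutagenic",
    "0",
    "negative",
    "neg",
    "inactive",
}
_UNKNOWN_ALIASES = {"", "unknown", "na", "nan", "none"}


class LabelError(ValueError):
    """An unrecognised Ames label string."""


class FormatError(ValueError):
    """An unknown or malformed input format."""


def parse_label(text: str | None) -> AmesLabel:
    if text is None:
        return AmesLabel.UNKNOWN
    t = text.strip().lower()
    if t in _POSITIVE_ALIASES:
        return AmesLabel.MUTAGEN
    if t in _NEGATIVE_ALIASES:
        return AmesLabel.NONMUTAGEN
    if t in _UNKNOWN_ALIASES:
        return AmesLabel.UNKNOWN
    raise LabelError(f"unrecognised Ames label {text!r}")


@dataclass
class MoleculeRecord:
    mol_id: str
    mol: Chem.Mol | None
    smiles: str
    ames_label: AmesLabel = AmesLabel.UNKNOWN
    set_tag: SetTag = SetTag.NONE
    parse_failed: bool = False
    flags: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.parse_failed and self.mol is not None

    def with_label(self, label: AmesLabel) -> "MoleculeRecord":
        return replace(self, ames_label=label)


def record_from_smiles(
    mol_id: str,
    smiles: str,
    label: AmesLabel = AmesLabel.UNKNOWN,
    set_tag: SetTag = SetTag.NONE,
) -> MoleculeRecord:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None or mol.GetNumAtoms() == 0:
        return MoleculeRecord(
            mol_id, None, smiles, label, set_tag, parse_failed=True, flags=["parse_error"]
        )
    return MoleculeRecord(mol_id, mol, Chem.MolToSmiles(mol), label, set_tag)


def standardize(record: MoleculeRecord) -> MoleculeRecord:
    """Keep the largest covalent fragment, perceive aromaticity and fold
    explicit hydrogens into attached-H counts.

    Charge states are kept as drawn (nitro groups written charge-separated
    stay charge-separated).  Idempotent; failures set ``parse_failed``.
    """
    if not record.ok:
        return record
    try:
        frags = Chem.GetMolFrags(record.mol, asMols=True, sanitizeFrags=False)
        mol = max(frags, key=lambda m: m.GetNumAtoms())
        if len(frags) > 1:
            record = replace(record, flags=record.flags + ["desalted"])
        mol = Chem.RemoveHs(mol)
        Chem.SanitizeMol(mol)
        smiles = Chem.MolToSmiles(mol)
    except Exception:  # pragma: no cover - sanitization failures are rare
        return replace(record, parse_failed=True, flags=record.flags + ["sanitize_error"])
    return replace(record, mol=mol, smiles=smiles)


def _read_smiles_file(path: Path) -> list[MoleculeRecord]:
    records = []
    for i, line in enumerate(path.read_text().splitlines()):
        line = line.strip()
        if not line:
            continue
        parts = line.split(None, 1)
        smiles = parts[0]
        mol_id = parts[1].strip() if len(parts) > 1 else f"mol{i + 1}"
        records.append(record_from_smiles(mol_id, smiles))
    return records


def _read_csv_file(path: Path) -> list[MoleculeRecord]:
    records = []
    with path.open(newline="") as fh:
        sniff = fh.read(4096)
        fh.seek(0)
        first_cells = [c.strip().lower() for c in sniff.splitlines()[0].split(",")] if sniff else []
        has_header = "smiles" in first_cells
        reader = csv.reader(fh)
        header = None
        for row_no, row in enumerate(reader):
            if not row or all(not c.strip() for c in row):
                continue
            if row_no == 0 and has_header:
                header = [c.strip().lower() for c in row]
                continue
            if header is not None:
                get = dict(zip(header, row)).get
                mol_id = (get("mol_id") or get("id") or f"mol{row_no}").strip()
                smiles = (get("smiles") or "").strip()
                label_txt = get("ames_label") or get("label")
                tag_txt = (get("set_tag") or "").strip().lower()
            else:  # headerless two/three column dialect: smiles,label[,id]
                smiles = row[0].strip()
                label_txt = row[1] if len(row) > 1 else None
                mol_id = row[2].strip() if len(row) > 2 else f"mol{row_no + 1}"
                tag_txt = ""
            try:
                label = parse_label(label_txt)
            except LabelError as exc:
                raise LabelError(f"{exc} (row {row_no + 1} of {path})") from None
            tag = SetTag(tag_txt) if tag_txt in ("train", "test") else SetTag.NONE
            records.append(record_from_smiles(mol_id, smiles, label, tag))
    return records


def _read_sdf_file(path: Path) -> list[MoleculeRecord]:
    records = []
    supplier = Chem.SDMolSupplier(str(path), sanitize=True, removeHs=True)
    for i, mol in enumerate(supplier):
        if mol is None:
            records.append(
                MoleculeRecord(
                    f"mol{i + 1}", None, "", parse_failed=True, flags=["parse_error"]
                )
            )
            continue
        mol_id = mol.GetProp("_Name") if mol.GetProp("_Name") else f"mol{i + 1}"
        label_txt = None
        for prop in ("ames_label", "Ames", "label", "ACTIVITY"):
            if mol.HasProp(prop):
                label_txt = mol.GetProp(prop)
                break
        records.append(
            MoleculeRecord(
                mol_id, mol, Chem.MolToSmiles(mol), parse_label(label_txt)
            )
        )
    return records


def read_dataset(path: str | Path, fmt: str | None = None) -> list[MoleculeRecord]:
    """Read molecule records from a SMILES list, SDF file or CSV table.

    ``fmt`` is one of ``smiles``, ``sdf``, ``csv``; inferred from the file
    suffix when omitted.  Unparseable entries are returned flagged, never
    dropped, so output length always equals input length.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if fmt is None:
        fmt = {".smi": "smiles", ".smiles": "smiles", ".sdf": "sdf", ".csv": "csv"}.get(
            path.suffix.lower()
        )
    if fmt == "smiles":
        return _read_smiles_file(path)
    if fmt == "csv":
        return _read_csv_file(path)
    if fmt == "sdf":
        return _read_sdf_file(path)
    raise FormatError(f"unknown input format {fmt!r} for {path}")


def write_dataset(records: Iterable[MoleculeRecord], path: str | Path) -> None:
    """Write records as a ``mol_id,smiles,ames_label,set_tag`` CSV."""
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["mol_id", "smiles", "ames_label", "set_tag"])
        for r in records:
            writer.writerow([r.mol_id, r.smiles, r.ames_label.value, r.set_tag.value])


def write_predictions(predictions: Sequence, path: str | Path, policy=None) -> None:
    """Write cascade predictions as CSV.

    Columns: ``mol_id,smiles,predicted_class,decision_stage,fired_alerts``
    plus a ``binary_<policy>`` column when a policy is given.
    """
    from .cascade import binarize  # local import to avoid a cycle

    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh)
        header = ["mol_id", "smiles", "predicted_class", "decision_stage", "fired_alerts"]
        if policy is not None:
            header.append(f"binary_{policy.name}")
        writer.writerow(header)
        for p in predictions:
            row = [p.mol_id, p.smiles, p.label.value, p.stage.value, ";".join(p.fired_alerts)]
            if policy is not None:
                row.append(binarize(p, policy).value)
            writer.writerow(row)
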