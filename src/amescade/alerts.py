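"""Structural-alert rulebase and substructure matching.

An alert fires when any of its SMARTS patterns matches and none of its
exception patterns does.  A rulebase carries a partition of its alerts
into *enhancing* (first checkpoint), *suspicious* (second checkpoint) and
*unused*; the shipped default file encodes the Benigni/Bossa mutagenicity
alerts (Toxtree lineage, best-effort SMARTS transcription).
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import yaml
from rdkit import Chem


class AlertClass(str, Enum):
    ENHANCING = "enhancing"
    SUSPICIOUS = "suspicious"
    UNUSED = "unused"


class RulebaseError(ValueError):
    """Malformed rulebase file."""


@dataclass(frozen=True)
class StructuralAlert:
    alert_id: str
    name: str
    patterns: tuple  # compiled query mols
    exceptions: tuple = ()
    literature_fp_rate_zero: bool = False
    provenance: str = ""


@dataclass
class AlertRulebase:
    alerts: list[StructuralAlert]
    partition: dict[str, AlertClass] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [a.alert_id for a in self.alerts]
        if len(set(ids)) != len(ids):
            raise RulebaseError("duplicate alert_id in rulebase")
        if not self.partition:
            self.partition = {i: AlertClass.UNUSED for i in ids}
        if set(self.partition) != set(ids):
            raise RulebaseError("partition does not cover exactly the alert ids")

    def subset(self, which: str | AlertClass) -> list[StructuralAlert]:
        if which == "all":
            return list(self.alerts)
        which = AlertClass(which)
        return [a for a in self.alerts if self.partition[a.alert_id] is which]

    def with_partition(self, partition: dict[str, AlertClass]) -> "AlertRulebase":
        full = {a.alert_id: AlertClass(partition.get(a.alert_id, AlertClass.UNUSED))
                for a in self.alerts}
        return AlertRulebase(list(self.alerts), full)

    def ids(self) -> list[str]:
        return [a.alert_id for a in self.alerts]


_DATA = Path(__file__).parent / "data"


def _compile(smarts_list: Iterable[str], alert_id: str) -> tuple:
    out = []
    for s in smarts_list:
        q = Chem.MolFromSmarts(s)
        if q is None:
            raise RulebaseError(f"alert {alert_id!r}: SMARTS does not compile: {s!r}")
        out.append(q)
    return tuple(out)


def load_rulebase(path: str | Path | None = None) -> AlertRulebase:
    """Load and compile a YAML rulebase; default is the shipped file."""
    src = Path(path) if path else _DATA / "benigni_bossa.yaml"
    raw = yaml.safe_load(src.read_text())
    alerts = []
    for item in raw["alerts"]:
        aid = str(item["alert_id"])
        patterns = item.get("patterns") or []
        if not patterns:
            raise RulebaseError(f"alert {aid!r} has no patterns")
        alerts.append(
            StructuralAlert(
                alert_id=aid,
                name=item.get("name", aid),
                patterns=_compile(patterns, aid),
                exceptions=_compile(item.get("exceptions") or [], aid),
                literature_fp_rate_zero=bool(item.get("literature_fp_rate_zero", False)),
                provenance=item.get("provenance", ""),
            )
        )
    rb = AlertRulebase(alerts)
    part = raw.get("partition")
    if part:
        mapping: dict[str, AlertClass] = {}
        for klass in ("enhancing", "suspicious", "unused"):
            for aid in part.get(klass, []) or []:
                if str(aid) in mapping:
                    raise RulebaseError(f"alert {aid!r} assigned to two partition classes")
                mapping[str(aid)] = AlertClass(klass)
        unknown = set(mapping) - set(rb.ids())
        if unknown:
            raise RulebaseError(f"partition names unknown alerts: {sorted(unknown)}")
        rb = rb.with_partition(mapping)
    return rb


@functools.lru_cache(maxsize=1)
def default_rulebase() -> AlertRulebase:
    return load_rulebase()


def match(alert: StructuralAlert, mol: Chem.Mol) -> bool:
    """True iff some pattern matches and no exception matches."""
    if not any(mol.HasSubstructMatch(p) for p in alert.patterns):
        return False
    return not any(mol.HasSubstructMatch(e) for e in alert.exceptions)


def screen(rulebase: AlertRulebase, mol: Chem.Mol, subset: str = "all") -> list[str]:
    """Fired alert ids, in rulebase order, for the given partition subset."""
    return [a.alert_id for a in rulebase.subset(subset) if match(a, mol)]
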