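"""The integrated three-output classifier.

Serial arrangement: compounds the SVM calls positive are labelled
*mutagenic* outright; predicted negatives pass through the enhancing-alert
checkpoint (fire -> *mutagenic*) and then the suspicious-alert checkpoint
(fire -> *suspicious*); survivors are *non-mutagenic*.  Compounds whose
descriptors cannot be computed are *unpredicted* -- reported, never
defaulted to a class.

Two binarization policies fold the suspicious warning label into a binary
call: ``max_accuracy`` treats suspicious as non-mutagen, ``min_fn``
treats it as mutagen.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Sequence

from .alerts import AlertRulebase, screen
from .descriptors import DescriptorTable
from .records import MoleculeRecord
from .svm import SvmModel, predict


class CascadeLabel(str, Enum):
    MUTAGENIC = "mutagenic"
    SUSPICIOUS = "suspicious"
    NONMUTAGENIC = "nonmutagenic"
    UNPREDICTED = "unpredicted"


class Stage(str, Enum):
    SVM = "svm"
    CHECKPOINT1 = "checkpoint1"
    CHECKPOINT2 = "checkpoint2"
    PASSTHROUGH = "passthrough"
    FAILED = "failed"


class BinaryCall(str, Enum):
    MUTAGEN = "mutagen"
    NONMUTAGEN = "nonmutagen"
    UNPREDICTED = "unpredicted"


@dataclass(frozen=True)
class Policy:
    name: str  # max_accuracy | min_fn
    suspicious_maps_to: BinaryCall

    @classmethod
    def from_name(cls, name: str) -> "Policy":
        if name == "max_accuracy":
            return MAX_ACCURACY
        if name == "min_fn":
            return MIN_FN
        raise ValueError(f"unknown policy {name!r}")


MAX_ACCURACY = Policy("max_accuracy", BinaryCall.NONMUTAGEN)
MIN_FN = Policy("min_fn", BinaryCall.MUTAGEN)


@dataclass
class CascadePrediction:
    mol_id: str
    label: CascadeLabel
    stage: Stage
    fired_alerts: list[str] = field(default_factory=list)
    smiles: str = ""


def _route(record: MoleculeRecord, svm_label: str, rulebase: AlertRulebase) -> CascadePrediction:
    if svm_label == "unpredicted" or not record.ok:
        return CascadePrediction(record.mol_id, CascadeLabel.UNPREDICTED, Stage.FAILED,
                                 smiles=record.smiles)
    if svm_label == "mutagen":
        return CascadePrediction(record.mol_id, CascadeLabel.MUTAGENIC, Stage.SVM,
                                 smiles=record.smiles)
    fired = screen(rulebase, record.mol, "enhancing")
    if fired:
        return CascadePrediction(record.mol_id, CascadeLabel.MUTAGENIC, Stage.CHECKPOINT1,
                                 fired, record.smiles)
    fired = screen(rulebase, record.mol, "suspicious")
    if fired:
        return CascadePrediction(record.mol_id, CascadeLabel.SUSPICIOUS, Stage.CHECKPOINT2,
                                 fired, record.smiles)
    return CascadePrediction(record.mol_id, CascadeLabel.NONMUTAGENIC, Stage.PASSTHROUGH,
                             smiles=record.smiles)


def classify(
    records: Sequence[MoleculeRecord],
    model: SvmModel,
    rulebase: AlertRulebase,
    table: DescriptorTable | None = None,
) -> list[CascadePrediction]:
    """Run the cascade over records; computes descriptors unless a
    precomputed (unscaled) table is supplied."""
    from .descriptors import compute_all

    if table is None:
        table = compute_all(records)
    scaled = model.scale(table.frame.fillna(0.0))
    svm_labels = predict(model, scaled, ok=table.ok.to_numpy())
    return [_route(r, s, rulebase) for r, s in zip(records, svm_labels)]


def binarize(prediction: CascadePrediction, policy: Policy) -> BinaryCall:
    """Fold the three-way label into a binary call under a policy."""
    if prediction.label is CascadeLabel.MUTAGENIC:
        return BinaryCall.MUTAGEN
    if prediction.label is CascadeLabel.NONMUTAGENIC:
        return BinaryCall.NONMUTAGEN
    if prediction.label is CascadeLabel.SUSPICIOUS:
        return policy.suspicious_maps_to
    return BinaryCall.UNPREDICTED
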