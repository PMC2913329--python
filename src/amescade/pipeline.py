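"""End-to-end workflows: train the cascade, evaluate it against a bare SVM.

``train_cascade`` runs the full recipe on labelled records: descriptors ->
max-abs scaling -> C-SVC fit -> cross-validated training-set predictions ->
rule audit and partition.  ``evaluate_cascade`` produces the confusion
matrix, both policy statistics and the false-negative reduction against
the bare statistical layer.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from . import svm
from .alerts import AlertRulebase, default_rulebase
from .cascade import MAX_ACCURACY, MIN_FN, CascadePrediction, classify
from .descriptors import DescriptorTable, compute_all, fit_scaling, apply_scaling
from .evaluate import BinaryStats, ConfusionMatrix3, confusion3, fn_reduction, stats_under_policy
from .records import AmesLabel, MoleculeRecord
from .rules import RuleAudit, SelectionPolicy, select_rules


@dataclass
class TrainedCascade:
    model: svm.SvmModel
    rulebase: AlertRulebase
    audits: list[RuleAudit]


def train_cascade(
    records: Sequence[MoleculeRecord],
    rulebase: AlertRulebase | None = None,
    C: float = svm.DEFAULT_C,
    gamma: float = svm.DEFAULT_GAMMA,
    cv_folds: int = 10,
    seed: int = 0,
    selection_policy: SelectionPolicy | None = None,
    table: DescriptorTable | None = None,
    tune: bool = False,
) -> TrainedCascade:
    """Full training recipe on labelled records.

    With ``tune=True`` a grid search replaces the default (C, gamma);
    otherwise the supplied values (default (8, 16)) are used directly.
    """
    if rulebase is None:
        rulebase = default_rulebase()
    labelled = [r for r in records if r.ames_label is not AmesLabel.UNKNOWN]
    if not labelled:
        raise ValueError("no labelled records to train on")
    if table is None:
        table = compute_all(labelled)
    ok_records = [r for r, ok in zip(labelled, table.ok) if ok]
    matrix = table.valid_matrix()
    labels = [r.ames_label for r in ok_records]
    scaling = fit_scaling(matrix)
    scaled = apply_scaling(matrix, scaling)
    if tune:
        C, gamma, _ = svm.tune_hyperparameters(scaled, labels, k=cv_folds, seed=seed)
    model = svm.train(scaled, labels, C, gamma, scaling)
    cv_preds = svm.cross_validated_predictions(scaled, labels, C, gamma, cv_folds, seed)
    partitioned, audits = select_rules(rulebase, ok_records, cv_preds, selection_policy)
    model.metadata.update({"cv_folds": cv_folds, "seed": seed, "n_train": len(ok_records)})
    return TrainedCascade(model, partitioned, audits)


@dataclass
class EvaluationReport:
    matrix: ConfusionMatrix3
    max_accuracy: BinaryStats
    min_fn: BinaryStats
    svm_reference: BinaryStats
    fn_reduction_max_accuracy: float
    fn_reduction_min_fn: float

    def to_dict(self) -> dict:
        return {
            "confusion_matrix": self.matrix.to_dict(),
            "max_accuracy": self.max_accuracy.to_dict(),
            "min_fn": self.min_fn.to_dict(),
            "svm_reference": self.svm_reference.to_dict(),
            "fn_reduction_max_accuracy": self.fn_reduction_max_accuracy,
            "fn_reduction_min_fn": self.fn_reduction_min_fn,
        }


def evaluate_cascade(
    records: Sequence[MoleculeRecord],
    trained: TrainedCascade,
    table: DescriptorTable | None = None,
) -> EvaluationReport:
    """Confusion matrix and policy statistics on labelled records, with the
    bare SVM layer (empty partition) as false-negative reference."""
    truths = [r.ames_label for r in records]
    predictions = classify(records, trained.model, trained.rulebase, table)
    matrix = confusion3(truths, predictions)
    bare = trained.rulebase.with_partition({})  # all unused -> SVM alone
    svm_predictions = classify(records, trained.model, bare, table)
    svm_matrix = confusion3(truths, svm_predictions)
    svm_stats = stats_under_policy(svm_matrix, MAX_ACCURACY)
    stats_max = stats_under_policy(matrix, MAX_ACCURACY)
    stats_min = stats_under_policy(matrix, MIN_FN)
    return EvaluationReport(
        matrix=matrix,
        max_accuracy=stats_max,
        min_fn=stats_min,
        svm_reference=svm_stats,
        fn_reduction_max_accuracy=fn_reduction(svm_stats, stats_max),
        fn_reduction_min_fn=fn_reduction(svm_stats, stats_min),
    )
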