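"""Rule selection: audit alerts against cross-validated predicted negatives.

The statistical layer's CV predictions stand in for its general behaviour;
each alert is then judged only on the compounds that layer would wave
through as safe.  On that subset an alert either catches residual true
mutagens (caught false negatives) or mislabels true non-mutagens
(generated false positives):

* enhancing  -- catches more FNs than it generates FPs;
* suspicious -- not enhancing, but retains real FN-removal power;
* unused     -- everything else.

Rules firing on too few compounds are statistically unreliable; they are
admitted to the enhancing set only when the source literature reports a
nominal 0% false-positive rate for them.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

from rdkit import Chem

from .alerts import AlertClass, AlertRulebase, match
from .records import AmesLabel, MoleculeRecord

DEFAULT_MIN_SUPPORT = 5
DEFAULT_SUSPICIOUS_FLOOR = 0.25


@dataclass
class SelectionPolicy:
    min_support: int = DEFAULT_MIN_SUPPORT
    #: minimum caught_fn / generated_fp ratio for the suspicious class
    suspicious_floor: float = DEFAULT_SUSPICIOUS_FLOOR


@dataclass
class RuleAudit:
    alert_id: str
    caught_fn: int
    generated_fp: int
    decision: AlertClass = AlertClass.UNUSED
    low_support_flag: bool = False

    @property
    def support(self) -> int:
        return self.caught_fn + self.generated_fp


def audit_rules(
    rulebase: AlertRulebase,
    records: Sequence[MoleculeRecord],
    cv_predictions: Sequence[str],
) -> list[RuleAudit]:
    """Count, per alert, FNs caught and FPs generated on the CV-predicted
    negative subset.  Predicted positives never reach the checkpoints, so
    they contribute nothing."""
    if len(records) != len(cv_predictions):
        raise ValueError("records and cv_predictions are misaligned")
    neg_records = [
        r for r, p in zip(records, cv_predictions) if p == "nonmutagen" and r.ok
    ]
    audits = []
    for alert in rulebase.alerts:
        caught = generated = 0
        for r in neg_records:
            if match(alert, r.mol):
                if r.ames_label is AmesLabel.MUTAGEN:
                    caught += 1
                elif r.ames_label is AmesLabel.NONMUTAGEN:
                    generated += 1
        audits.append(RuleAudit(alert.alert_id, caught, generated))
    return audits


def partition_rules(
    audits: Sequence[RuleAudit],
    rulebase: AlertRulebase,
    policy: SelectionPolicy | None = None,
) -> dict[str, AlertClass]:
    """Deterministic partition of audited rules.

    enhancing  <=> caught_fn > generated_fp (low-support rules only if the
                   literature reports a 0% FP rate for them);
    suspicious <=> not enhancing, caught_fn >= 1 and
                   caught_fn >= suspicious_floor * generated_fp.
    """
    if policy is None:
        policy = SelectionPolicy()
    lit_zero = {a.alert_id: a.literature_fp_rate_zero for a in rulebase.alerts}
    partition: dict[str, AlertClass] = {}
    for audit in audits:
        low_support = audit.support < policy.min_support
        audit.low_support_flag = low_support
        if audit.caught_fn > audit.generated_fp and audit.caught_fn >= 1:
            if low_support and not lit_zero.get(audit.alert_id, False):
                decision = AlertClass.UNUSED
            else:
                decision = AlertClass.ENHANCING
        elif (
            audit.caught_fn >= 1
            and not low_support
            and audit.caught_fn >= policy.suspicious_floor * audit.generated_fp
        ):
            decision = AlertClass.SUSPICIOUS
        else:
            decision = AlertClass.UNUSED
        audit.decision = decision
        partition[audit.alert_id] = decision
    return partition


def select_rules(
    rulebase: AlertRulebase,
    records: Sequence[MoleculeRecord],
    cv_predictions: Sequence[str],
    policy: SelectionPolicy | None = None,
) -> tuple[AlertRulebase, list[RuleAudit]]:
    """Audit + partition in one step; returns the partitioned rulebase."""
    audits = audit_rules(rulebase, records, cv_predictions)
    partition = partition_rules(audits, rulebase, policy)
    return rulebase.with_partition(partition), audits


def write_audit_report(audits: Sequence[RuleAudit], path: str | Path) -> None:
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            ["alert_id", "caught_fn", "generated_fp", "support", "decision", "low_support_flag"]
        )
        for a in audits:
            writer.writerow(
                [a.alert_id, a.caught_fn, a.generated_fp, a.support, a.decision.value,
                 int(a.low_support_flag)]
            )
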