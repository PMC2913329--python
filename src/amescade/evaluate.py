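"""Evaluation: stratified splitting, 2x3 confusion matrices, policy stats.

The three-output cascade is summarised by a 2x3 confusion matrix (true
mutagen / non-mutagen against predicted mutagenic / non-mutagenic /
suspicious), with unpredicted compounds tracked outside the matrix.
Binary statistics are obtained by folding the suspicious column into one
side according to the chosen policy; unpredicted compounds never enter
the denominators.
"""

from __future__ import annotations

import hashlib
import math
import random
from dataclasses import dataclass, field
from typing import Sequence

from .cascade import BinaryCall, CascadeLabel, CascadePrediction, Policy
from .records import AmesLabel, MoleculeRecord

_TRUE_CLASSES = (AmesLabel.MUTAGEN, AmesLabel.NONMUTAGEN)
_PRED_CLASSES = (CascadeLabel.MUTAGENIC, CascadeLabel.NONMUTAGENIC, CascadeLabel.SUSPICIOUS)


@dataclass
class ConfusionMatrix3:
    counts: dict = field(default_factory=dict)       # (true, pred) -> int
    unpredicted: dict = field(default_factory=dict)  # true -> int

    def __post_init__(self) -> None:
        for t in _TRUE_CLASSES:
            for p in _PRED_CLASSES:
                self.counts.setdefault((t, p), 0)
            self.unpredicted.setdefault(t, 0)

    @classmethod
    def from_counts(cls, mutagenic_row: Sequence[int], nonmutagenic_row: Sequence[int],
                    unpredicted=(0, 0)) -> "ConfusionMatrix3":
        """Build directly from two (mutagenic, non-mutagenic, suspicious)
        count rows, e.g. a printed confusion table."""
        m = cls()
        for p, v in zip(_PRED_CLASSES, mutagenic_row):
            m.counts[(AmesLabel.MUTAGEN, p)] = int(v)
        for p, v in zip(_PRED_CLASSES, nonmutagenic_row):
            m.counts[(AmesLabel.NONMUTAGEN, p)] = int(v)
        m.unpredicted[AmesLabel.MUTAGEN] = int(unpredicted[0])
        m.unpredicted[AmesLabel.NONMUTAGEN] = int(unpredicted[1])
        return m

    def total(self) -> int:
        return sum(self.counts.values()) + sum(self.unpredicted.values())

    def to_dict(self) -> dict:
        return {
            "mutagens": [self.counts[(AmesLabel.MUTAGEN, p)] for p in _PRED_CLASSES],
            "nonmutagens": [self.counts[(AmesLabel.NONMUTAGEN, p)] for p in _PRED_CLASSES],
            "unpredicted": [self.unpredicted[t] for t in _TRUE_CLASSES],
        }


def confusion3(truths: Sequence[AmesLabel], predictions: Sequence[CascadePrediction]
               ) -> ConfusionMatrix3:
    """Tally a 2x3(+unpredicted) confusion matrix from aligned vectors."""
    if len(truths) != len(predictions):
        raise ValueError("truths and predictions are misaligned")
    m = ConfusionMatrix3()
    for truth, pred in zip(truths, predictions):
        truth = AmesLabel(truth)
        if truth not in _TRUE_CLASSES:
            raise ValueError(f"evaluation requires a known label, got {truth}")
        if pred.label is CascadeLabel.UNPREDICTED:
            m.unpredicted[truth] += 1
        else:
            m.counts[(truth, pred.label)] += 1
    return m


@dataclass
class BinaryStats:
    tp: int
    fn: int
    tn: int
    fp: int

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.tn + self.fp

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / self.total if self.total else math.nan

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn) if (self.tp + self.fn) else math.nan

    @property
    def specificity(self) -> float:
        return self.tn / (self.tn + self.fp) if (self.tn + self.fp) else math.nan

    @property
    def fn_rate(self) -> float:
        return self.fn / (self.tp + self.fn) if (self.tp + self.fn) else math.nan

    def to_dict(self) -> dict:
        return {
            "tp": self.tp, "fn": self.fn, "tn": self.tn, "fp": self.fp,
            "accuracy": self.accuracy, "sensitivity": self.sensitivity,
            "specificity": self.specificity, "fn_rate": self.fn_rate,
        }


def stats_under_policy(matrix: ConfusionMatrix3, policy: Policy) -> BinaryStats:
    """Fold the suspicious column per policy and compute binary statistics.

    Unpredicted compounds are excluded from all denominators.
    """
    c = matrix.counts
    sus_mut = c[(AmesLabel.MUTAGEN, CascadeLabel.SUSPICIOUS)]
    sus_non = c[(AmesLabel.NONMUTAGEN, CascadeLabel.SUSPICIOUS)]
    tp = c[(AmesLabel.MUTAGEN, CascadeLabel.MUTAGENIC)]
    fn = c[(AmesLabel.MUTAGEN, CascadeLabel.NONMUTAGENIC)]
    fp = c[(AmesLabel.NONMUTAGEN, CascadeLabel.MUTAGENIC)]
    tn = c[(AmesLabel.NONMUTAGEN, CascadeLabel.NONMUTAGENIC)]
    if policy.suspicious_maps_to is BinaryCall.MUTAGEN:
        tp, fp = tp + sus_mut, fp + sus_non
    else:
        fn, tn = fn + sus_mut, tn + sus_non
    return BinaryStats(tp=tp, fn=fn, tn=tn, fp=fp)


def fn_reduction(reference: BinaryStats, cascade: BinaryStats) -> float:
    """Fractional reduction in false negatives relative to a reference
    classifier on the same evaluation set; NaN when the reference has none."""
    if reference.fn == 0:
        return math.nan
    return (reference.fn - cascade.fn) / reference.fn


# ---------------------------------------------------------------- split

def _stratum_key(record: MoleculeRecord, rulebase=None) -> str:
    """Label x alert-profile stratum; a reproducible proxy for functional-
    group stratification."""
    from .alerts import screen

    profile = ""
    if rulebase is not None and record.ok:
        fired = screen(rulebase, record.mol, "all")
        profile = hashlib.sha1(";".join(fired).encode()).hexdigest()[:6]
    return f"{record.ames_label.value}|{profile}"


def stratified_split(
    records: Sequence[MoleculeRecord],
    test_fraction: float,
    seed: int,
    rulebase=None,
) -> tuple[list[MoleculeRecord], list[MoleculeRecord]]:
    """Disjoint, exhaustive train/test split, stratified by
    (label x fired-alert profile), reproducible from ``seed``."""
    if not 0 < test_fraction < 1:
        raise ValueError("test_fraction must be in (0, 1)")
    strata: dict[str, list[MoleculeRecord]] = {}
    for r in records:
        strata.setdefault(_stratum_key(r, rulebase), []).append(r)
    rng = random.Random(seed)
    train: list[MoleculeRecord] = []
    test: list[MoleculeRecord] = []
    carry = 0.0  # distribute rounding error across strata
    for key in sorted(strata):
        members = strata[key][:]
        rng.shuffle(members)
        exact = test_fraction * len(members) + carry
        n_test = int(round(exact))
        n_test = min(n_test, len(members))
        carry = exact - n_test
        test.extend(members[:n_test])
        train.extend(members[n_test:])
    return train, test
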