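import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from amescade.cascade import MAX_ACCURACY, MIN_FN, CascadeLabel, CascadePrediction, Stage
from amescade.evaluate import (
    BinaryStats,
    ConfusionMatrix3,
    confusion3,
    fn_reduction,
    stats_under_policy,
    stratified_split,
)
from amescade.records import AmesLabel
from amescade.synth import FixtureSpec, generate


def pred(label):
    stage = {
        CascadeLabel.MUTAGENIC: Stage.SVM,
        CascadeLabel.NONMUTAGENIC: Stage.PASSTHROUGH,
        CascadeLabel.SUSPICIOUS: Stage.CHECKPOINT2,
        CascadeLabel.UNPREDICTED: Stage.FAILED,
    }[label]
    return CascadePrediction("m", label, stage)


class TestConfusion3:
    def test_basic_tally(self):
        truths = [AmesLabel.MUTAGEN, AmesLabel.NONMUTAGEN]
        preds = [pred(CascadeLabel.MUTAGENIC), pred(CascadeLabel.SUSPICIOUS)]
        m = confusion3(truths, preds)
        assert m.counts[(AmesLabel.MUTAGEN, CascadeLabel.MUTAGENIC)] == 1
        assert m.counts[(AmesLabel.NONMUTAGEN, CascadeLabel.SUSPICIOUS)] == 1
        assert sum(m.counts.values()) == 2

    def test_all_correct_has_zero_off_diagonal(self):
        truths = [AmesLabel.MUTAGEN] * 5 + [AmesLabel.NONMUTAGEN] * 5
        preds = [pred(CascadeLabel.MUTAGENIC)] * 5 + [pred(CascadeLabel.NONMUTAGENIC)] * 5
        m = confusion3(truths, preds)
        assert m.counts[(AmesLabel.MUTAGEN, CascadeLabel.NONMUTAGENIC)] == 0
        assert m.counts[(AmesLabel.NONMUTAGEN, CascadeLabel.MUTAGENIC)] == 0

    def test_totals_conserved_including_unpredicted(self):
        truths = [AmesLabel.MUTAGEN, AmesLabel.MUTAGEN, AmesLabel.NONMUTAGEN]
        preds = [pred(CascadeLabel.UNPREDICTED), pred(CascadeLabel.MUTAGENIC),
                 pred(CascadeLabel.NONMUTAGENIC)]
        m = confusion3(truths, preds)
        assert m.total() == 3
        assert m.unpredicted[AmesLabel.MUTAGEN] == 1

    def test_unknown_truth_rejected(self):
        with pytest.raises(ValueError):
            confusion3([AmesLabel.UNKNOWN], [pred(CascadeLabel.MUTAGENIC)])


class TestStatsUnderPolicy:
    """Desk arithmetic on a 2x3 matrix with rows (403, 48, 14) for mutagens
    and (88, 268, 16) for non-mutagens -- 837 evaluated compounds."""

    MATRIX = ConfusionMatrix3.from_counts([403, 48, 14], [88, 268, 16])

    def test_max_accuracy_folds_suspicious_into_negatives(self):
        s = stats_under_policy(self.MATRIX, MAX_ACCURACY)
        assert (s.tp, s.fn, s.tn, s.fp) == (403, 62, 284, 88)
        assert s.accuracy == pytest.approx(687 / 837)
        assert round(100 * s.accuracy, 1) == 82.1

    def test_min_fn_folds_suspicious_into_positives(self):
        s = stats_under_policy(self.MATRIX, MIN_FN)
        assert (s.tp, s.fn, s.tn, s.fp) == (417, 48, 268, 104)
        assert s.sensitivity == pytest.approx(417 / 465)
        assert round(100 * s.sensitivity, 1) == 89.7

    def test_perfect_matrix_gives_unit_statistics(self):
        m = ConfusionMatrix3.from_counts([10, 0, 0], [0, 10, 0])
        s = stats_under_policy(m, MAX_ACCURACY)
        assert s.accuracy == s.sensitivity == s.specificity == 1.0

    def test_zero_class_total_yields_nan_not_zero(self):
        m = ConfusionMatrix3.from_counts([0, 0, 0], [5, 5, 0])
        s = stats_under_policy(m, MAX_ACCURACY)
        assert math.isnan(s.sensitivity)

    def test_sensitivity_is_one_minus_fn_rate(self):
        s = stats_under_policy(self.MATRIX, MIN_FN)
        assert s.sensitivity == pytest.approx(1 - s.fn_rate)


@settings(deadline=None, max_examples=60)
@given(st.lists(st.integers(0, 200), min_size=6, max_size=6))
def test_min_fn_dominates_sensitivity_max_accuracy_dominates_specificity(cells):
    """Folding suspicious into positives can only raise sensitivity and
    lower specificity, for any 2x3 matrix with nonzero class totals."""
    m = ConfusionMatrix3.from_counts(cells[:3], cells[3:])
    s_min, s_max = stats_under_policy(m, MIN_FN), stats_under_policy(m, MAX_ACCURACY)
    if sum(cells[:3]):
        assert s_min.sensitivity >= s_max.sensitivity
    if sum(cells[3:]):
        assert s_min.specificity <= s_max.specificity


class TestFnReduction:
    def test_reference_values(self):
        ref = BinaryStats(tp=391, fn=74, tn=289, fp=83)
        assert fn_reduction(ref, BinaryStats(tp=417, fn=48, tn=268, fp=104)) == pytest.approx(
            26 / 74
        )
        assert fn_reduction(ref, BinaryStats(tp=403, fn=62, tn=284, fp=88)) == pytest.approx(
            12 / 74
        )

    def test_identical_stats_give_zero(self):
        s = BinaryStats(10, 5, 10, 5)
        assert fn_reduction(s, s) == 0.0

    def test_zero_reference_fn_is_nan(self):
        assert math.isnan(fn_reduction(BinaryStats(10, 0, 10, 0), BinaryStats(10, 0, 10, 0)))


class TestStratifiedSplit:
    def test_disjoint_exhaustive_and_sized(self, rulebase):
        records = generate(FixtureSpec(n=300, seed=21))
        train, test = stratified_split(records, 0.2, seed=4, rulebase=rulebase)
        assert len(train) + len(test) == 300
        ids = {r.mol_id for r in train} | {r.mol_id for r in test}
        assert len(ids) == 300
        assert abs(len(test) - 60) <= 5  # stratum rounding

    def test_class_proportions_preserved(self, rulebase):
        records = generate(FixtureSpec(n=400, seed=22))
        frac = sum(r.ames_label is AmesLabel.MUTAGEN for r in records) / 400
        _, test = stratified_split(records, 0.2, seed=4, rulebase=rulebase)
        test_frac = sum(r.ames_label is AmesLabel.MUTAGEN for r in test) / len(test)
        assert abs(test_frac - frac) <= 0.02

    def test_same_seed_identical_split(self, rulebase):
        records = generate(FixtureSpec(n=100, seed=23))
        a = stratified_split(records, 0.2, seed=7, rulebase=rulebase)
        b = stratified_split(records, 0.2, seed=7, rulebase=rulebase)
        assert [r.mol_id for r in a[1]] == [r.mol_id for r in b[1]]

    def test_bad_fraction_rejected(self):
        with pytest.raises(ValueError):
            stratified_split([], 1.5, seed=0)
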