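"""Hierarchical scoring: level scoping, the out-of-level convention, and
the relation between row-normalized confusions and per-class recall."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from ribfrac.aggregation import AggregatedPrediction
from ribfrac.classifier import LogitRecord
from ribfrac.errors import DataError
from ribfrac.evaluation import (
    ALL_LEVELS,
    HIGH_LEVEL,
    LOW_LEVEL,
    MID_LEVEL,
    assess_aggregated,
    assess_standard,
    score_level,
    summary_table,
)
from ribfrac.mining import PatchSample


def _records(truths, preds):
    out = []
    for i, (t, p) in enumerate(zip(truths, preds)):
        scores = np.zeros(5)
        scores[p] = 1.0
        sample = PatchSample(np.zeros((1, 1), np.uint8), "nondisplaced", "img", f"g{i}", (0, 0))
        out.append(LogitRecord(sample, int(t), int(p), scores))
    return out


class TestScoreLevel:
    @pytest.mark.parametrize("level", ALL_LEVELS, ids=lambda l: l.name)
    def test_perfect_predictions_score_one(self, level):
        truths = [0, 1, 2, 3, 4, 1, 2, 3, 4]
        r = score_level(truths, truths, level)
        assert r.accuracy == 1.0
        assert r.macro_f1 == r.macro_precision == r.macro_recall == 1.0
        off_diag = r.confusion_abs.copy()
        np.fill_diagonal(off_diag, 0)
        assert off_diag.sum() == 0

    def test_high_level_hand_example(self):
        # binary mapping: truths -> [0,0,1,1], preds -> [0,1,1,0]
        r = score_level([0, 0, 1, 3], [0, 4, 1, 0], HIGH_LEVEL)
        assert r.accuracy == 0.5
        assert r.confusion_abs.tolist() == [[1, 1], [1, 1]]

    def test_mid_level_out_of_level_hits_recall_not_precision(self):
        # one true displaced predicted no_fracture: recall denominator grows,
        # displaced precision untouched
        truths = [2, 2, 1]
        preds = [2, 0, 1]
        r = score_level(truths, preds, MID_LEVEL)
        assert r.col_names[-1] == "out_of_level"
        assert r.per_class["displaced"]["recall"] == 0.5
        assert r.per_class["displaced"]["precision"] == 1.0
        assert r.confusion_abs[1, -1] == 1

    def test_scope_restriction_counts_only_true_in_level(self):
        r = score_level([0, 0, 1, 2], [1, 2, 1, 2], MID_LEVEL)
        assert r.n_items == 2  # the two true fractures only
        r_low = score_level([0, 1, 2, 3, 4], [2, 2, 2, 3, 4], LOW_LEVEL)
        assert r_low.n_items == 3

    def test_relative_diag_equals_per_class_recall(self):
        rng = np.random.default_rng(0)
        truths = rng.integers(0, 5, 200)
        preds = rng.integers(0, 5, 200)
        for level in ALL_LEVELS:
            r = score_level(truths, preds, level)
            for i, name in enumerate(r.row_names):
                assert r.confusion_rel[i, i] == pytest.approx(
                    r.per_class[name]["recall"]
                )
            sums = r.confusion_rel.sum(axis=1)
            for i, name in enumerate(r.row_names):
                if name not in r.zero_support:
                    assert sums[i] == pytest.approx(1.0, abs=1e-9)

    def test_empty_in_scope_is_flagged(self):
        r = score_level([0, 0], [1, 0], LOW_LEVEL)
        assert r.empty and r.n_items == 0

    def test_length_mismatch_rejected(self):
        with pytest.raises(DataError):
            score_level([1, 2], [1], HIGH_LEVEL)

    @given(st.permutations(list(range(12))))
    def test_item_order_invariance(self, perm):
        truths = np.array([0, 1, 2, 3, 4, 0, 1, 2, 3, 4, 2, 2])
        preds = np.array([0, 2, 2, 0, 4, 1, 1, 3, 3, 4, 2, 0])
        p = np.array(perm)
        for level in ALL_LEVELS:
            a = score_level(truths, preds, level)
            b = score_level(truths[p], preds[p], level)
            assert np.array_equal(a.confusion_abs, b.confusion_abs)
            assert a.macro_f1 == b.macro_f1


class TestAssessments:
    def test_standard_counts_every_patch(self):
        records = _records([1] * 17, [1] * 17)
        r = assess_standard(records, HIGH_LEVEL)
        assert r.n_items == 17 and r.accuracy == 1.0

    def test_standard_and_aggregated_coincide_for_singleton_groups(self):
        truths = [0, 1, 2, 3, 4, 0, 2]
        preds = [0, 1, 2, 0, 4, 3, 2]
        records = _records(truths, preds)
        groups = []
        for r in records:
            final = r.predicted_label
            groups.append(
                AggregatedPrediction(
                    r.sample.group_id,
                    0 if final == 0 else 1,
                    final,
                    r.scores,
                    r.true_label,
                )
            )
        for level in ALL_LEVELS:
            a = assess_standard(records, level)
            b = assess_aggregated(groups, level)
            assert np.array_equal(a.confusion_abs, b.confusion_abs)
            assert a.macro_f1 == b.macro_f1

    def test_aggregated_counts_one_item_per_group(self):
        groups = [
            AggregatedPrediction("f1", 1, 2, np.zeros(5), 2),
            AggregatedPrediction("f2", 1, 1, np.zeros(5), 3),
            AggregatedPrediction("n1", 0, 0, np.zeros(5), 0),
        ]
        r = assess_aggregated(groups, HIGH_LEVEL)
        assert r.n_items == 3
        assert r.confusion_abs.sum() == 3

    def test_gate_beats_standard_when_every_group_has_a_correct_patch(self):
        # fracture group: 16 wrong-class votes, 1 correct -> aggregated item
        # is correct at high level while standard accuracy is 1/17
        truths = [2] * 17
        preds = [0] * 16 + [2]
        records = _records(truths, preds)
        for r in records:
            r.sample.group_id = "f0"
        std = assess_standard(records, HIGH_LEVEL)
        from ribfrac.aggregation import aggregate_group, groups_from_records

        agg = [aggregate_group(g) for g in groups_from_records(records)]
        agg_rep = assess_aggregated(agg, HIGH_LEVEL)
        assert agg_rep.accuracy == 1.0 > std.accuracy

    def test_empty_inputs_rejected(self):
        with pytest.raises(DataError):
            assess_standard([], HIGH_LEVEL)
        with pytest.raises(DataError):
            assess_aggregated([], HIGH_LEVEL)


def test_summary_table_lists_all_reports():
    records = _records([0, 1, 2, 3, 4], [0, 1, 2, 3, 4])
    reports = [assess_standard(records, level) for level in ALL_LEVELS]
    text = summary_table(reports)
    for level in ("high", "mid", "low"):
        assert level in text
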