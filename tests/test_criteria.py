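import pytest
from hypothesis import given, settings, strategies as st

import itemscreen as its
from itemscreen.types import ValidationError


def _stats(item_id="x", mean=2.0, frac_high=0.4, frac_low=0.56,
           completion=0.96, obs=(1, 4), upsetting=0.0, difficult=0.0,
           priority=0.0):
    return its.ItemStatistics(item_id, mean, obs[0], obs[1], frac_low,
                              frac_high, completion, upsetting, difficult,
                              priority)


class TestEvaluateCriteria:
    def test_printed_row_s08(self):
        s = _stats("s08", mean=2.1, frac_high=0.34, frac_low=0.62,
                   completion=0.96, difficult=0.07)
        f = its.evaluate_criteria(s)
        assert f.as_tuple() == (1, 0, 1, 1, 1, 0, 1, 0)
        assert f.screen_keep  # five of seven

    def test_printed_row_s34(self):
        s = _stats("s34", mean=2.6, frac_high=0.47, frac_low=0.38,
                   completion=0.85, difficult=0.05)
        f = its.evaluate_criteria(s)
        assert f.as_tuple() == (1, 0, 1, 1, 1, 0, 0, 0)
        assert not f.screen_keep  # four of seven and no priority

    def test_ceiling_fails_criterion_three(self):
        s = _stats(frac_high=1.0, frac_low=0.0, completion=1.0)
        assert not its.evaluate_criteria(s).c3

    def test_boundary_strictness(self):
        # criteria 1-7 strict, criterion 8 non-strict
        s = _stats(mean=1.5, frac_high=0.50, frac_low=0.10,
                   completion=0.95, upsetting=0.05, difficult=0.05,
                   priority=0.02)
        f = its.evaluate_criteria(s)
        assert f.as_tuple() == (0, 0, 0, 1, 0, 0, 0, 1)
        assert f.screen_keep  # via criterion 8 alone

    def test_degenerate_item_fails_first_four(self):
        s = its.ItemStatistics("z", None, None, None, 0.0, 0.0, 0.0,
                               0.0, 0.0, 0.0)
        f = its.evaluate_criteria(s)
        assert f.degenerate
        assert f.first_seven()[:4] == (False,) * 4
        assert f.c5 and f.c6 and not f.c7

    def test_thresholds_are_configurable(self):
        s = _stats(completion=0.90)
        assert not its.evaluate_criteria(s).c7
        relaxed = its.CriteriaThresholds(compliance_min=0.85)
        assert its.evaluate_criteria(s, relaxed).c7


class TestScreenDecision:
    def test_five_of_seven_keeps(self):
        f = its.CriterionFlags("x", 1, 0, 1, 1, 1, 0, 1, c8=False,
                               screen_keep=True)
        assert its.screen_decision(f)

    def test_four_of_seven_without_priority_drops(self):
        f = its.CriterionFlags("x", 1, 0, 1, 1, 1, 0, 0, c8=False,
                               screen_keep=False)
        assert not its.screen_decision(f)

    def test_priority_alone_keeps(self):
        f = its.CriterionFlags("x", *([False] * 7), c8=True, screen_keep=True)
        assert its.screen_decision(f)

    @given(flags=st.tuples(*[st.booleans()] * 8),
           idx=st.integers(0, 7))
    @settings(deadline=None, max_examples=200)
    def test_monotone_in_every_criterion(self, flags, idx):
        # turning any criterion true never flips keep -> drop
        t = its.CriteriaThresholds()
        raised = list(flags)
        raised[idx] = True
        def verdict(bits):
            keep = (sum(bits[:7]) >= t.keep_count) or bits[7]
            f = its.CriterionFlags("x", *bits[:7], c8=bits[7], screen_keep=keep)
            return its.screen_decision(f, t)
        assert verdict(tuple(raised)) >= verdict(flags)


class TestTabulateFlags:
    def test_empty_input_all_zero(self):
        assert its.tabulate_flags([]).as_tuple() == (0,) * 9

    def test_duplicate_ids_rejected(self):
        f = its.CriterionFlags("x", *([True] * 7), c8=False, screen_keep=True)
        with pytest.raises(ValidationError, match="duplicate"):
            its.tabulate_flags([f, f])

    def test_counts_flags_not_items(self):
        fa = its.CriterionFlags("a", *([True] * 7), c8=True, screen_keep=True)
        fb = its.CriterionFlags("b", *([False] * 7), c8=False, screen_keep=False)
        assert its.tabulate_flags([fa, fb]).as_tuple() == (1,) * 9


class TestMissingIssueScreen:
    def test_five_distinct_patients_trigger_addition(self):
        recs = [its.DebriefRecord(f"p{i}", missing_issues=("travel",))
                for i in range(5)]
        (issue,) = its.missing_issue_screen(recs)
        assert issue.n_patients == 5 and issue.add

    def test_repeat_mentions_by_one_patient_count_once(self):
        recs = [its.DebriefRecord("p1", missing_issues=("travel", "travel"))]
        (issue,) = its.missing_issue_screen(recs)
        assert issue.n_patients == 1 and not issue.add

    def test_no_label_reaching_threshold_yields_empty_addlist(self):
        recs = [its.DebriefRecord(f"p{i}",
                                  missing_issues=("travel",) if i < 4 else ())
                for i in range(48)]
        out = its.missing_issue_screen(recs)
        assert [m for m in out if m.add] == []


class TestApplyGroupDecisions:
    def _flags(self, ids, keep=True):
        return [its.CriterionFlags(i, *([True] * 7), c8=False,
                                   screen_keep=True) if keep else
                its.CriterionFlags(i, *([False] * 7), c8=False,
                                   screen_keep=False)
                for i in ids]

    def test_all_keep_is_identity(self):
        ids = [f"s{i:02d}" for i in range(1, 70)]
        decisions = [its.GroupDecision(i, "KEEP") for i in ids]
        r = its.apply_group_decisions(self._flags(ids), decisions)
        assert r.final_item_count == 69 and r.discordant == ()

    def test_roster_is_sum_of_resulting_counts(self):
        ids = ["a", "b", "c", "d"]
        decisions = [its.GroupDecision("a", "EXPAND", resulting_item_count=2),
                     its.GroupDecision("b", "KEEP"),
                     its.GroupDecision("c", "KEEP"),
                     its.GroupDecision("d", "KEEP")]
        r = its.apply_group_decisions(self._flags(ids), decisions)
        assert r.final_item_count == 5

    def test_expert_override_is_reported_not_rejected(self):
        flags = self._flags(["a"], keep=True)
        r = its.apply_group_decisions(flags, [its.GroupDecision("a", "DELETE")])
        assert r.discordant == ("a",)
        assert r.final_item_count == 0

    def test_missing_decision_rejected(self):
        with pytest.raises(ValidationError):
            its.apply_group_decisions(self._flags(["a", "b"]),
                                      [its.GroupDecision("a", "KEEP")])

    def test_duplicate_decision_rejected(self):
        with pytest.raises(ValidationError, match="duplicate"):
            its.apply_group_decisions(
                self._flags(["a"]),
                [its.GroupDecision("a", "KEEP"), its.GroupDecision("a", "KEEP")])


class TestAgainstPublishedTable:
    def test_recomputed_flags_match_printed_except_known_boundary_row(self, phase3):
        # fractions are printed at 2 decimals; s69's upsetting fraction
        # prints as 0.05 yet passed the < 5% rule, so it is the one
        # known divergence when recomputing from printed values
        divergent = []
        for s, f, _ in phase3["by_id"].values():
            if its.evaluate_criteria(s).as_tuple() != f.as_tuple():
                divergent.append(s.item_id)
        assert divergent == ["s69"]

    def test_screen_matches_printed_overall_column(self, phase3):
        for _, f, _ in phase3["by_id"].values():
            assert its.screen_decision(f) == f.screen_keep

    def test_expert_panel_outcome(self, phase3):
        r = its.apply_group_decisions(phase3["flags"], phase3["decisions"])
        assert (r.n_keep, r.n_delete, r.n_change, r.n_expand) == (47, 16, 5, 1)
        assert r.final_item_count == 54
        # every screen-dropped item was indeed deleted by the panel
        dropped = {f.item_id for f in phase3["flags"] if not f.screen_keep}
        assert dropped == {"s34", "s50"}
        assert dropped.isdisjoint(r.discordant)
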