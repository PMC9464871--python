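"""Agreement-threshold rejection, curves, stratified reports, flagging."""

import itertools

import numpy as np
import pandas as pd
import pytest

from noisyensemble import (
    VoteMatrix,
    accuracy_by_agreement,
    agreement_filter,
    apply_exclusion_list,
    exclusion_delta,
    flag_suspect_labels,
    stratified_performance,
)
from conftest import build_cohort


def vm_from_agreements(agreements, n=15, label=1):
    """Rows voting `label` with the requested agreement counts."""
    rows = []
    for a in agreements:
        row = [label] * a + [1 - label] * (n - a)
        rows.append(row)
    return VoteMatrix(tuple(f"t{i}" for i in range(len(agreements))), np.array(rows))


class TestAgreementFilter:
    def test_threshold_15_counts(self):
        vm = vm_from_agreements([15, 14, 15, 9])
        retained, discarded = agreement_filter(vm, 15)
        assert len(retained) == 2
        assert set(retained["tile_id"]) == {"t0", "t2"}
        assert set(discarded) == {"t1", "t3"}

    def test_minimum_threshold_retains_everything(self):
        vm = vm_from_agreements([15, 14, 9, 8])
        retained, discarded = agreement_filter(vm, 8)
        assert len(retained) == 4 and not discarded

    def test_out_of_range_threshold(self):
        vm = vm_from_agreements([15])
        with pytest.raises(ValueError, match=r"\[8, 15\]"):
            agreement_filter(vm, 7)
        with pytest.raises(ValueError):
            agreement_filter(vm, 16)

    @pytest.mark.parametrize("n", [3, 5, 7, 9])
    def test_partition_and_monotonicity_exhaustive(self, n):
        """Over all 2^n vote rows: retained/discarded partition the input and
        retention is non-increasing in the threshold."""
        rows = np.array(list(itertools.product([0, 1], repeat=n)))
        vm = VoteMatrix(tuple(map(str, range(len(rows)))), rows)
        lo = n // 2 + 1
        prev = None
        for t in range(lo, n + 1):
            retained, discarded = agreement_filter(vm, t)
            assert len(retained) + len(discarded) == len(rows)
            assert not (set(retained["tile_id"]) & set(discarded))
            if prev is not None:
                assert len(retained) <= prev
                assert set(retained["tile_id"]) <= prev_set
            prev, prev_set = len(retained), set(retained["tile_id"])


class TestAccuracyByAgreement:
    def test_unanimous_correct_rows(self):
        vm = vm_from_agreements([15, 15, 15])
        truth = {t: 1 for t in vm.tile_ids}
        curve = accuracy_by_agreement(vm, truth)
        assert (curve["accuracy"] == 1.0).all()
        assert (curve["n_retained"] == 3).all()

    def test_hand_built_six_tile_curve(self):
        """Six tiles with known votes; the whole curve is checked against a
        hand-computed table (n=5 members, class 1 positive)."""
        rows = np.array(
            [
                [1, 1, 1, 1, 1],  # t0: label 1, agr 5, truth 1 -> correct
                [1, 1, 1, 1, 0],  # t1: label 1, agr 4, truth 0 -> FP
                [0, 0, 0, 1, 1],  # t2: label 0, agr 3, truth 1 -> FN
                [0, 0, 0, 0, 0],  # t3: label 0, agr 5, truth 0 -> correct
                [1, 1, 1, 0, 0],  # t4: label 1, agr 3, truth 1 -> correct
                [0, 0, 1, 1, 1],  # t5: label 1, agr 3, truth 0 -> FP
            ]
        )
        vm = VoteMatrix(tuple(f"t{i}" for i in range(6)), rows)
        truth = {"t0": 1, "t1": 0, "t2": 1, "t3": 0, "t4": 1, "t5": 0}
        curve = accuracy_by_agreement(vm, truth).set_index("threshold")
        assert curve.loc[3, "n_retained"] == 6
        assert curve.loc[3, "accuracy"] == pytest.approx(3 / 6)
        assert curve.loc[3, "false_positives"] == 2
        assert curve.loc[3, "false_negatives"] == 1
        assert curve.loc[4, "n_retained"] == 3
        assert curve.loc[4, "accuracy"] == pytest.approx(2 / 3)
        assert curve.loc[4, "false_positives"] == 1
        assert curve.loc[4, "false_negatives"] == 0
        assert curve.loc[5, "n_retained"] == 2
        assert curve.loc[5, "accuracy"] == pytest.approx(1.0)
        assert curve.loc[5, "n_discarded_correct"] == 1
        assert curve.loc[5, "n_discarded_incorrect"] == 3

    def test_zero_retained_reports_nan_not_zero(self):
        vm = vm_from_agreements([8, 9], n=15)
        truth = {t: 1 for t in vm.tile_ids}
        curve = accuracy_by_agreement(vm, truth).set_index("threshold")
        assert curve.loc[15, "n_retained"] == 0
        assert np.isnan(curve.loc[15, "accuracy"])

    def test_fp_fn_sum_to_retained_errors(self):
        rng = np.random.default_rng(0)
        rows = rng.integers(0, 2, (40, 7))
        vm = VoteMatrix(tuple(map(str, range(40))), rows)
        truth = {str(i): int(v) for i, v in enumerate(rng.integers(0, 2, 40))}
        curve = accuracy_by_agreement(vm, truth)
        for row in curve.itertuples():
            if row.n_retained:
                errors = round((1 - row.accuracy) * row.n_retained)
                assert row.false_positives + row.false_negatives == errors


class TestStratifiedPerformance:
    def _votes_for(self, cohort, accuracy_by_site):
        """Votes that are correct for a site-dependent fraction of tiles."""
        ids, votes = [], []
        for t in cohort.tiles:
            correct = (hash(t.tile_id) % 100) / 100 < accuracy_by_site[t.site_id]
            lab = t.class_label if correct else 1 - t.class_label
            ids.append(t.tile_id)
            votes.append([lab] * 3)
        return VoteMatrix(tuple(ids), np.array(votes))

    def test_group_counts_partition_total(self):
        cohort = build_cohort({"A": 4, "B": 6}, grades={"A": 1, "B": 3})
        vm = self._votes_for(cohort, {"A": 0.9, "B": 0.6})
        for by in ("site", "quality", "patient"):
            report = stratified_performance(vm, cohort, by=by)
            assert report["n_tiles"].sum() == len(cohort)

    def test_single_group_equals_overall(self):
        cohort = build_cohort({"A": 5})
        vm = self._votes_for(cohort, {"A": 0.8})
        report = stratified_performance(vm, cohort, by="site")
        assert len(report) == 1
        y = np.array([t.class_label for t in cohort.tiles])
        overall = float((vm.ensemble_label == y).mean())
        assert report["accuracy"].iloc[0] == pytest.approx(overall)

    def test_unknown_grouping_key(self):
        cohort = build_cohort({"A": 5})
        vm = self._votes_for(cohort, {"A": 0.8})
        with pytest.raises(ValueError, match="one of"):
            stratified_performance(vm, cohort, by="scanner")


class TestExclusion:
    def test_empty_exclusion_is_identity(self):
        vm = vm_from_agreements([15, 12, 9])
        truth = {t: 1 for t in vm.tile_ids}
        delta = exclusion_delta(vm, truth, [])
        assert delta["delta"] == 0.0
        assert delta["n_excluded"] == 0

    def test_excluding_all_errors_gives_perfect_accuracy(self):
        rng = np.random.default_rng(1)
        rows = rng.integers(0, 2, (30, 5))
        vm = VoteMatrix(tuple(map(str, range(30))), rows)
        truth = {str(i): int(v) for i, v in enumerate(rng.integers(0, 2, 30))}
        y = np.array([truth[t] for t in vm.tile_ids])
        wrong = [t for t, ok in zip(vm.tile_ids, vm.ensemble_label == y) if not ok]
        delta = exclusion_delta(vm, truth, wrong)
        assert delta["accuracy_after"] == 1.0

    def test_random_20pct_exclusion_matches_recount(self):
        rng = np.random.default_rng(2)
        rows = rng.integers(0, 2, (50, 5))
        vm = VoteMatrix(tuple(map(str, range(50))), rows)
        truth = {str(i): int(v) for i, v in enumerate(rng.integers(0, 2, 50))}
        excluded = list(rng.choice(list(vm.tile_ids), 10, replace=False))
        delta = exclusion_delta(vm, truth, excluded)
        keep = [t for t in vm.tile_ids if t not in set(excluded)]
        y = np.array([truth[t] for t in keep])
        idx = [vm.tile_ids.index(t) for t in keep]
        manual = float((vm.ensemble_label[idx] == y).mean())
        assert delta["accuracy_after"] == pytest.approx(manual)
        assert delta["delta"] == pytest.approx(manual - delta["accuracy_before"])

    def test_unknown_ids_ignored_and_counted(self):
        retained, unknown = apply_exclusion_list(["a", "b"], ["b", "zzz"])
        assert retained == ("a",)
        assert unknown == 1


class TestFlagSuspectLabels:
    def test_confident_contradiction_ranks_first(self):
        vm = VoteMatrix(
            ("good", "weak", "blatant"),
            np.array([[1] * 15, [1] * 8 + [0] * 7, [1] * 15]),
        )
        truth = {"good": 1, "weak": 0, "blatant": 0}
        flags = flag_suspect_labels(vm, truth)
        assert list(flags["tile_id"]) == ["blatant", "weak"]
        assert flags.iloc[0]["agreement"] == 15

    def test_full_agreement_with_truth_flags_nothing(self):
        vm = vm_from_agreements([15, 15])
        truth = {t: 1 for t in vm.tile_ids}
        assert flag_suspect_labels(vm, truth).empty

    def test_review_threshold_filters_low_agreement(self):
        agreements = [15, 13, 12, 11, 9]
        vm = vm_from_agreements(agreements)
        truth = {t: 0 for t in vm.tile_ids}  # every tile contradicted
        flags = flag_suspect_labels(vm, truth, review_threshold=12)
        # brute-force filter oracle
        expected = [f"t{i}" for i, a in enumerate(agreements) if a >= 12]
        assert sorted(flags["tile_id"]) == sorted(expected)
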