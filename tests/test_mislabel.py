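import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import tilebayes as tb
from tilebayes.mislabel import (
    evaluate_identification,
    identify_mislabelled,
    per_class_thresholds,
    plant_label_noise,
)
from tilebayes.uncertainty import UncertaintyRecord


def percentile_oracle(values, p):
    """Sorted-list linear interpolation between closest ranks."""
    xs = sorted(values)
    if len(xs) == 1:
        return xs[0]
    rank = p / 100.0 * (len(xs) - 1)
    lo = int(np.floor(rank))
    hi = int(np.ceil(rank))
    frac = rank - lo
    return xs[lo] + frac * (xs[hi] - xs[lo])


def _rec(pid, label, predicted, h):
    return UncertaintyRecord(
        patch_id=pid, predicted=predicted, H=h, H_normalized=h, BALD=0.0, true_label=label
    )


class TestPerClassThresholds:
    def test_zeroth_percentile_is_the_minimum(self):
        records = [_rec(f"p{i}", 0, 0, 0.1 * (i + 1)) for i in range(10)]
        assert per_class_thresholds(records, 0)[0] == pytest.approx(0.1)

    def test_hundredth_percentile_is_the_maximum(self):
        records = [_rec(f"p{i}", 0, 0, 0.1 * (i + 1)) for i in range(10)]
        assert per_class_thresholds(records, 100)[0] == pytest.approx(1.0)

    def test_quarter_percentile_interpolates(self):
        records = [_rec(f"p{i}", 0, 0, 0.1 * (i + 1)) for i in range(10)]
        assert per_class_thresholds(records, 25)[0] == pytest.approx(0.325)

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(
        seed=st.integers(0, 2**31 - 1),
        n=st.integers(1, 40),
        p=st.floats(0, 100, allow_nan=False),
    )
    def test_matches_brute_force_oracle(self, seed, n, p):
        rng = np.random.default_rng(seed)
        values = rng.uniform(0, 2, size=n)
        records = [_rec(f"p{i}", 1, 1, v) for i, v in enumerate(values)]
        assert per_class_thresholds(records, p)[1] == pytest.approx(
            percentile_oracle(values, p), abs=1e-12
        )

    def test_thresholds_monotone_in_p_m(self):
        rng = np.random.default_rng(0)
        records = [_rec(f"p{i}", 0, 0, v) for i, v in enumerate(rng.uniform(0, 1, 30))]
        values = [per_class_thresholds(records, p)[0] for p in (0, 10, 25, 50, 90, 100)]
        assert values == sorted(values)


class TestIdentify:
    def test_no_misclassified_records_means_no_candidates(self):
        records = [_rec(f"p{i}", i % 2, i % 2, 0.1) for i in range(8)]
        assert identify_mislabelled(records, 50).candidate_ids == frozenset()

    def test_pm_100_flags_all_but_exact_maximum(self):
        records = [
            _rec("a", 0, 1, 0.1),
            _rec("b", 0, 1, 0.5),
            _rec("c", 0, 1, 0.9),  # at the class maximum; strict < excludes it
            _rec("d", 0, 0, 0.3),
        ]
        assert identify_mislabelled(records, 100).candidate_ids == {"a", "b"}

    def test_confident_misclassification_below_median_threshold(self):
        records = [_rec("a", 0, 1, 0.05), _rec("b", 0, 0, 0.5), _rec("c", 0, 0, 0.9)]
        report = identify_mislabelled(records, 50)
        assert report.thresholds[0] == pytest.approx(0.5)
        assert report.candidate_ids == {"a"}

    def test_candidate_sets_nest_as_pm_grows(self):
        rng = np.random.default_rng(1)
        records = [
            _rec(f"p{i}", int(rng.integers(3)), int(rng.integers(3)), float(rng.uniform(0, 1.5)))
            for i in range(60)
        ]
        previous = frozenset()
        for pm in (0, 10, 30, 60, 100):
            candidates = identify_mislabelled(records, pm).candidate_ids
            assert previous <= candidates
            previous = candidates

    def test_candidates_are_always_misclassified(self):
        rng = np.random.default_rng(2)
        records = [
            _rec(f"p{i}", int(rng.integers(2)), int(rng.integers(2)), float(rng.uniform(0, 1)))
            for i in range(40)
        ]
        by_id = {r.patch_id: r for r in records}
        for pid in identify_mislabelled(records, 70).candidate_ids:
            assert by_id[pid].predicted != by_id[pid].true_label


class TestPlantNoise:
    def test_zero_rate_changes_nothing(self):
        ds = tb.generate_dataset(3, 4, size=16, seed=0)
        noisy, planted = plant_label_noise(ds, 0, seed=1)
        assert planted == frozenset()
        assert list(noisy.labels()) == list(ds.labels())

    def test_exact_count_and_labels_always_change(self):
        ds = tb.generate_dataset(4, 25, size=16, seed=0)  # N = 100
        noisy, planted = plant_label_noise(ds, 10, seed=2)
        assert len(planted) == 10
        changed = [
            pid for pid, a, b in zip(ds.ids, ds.labels(), noisy.labels()) if a != b
        ]
        assert set(changed) == set(planted)

    def test_relabels_are_uniform_over_other_classes(self):
        # 1000 tiles (125 x 8), half mislabelled: each class receives a
        # near-uniform share of relabels across seeds
        ds = tb.generate_dataset(8, 125, size=8, seed=0)
        received = np.zeros(8)
        for seed in range(3):
            noisy, planted = plant_label_noise(ds, 50, seed=seed)
            for pid, old, new in zip(ds.ids, ds.labels(), noisy.labels()):
                if pid in planted:
                    received[new] += 1
        received /= 3
        assert len(planted) == 500
        assert np.all(np.abs(received - 500 / 7) <= 25)

    def test_rate_out_of_range_rejected(self):
        ds = tb.generate_dataset(2, 2, size=16, seed=0)
        with pytest.raises(ValueError):
            plant_label_noise(ds, 101, seed=0)


class TestEvaluate:
    def _report(self, candidates):
        return tb.MislabelReport(thresholds={}, candidate_ids=frozenset(candidates))

    def test_perfect_identification(self):
        planted = {"a", "b"}
        all_ids = {"a", "b", "c", "d"}
        rep = evaluate_identification(self._report(planted), planted, all_ids)
        assert rep.sensitivity == 1.0
        assert rep.specificity == 1.0
        assert rep.recall == 1.0

    def test_disjoint_candidates_have_zero_sensitivity(self):
        rep = evaluate_identification(self._report({"c"}), {"a"}, {"a", "b", "c"})
        assert rep.sensitivity == 0.0

    def test_partial_overlap_counts(self):
        all_ids = {f"i{k}" for k in range(100)}
        planted = {f"i{k}" for k in range(10)}
        candidates = {f"i{k}" for k in range(8)} | {"i50", "i51"}
        rep = evaluate_identification(self._report(candidates), planted, all_ids)
        assert rep.sensitivity == pytest.approx(0.8)
        assert rep.specificity == pytest.approx(88 / 90)
        assert rep.recall == pytest.approx(0.8)

    def test_no_candidates_leaves_sensitivity_undefined(self):
        rep = evaluate_identification(self._report(set()), {"a"}, {"a", "b"})
        assert rep.sensitivity is None
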