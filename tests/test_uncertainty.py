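import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import tilebayes as tb
from tilebayes.uncertainty import PredictivePosterior, bald, classify, entropy_H

from conftest import random_posterior


def entropy_oracle(p):
    """Brute-force Shannon entropy in nats (plain Python loop)."""
    total = 0.0
    for v in p:
        if v > 0:
            total -= float(v) * math.log(float(v))
    return total


def bald_oracle(samples):
    """Brute-force mutual information: H(mean) - mean of row entropies."""
    T = len(samples)
    mean = [sum(row[j] for row in samples) / T for j in range(len(samples[0]))]
    return entropy_oracle(mean) - sum(entropy_oracle(row) for row in samples) / T


class TestIdentities:
    def test_uniform_entropy_is_ln_m(self):
        post = PredictivePosterior(samples=np.full((3, 8), 1 / 8))
        assert entropy_H(post) == pytest.approx(np.log(8), abs=1e-12)

    def test_one_hot_entropy_is_zero(self):
        post = PredictivePosterior(samples=np.tile(np.eye(5)[2], (4, 1)))
        assert entropy_H(post) == 0.0

    def test_fifty_fifty_entropy_is_ln_2(self):
        post = PredictivePosterior(samples=np.array([[0.5, 0.5]]))
        assert entropy_H(post) == pytest.approx(np.log(2), abs=1e-12)

    def test_bald_vanishes_for_identical_rows(self):
        rng = np.random.default_rng(0)
        row = rng.dirichlet(np.ones(6))
        post = PredictivePosterior(samples=np.tile(row, (10, 1)))
        assert bald(post) == pytest.approx(0.0, abs=1e-12)

    def test_bald_is_ln_2_for_opposing_one_hot_rows(self):
        post = PredictivePosterior(samples=np.array([[1.0, 0.0], [0.0, 1.0]]))
        assert bald(post) == pytest.approx(np.log(2), abs=1e-12)

    def test_flat_agreeing_rows_are_aleatoric(self):
        # both passes maximally unsure but in agreement: H = ln 2, BALD = 0
        post = PredictivePosterior(samples=np.array([[0.5, 0.5], [0.5, 0.5]]))
        assert entropy_H(post) == pytest.approx(np.log(2))
        assert bald(post) == pytest.approx(0.0, abs=1e-12)

    def test_single_sample_mean_is_the_row(self):
        rng = np.random.default_rng(1)
        row = rng.dirichlet(np.ones(4))
        post = PredictivePosterior(samples=row[None, :])
        np.testing.assert_allclose(post.mean, row)


class TestAgainstBruteForce:
    @pytest.mark.parametrize("T,M", [(1, 2), (5, 3), (50, 8), (200, 16)])
    def test_measures_match_oracles(self, T, M):
        rng = np.random.default_rng(T * 1000 + M)
        for _ in range(10):
            post = random_posterior(rng, T, M)
            assert entropy_H(post) == pytest.approx(
                entropy_oracle(post.mean.tolist()), abs=1e-10
            )
            assert bald(post) == pytest.approx(
                max(bald_oracle(post.samples.tolist()), 0.0), abs=1e-10
            )

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(seed=st.integers(0, 2**31 - 1), T=st.integers(1, 30), M=st.integers(2, 12))
    def test_information_inequality(self, seed, T, M):
        """0 <= BALD <= H <= ln M for every predictive posterior."""
        post = random_posterior(np.random.default_rng(seed), T, M)
        h = entropy_H(post)
        b = bald(post)
        assert 0.0 <= b <= h + 1e-12
        assert h <= np.log(M) + 1e-12


class TestClassify:
    def test_argmax_of_mean(self):
        post = PredictivePosterior(samples=np.array([[0.1, 0.7, 0.2]]))
        assert classify(post) == 1

    def test_one_hot_mean(self):
        post = PredictivePosterior(samples=np.tile(np.eye(3)[2], (5, 1)))
        assert classify(post) == 2

    def test_exact_tie_goes_to_lowest_index(self):
        post = PredictivePosterior(samples=np.array([[0.5, 0.5]]))
        assert classify(post) == 0


class TestScoreDataset:
    def test_empty_dataset_gives_empty_records(self, trained_model):
        ds = tb.PatchDataset(patches=[], catalog=tb.default_catalog(4))
        assert tb.score_dataset(trained_model, ds, T=4) == []

    def test_records_satisfy_information_inequality(self, trained_model, easy_test):
        records = tb.score_dataset(trained_model, easy_test, T=8, seed=0)
        assert len(records) == len(easy_test)
        ln_m = np.log(4)
        for r in records:
            assert 0.0 <= r.BALD <= r.H + 1e-12 <= ln_m + 1e-12
            assert r.H_normalized == pytest.approx(r.H / ln_m)
            assert 0 <= r.predicted < 4

    def test_records_are_deterministic_under_seed(self, trained_model, easy_test):
        a = tb.score_dataset(trained_model, easy_test, T=8, seed=3)
        b = tb.score_dataset(trained_model, easy_test, T=8, seed=3)
        assert a == b

    def test_records_independent_of_batch_size(self, trained_model, easy_test):
        a = tb.score_dataset(trained_model, easy_test, T=8, seed=3, eval_batch=7)
        b = tb.score_dataset(trained_model, easy_test, T=8, seed=3, eval_batch=128)
        assert a == b

    def test_mc_predict_default_T(self, trained_model, easy_test):
        post = tb.mc_predict(trained_model, easy_test.patches[0])
        assert post.T == 50
        with pytest.raises(ValueError):
            tb.mc_predict(trained_model, easy_test.patches[0], T=0)

    def test_csv_round_trip(self, trained_model, easy_test, tmp_path):
        records = tb.score_dataset(trained_model, easy_test, T=4, seed=0)[:10]
        path = tmp_path / "records.csv"
        tb.uncertainty.save_records_csv(records, path)
        back = tb.uncertainty.load_records_csv(path)
        for r, s in zip(records, back):
            assert r.patch_id == s.patch_id
            assert r.predicted == s.predicted
            assert r.H == pytest.approx(s.H, rel=1e-8)


class TestConfusablePairUncertainty:
    def test_mean_H_higher_for_the_confusable_classes(self, confusable_model):
        model, _, test = confusable_model
        records = tb.score_dataset(model, test, T=16, seed=0)
        mean_h = {
            c: np.mean([r.H for r in records if r.true_label == c]) for c in range(4)
        }
        assert (mean_h[2] + mean_h[3]) / 2 > (mean_h[0] + mean_h[1]) / 2
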