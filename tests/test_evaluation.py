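"""Hold-out protocol and metric definitions."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from stenoscan import (
    ConfusionCounts,
    RuleModel,
    auroc_from_confusion,
    auroc_from_probabilities,
    binarize_gold,
    binarize_predictions,
    generate_corpus,
    internal_config,
    external_config,
    make_splits,
    run_experiment,
    sensitivity_specificity,
)
from stenoscan.evaluation import confusion_counts


def pair_counting_auroc(y, scores) -> float:
    """Independent oracle: P(score_pos > score_neg) + 0.5 P(tie) over all
    positive-negative pairs."""
    pos = [s for yy, s in zip(y, scores) if yy == 1]
    neg = [s for yy, s in zip(y, scores) if yy == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


class TestSplits:
    @pytest.mark.parametrize("n,expected", [(9614, (7692, 1922)),
                                            (10, (8, 2)), (9, (8, 1))])
    def test_ceil_train_sizes(self, n, expected):
        plan = make_splits(n, rounds=1, seed=0)[0]
        assert (len(plan.train_ids), len(plan.test_ids)) == expected

    def test_rounds_partition_and_differ(self):
        plans = make_splits(100, rounds=10, seed=3)
        assert len(plans) == 10
        for p in plans:
            merged = np.sort(np.concatenate([p.train_ids, p.test_ids]))
            assert (merged == np.arange(100)).all()
        # independent draws: test sets are not all identical
        assert len({tuple(p.test_ids) for p in plans}) > 1

    def test_deterministic(self):
        a = make_splits(50, rounds=3, seed=9)
        b = make_splits(50, rounds=3, seed=9)
        assert all((x.test_ids == y.test_ids).all() for x, y in zip(a, b))

    def test_too_small_corpus_rejected(self):
        with pytest.raises(ValueError):
            make_splits(1, rounds=1)


class TestConfusionMetrics:
    def test_worked_confusion_example(self):
        c = ConfusionCounts(tp=9, fn=1, tn=8, fp=2)
        assert auroc_from_confusion(c) == pytest.approx(0.85)
        assert sensitivity_specificity(c) == pytest.approx((0.9, 0.8))

    def test_perfect_and_always_positive(self):
        assert auroc_from_confusion(ConfusionCounts(5, 0, 5, 0)) == 1.0
        assert auroc_from_confusion(ConfusionCounts(5, 5, 0, 0)) == 0.5

    def test_all_missed(self):
        assert sensitivity_specificity(
            ConfusionCounts(tp=0, fn=5, tn=5, fp=0)) == (0.0, 1.0)

    def test_empty_class_warns_nan(self):
        with pytest.warns(UserWarning):
            assert np.isnan(
                auroc_from_confusion(ConfusionCounts(tp=1, fp=0, tn=0, fn=1)))


class TestProbabilisticAUROC:
    @pytest.mark.parametrize(
        "gold,probs,expected",
        [
            ([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9], 1.0),
            ([0, 1], [0.5, 0.5], 0.5),
            # positives score {0.3, 0.9}, negatives {0.4, 0.2}: 3 of the 4
            # positive-negative pairs are correctly ranked
            ([0, 1, 0, 1], [0.4, 0.3, 0.2, 0.9], 0.75),
        ],
    )
    def test_frozen_examples(self, gold, probs, expected):
        assert auroc_from_probabilities(gold, probs) == pytest.approx(expected)
        assert pair_counting_auroc(gold, probs) == pytest.approx(expected)

    @settings(max_examples=300, deadline=None)
    @given(st.lists(
        st.tuples(st.integers(0, 1),
                  st.sampled_from([0.0, 0.1, 0.25, 0.5, 0.5, 0.75, 1.0])),
        min_size=2, max_size=12))
    def test_matches_pair_counting_oracle(self, rows):
        y = [r[0] for r in rows]
        s = [r[1] for r in rows]
        if len(set(y)) < 2:
            return
        assert auroc_from_probabilities(y, s) == pytest.approx(
            pair_counting_auroc(y, s))

    def test_agrees_with_confusion_form_on_binary_predictions(self):
        rng = np.random.default_rng(12)
        for _ in range(200):
            n = int(rng.integers(4, 30))
            y = rng.integers(0, 2, n)
            p = rng.integers(0, 2, n)
            if len(np.unique(y)) < 2:
                continue
            assert auroc_from_probabilities(y, p) == pytest.approx(
                auroc_from_confusion(confusion_counts(y, p)))

    def test_single_class_warns_nan(self):
        with pytest.warns(UserWarning):
            assert np.isnan(auroc_from_probabilities([1, 1], [0.2, 0.9]))


class TestBinarize:
    def test_gold_any_and_pred_max_or(self):
        gold = np.array([[0] * 11, [0, 1] + [0] * 9])
        assert binarize_gold(gold).tolist() == [0, 1]
        probs = np.full((1, 11), 0.1)
        probs[0, 4] = 0.7
        assert binarize_predictions(probs, True)[0] == pytest.approx(0.7)
        hard = np.zeros((2, 11), dtype=int)
        hard[1, 3] = 1
        assert binarize_predictions(hard, False).tolist() == [0, 1]


class _ConstantModel:
    requires_training = False
    is_probabilistic = True

    def predict(self, texts):
        return np.full((len(texts), 11), 0.5)


class TestRunExperiment:
    @pytest.fixture(scope="class")
    def corpora(self):
        internal = generate_corpus(
            internal_config(250, noise_rate=0.0, seed=41))
        external = generate_corpus(
            external_config(120, noise_rate=0.0, oov_synonym_rate=0.0, seed=42))
        return internal, external

    def _texts_gold(self, corpus):
        return ([r.full_text for r in corpus],
                np.vstack([r.gold.to_array() for r in corpus]))

    def test_rule_engine_perfect_on_clean_corpus(self, corpora):
        internal, external = corpora
        it, ig = self._texts_gold(internal)
        et, eg = self._texts_gold(external)
        result = run_experiment(it, ig, et, eg, {"rule": RuleModel()},
                                rounds=3, seed=7)
        df = result.summary_frame()
        evaluated = df[df["n_rounds"] > 0]
        assert not evaluated.empty
        assert (evaluated["auroc_mean"] == 1.0).all()
        assert (evaluated["auroc_sd"] == 0.0).all()  # SD of constant rounds

    def test_constant_model_scores_half(self, corpora):
        internal, _ = corpora
        it, ig = self._texts_gold(internal)
        result = run_experiment(it, ig, [], np.zeros((0, 11)),
                                {"const": _ConstantModel()}, rounds=2, seed=7)
        df = result.summary_frame()
        evaluated = df[df["n_rounds"] > 0]
        assert (evaluated["auroc_mean"] == 0.5).all()

    def test_single_class_cells_logged_not_averaged(self, corpora):
        internal, _ = corpora
        it, ig = self._texts_gold(internal)
        # tiny test splits make single-class arteries likely
        result = run_experiment(it[:40], ig[:40], [], np.zeros((0, 11)),
                                {"rule": RuleModel()}, rounds=4, seed=7)
        df = result.summary_frame()
        assert (df["n_rounds"] + 0 <= 4).all()
        if result.excluded:
            assert all(rec["reason"] == "single-class test labels"
                       for rec in result.excluded)

    def test_rounds_bookkeeping(self, corpora):
        internal, external = corpora
        it, ig = self._texts_gold(internal)
        et, eg = self._texts_gold(external)
        result = run_experiment(it, ig, et, eg, {"rule": RuleModel()},
                                rounds=5, seed=1)
        df = result.summary_frame()
        assert (df["n_rounds"] <= 5).all()
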