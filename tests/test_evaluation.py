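import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import chi2_contingency

from clinneg.corpus import NEGATED, NOT_NEGATED
from clinneg.evaluation import (
    ConfusionCounts,
    approx_randomization,
    chi2_rank,
    chi2_statistic,
    feature_rank_table,
    learning_curve,
    micro_macro,
    prf,
    stratified_eval,
)
from clinneg.features import FeatureName
from clinneg.model import TrainConfig, TrainingInstance
from clinneg.synthetic import generate, preset_suite

from .conftest import make_corpus

labels = st.lists(st.sampled_from([NEGATED, NOT_NEGATED]), min_size=1, max_size=60)


def oracle_prf(preds, gold):
    tp = sum(1 for p, g in zip(preds, gold) if p == g == NEGATED)
    fp = sum(1 for p, g in zip(preds, gold) if p == NEGATED and g == NOT_NEGATED)
    fn = sum(1 for p, g in zip(preds, gold) if p == NOT_NEGATED and g == NEGATED)
    p = tp / (tp + fp) if tp + fp else 0.0
    r = tp / (tp + fn) if tp + fn else 0.0
    f = 2 * p * r / (p + r) if p + r else 0.0
    return p, r, f


class TestPrf:
    def test_all_correct_gives_ones(self):
        gold = [NEGATED, NOT_NEGATED, NEGATED]
        res = prf(gold, gold)
        assert (res.precision, res.recall, res.f1) == (1.0, 1.0, 1.0)

    def test_arithmetic_example(self):
        # tp=3, fp=1, fn=1 -> P = R = F1 = 0.75
        gold = [NEGATED] * 4 + [NOT_NEGATED] * 2
        pred = [NEGATED] * 3 + [NOT_NEGATED] + [NEGATED] + [NOT_NEGATED]
        res = prf(pred, gold)
        assert res.precision == pytest.approx(0.75)
        assert res.recall == pytest.approx(0.75)
        assert res.f1 == pytest.approx(0.75)

    def test_degenerate_no_positives_convention(self):
        with pytest.warns(UserWarning, match="no gold or predicted"):
            res = prf([NOT_NEGATED] * 3, [NOT_NEGATED] * 3)
        assert res.recall == 0.0 and res.f1 == 0.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="differ in length"):
            prf([NEGATED], [NEGATED, NEGATED])

    @settings(deadline=None, derandomize=True, max_examples=60)
    @given(st.data())
    def test_matches_brute_force_confusion_oracle(self, data):
        gold = data.draw(labels)
        pred = data.draw(
            st.lists(
                st.sampled_from([NEGATED, NOT_NEGATED]),
                min_size=len(gold),
                max_size=len(gold),
            )
        )
        res = prf(pred, gold)
        p, r, f = oracle_prf(pred, gold)
        assert res.precision == pytest.approx(p)
        assert res.recall == pytest.approx(r)
        assert res.f1 == pytest.approx(f)

    def test_per_document_counts_sum_to_total(self):
        gold = [NEGATED, NOT_NEGATED, NEGATED, NOT_NEGATED]
        pred = [NEGATED, NEGATED, NOT_NEGATED, NOT_NEGATED]
        docs = ["d1", "d1", "d2", "d2"]
        res = prf(pred, gold, doc_ids=docs)
        total = ConfusionCounts()
        for c in res.per_document:
            total = total + c
        assert (total.tp, total.fp, total.fn, total.tn) == (
            res.counts.tp,
            res.counts.fp,
            res.counts.fn,
            res.counts.tn,
        )


class TestMicroMacro:
    def test_identical_corpora_micro_equals_macro(self):
        gold = [NEGATED, NOT_NEGATED, NEGATED]
        r = prf(gold, gold)
        micro, macro = micro_macro([r, r, r])
        assert micro == pytest.approx(macro) == pytest.approx(1.0)

    def test_single_corpus_both_equal_its_f1(self):
        gold = [NEGATED] * 3 + [NOT_NEGATED] * 5
        pred = [NEGATED, NEGATED, NOT_NEGATED] + [NOT_NEGATED] * 5
        r = prf(pred, gold)
        micro, macro = micro_macro([r])
        assert micro == pytest.approx(r.f1) and macro == pytest.approx(r.f1)

    def test_micro_equals_pooled_count_f1_oracle(self):
        rng = np.random.default_rng(0)
        sizes = [10, 1000]
        results, pooled_pred, pooled_gold = [], [], []
        for n in sizes:
            gold = list(rng.choice([NEGATED, NOT_NEGATED], p=[0.3, 0.7], size=n))
            pred = [g if rng.random() > 0.2 else -g for g in gold]
            results.append(prf(pred, gold))
            pooled_pred += pred
            pooled_gold += gold
        micro, _ = micro_macro(results)
        _, _, f_oracle = oracle_prf(pooled_pred, pooled_gold)
        assert micro == pytest.approx(f_oracle, abs=1e-9)


class TestApproxRandomization:
    def _docs(self, n_docs, per_doc):
        return [f"d{i}" for i in range(n_docs) for _ in range(per_doc)]

    def test_identical_systems_give_p_one(self):
        rng = np.random.default_rng(1)
        docs = self._docs(10, 5)
        gold = list(rng.choice([NEGATED, NOT_NEGATED], p=[0.3, 0.7], size=len(docs)))
        pred = [g if rng.random() > 0.2 else -g for g in gold]
        res = approx_randomization(pred, pred, gold, n_shuffles=500, seed=0, doc_ids=docs)
        assert res.p_value == 1.0

    def test_perfect_vs_always_wrong_is_significant(self):
        docs = self._docs(20, 5)
        rng = np.random.default_rng(2)
        gold = list(rng.choice([NEGATED, NOT_NEGATED], p=[0.4, 0.6], size=len(docs)))
        wrong = [-g for g in gold]
        res = approx_randomization(gold, wrong, gold, n_shuffles=2000, seed=0, doc_ids=docs)
        assert res.p_value <= 0.05

    def test_symmetric_under_system_relabeling(self):
        rng = np.random.default_rng(3)
        docs = self._docs(12, 4)
        gold = list(rng.choice([NEGATED, NOT_NEGATED], p=[0.3, 0.7], size=len(docs)))
        a = [g if rng.random() > 0.2 else -g for g in gold]
        b = [g if rng.random() > 0.3 else -g for g in gold]
        r_ab = approx_randomization(a, b, gold, n_shuffles=1000, seed=9, doc_ids=docs)
        r_ba = approx_randomization(b, a, gold, n_shuffles=1000, seed=9, doc_ids=docs)
        assert r_ab.p_value == r_ba.p_value
        assert r_ab.f1_a == r_ba.f1_b

    def test_single_document_rejected(self):
        gold = [NEGATED, NOT_NEGATED]
        with pytest.raises(ValueError, match="at least 2 documents"):
            approx_randomization(gold, gold, gold, doc_ids=["d", "d"])

    def test_seeded_reproducible(self):
        rng = np.random.default_rng(4)
        docs = self._docs(8, 4)
        gold = list(rng.choice([NEGATED, NOT_NEGATED], p=[0.3, 0.7], size=len(docs)))
        a = [g if rng.random() > 0.25 else -g for g in gold]
        b = [g if rng.random() > 0.25 else -g for g in gold]
        r1 = approx_randomization(a, b, gold, n_shuffles=500, seed=7, doc_ids=docs)
        r2 = approx_randomization(a, b, gold, n_shuffles=500, seed=7, doc_ids=docs)
        assert r1 == r2


def inst(feats, label):
    return TrainingInstance(frozenset(FeatureName("BOW", k) for k in feats), label, "a", "d")


class TestChi2:
    def test_perfect_association_balanced_equals_n(self):
        # feature present iff negated, 50/50 over n=100
        insts = [inst(["x"], NEGATED) for _ in range(50)] + [
            inst(["y"], NOT_NEGATED) for _ in range(50)
        ]
        rows = {str(r.feature): r.chi2 for r in chi2_rank(insts)}
        assert rows["BOW:x"] == pytest.approx(100.0)

    def test_independent_feature_is_zero(self):
        insts = (
            [inst(["x"], NEGATED)] * 10
            + [inst([], NEGATED)] * 10
            + [inst(["x"], NOT_NEGATED)] * 10
            + [inst([], NOT_NEGATED)] * 10
        )
        rows = {str(r.feature): r.chi2 for r in chi2_rank(insts)}
        assert rows["BOW:x"] == pytest.approx(0.0)

    @pytest.mark.parametrize("seed", range(15))
    def test_agrees_with_scipy_oracle_on_random_tables(self, seed):
        rng = np.random.default_rng(seed)
        a, b, c, d = (int(x) for x in rng.integers(1, 50, size=4))
        expected = chi2_contingency([[a, b], [c, d]], correction=False)[0]
        assert chi2_statistic(a, b, c, d) == pytest.approx(expected, rel=1e-12)

    def test_rank_invariant_to_instance_order(self):
        insts = (
            [inst(["x", "z"], NEGATED)] * 5
            + [inst(["y"], NOT_NEGATED)] * 7
            + [inst(["z"], NOT_NEGATED)] * 3
        )
        r1 = chi2_rank(insts)
        r2 = chi2_rank(list(reversed(insts)))
        assert [(r.feature, r.chi2) for r in r1] == [(r.feature, r.chi2) for r in r2]

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            chi2_rank([inst(["x"], NEGATED)] * 3)

    def test_cross_model_rank_table(self):
        by_model = {
            "all": [inst(["x"], NEGATED)] * 5 + [inst(["y"], NOT_NEGATED)] * 5,
            "m1": [inst(["x"], NEGATED)] * 3 + [inst(["y"], NOT_NEGATED)] * 3,
        }
        rows = feature_rank_table(by_model, reference="all")
        assert rows[0].rank_by_model["all"] == 1
        assert "m1" in rows[0].rank_by_model


class TestStratified:
    def test_single_stratum_equals_overall(self):
        c = make_corpus(
            [("no cough", (1, 2), NEGATED), ("has pain", (1, 2), NOT_NEGATED)]
        )
        preds = [NEGATED, NOT_NEGATED]
        strata = stratified_eval(preds, c, "ne_length")
        assert list(strata) == [1]
        overall = prf(preds, c)
        assert strata[1].f1 == overall.f1

    def test_stratum_counts_sum_to_total(self):
        c = make_corpus(
            [
                ("no cough", (1, 2), NEGATED),
                ("without chest pain", (1, 3), NEGATED),
                ("has mild rash today", (1, 4), NOT_NEGATED),
            ]
        )
        preds = [NEGATED, NOT_NEGATED, NOT_NEGATED]
        strata = stratified_eval(preds, c, "ne_length")
        assert sum(r.counts.total for r in strata.values()) == 3

    def test_strata_recomputed_by_filtering_oracle(self):
        rng = np.random.default_rng(0)
        records = []
        for i in range(40):
            length = int(rng.integers(1, 4))
            text = "no " + " ".join(f"w{j}" for j in range(length)) + " trailing"
            records.append((text, (1, 1 + length), int(rng.choice([NEGATED, NOT_NEGATED]))))
        c = make_corpus(records)
        preds = [int(rng.choice([NEGATED, NOT_NEGATED])) for _ in records]
        strata = stratified_eval(preds, c, "ne_length")
        for length, res in strata.items():
            sel = [i for i, ne in enumerate(c.entities) if ne.length == length]
            _, _, f_oracle = oracle_prf([preds[i] for i in sel], [records[i][2] for i in sel])
            assert res.f1 == pytest.approx(f_oracle)

    def test_unknown_stratifier_rejected(self):
        c = make_corpus([("no cough", (1, 2), NEGATED)])
        with pytest.raises(ValueError):
            stratified_eval([NEGATED], c, "phase_of_moon")


class TestLearningCurve:
    def test_points_cover_proportions_and_average_runs(self):
        cfg = dataclasses.replace(
            preset_suite("shared_core"), n_documents=10, sentences_per_document=10, seed=2
        )
        corpora = generate(cfg)
        curves = learning_curve(
            corpora["source"],
            [corpora["target"]],
            train_config=TrainConfig(regularization_grid=(1.0,)),
            proportions=(0.5, 1.0),
            runs=2,
            seed=0,
        )
        pts = curves["target"]
        assert [p.proportion for p in pts] == [0.5, 1.0]
        for p in pts:
            assert p.n_runs == 2 and len(p.per_run_f1) == 2
            assert p.mean_f1 == pytest.approx(np.mean(p.per_run_f1))

    def test_empty_training_corpus_rejected(self):
        from clinneg.corpus import Corpus

        with pytest.raises(ValueError, match="empty"):
            learning_curve(Corpus("e", "d"), [])
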