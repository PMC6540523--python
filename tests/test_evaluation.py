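"""Evaluation metrics against independent oracles: all-pairs AUC, exhaustive
F1 scans, eligibility boundaries, bootstrap stability, peptidome scoring."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import mhcbind as m
from mhcbind.evaluation import (ScoredSet, auc, best_f1, bootstrap_auc_cv,
                                peptidome_score, per_allele_report)


def pairwise_auc(scores, labels):
    """Brute-force Mann-Whitney: mean over all (pos, neg) pairs of
    1[s_p > s_n] + 0.5 * 1[s_p == s_n]."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = (pos[:, None] > neg[None, :]).sum()
    ties = (pos[:, None] == neg[None, :]).sum()
    return (wins + 0.5 * ties) / (len(pos) * len(neg))


def exhaustive_best_f1(scores, labels):
    """Independent scan over every distinct threshold, ties to the higher."""
    best, best_t = -1.0, None
    for t in sorted(set(scores), reverse=True):
        pred = np.asarray(scores) >= t
        tp = int((pred & (np.asarray(labels) == 1)).sum())
        fp = int((pred & (np.asarray(labels) == 0)).sum())
        fn = int((~pred & (np.asarray(labels) == 1)).sum())
        f1 = 2 * tp / (2 * tp + fp + fn) if tp else 0.0
        if f1 > best:
            best, best_t = f1, t
    return best, best_t


class TestAUC:
    def test_perfect_separation(self):
        assert auc(scores=[0.9, 0.8, 0.2, 0.1], labels=[1, 1, 0, 0]) == 1.0

    def test_perfect_inversion(self):
        assert auc(scores=[0.3, 0.7], labels=[1, 0]) == 0.0

    def test_single_class_undefined(self):
        with pytest.raises(ValueError, match="one class"):
            auc(scores=[0.5, 0.6], labels=[1, 1])

    @given(st.integers(0, 2 ** 32 - 1))
    @settings(max_examples=60, deadline=None)
    def test_matches_pairwise_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 100))
        scores = rng.choice(np.round(rng.random(12), 2), size=n)
        labels = rng.integers(0, 2, size=n)
        if labels.min() == labels.max():
            labels[0] = 1 - labels[0]
        assert auc(scores=scores, labels=labels) == pytest.approx(
            pairwise_auc(scores, labels), abs=1e-12)


class TestBestF1:
    def test_three_point_example(self):
        f1, t = best_f1(scores=[0.9, 0.8, 0.2], labels=[1, 1, 0])
        assert f1 == 1.0 and t == 0.8

    def test_degenerate_inverted_scores(self):
        # all positives below all negatives: best is predict-everything
        p, n = 3, 4
        scores = [0.1] * p + [0.9] * n
        labels = [1] * p + [0] * n
        f1, t = best_f1(scores=scores, labels=labels)
        assert f1 == pytest.approx(2 * p / (2 * p + n))
        assert t == 0.1

    def test_constant_scores(self):
        p, n = 2, 3
        f1, t = best_f1(scores=[0.5] * (p + n), labels=[1] * p + [0] * n)
        assert f1 == pytest.approx(2 * p / (2 * p + n)) and t == 0.5

    @given(st.integers(0, 2 ** 32 - 1))
    @settings(max_examples=60, deadline=None)
    def test_matches_exhaustive_scan(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 60))
        scores = rng.choice(np.round(rng.random(8), 2), size=n)
        labels = rng.integers(0, 2, size=n)
        if labels.min() == labels.max():
            labels[0] = 1 - labels[0]
        f1, t = best_f1(scores=scores, labels=labels)
        ef1, et = exhaustive_best_f1(scores, labels)
        assert f1 == pytest.approx(ef1, abs=1e-12)
        assert t == pytest.approx(et, abs=1e-12)

    def test_value_dominates_every_threshold(self):
        rng = np.random.default_rng(3)
        scores = rng.random(50)
        labels = rng.integers(0, 2, size=50)
        f1, _ = best_f1(scores=scores, labels=labels)
        for t in np.unique(scores):
            pred = scores >= t
            tp = (pred & (labels == 1)).sum()
            fp = (pred & (labels == 0)).sum()
            fn = (~pred & (labels == 1)).sum()
            assert f1 >= (2 * tp / (2 * tp + fp + fn) if tp else 0.0) - 1e-12


class TestPerAlleleReport:
    @staticmethod
    def _scored(n, n_pos, allele="HLA-A*01:01", seed=0):
        rng = np.random.default_rng(seed)
        labels = np.array([1] * n_pos + [0] * (n - n_pos))
        scores = np.clip(labels * 0.6 + rng.random(n) * 0.4, 0, 1)
        return ScoredSet(scores, labels, alleles=[allele] * n)

    @pytest.mark.parametrize("n,n_pos,eligible", [
        (30, 5, True),      # exact boundary: 30 total, 5 pos, 25 neg
        (29, 5, False),     # below the record threshold
        (40, 4, False),     # too few positives
        (40, 36, False),    # too few negatives
        (30, 25, True),     # 5 negatives exactly
    ])
    def test_eligibility_boundaries(self, n, n_pos, eligible):
        report = per_allele_report(self._scored(n, n_pos))
        assert bool(report.per_allele.iloc[0]["eligible"]) is eligible

    def test_fold_averaging_when_folds_present(self):
        rng = np.random.default_rng(1)
        labels = np.tile([1] * 10 + [0] * 10, 2)
        scores = np.clip(labels * 0.5 + rng.random(40) * 0.5, 0, 1)
        folds = np.repeat([0, 1], 20)
        s = ScoredSet(scores, labels, alleles=["A*01:01"] * 40, folds=folds)
        report = per_allele_report(s)
        row = report.per_allele.iloc[0]
        per_fold = np.mean([
            auc(scores=scores[folds == f], labels=labels[folds == f])
            for f in (0, 1)])
        assert row["auc"] == pytest.approx(per_fold)
        assert not row["pooled"]


class TestBootstrap:
    def test_perfect_separation_has_zero_cv(self):
        s = ScoredSet(np.r_[np.full(100, 0.9), np.full(100, 0.1)],
                      np.r_[np.ones(100, int), np.zeros(100, int)])
        assert bootstrap_auc_cv(s, n_boot=50, seed=1) < 1e-6

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(2)
        labels = rng.integers(0, 2, 80)
        labels[:2] = [0, 1]
        s = ScoredSet(rng.random(80), labels)
        assert bootstrap_auc_cv(s, seed=7) == bootstrap_auc_cv(s, seed=7)


class TestPeptidomeScoring:
    class _AnchorModel:
        """Stand-in ensemble scoring by the synthetic ground-truth rule."""

        def __init__(self, rule, jitter=0.0):
            self.rule = rule
            self.jitter = jitter

        def predict_proba_pairs(self, peptides, alleles):
            base = np.array([self.rule(p, a)
                             for p, a in zip(peptides, alleles)], float)
            rng = np.random.default_rng(0)
            return np.clip(base * 0.8 + 0.1 + self.jitter * rng.random(len(base)),
                           0, 1)

    @pytest.fixture()
    def setup(self):
        names, pseudo, rule = m.generate_alleles(
            m.SyntheticAlleleSpec(n_alleles=5, seed=4))
        sample = m.generate_peptidome(names[:3], rule, 30, 30, seed=4)
        return names, rule, sample

    def test_rule_model_ranks_peptidome_perfectly(self, setup):
        _, rule, sample = setup
        scored = peptidome_score(self._AnchorModel(rule), sample)
        assert auc(scored) == 1.0

    def test_allele_order_invariance(self, setup):
        _, rule, sample = setup
        a = peptidome_score(self._AnchorModel(rule, 0.05), sample)
        sample.alleles = sample.alleles[::-1]
        b = peptidome_score(self._AnchorModel(rule, 0.05), sample)
        assert np.array_equal(a.scores, b.scores)

    def test_adding_allele_is_monotone(self, setup):
        names, rule, sample = setup
        base = peptidome_score(self._AnchorModel(rule, 0.05), sample)
        import copy
        bigger = copy.deepcopy(sample)
        bigger.alleles = bigger.alleles + [names[3]]
        more = peptidome_score(self._AnchorModel(rule, 0.05), bigger)
        assert np.all(more.scores >= base.scores - 1e-12)

    def test_training_overlap_removed(self, setup):
        _, rule, sample = setup
        overlap = {sample.positives[0], sample.negatives[0]}
        scored = peptidome_score(self._AnchorModel(rule), sample,
                                 training_peptides=overlap)
        assert len(scored.scores) == len(sample.positives) \
            + len(sample.negatives) - 2
        assert not overlap & set(scored.peptides)

    def test_single_allele_equals_plain_prediction(self, setup):
        names, rule, sample = setup
        import copy
        solo = copy.deepcopy(sample)
        solo.alleles = [sample.alleles[0]]
        model = self._AnchorModel(rule, 0.05)
        scored = peptidome_score(model, solo)
        direct = model.predict_proba_pairs(
            scored.peptides, [solo.alleles[0]] * len(scored.peptides))
        assert np.array_equal(scored.scores, direct)
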