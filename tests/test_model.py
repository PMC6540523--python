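"""Binding classifier: construction contracts, inference behavior, grouped
cross-validation and the median ensemble."""

import numpy as np
import pandas as pd
import pytest

import mhcbind as m
from mhcbind.embedding import one_hot_table, train_skipgram
from mhcbind.model import (BindingClassifier, EnsembleModel, FinetuneSchedule,
                           cross_validate, ensemble_predict, grouped_folds)


def small_clf(**kw):
    base = dict(gru_units=8, mhc_fc_units=50, head_fc_units=64,
                max_epochs=2, patience=2, random_state=0)
    base.update(kw)
    return BindingClassifier(**base)


def tiny_fit(clf, study, n=120):
    df = study["dataset"].to_frame().head(n)
    clf.fit(df[["peptide", "allele"]], df["label"].to_numpy())
    return clf, df


class TestConstruction:
    def test_sequence_mode_requires_pseudo_table(self, synthetic_study):
        df = synthetic_study["dataset"].to_frame().head(60)
        clf = small_clf(mhc_repr="sequence", pseudo_sequences=None)
        with pytest.raises(ValueError, match="pseudo"):
            clf.fit(df[["peptide", "allele"]], df["label"].to_numpy())

    def test_gram1_embedding_dimension_propagates(self, synthetic_study):
        corpus = [list("ACDEFGHIKLMNPQRSTVWY")] * 30
        table = train_skipgram(corpus, dim=5, epochs=1, seed=0)
        clf = small_clf(pep_dim=5, pretrained_embeddings=table,
                        pseudo_sequences=synthetic_study["pseudo"])
        clf, _ = tiny_fit(clf, synthetic_study)
        assert clf._net.pep_embedding.table.shape[1] == 5

    def test_gram3_requires_100_dim_table(self, synthetic_study):
        corpus = [list("ACDEFGHIKLMNPQRSTVWY")] * 5
        table = train_skipgram(corpus, dim=4, epochs=1, seed=0)
        clf = small_clf(peptide_repr="gram3", pretrained_embeddings=table,
                        pseudo_sequences=synthetic_study["pseudo"])
        df = synthetic_study["dataset"].to_frame().head(60)
        with pytest.raises(ValueError, match="100"):
            clf.fit(df[["peptide", "allele"]], df["label"].to_numpy())

    def test_one_hot_peptide_table_is_identity_sized(self, synthetic_study):
        clf = small_clf(peptide_repr="one_hot",
                        pseudo_sequences=synthetic_study["pseudo"])
        clf, _ = tiny_fit(clf, synthetic_study)
        tab = clf._net.pep_embedding.table.data
        assert tab.shape[0] == tab.shape[1] == len(clf._pep_vocab)

    def test_empty_or_single_class_training_rejected(self, synthetic_study):
        clf = small_clf(pseudo_sequences=synthetic_study["pseudo"])
        with pytest.raises(ValueError, match="empty"):
            clf.fit(np.empty((0, 2), dtype=object), np.empty(0))
        df = synthetic_study["dataset"].to_frame()
        pos = df[df["label"] == 1].head(40)
        with pytest.raises(ValueError, match="single class"):
            clf.fit(pos[["peptide", "allele"]], pos["label"].to_numpy())

    def test_invalid_dropout_rejected(self, synthetic_study):
        clf = small_clf(dropout_fc_out=1.0,
                        pseudo_sequences=synthetic_study["pseudo"])
        df = synthetic_study["dataset"].to_frame().head(60)
        with pytest.raises(ValueError, match="dropout"):
            clf.fit(df[["peptide", "allele"]], df["label"].to_numpy())


class TestInference:
    def test_output_in_open_unit_interval(self, trained_sequence_model,
                                          synthetic_study):
        df = synthetic_study["dataset"].to_frame().head(200)
        p = trained_sequence_model.predict_proba(df[["peptide", "allele"]])[:, 1]
        assert np.all(p > 0) and np.all(p < 1)

    def test_inference_is_deterministic(self, trained_sequence_model,
                                        synthetic_study):
        df = synthetic_study["dataset"].to_frame().head(50)
        a = trained_sequence_model.predict_proba(df[["peptide", "allele"]])
        b = trained_sequence_model.predict_proba(df[["peptide", "allele"]])
        assert np.array_equal(a, b)

    def test_length_flexibility_8_to_15(self, trained_sequence_model,
                                        synthetic_study):
        allele = synthetic_study["alleles"][0]
        for k in range(8, 16):
            p = trained_sequence_model.predict_pair("ACDEFGHIKLMNPQR"[:k],
                                                    allele)
            assert 0 < p < 1

    def test_one_hot_mode_rejects_unseen_allele(self, trained_onehot_model):
        with pytest.raises(KeyError, match="registry"):
            trained_onehot_model.predict_pair("ACDEFGHIK", "SYN-A*99:01")

    def test_sequence_mode_scores_unseen_allele_with_pseudo(self,
                                                            synthetic_study):
        # an allele absent from training is scorable once its groove
        # sequence is known
        names, pseudo, _ = m.generate_alleles(
            m.SyntheticAlleleSpec(n_alleles=7, seed=99))
        full = dict(synthetic_study["pseudo"])
        full["NEW-X*01:01"] = pseudo[names[6]]
        clf = small_clf(pseudo_sequences=full)
        clf, _ = tiny_fit(clf, synthetic_study)
        assert 0 < clf.predict_pair("ACDEFGHIK", "NEW-X*01:01") < 1

    def test_unknown_pseudo_sequence_raises(self, trained_sequence_model):
        with pytest.raises(KeyError, match="pseudo"):
            trained_sequence_model.predict_pair("ACDEFGHIK", "NOPE-*01:01")

    def test_ambiguous_peptide_letters_rejected(self, trained_sequence_model,
                                                synthetic_study):
        with pytest.raises(ValueError, match="invalid"):
            trained_sequence_model.predict_pair("SIXNFEKLM",
                                                synthetic_study["alleles"][0])


class TestTraining:
    def test_best_validation_weights_restored(self, trained_sequence_model):
        h = trained_sequence_model.history_["val_loss"]
        assert trained_sequence_model.best_val_loss_ <= h[-1] + 1e-9
        assert trained_sequence_model.best_val_loss_ == pytest.approx(min(h))

    def test_explicit_validation_disjointness_enforced(self, synthetic_study):
        df = synthetic_study["dataset"].to_frame().head(80)
        clf = small_clf(pseudo_sequences=synthetic_study["pseudo"])
        with pytest.raises(ValueError, match="share peptides"):
            clf.fit(df[["peptide", "allele"]], df["label"].to_numpy(),
                    validation=(df[["peptide", "allele"]],
                                df["label"].to_numpy()))

    def test_finetune_schedule_runs_three_phases(self, synthetic_study):
        df = synthetic_study["dataset"].to_frame().head(300)
        clf = small_clf(peptide_repr="gram3", max_epochs=8,
                        finetune=FinetuneSchedule(unfreeze_epochs=2),
                        pseudo_sequences=synthetic_study["pseudo"])
        clf.fit(df[["peptide", "allele"]], df["label"].to_numpy())
        phases = clf.history_["phase"]
        assert phases.count("adapt") <= 2
        assert phases[0] == "frozen"
        # adaptation happens strictly between the two frozen stretches
        if "adapt" in phases:
            first = phases.index("adapt")
            assert all(p == "frozen" for p in phases[:first])

    def test_invalid_finetune_epochs(self):
        with pytest.raises(ValueError):
            FinetuneSchedule(unfreeze_epochs=4)

    def test_reproducible_under_seed(self, synthetic_study):
        df = synthetic_study["dataset"].to_frame().head(150)
        scores = []
        for _ in range(2):
            clf = small_clf(pseudo_sequences=synthetic_study["pseudo"],
                            random_state=11)
            clf.fit(df[["peptide", "allele"]], df["label"].to_numpy())
            scores.append(clf.predict_proba(df[["peptide", "allele"]])[:, 1])
        assert np.array_equal(scores[0], scores[1])


class TestGroupedCV:
    def test_no_peptide_spans_folds(self, synthetic_study):
        df = synthetic_study["dataset"].to_frame()
        folds = grouped_folds(df["peptide"].tolist(), 5, seed=0)
        spans = pd.DataFrame({"peptide": df["peptide"], "fold": folds}) \
            .groupby("peptide")["fold"].nunique()
        assert (spans == 1).all()

    def test_fold_balance_within_largest_group(self):
        rng = np.random.default_rng(0)
        peptides = []
        for i in range(200):
            peptides.extend([f"PEP{i:04d}"] * rng.integers(1, 6))
        folds = grouped_folds(peptides, 5, seed=1)
        counts = np.bincount(folds, minlength=5)
        assert counts.max() - counts.min() <= 5   # <= largest group size

    def test_too_few_groups_rejected(self):
        with pytest.raises(ValueError):
            grouped_folds(["AAA", "AAA", "BBB"], 5)

    def test_every_record_scored_once_out_of_fold(self, synthetic_study):
        df = synthetic_study["dataset"].to_frame().head(400)
        ds = m.CleanedDataset([r for r in synthetic_study["dataset"].records][:400])
        _, oof = cross_validate(
            ds, estimator_params=dict(
                gru_units=8, mhc_fc_units=50, head_fc_units=64, max_epochs=2,
                pseudo_sequences=synthetic_study["pseudo"]),
            seed=4)
        assert len(oof) == 400
        assert oof["score"].notna().all()
        assert set(oof["fold"].unique()) == set(range(5))


class TestEnsemble:
    class _Const:
        def __init__(self, value):
            self.value = value

        def predict_proba(self, X):
            p = np.full(len(np.asarray(X, dtype=object)), self.value)
            return np.column_stack([1 - p, p])

    def _ensemble(self, values):
        return EnsembleModel([self._Const(v) for v in values])

    def test_median_of_five(self):
        e = self._ensemble([0.1, 0.2, 0.9, 0.95, 0.99])
        assert ensemble_predict(e, "ACDEFGHIK", "X") == pytest.approx(0.9)

    def test_identical_members(self):
        e = self._ensemble([0.5] * 5)
        assert e.predict_pair("ACDEFGHIK", "X") == 0.5

    def test_bounded_by_member_range(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            vals = rng.random(5)
            e = self._ensemble(vals)
            p = e.predict_pair("ACDEFGHIK", "X")
            assert vals.min() <= p <= vals.max()

    def test_member_count_enforced(self):
        with pytest.raises(ValueError):
            EnsembleModel([self._Const(0.5)] * 4)


class TestPersistence:
    def test_checkpoint_roundtrip(self, trained_sequence_model, tmp_path,
                                  synthetic_study):
        from mhcbind.persistence import load_model, save_model
        save_model(trained_sequence_model, tmp_path / "ckpt")
        back = load_model(tmp_path / "ckpt")
        df = synthetic_study["dataset"].to_frame().head(40)
        a = trained_sequence_model.predict_proba(df[["peptide", "allele"]])
        b = back.predict_proba(df[["peptide", "allele"]])
        assert np.array_equal(a, b)

    def test_wrong_format_version_rejected(self, trained_sequence_model,
                                           tmp_path):
        import json
        from mhcbind.persistence import load_model, save_model
        save_model(trained_sequence_model, tmp_path / "ckpt")
        meta = json.loads((tmp_path / "ckpt" / "model.json").read_text())
        meta["format_version"] = 99
        (tmp_path / "ckpt" / "model.json").write_text(json.dumps(meta))
        with pytest.raises(ValueError, match="format"):
            load_model(tmp_path / "ckpt")
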