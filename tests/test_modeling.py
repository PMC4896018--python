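"""Cross-validation, grid search, final training, selection and persistence."""

import numpy as np
import pytest

from otolabel import (ALGORITHMS, FeatureConfig, MetricsReport, ModelCandidate,
                      cross_validate, grid_search, load_bundle, predict,
                      run_experiment, save_bundle, select_best_region_model,
                      stratified_split, train_final)
from otolabel.modeling import compact_grid, paper_grid
from otolabel.synthetic import SyntheticConfig, generate_corpus

LR = ModelCandidate("logistic_regression", {"l": 1.0},
                    FeatureConfig("word", 1, 1, "count"))


def _metrics(accuracy, f1):
    return MetricsReport(accuracy=accuracy, f1=f1, ppv=f1, npv=f1,
                         sensitivity=f1, specificity=f1)


class TestCrossValidate:
    def test_separable_corpus_reaches_perfect_accuracy(self, toy_corpus):
        docs, labels = toy_corpus
        result = cross_validate(LR, docs, labels, folds=5, seed=0)
        assert result.mean_accuracy == 1.0
        assert len(result.fold_accuracies) == 5

    def test_single_class_corpus_rejected(self):
        docs = [["a"]] * 10
        with pytest.raises(ValueError, match="single class"):
            cross_validate(LR, docs, [True] * 10)

    def test_too_few_class_members_rejected(self):
        docs = [["pos"]] * 3 + [["neg"]] * 20
        labels = [True] * 3 + [False] * 20
        with pytest.raises(ValueError, match="at least"):
            cross_validate(LR, docs, labels, folds=5)

    def test_folds_partition_the_training_set(self, toy_corpus):
        docs, labels = toy_corpus
        from otolabel.modeling import _cv_folds
        folds = _cv_folds(np.asarray(labels), 5, seed=1)
        val_all = np.concatenate([v for _, v in folds])
        assert sorted(val_all.tolist()) == list(range(len(docs)))
        for fit_idx, val_idx in folds:
            assert abs(len(val_idx) - len(docs) / 5) <= 1
            assert not set(fit_idx) & set(val_idx)

    def test_deterministic_for_fixed_seed(self, small_docs_labels):
        docs, labels = small_docs_labels
        a = cross_validate(LR, docs, labels["middle"], seed=7)
        b = cross_validate(LR, docs, labels["middle"], seed=7)
        assert a.fold_accuracies == b.fold_accuracies

    def test_no_vocabulary_leakage_between_folds(self, small_corpus):
        # a token unique to a validation document must not enter that fold's
        # vocabulary
        from otolabel.modeling import _cv_folds
        from otolabel.preprocess import preprocess_report
        docs = [preprocess_report(r.text) for r in small_corpus[:60]]
        for i, doc in enumerate(docs):
            doc.append(f"uniquetoken{i}")
        labels = [r.labels.any_abnormal for r in small_corpus[:60]]
        result = cross_validate(LR, docs, labels, seed=0,
                                collect_vocabularies=True)
        folds = _cv_folds(np.asarray(labels), 5, seed=0)
        for vocab, (fit_idx, val_idx) in zip(result.fold_vocabularies, folds):
            vocab = set(vocab)
            for i in val_idx:
                assert f"uniquetoken{i}" not in vocab
            for i in fit_idx:
                assert f"uniquetoken{i}" in vocab


class TestGridSearch:
    def test_degenerate_candidate_not_selected(self):
        # "aabb" and "abab" have identical character-unigram counts, so the
        # first candidate sees constant features and cannot split
        docs = [["aabb", "fill"]] * 20 + [["abab", "fill"]] * 20
        labels = [True] * 20 + [False] * 20
        useless = ModelCandidate("decision_tree", {"max_depth": 1},
                                 FeatureConfig("character", 1, 1, "count"))
        stump = ModelCandidate("decision_tree", {"max_depth": 1},
                               FeatureConfig("word", 1, 1, "count"))
        result = grid_search("decision_tree", [useless, stump], docs, labels,
                             seed=0)
        assert result.best == stump

    def test_matches_bruteforce_exhaustive_cv(self, small_docs_labels):
        # oracle: evaluate every candidate independently via cross_validate
        docs, labels = small_docs_labels
        docs, labels = docs[:120], labels["middle"][:120]
        grid = [
            ModelCandidate("logistic_regression", {"l": l}, fc)
            for l in (0.1, 1.0)
            for fc in (FeatureConfig("word", 1, 1, "count"),
                       FeatureConfig("word", 1, 2, "binary"))
        ]
        result = grid_search("logistic_regression", grid, docs, labels, seed=4)
        oracle = [cross_validate(c, docs, labels, seed=4) for c in grid]
        for got, exp in zip(result.results, oracle):
            assert got.fold_accuracies == pytest.approx(exp.fold_accuracies)
        means = [r.mean_accuracy for r in oracle]
        assert result.best == grid[int(np.argmax(means))]

    def test_empty_grid_rejected(self, toy_corpus):
        docs, labels = toy_corpus
        with pytest.raises(ValueError, match="empty"):
            grid_search("logistic_regression", [], docs, labels)

    def test_mismatched_algorithm_rejected(self, toy_corpus):
        docs, labels = toy_corpus
        with pytest.raises(ValueError, match="expected"):
            grid_search("svm_linear", [LR], docs, labels)

    def test_default_grids_cover_published_optima(self):
        lr = {(c.hyperparameters.get("l"),
               (c.feature_config.unit, c.feature_config.n_min,
                c.feature_config.n_max)) for c in paper_grid("logistic_regression")}
        assert (0.1, ("word", 1, 3)) in lr
        svm = {(c.hyperparameters.get("C"),
                (c.feature_config.unit, c.feature_config.n_min,
                 c.feature_config.n_max)) for c in paper_grid("svm_linear")}
        assert (0.1, ("word", 1, 2)) in svm
        assert (0.333, ("word", 1, 3)) in svm
        dt = {(c.hyperparameters.get("max_depth"),
               (c.feature_config.unit, c.feature_config.n_min,
                c.feature_config.n_max)) for c in paper_grid("decision_tree")}
        assert (2, ("character", 1, 3)) in dt

    def test_naive_bayes_requires_binary_features(self):
        with pytest.raises(ValueError, match="binary"):
            ModelCandidate("naive_bayes", {},
                           FeatureConfig("word", 1, 1, "count"))


class TestTrainFinalAndPredict:
    def test_training_accuracy_on_separable_corpus(self, toy_corpus):
        docs, labels = toy_corpus
        clf = train_final(LR, docs, labels, seed=0)
        assert np.array_equal(clf.predict_docs(docs), np.asarray(labels))

    def test_logistic_scores_are_probabilities(self, toy_corpus):
        docs, labels = toy_corpus
        clf = train_final(LR, docs, labels, seed=0)
        scores = clf.score_docs(docs)
        assert np.all((scores >= 0) & (scores <= 1))

    def test_predict_on_training_exemplar_text(self, small_corpus):
        from otolabel.preprocess import preprocess_report
        docs = [preprocess_report(r.text) for r in small_corpus]
        labels = [r.labels["middle"] for r in small_corpus]
        clf = train_final(LR, docs, labels, seed=0, region="middle")
        exemplar = next(r for r in small_corpus if r.labels["middle"])
        label, score = predict(clf, exemplar.text)
        assert isinstance(label, bool) and isinstance(score, float)

    def test_out_of_vocabulary_text_is_deterministic(self, toy_corpus):
        docs, labels = toy_corpus
        clf = train_final(LR, docs, labels, seed=0)
        first = predict(clf, "zzz qqq completely unseen words")
        assert first == predict(clf, "other fully unseen vocabulary here")

    def test_batch_prediction_preserves_order_and_length(self, toy_corpus):
        docs, labels = toy_corpus
        clf = train_final(LR, docs, labels, seed=0)
        pred = clf.predict_docs(docs[:7])
        assert len(pred) == 7
        assert pred.tolist() == [clf.predict_docs([d])[0] for d in docs[:7]]

    def test_persistence_round_trip_preserves_predictions(self, tmp_path,
                                                          small_corpus):
        from otolabel.preprocess import preprocess_report
        docs = [preprocess_report(r.text) for r in small_corpus]
        classifiers = {}
        for region in ("inner", "middle", "outer", "mastoid"):
            labels = [r.labels[region] for r in small_corpus]
            classifiers[region] = train_final(LR, docs, labels, seed=0,
                                              region=region)
        save_bundle(classifiers, tmp_path / "b", seed=0)
        bundle = load_bundle(tmp_path / "b")
        for region, clf in classifiers.items():
            loaded = bundle.classifiers[region]
            assert loaded.feature_space == clf.feature_space
            assert np.array_equal(loaded.predict_docs(docs),
                                  clf.predict_docs(docs))
            assert np.array_equal(loaded.score_docs(docs),
                                  clf.score_docs(docs))

    def test_load_bundle_missing_region_artifact_fails(self, tmp_path,
                                                       toy_corpus):
        docs, labels = toy_corpus
        clf = train_final(LR, docs, labels, seed=0, region="inner")
        save_bundle({"inner": clf}, tmp_path / "b", seed=0)
        (tmp_path / "b" / "inner.model.joblib").unlink()
        with pytest.raises(ValueError, match="missing artifacts"):
            load_bundle(tmp_path / "b")


class TestSelectBest:
    def test_accuracy_tie_broken_by_f1(self):
        table = {"logistic_regression": _metrics(0.90, 0.80),
                 "svm_linear": _metrics(0.90, 0.82)}
        assert select_best_region_model(table) == "svm_linear"

    def test_higher_accuracy_wins(self):
        table = {"logistic_regression": _metrics(0.93, 0.1),
                 "svm_linear": _metrics(0.82, 0.9)}
        assert select_best_region_model(table) == "logistic_regression"

    def test_single_entry(self):
        assert select_best_region_model(
            {"naive_bayes": _metrics(0.5, 0.5)}) == "naive_bayes"

    def test_full_tie_falls_back_to_enumeration_order(self):
        table = {"random_forest": _metrics(0.9, 0.8),
                 "decision_tree": _metrics(0.9, 0.8)}
        assert select_best_region_model(table) == "decision_tree"

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            select_best_region_model({})


def test_every_family_learns_separable_region_vocabulary():
    """With cleanly separable region vocabularies (no negation, no noise),
    every algorithm family reaches >= 0.95 test accuracy at n_train = 400."""
    corpus = generate_corpus(SyntheticConfig(
        n_reports=500, negation_rate=0.0, vocabulary_noise=0.0,
        label_noise=0.0, seed=5))
    split = stratified_split(corpus, 0.8, seed=5)
    result = run_experiment(split.train, split.test, seed=5, grid="compact")
    for region, rr in result.regions.items():
        for algo in ALGORITHMS:
            acc = rr.outcomes[algo].metrics.accuracy
            assert acc >= 0.95, f"{region}/{algo}: {acc}"
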