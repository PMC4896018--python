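"""Shared fixtures: synthetic corpora, a full pipeline run, a trained bundle."""

from __future__ import annotations

import pytest

from otolabel import (REGIONS, FeatureConfig, LabeledReport, ModelCandidate,
                      RegionLabelSet, SyntheticConfig, generate_corpus,
                      make_paper_scale_corpus, run_experiment, save_bundle,
                      stratified_split, train_final)
from otolabel.preprocess import preprocess_report


def make_toy_corpus(n_pos: int = 20, n_neg: int = 20):
    """A linearly separable toy corpus: a distinct marker token per class."""
    docs = ([["abnormalmarker", "filler", "tissue"]] * n_pos
            + [["normalmarker", "filler", "tissue"]] * n_neg)
    labels = [True] * n_pos + [False] * n_neg
    return docs, labels


@pytest.fixture(scope="session")
def toy_corpus():
    return make_toy_corpus()


@pytest.fixture(scope="session")
def small_corpus():
    """200 synthetic reports, no label noise; cheap enough for repeated fits."""
    return generate_corpus(SyntheticConfig(n_reports=200, label_noise=0.0,
                                           seed=3))


@pytest.fixture(scope="session")
def small_docs_labels(small_corpus):
    docs = [preprocess_report(r.text) for r in small_corpus]
    labels = {region: [r.labels[region] for r in small_corpus]
              for region in REGIONS}
    return docs, labels


@pytest.fixture(scope="session")
def paper_experiment():
    """The full pipeline on a noise-free study-scale corpus (726 reports)."""
    corpus = make_paper_scale_corpus(seed=1, label_noise=0.0)
    split = stratified_split(corpus, 0.8, seed=1)
    result = run_experiment(split.train, split.test, seed=1, grid="compact")
    return corpus, split, result


@pytest.fixture(scope="session")
def trained_bundle_dir(tmp_path_factory, small_corpus):
    """A four-region bundle trained with one fixed candidate (fast)."""
    path = tmp_path_factory.mktemp("bundle")
    docs = [preprocess_report(r.text) for r in small_corpus]
    candidate = ModelCandidate("logistic_regression", {"l": 1.0},
                               FeatureConfig("word", 1, 2, "count"))
    classifiers = {}
    for region in REGIONS:
        labels = [r.labels[region] for r in small_corpus]
        classifiers[region] = train_final(candidate, docs, labels, seed=0,
                                          region=region)
    save_bundle(classifiers, path, seed=0)
    return path
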