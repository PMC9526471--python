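"""Featurization, classifier training, prediction, locking, and dilution
behavior of the decision score."""

import numpy as np
import pandas as pd
import pytest

from mtcseq import classify
from mtcseq.containers import CountMatrix
from mtcseq.simulate import dilute_sample, sample_counts


def _matrix(counts, labels, cohort="train_fnab"):
    counts = np.asarray(counts)
    n = counts.shape[1]
    meta = pd.DataFrame({
        "sample_id": [f"s{i}" for i in range(n)],
        "cohort": cohort, "label": labels, "bethesda": "NA",
        "replicate_group": [None] * n, "dilution_fraction": [np.nan] * n,
    })
    return CountMatrix(counts=counts,
                       gene_ids=[f"g{i}" for i in range(counts.shape[0])],
                       sample_meta=meta)


SEPARABLE_TOY = np.array([
    # g0 high in the two MTC samples, g1 high in the two non-MTC samples,
    # g2 constant ballast
    [400, 380, 4, 6],
    [5, 8, 300, 320],
    [1000, 1000, 1000, 1000],
])
TOY_LABELS = ["MTC", "MTC", "non-MTC", "non-MTC"]


def test_featurize_standardizes_training_data(cohorts):
    train = cohorts.cohort("train_fnab")
    genes = train.gene_ids[:25]
    norm = classify.fit_normalization(train, genes)
    x = classify.featurize(train, genes, norm)
    assert np.allclose(x.mean(axis=0), 0.0, atol=1e-10)
    assert np.allclose(x.std(axis=0), 1.0, atol=1e-10)


def test_featurize_library_size_invariance():
    cm = _matrix(SEPARABLE_TOY, TOY_LABELS)
    doubled = SEPARABLE_TOY.copy()
    doubled[:, 0] *= 2
    cm2 = _matrix(doubled, TOY_LABELS)
    norm = classify.fit_normalization(cm, cm.gene_ids)
    a = classify.featurize(cm, cm.gene_ids, norm)
    b = classify.featurize(cm2, cm.gene_ids, norm)
    assert np.allclose(a[0], b[0])


def test_featurize_missing_gene_lists_ids(cohorts):
    train = cohorts.cohort("train_fnab")
    norm = classify.Normalization(mean=np.zeros(2), scale=np.ones(2))
    with pytest.raises(KeyError, match="NOPE"):
        classify.featurize(train, ["NOPE1", "NOPE2"], norm)


@pytest.mark.parametrize("family", classify.FAMILIES)
def test_separable_toy_trains_without_error(family):
    cm = _matrix(SEPARABLE_TOY, TOY_LABELS)
    clf = classify.train(cm, cm.gene_ids, family, seed=1)
    sv = classify.predict(clf, cm)
    assert list(sv.calls) == ["positive", "positive", "negative", "negative"]


def test_single_class_training_rejected():
    cm = _matrix(SEPARABLE_TOY, ["MTC"] * 4)
    with pytest.raises(ValueError):
        classify.train(cm, cm.gene_ids, "svm")


def test_enet_infinite_penalty_zeroes_weights(cohorts, candidate_sets):
    train = cohorts.cohort("train_fnab").select_samples(np.arange(80))
    clf = classify.train(train, candidate_sets[1].genes[:20], "enet_logistic",
                         hyperparams={"C": 1e-8})
    assert np.allclose(clf.weights, 0.0, atol=1e-6)


def test_training_performance_is_perfect_on_default_sim(cohorts, svm_set2):
    train = cohorts.cohort("train_fnab")
    sv = classify.predict(svm_set2, train)
    y = train.labels()
    assert np.all(sv.calls[y == "MTC"] == "positive")
    assert np.all(sv.calls[y == "non-MTC"] == "negative")


def test_predict_is_deterministic(cohorts, svm_set2):
    train = cohorts.cohort("train_fnab")
    a = classify.predict(svm_set2, train)
    b = classify.predict(svm_set2, train)
    assert np.array_equal(a.scores, b.scores)
    assert (a.calls == (a.scores > svm_set2.threshold)
            .choose(["negative", "positive"])).all()


def test_lock_round_trip_reproduces_scores(cohorts, svm_set2, tmp_path):
    from mtcseq.io import read_model, write_model
    clf = classify.TrainedClassifier.from_dict(svm_set2.to_dict())
    clf.lock()
    path = tmp_path / "model.json"
    write_model(clf, path)
    clf2 = read_model(path)
    assert clf2.locked
    valid = cohorts.cohort("valid_fnab")
    s1 = classify.predict(clf, valid).scores
    s2 = classify.predict(clf2, valid).scores
    assert np.max(np.abs(s1 - s2)) < 1e-9


def test_locked_classifier_is_immutable(svm_set2):
    clf = classify.TrainedClassifier.from_dict(svm_set2.to_dict())
    clf.lock()
    with pytest.raises(AttributeError):
        clf.threshold = 1.0
    with pytest.raises(AttributeError):
        clf.weights = np.zeros(len(clf.genes))


def dilution_scores(truth, default_config, clf, fractions, n_reps=5):
    """Mean classifier score of NB draws from diluted MTC profiles."""
    rng = np.random.default_rng(12345)
    mtc = truth.profile("MTC")
    ben = truth.profile("benign")
    means = []
    for f in fractions:
        prof = dilute_sample(mtc, ben, f)
        counts = sample_counts(np.column_stack([prof] * n_reps),
                               default_config, rng,
                               size_factors=np.ones(n_reps))
        cm = _diluted_matrix(counts, truth.gene_ids, f)
        means.append(classify.predict(clf, cm).scores.mean())
    return np.array(means)


def _diluted_matrix(counts, gene_ids, f):
    n = counts.shape[1]
    meta = pd.DataFrame({
        "sample_id": [f"d{f}_{i}" for i in range(n)],
        "cohort": "valid_fnab", "label": "MTC", "bethesda": "NA",
        "replicate_group": [None] * n, "dilution_fraction": [f] * n,
    })
    return CountMatrix(counts=counts, gene_ids=gene_ids, sample_meta=meta)


def test_dilution_monotonicity_and_75pct_tolerance(truth, default_config,
                                                   svm_set2):
    """Scores fall monotonically with the benign fraction, and the call is
    still positive at 75% benign dilution."""
    fractions = [0.0, 0.25, 0.5, 0.75, 1.0]
    means = dilution_scores(truth, default_config, svm_set2, fractions)
    assert np.all(np.diff(means) < 0)
    assert np.all(means[:4] > svm_set2.threshold)  # positive through 75%
    assert means[4] < svm_set2.threshold            # pure benign is negative
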