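"""Cross-validated model competition and the four-criterion selection."""

import numpy as np
import pandas as pd
import pytest

from conftest import small_sim
from mtcseq import classify, model_selection
from mtcseq.feature_sets import CandidateFeatureSet
from mtcseq.model_selection import (SelectionCriteria, compute_criteria,
                                    pooled_within_group_sd, repeated_cv,
                                    select_final)
from mtcseq.simulate import gene_params, simulate_cohorts, simulate_controls


@pytest.fixture(scope="module")
def small_world():
    cfg = small_sim(seed=13)
    cm = simulate_cohorts(cfg)
    truth = gene_params(cfg)
    train = cm.cohort("train_fnab")
    fset = CandidateFeatureSet(
        set_id=2, rule="signature", genes=truth.signature_genes,
        mandatory_genes=truth.cassette_genes)
    return cfg, cm, train, truth, fset


def test_repeated_cv_is_deterministic_and_complete(small_world):
    _, _, train, _, fset = small_world
    a = repeated_cv(train, [(fset, "svm")], k=4, repeats=2, seed=3)
    b = repeated_cv(train, [(fset, "svm")], k=4, repeats=2, seed=3)
    assert a.equals(b)
    assert len(a) == 8  # 2 repeats x 4 folds for the single setting
    assert a["sensitivity"].between(0, 1).all()


def test_cv_perfect_on_planted_signal(small_world):
    _, _, train, _, fset = small_world
    rep = repeated_cv(train, [(fset, "svm"), (fset, "enet_logistic")],
                      k=4, repeats=2, seed=3)
    summary = model_selection.cv_summary(rep)
    assert (summary["mean_sensitivity"] == 1.0).all()
    assert (summary["mean_specificity"] == 1.0).all()


def test_permuted_labels_destroy_sensitivity(small_world):
    _, _, train, _, fset = small_world
    rng = np.random.default_rng(4)
    shuffled = train.sample_meta.copy()
    shuffled["label"] = rng.permutation(shuffled["label"].to_numpy())
    from mtcseq.containers import CountMatrix
    permuted = CountMatrix(counts=train.counts, gene_ids=train.gene_ids,
                           sample_meta=shuffled)
    rep = repeated_cv(permuted, [(fset, "svm")], k=4, repeats=2, seed=3)
    assert rep["sensitivity"].mean() < 0.9


def test_too_few_mtc_for_stratification(small_world):
    _, _, train, _, fset = small_world
    with pytest.raises(ValueError):
        repeated_cv(train, [(fset, "svm")], k=50, repeats=1, seed=0)


def test_margin_and_control_sd_arithmetic(small_world, monkeypatch):
    """min(MTC)=2, max(non-MTC)=-3 gives margin 5; identical within-group
    control scores give control_sd = 0."""
    _, cm, train, truth, fset = small_world
    controls = simulate_controls(small_sim(seed=13))
    clf = classify.train(train, fset.genes, "svm", feature_set_id=2)

    y = train.labels()
    fixed_train = np.where(y == "MTC", 2.0, -3.0)
    fixed_train[np.argmax(y == "MTC")] = 2.0
    groups = controls.sample_meta["replicate_group"].to_numpy()
    fixed_ctl = np.array([float(g[1:]) for g in groups])  # constant per group

    def fake_predict(classifier, counts):
        scores = fixed_train if counts.n_samples == train.n_samples \
            else fixed_ctl
        return classify.ScoreVector(sample_ids=counts.sample_ids,
                                    scores=scores,
                                    calls=np.where(scores > 0, "positive",
                                                   "negative"))

    monkeypatch.setattr(classify, "predict", fake_predict)
    ref = np.linspace(-1, 1, train.n_samples)
    crit = compute_criteria(clf, train, controls, ref)
    assert crit.margin == pytest.approx(5.0)
    assert crit.control_sd == pytest.approx(0.0)


def test_pooled_within_group_sd():
    scores = np.array([1.0, 1.0, 5.0, 7.0])
    groups = np.array(["a", "a", "b", "b"])
    # group a contributes 0, group b (5,7): ss=2, df=2 total
    assert pooled_within_group_sd(scores, groups) == pytest.approx(1.0)
    with pytest.raises(ValueError):
        pooled_within_group_sd(np.array([1.0]), np.array(["a"]))


def test_cassette_model_correlates_more_with_reference(small_world):
    _, cm, train, truth, _ = small_world
    controls = simulate_controls(small_sim(seed=13))
    ref = model_selection.reference_cassette_score(
        train, truth.core_cassette_genes)
    cassette_set = CandidateFeatureSet(
        set_id=1, rule="cassette", genes=truth.cassette_genes,
        mandatory_genes=truth.cassette_genes)
    null_genes = [g for g in train.gene_ids
                  if g not in set(truth.signature_genes)][:34]
    null_set = CandidateFeatureSet(set_id=2, rule="null", genes=null_genes,
                                   mandatory_genes=null_genes)
    crits = []
    for fset in (cassette_set, null_set):
        clf = classify.train(train, fset.genes, "svm",
                             feature_set_id=fset.set_id)
        crits.append(compute_criteria(
            clf, train, controls, ref))
    assert crits[0].ref_corr > crits[1].ref_corr


def _crit(set_id, family, margin, sd, corr, n):
    return SelectionCriteria(set_id=set_id, family=family, margin=margin,
                             control_sd=sd, ref_corr=corr, n_genes=n)


def test_select_final_singleton_and_dominance():
    only = _crit(4, "svm", 3.0, 0.1, 0.8, 50)
    winner, _ = select_final([only])
    assert (winner.set_id, winner.family) == (4, "svm")

    a = _crit(1, "svm", 5.0, 0.05, 0.9, 40)   # dominates b on all four
    b = _crit(2, "svm", 3.0, 0.10, 0.7, 60)
    winner, table = select_final([a, b])
    assert winner.set_id == 1
    assert table["rank_sum"].iloc[0] < table["rank_sum"].iloc[1]


def test_select_final_tie_broken_by_fewest_genes():
    # a and b tie on rank sum (each wins two criteria); b has fewer genes
    a = _crit(1, "svm", 5.0, 0.10, 0.9, 60)
    b = _crit(2, "svm", 3.0, 0.05, 0.7, 40)
    winner, table = select_final([a, b])
    assert table["rank_sum"].nunique() == 1
    assert winner.set_id == 2
    with pytest.raises(ValueError):
        select_final([])


def test_select_final_never_returns_dominated_candidate():
    rng = np.random.default_rng(17)
    for _ in range(30):
        crits = [
            _crit(i + 1, "svm", rng.normal(), rng.uniform(0.01, 1),
                  rng.uniform(-1, 1), int(rng.integers(34, 200)))
            for i in range(5)
        ]
        winner, _ = select_final(crits)
        for other in crits:
            if other is winner:
                continue
            dominates = (other.margin > winner.margin
                         and other.control_sd < winner.control_sd
                         and other.ref_corr > winner.ref_corr
                         and other.n_genes < winner.n_genes)
            assert not dominates
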