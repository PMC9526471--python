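"""Differential expression: normalization, the NB Wald test, BH adjustment,
and the dual-context intersection rule."""

import numpy as np
import pandas as pd
import pytest
from statsmodels.stats.multitest import multipletests

from conftest import small_sim
from mtcseq.containers import CountMatrix
from mtcseq.diffexp import (bh_adjust, dual_context_de, nb_wald_test,
                            size_factors)
from mtcseq.simulate import simulate_cohorts


def _matrix(counts, labels, cohort="train_fnab"):
    counts = np.asarray(counts)
    n = counts.shape[1]
    meta = pd.DataFrame({
        "sample_id": [f"s{i}" for i in range(n)],
        "cohort": cohort, "label": labels,
        "bethesda": "NA", "replicate_group": [None] * n,
        "dilution_fraction": [np.nan] * n,
    })
    return CountMatrix(counts=counts, gene_ids=[f"g{i}" for i in
                                                range(counts.shape[0])],
                       sample_meta=meta)


# -- size factors ---------------------------------------------------------

def test_size_factors_identical_samples_are_unit():
    rng = np.random.default_rng(0)
    col = rng.poisson(20, size=60)
    cm = np.column_stack([col, col])
    assert np.allclose(size_factors(cm), [1.0, 1.0])


def test_size_factors_doubling_scales_by_two():
    rng = np.random.default_rng(1)
    a = rng.poisson(30, size=80) + 1
    sf = size_factors(np.column_stack([a, 2 * a]))
    assert np.isclose(sf[1] / sf[0], 2.0)
    assert np.isclose(np.exp(np.mean(np.log(sf))), 1.0)


def test_size_factors_match_brute_force_median_of_ratios():
    rng = np.random.default_rng(2)
    mat = rng.poisson(15, size=(50, 7)).astype(float)
    mat[mat == 0] = 1  # keep all geometric means positive for the oracle

    # independent brute-force median-of-ratios
    geo = np.exp(np.mean(np.log(mat), axis=1))
    raw = np.array([np.median(mat[:, j] / geo) for j in range(7)])
    expected = raw / np.exp(np.mean(np.log(raw)))

    assert np.allclose(size_factors(mat), expected)


def test_size_factors_all_zero_sample_named():
    mat = np.array([[3, 0], [5, 0]])
    cm = _matrix(mat, ["MTC", "non-MTC"])
    with pytest.raises(ValueError, match="s1"):
        size_factors(cm)


# -- BH adjustment --------------------------------------------------------

def test_bh_hand_example_and_edges():
    assert np.allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)
    assert np.allclose(bh_adjust([0.37]), [0.37])
    assert np.allclose(bh_adjust([0.2, 0.2, 0.2]), [0.2] * 3)
    with pytest.raises(ValueError):
        bh_adjust([0.5, 1.2])


def _bh_brute_force(p):
    """Literal step-up definition: adj_i = min over j with p_j >= p_i of
    n*p_j/rank_j, capped at 1."""
    p = np.asarray(p, dtype=float)
    n = len(p)
    order = np.argsort(p, kind="mergesort")
    adj = np.empty(n)
    for pos, i in enumerate(order):
        candidates = [n * p[order[k]] / (k + 1) for k in range(pos, n)]
        adj[i] = min(1.0, min(candidates))
    return adj


def test_bh_equals_brute_force_and_statsmodels_on_permutations():
    rng = np.random.default_rng(3)
    from itertools import permutations
    base = rng.uniform(size=6)
    for perm in permutations(range(6)):
        p = base[list(perm)]
        ours = bh_adjust(p)
        assert np.allclose(ours, _bh_brute_force(p))
        assert np.allclose(
            ours, multipletests(p, method="fdr_bh")[1])


def test_bh_invariants_on_random_vectors():
    rng = np.random.default_rng(4)
    for _ in range(20):
        p = rng.uniform(size=rng.integers(1, 40))
        adj = bh_adjust(p)
        assert np.all(adj >= p - 1e-15)
        assert np.all(adj <= 1.0)
        order = np.argsort(p, kind="mergesort")
        assert np.all(np.diff(adj[order]) >= -1e-15)


# -- NB Wald test ---------------------------------------------------------

def test_null_gene_small_effect_large_n():
    rng = np.random.default_rng(5)
    n = 300
    counts = rng.negative_binomial(10, 10 / (10 + 50.0), size=(40, 2 * n))
    cm = _matrix(counts, ["MTC"] * n + ["non-MTC"] * n)
    tab = nb_wald_test(cm, "train_fnab")
    assert np.all(np.abs(tab["log2fc"]) < 0.5)
    # p-values roughly uniform: not all tiny
    assert (tab["wald_p"] < 0.05).mean() < 0.2


def test_planted_signature_detected_in_both_contexts(detable, truth,
                                                     default_config):
    """>= 95% of planted signature genes reach adjusted p < 1e-6 with
    log2FC > 6 in both the FNAB and tissue contexts."""
    hits = dual_context_de(detable, p_cut=1e-6, fc_cut=6.0)
    recovered = set(hits) & set(truth.signature_genes)
    assert len(recovered) >= 0.95 * default_config.n_signature
    assert len(set(hits) - set(truth.signature_genes)) <= 1


def test_poisson_limit_se_matches_delta_method():
    rng = np.random.default_rng(6)
    n1, n0, mu1, mu0 = 200, 300, 80.0, 40.0
    counts = np.vstack([
        np.concatenate([rng.poisson(mu1, n1), rng.poisson(mu0, n0)]),
        np.concatenate([rng.poisson(50.0, n1), rng.poisson(50.0, n0)]),
    ])
    cm = _matrix(counts, ["MTC"] * n1 + ["non-MTC"] * n0)
    tab = nb_wald_test(cm, "train_fnab")
    m1 = counts[0, :n1].mean()
    m0 = counts[0, n1:].mean()
    # two-group Poisson delta-method se of a log2 ratio of means
    expected = np.sqrt(1 / (n1 * m1) + 1 / (n0 * m0)) / np.log(2)
    assert abs(tab["se"][0] - expected) / expected < 0.05


def test_single_sample_class_rejected():
    counts = np.abs(np.random.default_rng(7).poisson(10, size=(10, 4)))
    cm = _matrix(counts, ["MTC", "non-MTC", "non-MTC", "non-MTC"])
    with pytest.raises(ValueError):
        nb_wald_test(cm, "train_fnab")


def test_agrees_with_deseq2_style_reference_on_small_fixture():
    """Independent oracle: on a small planted simulation, the shrinkage-free
    two-group test ranks and calls the same genes as pydeseq2."""
    from pydeseq2.dds import DeseqDataSet
    from pydeseq2.ds import DeseqStats

    cfg = small_sim(seed=3, n_genes=300, n_signature=20, n_cassette=5,
                    n_cassette_core=2, n_nuisance=0,
                    cohort_sizes={"train_fnab": (12, 30), "tissue": (5, 5),
                                  "valid_fnab": (2, 2)})
    cm = simulate_cohorts(cfg).cohort("train_fnab")
    ours = nb_wald_test(cm, "train_fnab")

    meta = pd.DataFrame({"label": cm.labels()}, index=cm.sample_ids)
    dds = DeseqDataSet(
        counts=pd.DataFrame(cm.counts.T, index=cm.sample_ids,
                            columns=cm.gene_ids),
        metadata=meta, design="~label", quiet=True)
    dds.deseq2()
    ds = DeseqStats(dds, contrast=["label", "non-MTC", "MTC"], quiet=True)
    ds.summary()
    ref = ds.results_df
    lfc_ref = -ref["log2FoldChange"].to_numpy()  # flip to MTC vs non-MTC

    ok = np.isfinite(lfc_ref)
    assert np.corrcoef(lfc_ref[ok], ours["log2fc"].to_numpy()[ok])[0, 1] > 0.98
    ours_sig = set(ours.gene_id[ours.adj_p < 1e-6])
    ref_sig = set(ref.index[ref.padj < 1e-6])
    jaccard = len(ours_sig & ref_sig) / len(ours_sig | ref_sig)
    assert jaccard > 0.9


# -- dual-context intersection --------------------------------------------

def _toy_detable():
    rows = []
    for ctx, ps in (("train_fnab", [1e-9, 1e-9, 0.5]),
                    ("tissue", [1e-9, 0.5, 1e-9])):
        for g, p in zip(["a", "b", "c"], ps):
            rows.append({"gene_id": g, "context": ctx, "base_mean": 10.0,
                         "log2fc": 7.0, "se": 1.0, "wald_p": p, "adj_p": p})
    return pd.DataFrame(rows)


def test_dual_context_requires_both_contexts():
    tab = _toy_detable()
    assert dual_context_de(tab, p_cut=1.1) == ["a", "b", "c"]
    assert dual_context_de(tab, p_cut=1e-6) == ["a"]  # b: FNAB only; c: tissue only
    with pytest.raises(ValueError):
        dual_context_de(tab[tab.context == "tissue"], p_cut=0.05)


def test_fold_change_filter_is_subset(detable):
    with_fc = set(dual_context_de(detable, 1e-6, fc_cut=6.0))
    without = set(dual_context_de(detable, 1e-6))
    assert with_fc <= without
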