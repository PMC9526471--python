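"""Two-group negative-binomial Wald differential expression, per cohort context.

Feature selection for the classifier rests on genes differentially expressed
between MTC and non-MTC in BOTH the FNAB and the surgical-tissue context,
which guards against FNAB-specific artifacts.  The test here is a two-group
NB Wald test on median-of-ratios-normalized counts: per-gene dispersion by
method of moments (floored), log2 fold change from normalized class means,
standard error by the delta method under the NB variance function, and
Benjamini-Hochberg adjustment within each context.

This is deliberately the plain two-group special case — no dispersion
shrinkage across genes, no outlier refitting, no independent filtering —
because downstream only the ranked gene filter is consumed.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .containers import CountMatrix

LOG2 = float(np.log(2.0))

DE_COLUMNS = ["gene_id", "context", "base_mean", "log2fc", "se", "wald_p", "adj_p"]

_DISP_FLOOR = 1e-8
_PSEUDOCOUNT = 0.5


def size_factors(counts) -> np.ndarray:
    """Median-of-ratios per-sample normalization factors.

    For each sample, the factor is the median over genes (restricted to
    genes with a positive geometric mean across samples) of
    ``count / geometric_mean``; factors are rescaled to geometric mean 1.
    """
    mat = counts.counts if isinstance(counts, CountMatrix) else np.asarray(counts)
    mat = mat.astype(float)
    if np.any(mat.sum(axis=0) == 0):
        ids = (counts.sample_ids if isinstance(counts, CountMatrix)
               else list(range(mat.shape[1])))
        bad = [ids[j] for j in np.flatnonzero(mat.sum(axis=0) == 0)]
        raise ValueError(f"all-zero sample(s): {bad}")
    with np.errstate(divide="ignore"):
        log_mat = np.log(mat)
    log_geo = log_mat.mean(axis=1)
    usable = np.isfinite(log_geo)
    if not usable.any():
        raise ValueError("no gene has nonzero counts in every sample")
    ratios = mat[usable] / np.exp(log_geo[usable])[:, None]
    sf = np.median(ratios, axis=0)
    return sf / np.exp(np.mean(np.log(sf)))


def _moment_dispersion(norm: np.ndarray, groups: list[np.ndarray]) -> np.ndarray:
    """Per-gene NB dispersion alpha from within-class moments, floored.

    alpha solves var = mean + alpha * mean^2 per class; classes are combined
    by degrees of freedom.
    """
    num = np.zeros(norm.shape[0])
    den = 0.0
    for idx in groups:
        n = len(idx)
        if n < 2:
            raise ValueError("each class needs >= 2 samples to estimate variance")
        m = norm[:, idx].mean(axis=1)
        v = norm[:, idx].var(axis=1, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            a = np.where(m > 0, (v - m) / np.square(m), 0.0)
        num += (n - 1) * a
        den += n - 1
    return np.maximum(num / den, _DISP_FLOOR)


def nb_wald_test(counts: CountMatrix, context: str) -> pd.DataFrame:
    """DE table (one row per gene) for one context ("train_fnab"/"tissue").

    Returns columns ``gene_id, context, base_mean, log2fc, se, wald_p,
    adj_p`` where log2fc is MTC over non-MTC.  Genes with zero counts in
    both classes get p = 1 and log2fc = 0.
    """
    sub = counts.cohort(context) if context in set(
        counts.sample_meta["cohort"]) else counts
    labels = sub.labels()
    mtc = np.flatnonzero(labels == "MTC")
    non = np.flatnonzero(labels == "non-MTC")
    if len(mtc) == 0 or len(non) == 0:
        raise ValueError(f"context {context!r} must contain both classes")
    if len(mtc) < 2 or len(non) < 2:
        raise ValueError("each class needs >= 2 samples (variance unidentifiable)")

    sf = size_factors(sub)
    norm = sub.counts / sf[None, :]
    alpha = _moment_dispersion(norm, [mtc, non])

    q1 = norm[:, mtc].mean(axis=1)   # MTC class mean
    q0 = norm[:, non].mean(axis=1)
    base_mean = norm.mean(axis=1)

    # pseudocount only when a class mean is zero, to keep log2fc finite
    needs_pc = (q1 == 0) | (q0 == 0)
    q1p = np.where(needs_pc, q1 + _PSEUDOCOUNT, q1)
    q0p = np.where(needs_pc, q0 + _PSEUDOCOUNT, q0)
    log2fc = np.log2(q1p / q0p)

    # delta-method variance of log class-mean under var(count) = s*q + a*(s*q)^2:
    # Var(mean_j count_j/s_j) = q * mean(1/s)/n + a q^2 / n
    inv1 = np.mean(1.0 / sf[mtc])
    inv0 = np.mean(1.0 / sf[non])
    v_log1 = inv1 / (len(mtc) * q1p) + alpha / len(mtc)
    v_log0 = inv0 / (len(non) * q0p) + alpha / len(non)
    se = np.sqrt(v_log1 + v_log0) / LOG2

    with np.errstate(divide="ignore", invalid="ignore"):
        z = log2fc / se
    wald_p = 2.0 * stats.norm.sf(np.abs(z))

    all_zero = (sub.counts[:, mtc].sum(axis=1) == 0) & \
               (sub.counts[:, non].sum(axis=1) == 0)
    log2fc[all_zero] = 0.0
    wald_p[all_zero] = 1.0
    se[all_zero] = np.inf

    return pd.DataFrame({
        "gene_id": sub.gene_ids,
        "context": context,
        "base_mean": base_mean,
        "log2fc": log2fc,
        "se": se,
        "wald_p": np.clip(wald_p, 0.0, 1.0),
        "adj_p": bh_adjust(np.clip(wald_p, 0.0, 1.0)),
    })


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    ``adj_p[i] = min_{j: p_j >= p_i} (n * p_j / rank_j)``, capped at 1 —
    the usual step-up rule with cumulative-minimum enforcement.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        p = p.ravel()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    n = len(p)
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * n / np.arange(1, n + 1)
    adj_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.empty(n)
    adj[order] = np.minimum(adj_sorted, 1.0)
    return adj


def dual_context_table(counts: CountMatrix) -> pd.DataFrame:
    """Stacked DE table for the training-FNAB and tissue contexts."""
    tables = [nb_wald_test(counts, ctx) for ctx in ("train_fnab", "tissue")]
    return pd.concat(tables, ignore_index=True)


def dual_context_de(detable: pd.DataFrame, p_cut: float,
                    fc_cut: float | None = None) -> list[str]:
    """Genes passing ``adj_p < p_cut`` (and ``log2fc > fc_cut`` if given)
    in BOTH contexts.

    The fold-change condition is one-sided — over-expressed in MTC — which
    matches selecting a positively activated marker cassette.
    """
    contexts = sorted(set(detable["context"]))
    if len(contexts) < 2:
        raise ValueError(f"need two contexts, found {contexts}")
    keep = None
    for ctx in contexts:
        sub = detable[detable["context"] == ctx]
        ok = sub["adj_p"].to_numpy() < p_cut
        if fc_cut is not None:
            ok &= sub["log2fc"].to_numpy() > fc_cut
        genes = set(sub["gene_id"].to_numpy()[ok])
        keep = genes if keep is None else keep & genes
    gene_order = {g: i for i, g in enumerate(
        detable["gene_id"].drop_duplicates())}
    return sorted(keep, key=gene_order.get)
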