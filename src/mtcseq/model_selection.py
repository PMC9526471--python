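"""The 16-setting model competition and the four-criterion final selection.

Eight candidate feature sets x two classifier families are compared under
stratified 5-fold cross-validation repeated 10 times.  Among the settings
with perfect cross-validated sensitivity and specificity, a single model is
selected by four robustness criteria:

1. greatest margin between the minimum MTC and maximum non-MTC logit score
   on the full training fit;
2. smallest pooled within-replicate-group score standard deviation on
   technical control samples;
3. highest Pearson correlation between the model's scores and a reference
   cassette score (the mean standardized log-CPM of the 5 legacy cassette
   genes, standing in for the historical microarray cassette score);
4. fewest genes.

The four criteria are combined by rank sum (scale-free across heterogeneous
quantities); ties break toward fewer genes, then smaller set id.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import StratifiedKFold

from . import classify
from .containers import CountMatrix
from .feature_sets import CandidateFeatureSet


@dataclass
class SelectionCriteria:
    """Four-criterion summary for one (feature set, family) setting."""

    set_id: int
    family: str
    margin: float
    control_sd: float | None
    ref_corr: float
    n_genes: int

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("empty gene list")
        if self.control_sd is not None and self.control_sd < 0:
            raise ValueError("control_sd must be non-negative")
        if not -1.0 - 1e-9 <= self.ref_corr <= 1.0 + 1e-9:
            raise ValueError("ref_corr outside [-1, 1]")


def _fold_rates(calls: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    pos = calls == "positive"
    sens = float(np.mean(pos[y == 1])) if np.any(y == 1) else np.nan
    spec = float(np.mean(~pos[y == 0])) if np.any(y == 0) else np.nan
    return sens, spec


def repeated_cv(counts: CountMatrix,
                settings: list[tuple[CandidateFeatureSet, str]],
                k: int = 5, repeats: int = 10,
                seed: int = 0) -> pd.DataFrame:
    """Stratified k-fold CV repeated ``repeats`` times for every setting.

    Fold assignments depend only on (repeat, seed), so all settings see the
    same partitions.  Normalization and any penalty selection are refit
    inside each training fold — no information leaks from held-out samples.
    Returns a long table (set_id, family, repeat, fold, sensitivity,
    specificity).
    """
    y = (counts.labels() == "MTC").astype(int)
    if y.sum() < k:
        raise ValueError(f"need >= {k} MTC samples for {k}-fold stratification")
    folds_by_repeat = []
    for r in range(repeats):
        skf = StratifiedKFold(n_splits=k, shuffle=True,
                              random_state=(seed * 1009 + r) % (2**31 - 1))
        folds_by_repeat.append(list(skf.split(np.zeros(len(y)), y)))

    rows = []
    for fset, family in settings:
        for r, folds in enumerate(folds_by_repeat):
            for f, (tr, te) in enumerate(folds):
                sub_tr = counts.select_samples(tr)
                sub_te = counts.select_samples(te)
                clf = classify.train(
                    sub_tr, fset.genes, family,
                    feature_set_id=fset.set_id,
                    seed=(seed * 7919 + r * 17 + f) % (2**31 - 1))
                sv = classify.predict(clf, sub_te)
                sens, spec = _fold_rates(sv.calls, y[te])
                rows.append((fset.set_id, family, r, f, sens, spec))
    return pd.DataFrame(
        rows, columns=["set_id", "family", "repeat", "fold",
                       "sensitivity", "specificity"])


def cv_summary(report: pd.DataFrame) -> pd.DataFrame:
    """Per-setting mean and sd of fold-level sensitivity/specificity."""
    g = report.groupby(["set_id", "family"])
    out = g.agg(
        mean_sensitivity=("sensitivity", "mean"),
        sd_sensitivity=("sensitivity", "std"),
        mean_specificity=("specificity", "mean"),
        sd_specificity=("specificity", "std"),
        n_folds=("sensitivity", "size"),
    ).reset_index()
    return out


def reference_cassette_score(counts: CountMatrix,
                             cassette_genes: list[str]) -> np.ndarray:
    """Mean standardized log-CPM of the legacy cassette genes, per sample.

    Serves as the stand-in for the historical microarray cassette score in
    selection criterion 3.
    """
    x = classify.log_cpm(counts, cassette_genes)
    sd = x.std(axis=0, ddof=0)
    sd = np.where(sd < 1e-12, 1.0, sd)
    z = (x - x.mean(axis=0)[None, :]) / sd[None, :]
    return z.mean(axis=1)


def pooled_within_group_sd(scores: np.ndarray,
                           groups: np.ndarray) -> float:
    """sqrt of the replicate-variance estimate pooled over groups."""
    ss, df = 0.0, 0
    for g in pd.unique(groups):
        s = scores[groups == g]
        if len(s) >= 2:
            ss += float(np.sum((s - s.mean()) ** 2))
            df += len(s) - 1
    if df == 0:
        raise ValueError("no replicate group has >= 2 replicates")
    return float(np.sqrt(ss / df))


def compute_criteria(classifier, train_counts: CountMatrix,
                     controls: CountMatrix | None,
                     reference_scores: np.ndarray) -> SelectionCriteria:
    """Evaluate the four selection criteria for one trained setting."""
    sv = classify.predict(classifier, train_counts)
    y = (train_counts.labels() == "MTC")
    margin = float(sv.scores[y].min() - sv.scores[~y].max())

    if controls is None or controls.n_samples == 0:
        warnings.warn("no control samples; control-variability criterion "
                      "skipped")
        control_sd = None
    else:
        csv_ = classify.predict(classifier, controls)
        control_sd = pooled_within_group_sd(
            csv_.scores, controls.sample_meta["replicate_group"].to_numpy())

    if np.std(sv.scores) < 1e-12 or np.std(reference_scores) < 1e-12:
        ref_corr = 0.0
    else:
        ref_corr = float(stats.pearsonr(sv.scores, reference_scores)[0])

    return SelectionCriteria(
        set_id=classifier.feature_set_id, family=classifier.family,
        margin=margin, control_sd=control_sd, ref_corr=ref_corr,
        n_genes=len(classifier.genes))


def criteria_table(criteria: list[SelectionCriteria]) -> pd.DataFrame:
    return pd.DataFrame([{
        "set_id": c.set_id, "family": c.family, "margin": c.margin,
        "control_sd": np.nan if c.control_sd is None else c.control_sd,
        "ref_corr": c.ref_corr, "n_genes": c.n_genes,
    } for c in criteria])


def select_final(criteria: list[SelectionCriteria]) -> tuple[
        SelectionCriteria, pd.DataFrame]:
    """Rank-sum winner across the four criteria.

    Margin and reference correlation rank descending (bigger is better);
    control variability and gene count rank ascending.  The candidate with
    the smallest rank sum wins; ties break by fewest genes, then set id.
    Returns the winner and the full rank table for audit.
    """
    if not criteria:
        raise ValueError("no candidate settings to select from")
    tab = criteria_table(criteria)
    ranks = pd.DataFrame(index=tab.index)
    ranks["margin"] = stats.rankdata(-tab["margin"])
    ranks["ref_corr"] = stats.rankdata(-tab["ref_corr"])
    ranks["n_genes"] = stats.rankdata(tab["n_genes"])
    if tab["control_sd"].notna().all():
        ranks["control_sd"] = stats.rankdata(tab["control_sd"])
    else:
        warnings.warn("control_sd missing for some candidates; criterion "
                      "dropped from the rank sum")
    tab = tab.join(ranks.add_prefix("rank_"))
    tab["rank_sum"] = ranks.sum(axis=1)
    order = tab.sort_values(
        ["rank_sum", "n_genes", "set_id", "family"]).index
    winner = criteria[order[0]]
    return winner, tab
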