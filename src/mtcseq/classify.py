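"""Classifier families, featurization, and the locked-model contract.

Two families compete: a linear soft-margin support vector machine and
elastic-net-penalized logistic regression.  Both consume the same features
— log2(CPM + 1) per gene, centered and scaled by parameters estimated on
training samples only — and both emit a continuous "logit score" (the SVM's
signed decision value, or the logistic model's log-odds) with a fixed
decision threshold of 0.

A trained classifier can be *locked*: after locking, any attempt to mutate
its genes, weights, normalization or threshold raises, and serialization
round-trips scores bit-near-exactly.  Locking before any contact with the
validation cohort is what makes the blinded validation claim meaningful.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .containers import CountMatrix

FAMILIES = ("svm", "enet_logistic")

#: Inner-CV grid of inverse penalty strengths for the elastic net.
ENET_C_GRID = (0.03, 0.3, 3.0)


@dataclass
class Normalization:
    """Per-gene center/scale parameters over log2(CPM + 1) features."""

    mean: np.ndarray
    scale: np.ndarray

    def to_dict(self) -> dict:
        return {"mean": self.mean.tolist(), "scale": self.scale.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "Normalization":
        return cls(mean=np.asarray(d["mean"], dtype=float),
                   scale=np.asarray(d["scale"], dtype=float))


def log_cpm(counts: CountMatrix, genes: list[str]) -> np.ndarray:
    """log2(CPM + 1) feature block, samples x genes.

    CPM uses each sample's own total count, so features are invariant to
    library size by construction.
    """
    idx = counts.gene_index(genes)
    totals = counts.counts.sum(axis=0).astype(float)
    if np.any(totals == 0):
        raise ValueError("sample with zero total count")
    cpm = counts.counts[idx, :] / totals[None, :] * 1e6
    return np.log2(cpm + 1.0).T


def fit_normalization(counts: CountMatrix, genes: list[str]) -> Normalization:
    x = log_cpm(counts, genes)
    mean = x.mean(axis=0)
    scale = x.std(axis=0, ddof=0)
    scale = np.where(scale < 1e-12, 1.0, scale)
    return Normalization(mean=mean, scale=scale)


def featurize(counts: CountMatrix, genes: list[str],
              normalization: Normalization) -> np.ndarray:
    """Standardized log-CPM features using *stored* training parameters.

    Validation samples are transformed with the training-derived center and
    scale unchanged — never refit.
    """
    x = log_cpm(counts, genes)
    return (x - normalization.mean[None, :]) / normalization.scale[None, :]


@dataclass
class TrainedClassifier:
    """A frozen linear decision rule over a fixed gene list.

    ``score(x) = weights . features(x) + intercept``; the call is positive
    iff the score exceeds ``threshold``.  Once ``locked``, every field is
    immutable.
    """

    family: str
    feature_set_id: int
    genes: list[str]
    normalization: Normalization = field(repr=False)
    weights: np.ndarray = field(repr=False)
    intercept: float = 0.0
    threshold: float = 0.0
    locked: bool = False
    training_hash: str | None = None

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        self.weights = np.asarray(self.weights, dtype=float)
        if len(self.weights) != len(self.genes):
            raise ValueError("one weight per gene required")

    def __setattr__(self, name, value):
        if getattr(self, "locked", False):
            raise AttributeError(
                f"classifier is locked; cannot set {name!r}")
        super().__setattr__(name, value)

    def lock(self) -> "TrainedClassifier":
        self.training_hash = self.content_hash()
        self.locked = True
        return self

    def content_hash(self) -> str:
        payload = json.dumps({
            "family": self.family,
            "genes": self.genes,
            "normalization": self.normalization.to_dict(),
            "weights": self.weights.tolist(),
            "intercept": self.intercept,
            "threshold": self.threshold,
        }, sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()

    # -- serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "family": self.family,
            "feature_set_id": self.feature_set_id,
            "genes": list(self.genes),
            "normalization": self.normalization.to_dict(),
            "weights": self.weights.tolist(),
            "intercept": float(self.intercept),
            "threshold": float(self.threshold),
            "locked": bool(self.locked),
            "training_hash": self.training_hash,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TrainedClassifier":
        clf = cls(
            family=d["family"],
            feature_set_id=d["feature_set_id"],
            genes=list(d["genes"]),
            normalization=Normalization.from_dict(d["normalization"]),
            weights=np.asarray(d["weights"], dtype=float),
            intercept=float(d["intercept"]),
            threshold=float(d["threshold"]),
            locked=False,
            training_hash=d.get("training_hash"),
        )
        if d.get("locked"):
            clf.locked = True
        return clf


@dataclass
class ScoreVector:
    """Continuous per-sample logit scores and binary positive/negative calls."""

    sample_ids: list[str]
    scores: np.ndarray
    calls: np.ndarray  # "positive" / "negative"

    def positives(self) -> np.ndarray:
        return self.calls == "positive"


def _choose_enet_c(x: np.ndarray, y: np.ndarray, l1_ratio: float,
                   seed: int) -> float:
    """Penalty strength by nested stratified 3-fold CV (balanced accuracy);
    ties favor the stronger penalty (smaller C).

    Inner fits are deliberately early-stopped (loose tolerance, capped
    iterations): they only rank penalties, and on near-separable data full
    convergence of the unregularized direction is irrelevant to that rank.
    """
    best_c, best_acc = None, -np.inf
    n_splits = min(3, int(np.bincount(y).min()))
    if n_splits < 2:
        return ENET_C_GRID[len(ENET_C_GRID) // 2]
    skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
    folds = list(skf.split(x, y))
    for c in ENET_C_GRID:
        accs = []
        for tr, te in folds:
            if len(np.unique(y[tr])) < 2:
                continue
            m = LogisticRegression(
                solver="saga", l1_ratio=l1_ratio,
                C=c, class_weight="balanced", max_iter=150, tol=1e-2)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", ConvergenceWarning)
                m.fit(x[tr], y[tr])
            pred = m.predict(x[te])
            sens = np.mean(pred[y[te] == 1] == 1) if np.any(y[te] == 1) else 1.0
            spec = np.mean(pred[y[te] == 0] == 0) if np.any(y[te] == 0) else 1.0
            accs.append(0.5 * (sens + spec))
        acc = float(np.mean(accs)) if accs else -np.inf
        if acc > best_acc + 1e-12:
            best_acc, best_c = acc, c
    return best_c if best_c is not None else ENET_C_GRID[0]


def train(counts: CountMatrix, genes: list[str], family: str,
          feature_set_id: int = 0, hyperparams: dict | None = None,
          seed: int = 0) -> TrainedClassifier:
    """Fit one classifier on the given samples and gene list.

    MTC is the positive class.  The SVM is a linear-kernel soft-margin
    machine with class weights inverse to class frequency (cost C
    configurable, default 1); the elastic net uses mixing ``l1_ratio``
    (default 0.5) with the penalty strength chosen by nested stratified
    3-fold cross-validation inside the training data.
    """
    hyperparams = dict(hyperparams or {})
    labels = counts.labels()
    y = (labels == "MTC").astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError("training data must contain both classes")
    norm = fit_normalization(counts, genes)
    x = featurize(counts, genes, norm)

    if family == "svm":
        model = SVC(kernel="linear", C=hyperparams.get("C", 1.0),
                    class_weight="balanced")
        model.fit(x, y)
        w = model.coef_.ravel()
        b = float(model.intercept_[0])
    elif family == "enet_logistic":
        l1_ratio = hyperparams.get("l1_ratio", 0.5)
        c = hyperparams.get("C")
        if c is None:
            c = _choose_enet_c(x, y, l1_ratio, seed)
        model = LogisticRegression(
            solver="saga", l1_ratio=l1_ratio, C=c,
            class_weight="balanced", max_iter=2000, tol=1e-4)
        model.fit(x, y)
        w = model.coef_.ravel()
        b = float(model.intercept_[0])
    else:
        raise ValueError(f"unknown family {family!r}")

    return TrainedClassifier(
        family=family, feature_set_id=feature_set_id, genes=list(genes),
        normalization=norm, weights=w, intercept=b)


def predict(classifier: TrainedClassifier, counts: CountMatrix) -> ScoreVector:
    """Deterministic scores and calls; never refits anything."""
    x = featurize(counts, classifier.genes, classifier.normalization)
    scores = x @ classifier.weights + classifier.intercept
    calls = np.where(scores > classifier.threshold, "positive", "negative")
    return ScoreVector(sample_ids=counts.sample_ids, scores=scores,
                       calls=calls)
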