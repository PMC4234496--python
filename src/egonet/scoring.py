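"""Gene-set scoring: cross-validated classification accuracy and the
aggregated-Z mutual-information baseline.

The module score S_i of a gene set is the mean accuracy of a classifier over
stratified cross-validation folds, with each gene standardised using the
training fold's mean and standard deviation.  The baseline score is the
mutual information (in bits) between the per-sample mean of member z-scores
("subnetwork activity") and the class labels, after equal-width discretisation
of the activity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable

import networkx as nx
import numpy as np
import sklearn
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC

from .io import ExpressionDataset

logger = logging.getLogger(__name__)

__all__ = [
    "ScorerConfig",
    "score_gene_set",
    "cv_auc",
    "chuang_score",
    "greedy_chuang_search",
]

CLASSIFIERS = ("svm", "knn", "rf")


@dataclass
class ScorerConfig:
    """Configuration of the cross-validated gene-set scorer.

    classifier : 'svm' (RBF kernel, C=1, scale gamma), 'knn' (k=5, Euclidean)
        or 'rf' (500 trees by default).
    folds : stratified CV folds; must not exceed the smaller class size.
    repeats : number of CV repetitions (distinct fold splits), averaged.
    seed : controls fold assignment and any classifier randomness.
    params : extra keyword arguments forwarded to the classifier constructor.
    """

    classifier: str = "svm"
    folds: int = 5
    repeats: int = 1
    seed: int = 0
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.classifier not in CLASSIFIERS:
            raise ValueError(f"classifier must be one of {CLASSIFIERS}")
        if self.folds < 2:
            raise ValueError("folds must be >= 2")
        if self.repeats < 1:
            raise ValueError("repeats must be >= 1")

    def to_file(self, path) -> None:
        """Serialise as flat ``key=value`` lines (classifier params prefixed)."""
        with open(path, "w") as fh:
            fh.write(f"classifier={self.classifier}\n")
            fh.write(f"folds={self.folds}\n")
            fh.write(f"repeats={self.repeats}\n")
            fh.write(f"seed={self.seed}\n")
            for key in sorted(self.params):
                fh.write(f"param.{key}={self.params[key]!r}\n")

    @classmethod
    def from_file(cls, path) -> "ScorerConfig":
        import ast

        fields: dict = {"params": {}}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                key, _, value = line.partition("=")
                if key.startswith("param."):
                    fields["params"][key[6:]] = ast.literal_eval(value)
                elif key == "classifier":
                    fields[key] = value
                else:
                    fields[key] = int(value)
        return cls(**fields)

    def make_classifier(self, seed: int):
        if self.classifier == "svm":
            kw = {"kernel": "rbf", "C": 1.0, "gamma": "scale", **self.params}
            return SVC(**kw)
        if self.classifier == "knn":
            kw = {"n_neighbors": 5, **self.params}
            return KNeighborsClassifier(**kw)
        kw = {"n_estimators": 500, **self.params}
        return RandomForestClassifier(random_state=seed, **kw)


def _standardize_fold(X: np.ndarray, train: np.ndarray, test: np.ndarray):
    mu = X[train].mean(axis=0)
    sd = X[train].std(axis=0)
    sd[sd == 0.0] = 1.0  # constant feature in the training fold: centred only
    return (X[train] - mu) / sd, (X[test] - mu) / sd


def _check_folds(labels: np.ndarray, folds: int) -> None:
    smaller = int(min(np.bincount(labels, minlength=2)))
    if folds > smaller:
        raise ValueError(
            f"folds={folds} exceeds the smaller class size ({smaller})"
        )


def score_gene_set(
    data: ExpressionDataset, genes: Iterable[str], cfg: ScorerConfig
) -> float:
    """Mean stratified-CV accuracy of ``cfg.classifier`` on a gene set.

    Each gene is standardised per fold with the training fold's mean/sd.
    Deterministic for a fixed ``cfg.seed``; invariant to gene order.
    """
    X = data.feature_matrix(genes)
    y = data.labels
    _check_folds(y, cfg.folds)
    accs = []
    # inputs are validated and finite by construction; skip sklearn's
    # per-fit re-validation, which otherwise dominates small-module scoring
    with sklearn.config_context(assume_finite=True, skip_parameter_validation=True):
        for r in range(cfg.repeats):
            split_seed = cfg.seed + r
            skf = StratifiedKFold(cfg.folds, shuffle=True, random_state=split_seed)
            for train, test in skf.split(X, y):
                Xtr, Xte = _standardize_fold(X, train, test)
                clf = cfg.make_classifier(split_seed)
                clf.fit(Xtr, y[train])
                accs.append(float((clf.predict(Xte) == y[test]).mean()))
    return float(np.mean(accs))


def cv_auc(data: ExpressionDataset, genes: Iterable[str], cfg: ScorerConfig) -> float:
    """Held-out AUC of a gene set from cross-validated decision scores.

    Decision values (decision_function where available, else the class-1
    probability or vote fraction) are collected on each held-out fold and a
    single ROC AUC is computed over all samples.
    """
    X = data.feature_matrix(genes)
    y = data.labels
    _check_folds(y, cfg.folds)
    scores = np.empty(len(y), dtype=float)
    skf = StratifiedKFold(cfg.folds, shuffle=True, random_state=cfg.seed)
    with sklearn.config_context(assume_finite=True, skip_parameter_validation=True):
        for train, test in skf.split(X, y):
            Xtr, Xte = _standardize_fold(X, train, test)
            clf = cfg.make_classifier(cfg.seed)
            clf.fit(Xtr, y[train])
            if hasattr(clf, "decision_function"):
                s = clf.decision_function(Xte)
            else:
                s = clf.predict_proba(Xte)[:, list(clf.classes_).index(1)]
            scores[test] = s
    return float(roc_auc_score(y, scores))


def _zscores(data: ExpressionDataset, genes: Iterable[str]) -> np.ndarray:
    """Per-gene z-scores across samples; zero-variance genes contribute zeros."""
    X = data.feature_matrix(genes)  # samples x genes
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    flat = sd == 0.0
    if flat.any():
        logger.info("chuang_score: %d zero-variance gene(s) contribute zeros", int(flat.sum()))
        sd = np.where(flat, 1.0, sd)
    Z = (X - mu) / sd
    Z[:, flat] = 0.0
    return Z


def _binned_mi_bits(activity: np.ndarray, labels: np.ndarray, n_bins: int) -> float:
    """Plug-in MI (bits) between equal-width-binned activity and binary labels."""
    lo, hi = float(activity.min()), float(activity.max())
    if hi == lo:
        return 0.0
    edges = np.linspace(lo, hi, n_bins + 1)
    binned = np.clip(np.digitize(activity, edges[1:-1]), 0, n_bins - 1)
    joint = np.bincount(binned * 2 + labels, minlength=2 * n_bins).reshape(n_bins, 2)
    joint = joint / joint.sum()
    pa = joint.sum(axis=1, keepdims=True)
    py = joint.sum(axis=0, keepdims=True)
    nz = joint > 0
    return float((joint[nz] * np.log2(joint[nz] / (pa @ py)[nz])).sum())


def chuang_score(
    data: ExpressionDataset, genes: Iterable[str], n_bins: int = 8
) -> float:
    """Aggregated-Z activity score: MI (bits) between binned subnetwork activity
    and the class labels.

    Activity is the per-sample mean of the member genes' z-scores, discretised
    into ``n_bins`` equal-width bins.  The plug-in estimate from the joint
    histogram is returned; it is 0 for constant activity and at most the label
    entropy.
    """
    genes = sorted(set(genes))
    if not genes:
        raise ValueError("at least one gene is required")
    activity = _zscores(data, genes).mean(axis=1)
    return _binned_mi_bits(activity, data.labels, n_bins)


def greedy_chuang_search(
    net: nx.Graph, data: ExpressionDataset, seed_gene: str, n_bins: int = 8
) -> frozenset[str]:
    """Greedy subnetwork growth from a seed gene, maximising the activity MI.

    At each step the neighbouring gene (of the current set) whose addition
    maximally increases :func:`chuang_score` is added; growth stops when no
    neighbour gives a strict improvement.  Ties break on the lexicographically
    smallest gene for determinism.
    """
    if seed_gene not in net:
        raise KeyError(f"seed gene {seed_gene!r} not in network")
    if seed_gene not in data:
        raise KeyError(f"seed gene {seed_gene!r} not in expression data")
    # z-scores for every scorable gene once; activity updates are incremental
    universe = sorted(g for g in data.genes if g in net)
    Z = _zscores(data, universe)
    col = {g: j for j, g in enumerate(universe)}
    labels = data.labels

    current: set[str] = {seed_gene}
    act_sum = Z[:, col[seed_gene]].copy()
    best = _binned_mi_bits(act_sum, labels, n_bins)
    while True:
        frontier = sorted(
            g
            for g in set().union(*(set(net.neighbors(v)) for v in current)) - current
            if g in col
        )
        if not frontier:
            break
        k1 = len(current) + 1
        cand_scores = [
            _binned_mi_bits((act_sum + Z[:, col[g]]) / k1, labels, n_bins)
            for g in frontier
        ]
        top = int(np.argmax(cand_scores))
        if cand_scores[top] <= best:
            break
        best = cand_scores[top]
        act_sum += Z[:, col[frontier[top]]]
        current.add(frontier[top])
    return frozenset(current)
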