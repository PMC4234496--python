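"""Scikit-learn-style estimator wrapping the full module-discovery pipeline."""

from __future__ import annotations

import logging

import networkx as nx
import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .inference import (
    ImportanceConfig,
    SignificanceConfig,
    de_flags,
    node_importance,
    permutation_pvalue,
    rank_genes,
)
from .io import ExpressionDataset, ModuleReport, align
from .neighborhood import enumerate_modules, module_sort_key
from .scoring import ScorerConfig

logger = logging.getLogger(__name__)

__all__ = ["EgoNet"]


class EgoNet(TransformerMixin, BaseEstimator):
    """Discover ego-network modules whose expression predicts a binary phenotype.

    Starting from every network node with degree >= 2, a module is grown
    outward level by level (snowball sampling) and scored by the stratified
    cross-validated accuracy of a classifier on the member genes; growth stops
    at the first accuracy drop.  Modules at or above ``score_cutoff`` are kept,
    optionally tested by label permutation, and their genes are ranked by

        M_j = sum_i S_i * V_ij

    where S_i is module i's accuracy and V_ij the out-of-bag permutation
    importance of gene j in module i.

    Parameters
    ----------
    network : networkx.Graph
        Undirected interaction network over the gene identifiers.
    classifier : {'svm', 'knn', 'rf'}, default 'svm'
        Module-scoring classifier.
    folds, repeats : stratified CV settings for the module score.
    classifier_params : dict, optional
        Extra constructor arguments for the scoring classifier.
    max_level : maximum snowball level (default 3).
    node_cap : stop growth before a level that would exceed this many nodes.
    score_cutoff : float, default 0.9
        Accuracy threshold a module must reach to be retained and to
        contribute to the gene ranking.
    n_permutations : int, default 0
        Label permutations B for module p-values; 0 skips the test.
    importance_trees : trees T in the importance forest (default 500).
    de_fdr : BH-adjusted FDR threshold for the differential-expression flag.
    random_state : seed for every stochastic step.

    Attributes
    ----------
    modules_ : list of ModuleReport
        Retained modules (score >= ``score_cutoff``) sorted by score.
    all_modules_ : list of GrownModule
        Every grown module before the cutoff.
    ranking_ : pandas.DataFrame
        Columns gene, M, de_flag, de_fdr, sorted by M descending.
    selected_genes_ : sorted union of retained modules' member genes.

    Examples
    --------
    >>> import networkx as nx, numpy as np, pandas as pd
    >>> net = nx.Graph([("A", "B"), ("B", "C"), ("C", "A"), ("C", "D")])
    >>> rng = np.random.default_rng(0)
    >>> X = pd.DataFrame(rng.standard_normal((40, 4)), columns=list("ABCD"))
    >>> y = (X["A"] + X["B"] > 0).astype(int)
    >>> model = EgoNet(network=net, score_cutoff=0.0).fit(X, y)
    >>> model.ranking_.columns.tolist()
    ['gene', 'M', 'de_flag', 'de_fdr']
    """

    def __init__(
        self,
        network: nx.Graph | None = None,
        classifier: str = "svm",
        folds: int = 5,
        repeats: int = 1,
        classifier_params: dict | None = None,
        max_level: int = 3,
        node_cap: int = 300,
        score_cutoff: float = 0.9,
        n_permutations: int = 0,
        importance_trees: int = 500,
        de_fdr: float = 0.05,
        random_state: int = 0,
    ) -> None:
        self.network = network
        self.classifier = classifier
        self.folds = folds
        self.repeats = repeats
        self.classifier_params = classifier_params
        self.max_level = max_level
        self.node_cap = node_cap
        self.score_cutoff = score_cutoff
        self.n_permutations = n_permutations
        self.importance_trees = importance_trees
        self.de_fdr = de_fdr
        self.random_state = random_state

    def _as_dataset(self, X, y) -> ExpressionDataset:
        if isinstance(X, ExpressionDataset):
            return X
        if not isinstance(X, pd.DataFrame):
            raise TypeError(
                "X must be a pandas DataFrame (samples x named gene columns) "
                "or an ExpressionDataset"
            )
        if y is None:
            raise ValueError("y (binary phenotype) is required")
        y = np.asarray(y, dtype=int)
        return ExpressionDataset(
            genes=[str(c) for c in X.columns],
            samples=[str(s) for s in X.index],
            values=X.to_numpy(dtype=float).T,
            labels=y,
        )

    def fit(self, X, y=None):
        """Discover, test and rank modules from expression ``X`` and labels ``y``.

        ``X`` is a samples-by-genes DataFrame whose column names match the
        network's node identifiers (or an ``ExpressionDataset``, in which case
        ``y`` is ignored).
        """
        if self.network is None:
            raise ValueError("a network is required to fit EgoNet")
        data = self._as_dataset(X, y)
        self.feature_names_in_ = np.asarray(data.genes, dtype=object)
        self.n_features_in_ = len(data.genes)
        net, aligned = align(self.network, data)

        scorer = ScorerConfig(
            classifier=self.classifier,
            folds=self.folds,
            repeats=self.repeats,
            seed=self.random_state,
            params=dict(self.classifier_params or {}),
        )
        grown = enumerate_modules(
            net, aligned, scorer, self.max_level, self.node_cap
        )
        grown.sort(key=module_sort_key)
        self.all_modules_ = grown

        reports: list[ModuleReport] = []
        for m in grown:
            if m.score < self.score_cutoff:
                continue
            p_value = None
            if self.n_permutations > 0:
                p_value = permutation_pvalue(
                    aligned,
                    m.members,
                    m.score,
                    scorer,
                    SignificanceConfig(B=self.n_permutations, seed=self.random_state),
                )
            importances = node_importance(
                aligned,
                m.members,
                ImportanceConfig(T=self.importance_trees, seed=self.random_state),
            )
            reports.append(
                ModuleReport(
                    ego=m.ego,
                    level=m.chosen_level,
                    members=m.members,
                    score=m.score,
                    p_value=p_value,
                    importances=importances,
                )
            )
        self.modules_ = reports
        self.selected_genes_ = sorted(set().union(*(m.members for m in reports))) if reports else []

        de = de_flags(aligned, fdr_threshold=self.de_fdr)
        ranking = rank_genes(reports, score_cutoff=None, all_genes=aligned.genes)
        self.ranking_ = pd.DataFrame(
            [
                {
                    "gene": g,
                    "M": m_value,
                    "de_flag": de[g][0] if g in de else False,
                    "de_fdr": de[g][1] if g in de else 1.0,
                }
                for g, m_value in ranking
            ]
        )
        self.de_ = de
        return self

    def get_support(self, indices: bool = False):
        """Boolean mask (or indices) of input genes in any retained module."""
        check_is_fitted(self, "modules_")
        selected = set(self.selected_genes_)
        mask = np.array([g in selected for g in self.feature_names_in_])
        return np.where(mask)[0] if indices else mask

    def transform(self, X):
        """Select the columns of ``X`` belonging to retained modules."""
        check_is_fitted(self, "modules_")
        if isinstance(X, pd.DataFrame):
            missing = [g for g in self.selected_genes_ if g not in X.columns]
            if missing:
                raise KeyError(f"genes missing from X: {missing[:5]}")
            return X.loc[:, self.selected_genes_]
        X = np.asarray(X)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X has {X.shape[1]} features, expected {self.n_features_in_}"
            )
        return X[:, self.get_support()]
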