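"""Statistical inference on discovered modules: permutation significance,
out-of-bag node importance, global gene ranking and differential-expression
flags.

The gene-ranking metric for gene j is

    M_j = sum_i S_i * V_ij

over the considered modules i, where S_i is module i's cross-validated
accuracy and V_ij the out-of-bag permutation importance of gene j in module i
(zero when j is not a member).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import sklearn
from scipy import stats
from sklearn.ensemble import BaggingClassifier
from sklearn.tree import DecisionTreeClassifier
from statsmodels.stats.multitest import multipletests

from .io import ExpressionDataset, ModuleReport
from .scoring import ScorerConfig, score_gene_set

logger = logging.getLogger(__name__)

__all__ = [
    "SignificanceConfig",
    "ImportanceConfig",
    "permutation_pvalue",
    "node_importance",
    "rank_genes",
    "de_flags",
]


@dataclass
class SignificanceConfig:
    """Permutation-test settings: B label permutations, seeded."""

    B: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.B < 1:
            raise ValueError("B must be >= 1")


@dataclass
class ImportanceConfig:
    """Random-forest importance settings: T trees, seeded."""

    T: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        if self.T < 1:
            raise ValueError("T must be >= 1")


def permutation_pvalue(
    data: ExpressionDataset,
    genes: Iterable[str],
    observed_score: float,
    scorer: ScorerConfig,
    sig: SignificanceConfig,
) -> float:
    """Permutation p-value of a module score against the label-shuffled null.

    The null distribution is built by permuting the phenotype labels B times
    and rescoring the same gene set with the same scorer; the add-one estimate
    p = (1 + #{null >= observed}) / (B + 1) is returned, so p >= 1/(B+1).
    """
    genes = sorted(set(genes))
    rng = np.random.default_rng(sig.seed)
    exceed = 0
    for _ in range(sig.B):
        permuted = data.with_labels(rng.permutation(data.labels))
        if score_gene_set(permuted, genes, scorer) >= observed_score:
            exceed += 1
    return (1 + exceed) / (sig.B + 1)


def node_importance(
    data: ExpressionDataset, genes: Iterable[str], cfg: ImportanceConfig
) -> dict[str, float]:
    """Out-of-bag permutation importance V_ij of each gene in a module.

    A bagged ensemble of T decision trees (each tree drawing a bootstrap
    sample and splitting on sqrt-of-features candidates, i.e. a random
    forest) is fitted on the module's genes.  For each tree t with
    out-of-bag sample OOB_t and error errOOB_t, gene j's values are permuted
    within OOB_t and the error recomputed; the importance is the mean over
    trees of the error increase:

        VI(X^j) = (1/T) * sum_t (errOOB~_tj - errOOB_t)

    Labels are binary, so the error is the OOB misclassification rate.
    Negative values are possible for uninformative genes.
    """
    genes = sorted(set(genes))
    if len(genes) < 2:
        raise ValueError("node importance needs at least 2 genes")
    X = data.feature_matrix(genes)
    y = data.labels
    n = len(y)
    forest = BaggingClassifier(
        estimator=DecisionTreeClassifier(max_features="sqrt"),
        n_estimators=cfg.T,
        bootstrap=True,
        random_state=cfg.seed,
    )
    with sklearn.config_context(assume_finite=True, skip_parameter_validation=True):
        forest.fit(X, y)
        rng = np.random.default_rng(cfg.seed)
        totals = np.zeros(len(genes))
        n_oob_trees = 0
        for tree, sampled in zip(forest.estimators_, forest.estimators_samples_):
            oob = np.setdiff1d(np.arange(n), sampled)
            if oob.size == 0:
                continue
            n_oob_trees += 1
            X_oob, y_oob = X[oob], y[oob]
            err = float((tree.predict(X_oob) != y_oob).mean())
            for j in range(len(genes)):
                X_perm = X_oob.copy()
                X_perm[:, j] = X_perm[rng.permutation(oob.size), j]
                err_perm = float((tree.predict(X_perm) != y_oob).mean())
                totals[j] += err_perm - err
    if n_oob_trees == 0:
        raise ValueError("no tree had a non-empty out-of-bag sample")
    vi = totals / cfg.T
    return {g: float(v) for g, v in zip(genes, vi)}


def rank_genes(
    modules: Sequence[ModuleReport],
    score_cutoff: float | None = None,
    all_genes: Iterable[str] | None = None,
) -> list[tuple[str, float]]:
    """Rank genes by M_j = sum_i S_i * V_ij over the considered modules.

    Modules with ``score < score_cutoff`` are excluded when a cutoff is given
    (the contributing-set rule); pass ``None`` to use every module.  Genes in
    ``all_genes`` but in no contributing module get M = 0.  Sorted by M
    descending, ties broken lexicographically.
    """
    considered = [
        m
        for m in modules
        if score_cutoff is None or m.score >= score_cutoff
    ]
    M: dict[str, float] = {g: 0.0 for g in (all_genes or [])}
    for m in considered:
        if m.importances is None:
            raise ValueError(f"module {m.ego!r} carries no importances")
        for gene, vij in m.importances.items():
            M[gene] = M.get(gene, 0.0) + m.score * vij
    return sorted(M.items(), key=lambda kv: (-kv[1], kv[0]))


def de_flags(
    data: ExpressionDataset,
    fdr_threshold: float = 0.05,
    equal_var: bool = False,
) -> dict[str, tuple[bool, float]]:
    """Per-gene differential-expression flags between the two classes.

    Two-sample two-tailed t-test (Welch by default) per gene, followed by
    Benjamini-Hochberg adjustment across all tested genes; a gene is flagged
    when its adjusted p-value is below ``fdr_threshold``.  Genes with zero
    within-class variance in both classes get p = 1 (logged).
    """
    mask1 = data.labels == 1
    a = data.values[:, mask1]
    b = data.values[:, ~mask1]
    with np.errstate(divide="ignore", invalid="ignore"):
        res = stats.ttest_ind(a, b, axis=1, equal_var=equal_var)
    pvals = np.asarray(res.pvalue, dtype=float)
    degenerate = ~np.isfinite(pvals)
    if degenerate.any():
        logger.info("de_flags: %d degenerate gene(s) set to p=1", int(degenerate.sum()))
        pvals[degenerate] = 1.0
    flags, adjusted, _, _ = multipletests(pvals, alpha=fdr_threshold, method="fdr_bh")
    flags = adjusted < fdr_threshold
    return {
        g: (bool(f), float(q))
        for g, f, q in zip(data.genes, flags, adjusted)
    }
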