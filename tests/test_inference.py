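import numpy as np
import pytest

import egonet.inference as inf
from egonet import (
    ImportanceConfig,
    ModuleReport,
    ScorerConfig,
    SignificanceConfig,
    de_flags,
    node_importance,
    permutation_pvalue,
    rank_genes,
)
from conftest import make_dataset


class TestPermutationPvalue:
    def test_add_one_formula_when_observed_tops_all(self, monkeypatch, toy_dataset):
        monkeypatch.setattr(inf, "score_gene_set", lambda d, g, c: 0.5)
        p = permutation_pvalue(
            toy_dataset, ["A", "B"], 1.0, ScorerConfig(), SignificanceConfig(B=99)
        )
        assert p == pytest.approx(0.01)

    def test_p_is_one_when_all_nulls_reach_observed(self, monkeypatch, toy_dataset):
        monkeypatch.setattr(inf, "score_gene_set", lambda d, g, c: 0.9)
        p = permutation_pvalue(
            toy_dataset, ["A", "B"], 0.3, ScorerConfig(), SignificanceConfig(B=99)
        )
        assert p == 1.0

    def test_bounds_hold_on_real_scores(self, toy_dataset):
        cfg = ScorerConfig("svm", seed=0)
        obs = 0.75
        for B in (1, 9):
            p = permutation_pvalue(
                toy_dataset, ["A", "B"], obs, cfg, SignificanceConfig(B=B, seed=2)
            )
            assert 1 / (B + 1) <= p <= 1.0

    def test_deterministic(self, toy_dataset):
        cfg = ScorerConfig("svm", seed=0)
        sig = SignificanceConfig(B=9, seed=5)
        ps = {
            permutation_pvalue(toy_dataset, ["A", "B"], 0.8, cfg, sig)
            for _ in range(2)
        }
        assert len(ps) == 1


class TestNodeImportance:
    def test_signal_gene_beats_noise_gene(self):
        rng = np.random.default_rng(1)
        labels = np.array([0, 1] * 30)
        values = np.vstack(
            [labels + 0.1 * rng.standard_normal(60), rng.standard_normal(60)]
        )
        data = make_dataset(n_genes=2, n_samples=60, signal_genes=(), seed=0)
        data.values[:] = values
        vi = node_importance(data, data.genes, ImportanceConfig(T=100, seed=0))
        assert vi["A"] > vi["B"]

    def test_independent_gene_mean_importance_near_zero(self):
        # over 50 forests, the mean VI of a label-independent gene is ~0
        rng = np.random.default_rng(3)
        labels = np.array([0, 1] * 20)
        vis = []
        for seed in range(50):
            values = np.vstack(
                [labels + 0.3 * rng.standard_normal(40), rng.standard_normal(40)]
            )
            data = make_dataset(n_genes=2, n_samples=40, signal_genes=(), seed=0)
            data.values[:] = values
            vi = node_importance(data, data.genes, ImportanceConfig(T=30, seed=seed))
            vis.append(vi["B"])
        assert abs(np.mean(vis)) < 0.02

    def test_single_tree_matches_manual_oob_bookkeeping(self):
        # recompute VI for T=1 from the tree's own OOB sample and predictions
        data = make_dataset(n_genes=3, n_samples=10, signal_genes=(0,), seed=8)
        cfg = ImportanceConfig(T=1, seed=21)
        vi = node_importance(data, data.genes, cfg)

        from sklearn.ensemble import BaggingClassifier
        from sklearn.tree import DecisionTreeClassifier

        X = data.feature_matrix(data.genes)
        y = data.labels
        forest = BaggingClassifier(
            estimator=DecisionTreeClassifier(max_features="sqrt"),
            n_estimators=1,
            bootstrap=True,
            random_state=cfg.seed,
        ).fit(X, y)
        tree = forest.estimators_[0]
        oob = np.setdiff1d(np.arange(10), forest.estimators_samples_[0])
        err = np.mean(tree.predict(X[oob]) != y[oob])
        rng = np.random.default_rng(cfg.seed)
        expected = {}
        for j, gene in enumerate(sorted(data.genes)):
            Xp = X[oob].copy()
            Xp[:, j] = Xp[rng.permutation(oob.size), j]
            expected[gene] = float(np.mean(tree.predict(Xp) != y[oob]) - err)
        assert vi == pytest.approx(expected)

    def test_requires_two_genes(self, toy_dataset):
        with pytest.raises(ValueError):
            node_importance(toy_dataset, ["A"], ImportanceConfig(T=5))


def module(ego, members, score, importances):
    return ModuleReport(
        ego=ego,
        level=1,
        members=frozenset(members),
        score=score,
        importances=importances,
    )


class TestRankGenes:
    def test_gene_in_no_module_gets_zero(self):
        mods = [module("a", {"a", "b"}, 0.9, {"a": 0.5, "b": 0.1})]
        ranking = dict(rank_genes(mods, all_genes=["a", "b", "z"]))
        assert ranking["z"] == 0.0

    def test_single_module_arithmetic(self):
        mods = [module("a", {"a", "b"}, 0.9, {"a": 0.5, "b": 0.1})]
        assert dict(rank_genes(mods))["a"] == pytest.approx(0.45)

    def test_two_module_summation(self):
        mods = [
            module("a", {"a", "g"}, 0.9, {"a": 0.1, "g": 0.2}),
            module("b", {"b", "g"}, 0.8, {"b": 0.3, "g": 0.1}),
        ]
        assert dict(rank_genes(mods))["g"] == pytest.approx(0.9 * 0.2 + 0.8 * 0.1)

    def test_linearity_in_scores(self, rng):
        mods = []
        for i in range(5):
            members = {f"e{i}"} | {f"g{j}" for j in rng.choice(8, 3, replace=False)}
            imps = {g: float(rng.normal()) for g in members}
            mods.append(module(f"e{i}", members, float(rng.uniform(0.5, 0.9)), imps))
        base = dict(rank_genes(mods))
        doubled_mods = [
            ModuleReport(
                ego=m.ego,
                level=m.level,
                members=m.members,
                score=min(1.0, m.score),  # scores live in [0,1]; scale inputs instead
                importances={g: 2 * v for g, v in m.importances.items()},
            )
            for m in mods
        ]
        doubled = dict(rank_genes(doubled_mods))
        for g in base:
            assert doubled[g] == pytest.approx(2 * base[g])

    def test_cutoff_excludes_low_scoring_modules(self):
        mods = [
            module("a", {"a", "b"}, 0.95, {"a": 1.0, "b": 1.0}),
            module("c", {"c", "b"}, 0.5, {"c": 1.0, "b": 1.0}),
        ]
        ranking = dict(rank_genes(mods, score_cutoff=0.9))
        assert "c" not in ranking or ranking["c"] == 0.0
        assert ranking["b"] == pytest.approx(0.95)

    def test_membership_breadth_raises_rank(self):
        # equal per-module importances: a gene in more high-scoring modules
        # accumulates a weakly higher M (the hub-enrichment property)
        hub_mods = [
            module(f"e{i}", {f"e{i}", "hub"}, 0.9, {f"e{i}": 0.2, "hub": 0.2})
            for i in range(3)
        ]
        lone = module("x", {"x", "leaf"}, 0.9, {"x": 0.2, "leaf": 0.2})
        ranking = dict(rank_genes(hub_mods + [lone]))
        assert ranking["hub"] > ranking["leaf"]

    def test_sorted_desc_with_lex_ties(self):
        mods = [module("a", {"a", "b"}, 1.0, {"a": 0.3, "b": 0.3})]
        ranking = rank_genes(mods)
        assert ranking == [("a", pytest.approx(0.3)), ("b", pytest.approx(0.3))]


class TestDeFlags:
    def test_null_gene_not_flagged(self):
        data = make_dataset(n_genes=5, n_samples=60, signal_genes=(), seed=0)
        flags = de_flags(data)
        assert not any(flag for flag, _ in flags.values())

    def test_strong_effect_flagged(self):
        # class means -2 vs +2, sd 1, n=50/class: power is essentially 1
        rng = np.random.default_rng(0)
        data = make_dataset(n_genes=4, n_samples=100, signal_genes=(), seed=1)
        data.values[0] = rng.standard_normal(100) + np.where(data.labels == 1, 2, -2)
        flags = de_flags(data)
        assert flags[data.genes[0]][0]

    def test_constant_gene_gets_p_one(self):
        data = make_dataset(n_genes=3, n_samples=20, signal_genes=(), seed=2)
        data.values[1] = 1.0
        flags = de_flags(data)
        assert not flags[data.genes[1]][0]
        assert flags[data.genes[1]][1] == 1.0

    def test_bh_null_false_discovery_fraction(self):
        # global null, 200 genes x 30 reps: mean flagged fraction stays below alpha
        fracs = []
        for seed in range(30):
            data = make_dataset(n_genes=200, n_samples=40, signal_genes=(), seed=seed)
            flags = de_flags(data, fdr_threshold=0.05)
            fracs.append(np.mean([f for f, _ in flags.values()]))
        assert np.mean(fracs) <= 0.05
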