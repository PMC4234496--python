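"""Preset benchmark studies at desk scale.

These presets fix the simulation-study conditions the package uses to
validate itself on a single CPU in minutes rather than hours.  The
distributional conditions (standard-normal expression, 100 samples, planted
ego of degree 5-20, 80% disease fraction, preferential attachment m=3) are
the reference conditions of :class:`~egonet.simulate.SimulationConfig`; only
the problem sizes are reduced:

* ``table1_scaled`` — recovery of the planted module with the SVM scorer on
  200-node networks, 30 instances per outcome model, top-1 and top-5.
* ``classifier_direction_scaled`` — SVM versus RF top-1 recovery under the
  cubic outcome on 50-node networks, 50 paired instances.  The node cap
  scales proportionally with the graph (30 = 300 x 50/500) and the forest
  is reduced to 25 trees with 3-fold CV to keep the forest's per-tree cost
  tractable at this instance count.
* ``comparison_scaled`` — ego-network discovery versus the greedy
  aggregated-Z baseline on 100-node networks, 30 instances, in the scenario
  where the ego itself is not linked to the outcome.
"""

from __future__ import annotations

from .simulate import SimulationConfig, comparison_study, recovery_rates

__all__ = [
    "table1_scaled",
    "classifier_direction_scaled",
    "comparison_scaled",
]


def table1_scaled(seed: int = 0, n_sims: int = 30) -> dict[str, dict[int, float]]:
    """SVM recovery rates (%) by outcome model and top-k at reduced scale.

    Returns ``{outcome: {1: rate, 5: rate}}``.
    """
    out: dict[str, dict[int, float]] = {}
    for outcome in ("linear", "nonlinear"):
        cfg = SimulationConfig(
            n_nodes=200, n_samples=100, n_sims=n_sims, outcome=outcome, seed=seed
        )
        out[outcome] = recovery_rates(cfg, classifier="svm", top_ks=(1, 5), folds=5)
    return out


def classifier_direction_scaled(seed: int = 0, n_sims: int = 50) -> dict[str, float]:
    """Top-1 recovery (%) of SVM and RF under the cubic outcome, paired instances."""
    cfg = SimulationConfig(
        n_nodes=50, n_samples=100, n_sims=n_sims, outcome="nonlinear", seed=seed
    )
    svm = recovery_rates(cfg, "svm", top_ks=(1,), folds=3, node_cap=30)[1]
    rf = recovery_rates(
        cfg,
        "rf",
        top_ks=(1,),
        folds=3,
        classifier_params={"n_estimators": 25},
        node_cap=30,
    )[1]
    return {"svm": svm, "rf": rf}


def comparison_scaled(seed: int = 0, n_sims: int = 30) -> dict[str, dict[str, float]]:
    """Ego-network discovery vs the greedy aggregated-Z baseline, ego-excluded scenario."""
    cfg = SimulationConfig(
        n_nodes=100,
        n_samples=100,
        n_sims=n_sims,
        outcome="linear",
        scenario="ego_excluded",
        seed=seed,
    )
    return comparison_study(cfg, folds=5)
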