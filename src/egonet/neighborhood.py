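"""Ego-network construction and snowball-sampling module growth.

A level-k ego-network of a node is the closed breadth-first neighbourhood of
radius k: the ego plus every node within graph distance k.  A module is grown
outward level by level from each eligible ego (degree >= 2) and the growth
stops at the first level whose cross-validated accuracy drops below the
previous level's — the snowball-sampling rule.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx

from .io import ExpressionDataset
from .scoring import ScorerConfig, score_gene_set

logger = logging.getLogger(__name__)

__all__ = [
    "EgoNeighborhood",
    "GrownModule",
    "ego_neighborhood",
    "eligible_egos",
    "grow_module",
    "enumerate_modules",
    "module_sort_key",
]

DEFAULT_MAX_LEVEL = 3
DEFAULT_NODE_CAP = 300


@dataclass(frozen=True)
class EgoNeighborhood:
    ego: str
    level: int
    members: frozenset[str]


@dataclass(frozen=True)
class GrownModule:
    """A grown ego-network module.

    ``chosen_level`` is the level with the maximal score in ``score_trace``
    (the earliest on ties); by the stopping rule that is also the last level
    before the first accuracy drop.
    """

    ego: str
    chosen_level: int
    members: frozenset[str]
    score: float
    score_trace: tuple[tuple[int, float], ...]


def ego_neighborhood(net: nx.Graph, ego: str, level: int) -> EgoNeighborhood:
    """Closed breadth-first neighbourhood of radius ``level`` around ``ego``."""
    if ego not in net:
        raise KeyError(f"ego {ego!r} not in network")
    if level < 0:
        raise ValueError("level must be >= 0")
    reach = nx.single_source_shortest_path_length(net, ego, cutoff=level)
    return EgoNeighborhood(ego=ego, level=level, members=frozenset(reach))


def eligible_egos(net: nx.Graph) -> list[str]:
    """Nodes with degree >= 2 (more than one connection), sorted."""
    return sorted(v for v, d in net.degree() if d >= 2)


def grow_module(
    net: nx.Graph,
    data: ExpressionDataset,
    ego: str,
    scorer: ScorerConfig,
    max_level: int = DEFAULT_MAX_LEVEL,
    node_cap: int = DEFAULT_NODE_CAP,
) -> GrownModule | None:
    """Grow one ego's module by snowball sampling with the accuracy-drop rule.

    Scores the level-1 neighbourhood, then repeatedly scores level k+1,
    stopping at the first strict score drop, at ``max_level``, when a level
    adds no new node, or when the next level would exceed ``node_cap`` nodes.
    Returns the level with the maximal score (earliest on ties), or ``None``
    (with a logged reason) when the module has fewer than two scorable genes.
    """
    if max_level < 1:
        raise ValueError("max_level must be >= 1")
    trace: list[tuple[int, float]] = []
    level_members: dict[int, frozenset[str]] = {}
    prev: frozenset[str] | None = None
    for level in range(1, max_level + 1):
        members = ego_neighborhood(net, ego, level).members
        if prev is not None and members == prev:
            break  # component exhausted; nothing new to add
        scorable = frozenset(g for g in members if g in data)
        if len(scorable) < 2:
            logger.info("skipping ego %s: fewer than 2 scorable genes", ego)
            return None
        if prev is not None and len(members) > node_cap:
            break  # hub blow-up guard: keep the previous level
        score = score_gene_set(data, scorable, scorer)
        if trace and score < trace[-1][1]:
            trace.append((level, score))
            break  # first drop: stop spreading
        trace.append((level, score))
        level_members[level] = members
        prev = members
    best_level, best_score = max(trace, key=lambda t: (t[1], -t[0]))
    return GrownModule(
        ego=ego,
        chosen_level=best_level,
        members=level_members[best_level],
        score=best_score,
        score_trace=tuple(trace),
    )


def enumerate_modules(
    net: nx.Graph,
    data: ExpressionDataset,
    scorer: ScorerConfig,
    max_level: int = DEFAULT_MAX_LEVEL,
    node_cap: int = DEFAULT_NODE_CAP,
) -> list[GrownModule]:
    """Grow a module from every eligible ego, in lexicographic ego order."""
    modules = []
    n_skipped = 0
    for ego in eligible_egos(net):
        grown = grow_module(net, data, ego, scorer, max_level, node_cap)
        if grown is None:
            n_skipped += 1
        else:
            modules.append(grown)
    if n_skipped:
        logger.info("enumerate_modules: skipped %d ego(s)", n_skipped)
    return modules


def module_sort_key(module: GrownModule):
    """Sort key for ranking modules: score desc, then smaller, then ego id."""
    return (-module.score, len(module.members), module.ego)
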