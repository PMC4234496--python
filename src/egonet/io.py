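"""Readers, writers and containers for networks, expression matrices and module reports.

The on-disk dialects are deliberately plain: an edge list is two (or three,
SIF-style) whitespace/tab-separated columns of gene identifiers; an expression
matrix is a tab-separated table with gene identifiers down the first column and
sample identifiers across the first row; phenotype labels are a two-column TSV
mapping sample identifier to 0/1.  Gene identifiers are opaque, case-sensitive
strings — no symbol mapping is attempted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionDataset",
    "ModuleReport",
    "read_network",
    "write_network",
    "read_expression",
    "align",
    "write_module_reports",
    "read_module_reports",
    "write_ranking",
]


@dataclass
class ExpressionDataset:
    """A gene-by-sample expression matrix with a binary phenotype per sample.

    Parameters
    ----------
    genes : ordered gene identifiers (matrix rows).
    samples : ordered sample identifiers (matrix columns).
    values : float matrix of shape ``(len(genes), len(samples))``.
    labels : 0/1 phenotype per sample; both classes must be present.
    """

    genes: list[str]
    samples: list[str]
    values: np.ndarray
    labels: np.ndarray
    _index: dict[str, int] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.values.shape != (len(self.genes), len(self.samples)):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.genes)} genes x {len(self.samples)} samples"
            )
        if self.labels.shape != (len(self.samples),):
            raise ValueError("one label per sample is required")
        classes = set(self.labels.tolist())
        if not classes <= {0, 1}:
            raise ValueError(f"labels must be 0/1, got {sorted(classes)}")
        if len(classes) != 2:
            raise ValueError("both phenotype classes must be present")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("duplicate gene identifiers in expression data")
        self._index = {g: i for i, g in enumerate(self.genes)}

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def feature_matrix(self, genes: Iterable[str]) -> np.ndarray:
        """Samples-by-genes matrix for a gene set, columns in sorted gene order."""
        ordered = sorted(set(genes))
        missing = [g for g in ordered if g not in self._index]
        if missing:
            raise KeyError(f"genes absent from expression data: {missing[:5]}")
        rows = [self._index[g] for g in ordered]
        return self.values[rows].T.copy()

    def expression_of(self, gene: str) -> np.ndarray:
        return self.values[self._index[gene]]

    def __contains__(self, gene: str) -> bool:
        return gene in self._index

    def with_labels(self, labels: np.ndarray) -> "ExpressionDataset":
        """Same expression values with replacement labels (for permutation tests)."""
        return replace(self, labels=np.asarray(labels, dtype=int))

    def subset_genes(self, genes: Iterable[str]) -> "ExpressionDataset":
        keep = [g for g in self.genes if g in set(genes)]
        rows = [self._index[g] for g in keep]
        return ExpressionDataset(keep, list(self.samples), self.values[rows], self.labels)


@dataclass
class ModuleReport:
    """One discovered ego-network module with its score and statistics.

    ``score`` is the module score S_i (cross-validated classification accuracy
    of the member genes), ``p_value`` its permutation p-value, and
    ``importances`` maps each member gene j to its node importance V_ij.
    """

    ego: str
    level: int
    members: frozenset[str]
    score: float
    p_value: float | None = None
    importances: dict[str, float] | None = None

    def __post_init__(self) -> None:
        self.members = frozenset(self.members)
        if self.ego not in self.members:
            raise ValueError(f"ego {self.ego!r} not among module members")
        if not 0.0 <= self.score <= 1.0:
            raise ValueError(f"score {self.score} outside [0, 1]")
        if self.p_value is not None and not 0.0 < self.p_value <= 1.0:
            raise ValueError(f"p-value {self.p_value} outside (0, 1]")


def read_network(path: str | Path) -> nx.Graph:
    """Read an undirected simple graph from a two-column edge list.

    Tab- or whitespace-delimited, one edge per line; a SIF-style middle
    interaction-type column in three-column lines is ignored; an optional
    single header line is tolerated only insofar as it parses as an edge.
    Self-loops are dropped with a warning and duplicate edges collapse.
    """
    graph = nx.Graph()
    n_self, n_dup = 0, 0
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) == 3:  # SIF dialect: source, interaction type, target
                u, _, v = parts
            elif len(parts) == 2:
                u, v = parts
            else:
                raise ValueError(
                    f"{path}: line {lineno}: expected 2 columns, got {len(parts)}"
                )
            if u == v:
                n_self += 1
                continue
            if graph.has_edge(u, v):
                n_dup += 1
            graph.add_edge(u, v)
    if n_self:
        logger.warning("%s: dropped %d self-loop(s)", path, n_self)
    if n_dup:
        logger.info("%s: collapsed %d duplicate edge(s)", path, n_dup)
    return graph


def write_network(graph: nx.Graph, path: str | Path) -> None:
    """Write an edge list, one tab-separated edge per line, in sorted order."""
    with open(path, "w") as fh:
        for u, v in sorted(tuple(sorted(e)) for e in graph.edges()):
            fh.write(f"{u}\t{v}\n")


def _read_labels(label_path: str | Path) -> dict[str, int]:
    labels: dict[str, int] = {}
    with open(label_path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) != 2:
                raise ValueError(
                    f"{label_path}: line {lineno}: expected 'sample<TAB>label'"
                )
            sample, value = parts
            if lineno == 1 and value not in {"0", "1"}:
                continue  # header line
            if value not in {"0", "1"}:
                raise ValueError(
                    f"{label_path}: line {lineno}: label must be 0 or 1, got {value!r}"
                )
            if sample in labels:
                raise ValueError(f"{label_path}: duplicate sample {sample!r}")
            labels[sample] = int(value)
    return labels


def read_expression(path: str | Path, label_path: str | Path) -> ExpressionDataset:
    """Read a tab-delimited expression matrix and a sample-label TSV.

    The matrix has gene identifiers in the first column and sample identifiers
    in the first row.  Every sample must have a label; non-numeric entries and
    duplicate gene rows are errors (no imputation or aggregation is done).
    """
    frame = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if frame.index.has_duplicates:
        dups = frame.index[frame.index.duplicated()].unique().tolist()
        raise ValueError(f"{path}: duplicate gene rows: {dups[:5]}")
    values = np.empty(frame.shape, dtype=float)
    for j, sample in enumerate(frame.columns):
        col = pd.to_numeric(frame.iloc[:, j], errors="coerce")
        if col.isna().any():
            gene = frame.index[int(np.argmax(col.isna().to_numpy()))]
            raise ValueError(
                f"{path}: non-numeric expression value for gene {gene!r} "
                f"in sample {sample!r}"
            )
        values[:, j] = col.to_numpy()

    label_map = _read_labels(label_path)
    samples = [str(s) for s in frame.columns]
    missing = [s for s in samples if s not in label_map]
    if missing:
        raise ValueError(f"{label_path}: no label for sample(s) {missing[:5]}")
    unknown = sorted(set(label_map) - set(samples))
    if unknown:
        raise ValueError(f"{label_path}: unknown sample(s) {unknown[:5]}")
    labels = np.array([label_map[s] for s in samples], dtype=int)
    for cls in (0, 1):
        if int((labels == cls).sum()) < 2:
            raise ValueError(f"fewer than 2 samples in class {cls}")
    return ExpressionDataset([str(g) for g in frame.index], samples, values, labels)


def align(
    network: nx.Graph, data: ExpressionDataset
) -> tuple[nx.Graph, ExpressionDataset]:
    """Restrict network and expression data to their common gene set.

    Genes present in only one of the two inputs carry no usable signal for
    module scoring and are dropped (counts logged).  Idempotent.
    """
    net_genes = set(network.nodes)
    expr_genes = set(data.genes)
    common = net_genes & expr_genes
    if not common:
        raise ValueError("network and expression data share no genes")
    dropped_net = len(net_genes - common)
    dropped_expr = len(expr_genes - common)
    if dropped_net or dropped_expr:
        logger.info(
            "align: dropped %d network-only and %d expression-only gene(s); "
            "%d genes remain",
            dropped_net,
            dropped_expr,
            len(common),
        )
    sub = network.subgraph(common).copy() if dropped_net else network
    data2 = data.subset_genes(common) if dropped_expr else data
    return sub, data2


_FLOAT_FMT = "%.6g"


def _fmt(x: float | None) -> str:
    return "NA" if x is None else _FLOAT_FMT % x


def write_module_reports(modules: Sequence[ModuleReport], path: str | Path) -> None:
    """Write modules as TSV: ego, level, score, p_value, comma-joined members."""
    with open(path, "w") as fh:
        fh.write("ego\tlevel\tscore\tp_value\tn_members\tmembers\n")
        for m in modules:
            members = ",".join(sorted(m.members))
            fh.write(
                f"{m.ego}\t{m.level}\t{_fmt(m.score)}\t{_fmt(m.p_value)}"
                f"\t{len(m.members)}\t{members}\n"
            )


def read_module_reports(path: str | Path) -> list[ModuleReport]:
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    modules = []
    for _, row in frame.iterrows():
        p = None if row["p_value"] == "NA" else float(row["p_value"])
        modules.append(
            ModuleReport(
                ego=row["ego"],
                level=int(row["level"]),
                members=frozenset(row["members"].split(",")),
                score=float(row["score"]),
                p_value=p,
            )
        )
    return modules


def write_ranking(
    ranking: Sequence[tuple[str, float]],
    path: str | Path,
    de: Mapping[str, tuple[bool, float]] | None = None,
) -> None:
    """Write the gene-ranking table: gene, M value, DE flag, DE FDR."""
    with open(path, "w") as fh:
        fh.write("gene\tM\tde_flag\tde_fdr\n")
        for gene, m in ranking:
            if de is not None and gene in de:
                flag, fdr = de[gene]
                fh.write(f"{gene}\t{_fmt(m)}\t{'YES' if flag else 'NO'}\t{_fmt(fdr)}\n")
            else:
                fh.write(f"{gene}\t{_fmt(m)}\tNA\tNA\n")
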