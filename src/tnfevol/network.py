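"""Expression-correlation and immune top-k overlap networks.

Expression matrices hold transcripts-per-million values for genes
across cell types (the reference design is 18 TNF-superfamily genes by
81 human cell types, 11 of which are immune).  Two networks are built:

* the correlation network links gene pairs whose Spearman rank
  correlation survives Benjamini-Hochberg FDR control (positive
  correlations only by default);
* the immune-overlap network links pairs whose top-k expressing cell
  types share at least ``min_shared`` immune types.  The null
  probability of that overlap, with each gene's top-k membership taken
  as independent and uniform, is a binomial tail:
  ``P(X >= min_shared)`` for ``X ~ Binom(immune_n, (top_k/total)**2)``,
  which is ~5.3e-4 at the reference design (81 types, top 10, 11 immune,
  >=3 shared).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import FormatError


@dataclass
class ExpressionMatrix:
    """Genes x cell types expression values (TPM) with an immune subset."""

    values: pd.DataFrame
    immune_types: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if (self.values.values < 0).any():
            raise FormatError("expression values must be non-negative")
        extra = self.immune_types - set(self.values.columns)
        if extra:
            raise FormatError(f"immune cell types not in matrix: {sorted(extra)}")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def cell_types(self) -> list[str]:
        return list(self.values.columns)

    def drop_cell_types(self, exclude: set[str]) -> "ExpressionMatrix":
        keep = [c for c in self.values.columns if c not in exclude]
        return ExpressionMatrix(values=self.values[keep],
                                immune_types=frozenset(self.immune_types) - exclude)


@dataclass
class NetworkConfig:
    alpha: float = 0.05       # FDR level
    top_k: int = 10           # highest-expression cell types per gene
    immune_n: int = 11        # size of the immune subset
    min_shared: int = 3       # shared immune top-k types for a link
    positive_only: bool = True

    def validate(self, n_cell_types: Optional[int] = None) -> None:
        if not 0 < self.alpha < 1:
            raise FormatError("alpha must be in (0, 1)")
        if n_cell_types is not None and self.top_k > n_cell_types:
            raise FormatError("top_k exceeds the number of cell types")
        if self.min_shared > self.immune_n:
            raise FormatError("min_shared cannot exceed the immune subset size")


# Elementary statistics --------------------------------------------------------


def spearman_rho(x: Sequence[float], y: Sequence[float]) -> float:
    """Spearman rank correlation (Pearson on mid-ranked data).

    Returns ``nan`` when either vector is constant (no correlation
    computable).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise FormatError("spearman_rho requires two equal-length vectors, n >= 3")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return float("nan")
    rho = stats.spearmanr(x, y).statistic
    return float(rho)


def spearman_pvalue(rho: float, n: int) -> float:
    """Two-sided p-value for a Spearman coefficient via the t-statistic
    ``t = rho * sqrt((n - 2) / (1 - rho**2))`` on n-2 degrees of freedom."""
    if n < 4:
        raise FormatError("spearman_pvalue requires n >= 4")
    if math.isnan(rho):
        return float("nan")
    if abs(rho) > 1:
        raise FormatError("|rho| cannot exceed 1")
    if abs(rho) == 1.0:
        return 0.0
    t = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
    return float(2.0 * stats.t.sf(abs(t), df=n - 2))


def bh_fdr(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise FormatError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# Correlation network ----------------------------------------------------------


@dataclass
class CorrelationEdge:
    gene_a: str
    gene_b: str
    rho: float
    p: float
    q: float


@dataclass
class CorrelationNetwork:
    """Simple graph over genes; nodes carry ancestral-class colors."""

    graph: nx.Graph
    edges: list[CorrelationEdge] = field(default_factory=list)

    def degree_of(self, gene: str) -> int:
        return self.graph.degree[gene]


def correlation_network(expr: ExpressionMatrix, cfg: Optional[NetworkConfig] = None,
                        exclude_cell_types: Optional[set[str]] = None,
                        class_map: Optional[dict[str, str]] = None
                        ) -> CorrelationNetwork:
    """Test all unordered gene pairs; keep edges with q < alpha.

    With ``positive_only`` (the default) only positive correlations
    become links.  Isolated genes are retained as nodes.  Excluding
    cell types (e.g. the immune subset) reruns the analysis on the
    remaining columns.
    """
    cfg = cfg or NetworkConfig()
    mat = expr.drop_cell_types(exclude_cell_types) if exclude_cell_types else expr
    n = len(mat.cell_types)
    if n < 4:
        raise FormatError("need >= 4 cell types after exclusion")
    cfg.validate()

    genes = mat.genes
    pairs: list[tuple[str, str, float, float]] = []
    for i, a in enumerate(genes):
        xa = mat.values.loc[a].to_numpy()
        for b in genes[i + 1:]:
            rho = spearman_rho(xa, mat.values.loc[b].to_numpy())
            p = spearman_pvalue(rho, n) if not math.isnan(rho) else float("nan")
            pairs.append((a, b, rho, p))

    tested = [(a, b, rho, p) for a, b, rho, p in pairs if not math.isnan(p)]
    qvals = bh_fdr([p for _, _, _, p in tested]) if tested else np.array([])

    g = nx.Graph()
    for gene in genes:
        g.add_node(gene, ancestral_class=(class_map or {}).get(gene))
    edges = []
    for (a, b, rho, p), q in zip(tested, qvals):
        if q < cfg.alpha and (rho > 0 or not cfg.positive_only):
            g.add_edge(a, b, rho=rho, p=p, q=float(q))
            edges.append(CorrelationEdge(a, b, rho=rho, p=p, q=float(q)))
    return CorrelationNetwork(graph=g, edges=edges)


# Immune top-k overlap ---------------------------------------------------------


def _topk_types(expr: ExpressionMatrix, gene: str, k: int) -> set[str]:
    row = expr.values.loc[gene]
    # rank by value descending; ties at the k-th value break by cell-type name
    ordered = sorted(row.items(), key=lambda kv: (-kv[1], kv[0]))
    return {ct for ct, _ in ordered[:k]}


def topk_overlap(expr: ExpressionMatrix, gene_a: str, gene_b: str,
                 cfg: Optional[NetworkConfig] = None) -> tuple[set[str], bool]:
    """Shared immune cell types among both genes' top-k, and whether the
    pair counts as similar (>= min_shared shared immune types)."""
    cfg = cfg or NetworkConfig()
    cfg.validate(n_cell_types=len(expr.cell_types))
    for gene in (gene_a, gene_b):
        if gene not in expr.values.index:
            raise FormatError(f"gene {gene!r} not in expression matrix")
    ta = _topk_types(expr, gene_a, cfg.top_k) & expr.immune_types
    tb = _topk_types(expr, gene_b, cfg.top_k) & expr.immune_types
    shared = ta & tb
    return shared, len(shared) >= cfg.min_shared


def overlap_null_pvalue(cfg: Optional[NetworkConfig] = None,
                        total_types: int = 81) -> float:
    """Binomial tail P(X >= min_shared), X ~ Binom(immune_n, (top_k/total)^2).

    Each immune cell type lands in one gene's top-k with probability
    top_k/total_types; for a shared appearance in two independent genes
    the per-trial success is the square.
    """
    cfg = cfg or NetworkConfig()
    if cfg.min_shared <= 0:
        return 1.0
    if cfg.min_shared > cfg.immune_n:
        return 0.0
    p_trial = (cfg.top_k / total_types) ** 2
    return float(stats.binom.sf(cfg.min_shared - 1, cfg.immune_n, p_trial))


def overlap_network(expr: ExpressionMatrix, cfg: Optional[NetworkConfig] = None,
                    class_map: Optional[dict[str, str]] = None
                    ) -> CorrelationNetwork:
    """Link gene pairs whose immune top-k overlap reaches min_shared."""
    cfg = cfg or NetworkConfig()
    g = nx.Graph()
    for gene in expr.genes:
        g.add_node(gene, ancestral_class=(class_map or {}).get(gene))
    genes = expr.genes
    for i, a in enumerate(genes):
        for b in genes[i + 1:]:
            shared, similar = topk_overlap(expr, a, b, cfg)
            if similar:
                g.add_edge(a, b, shared_types=sorted(shared))
    return CorrelationNetwork(graph=g)


def degree_stats_by_class(net: CorrelationNetwork,
                          class_map: dict[str, str]) -> dict[str, float]:
    """Arithmetic mean node degree per ancestral class."""
    sums: dict[str, list[int]] = {}
    for node in net.graph.nodes:
        if node not in class_map:
            raise FormatError(f"gene {node!r} missing from the class map")
        acc = sums.setdefault(class_map[node], [0, 0])
        acc[0] += net.graph.degree[node]
        acc[1] += 1
    return {cls: s / n for cls, (s, n) in sums.items()}
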