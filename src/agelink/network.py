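"""Protein-interaction and co-expression network computations.

The graph wrapper keeps the invariants (no self-loops, no duplicate pairs)
at construction time; all heavy graph algorithms delegate to networkx.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .catalog import read_edge_list, write_edge_list


@dataclass(frozen=True)
class InteractionGraph:
    """Undirected simple graph over gene symbols."""

    graph: nx.Graph

    @classmethod
    def from_edges(
        cls, edges: Iterable[tuple[str, str]], extra_nodes: Iterable[str] = ()
    ) -> "InteractionGraph":
        g = nx.Graph()
        g.add_nodes_from(extra_nodes)
        for a, b in edges:
            if a == b:
                continue
            g.add_edge(a, b)
        return cls(graph=g)

    @classmethod
    def from_tsv(cls, path: str | Path, **kwargs) -> "InteractionGraph":
        return cls.from_edges(read_edge_list(path, **kwargs))

    def to_tsv(self, path: str | Path) -> None:
        write_edge_list(self.graph.edges(), path)

    @property
    def nodes(self) -> frozenset[str]:
        return frozenset(self.graph.nodes())

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def degree(self, gene: str) -> int:
        return self.graph.degree(gene) if gene in self.graph else 0

    def degrees(self, genes: Iterable[str] | None = None) -> dict[str, int]:
        if genes is None:
            return dict(self.graph.degree())
        return {g: self.degree(g) for g in genes}

    def neighbors(self, gene: str) -> set[str]:
        return set(self.graph.neighbors(gene)) if gene in self.graph else set()

    def mean_degree(self) -> float:
        n = self.graph.number_of_nodes()
        return 2 * self.n_edges / n if n else float("nan")

    def median_degree(self) -> float:
        degs = [d for _, d in self.graph.degree()]
        return float(np.median(degs)) if degs else float("nan")


@dataclass(frozen=True)
class SetNetworkSummary:
    set_name: str
    n_in_graph: int
    mean_degree: float  # NaN when the set misses the graph entirely
    mean_clustering: float
    core_size: int


def set_network_summary(
    s: Iterable[str], g: InteractionGraph, name: str = "set"
) -> SetNetworkSummary:
    """Degree / clustering / connected-core summary for one gene set.

    Degree counts neighbors anywhere in the graph; clustering is the mean
    local clustering coefficient over in-graph members (degree < 2 members
    contribute 0); the core is the largest connected component of the
    induced subgraph.
    """
    members = frozenset(s)
    present = members & g.nodes
    if not present:
        return SetNetworkSummary(name, 0, float("nan"), float("nan"), 0)
    degs = [g.degree(x) for x in sorted(present)]
    clustering = nx.clustering(g.graph, nodes=sorted(present))
    sub = g.graph.subgraph(present)
    core = max((len(c) for c in nx.connected_components(sub)), default=0)
    return SetNetworkSummary(
        set_name=name,
        n_in_graph=len(present),
        mean_degree=float(np.mean(degs)),
        mean_clustering=float(np.mean(list(clustering.values()))),
        core_size=core,
    )


@dataclass(frozen=True)
class EdgePartition:
    within_a: int
    within_b: int
    cross: int


def edge_partition(
    a: Iterable[str], b: Iterable[str], g: InteractionGraph
) -> EdgePartition:
    """Classify induced edges of A ∪ B as within-A, within-B or cross.

    Genes in both sets are excluded (with a warning) so the three counts
    partition the induced edge set exactly.
    """
    import warnings

    a, b = frozenset(a), frozenset(b)
    both = a & b
    if both:
        warnings.warn(f"edge_partition: excluding {len(both)} genes present in both sets", stacklevel=2)
        a, b = a - both, b - both
    sub = g.graph.subgraph((a | b) & g.nodes)
    wa = wb = cross = 0
    for u, v in sub.edges():
        if u in a and v in a:
            wa += 1
        elif u in b and v in b:
            wb += 1
        else:
            cross += 1
    return EdgePartition(within_a=wa, within_b=wb, cross=cross)


def first_order_expansion(seed: Iterable[str], g: InteractionGraph) -> frozenset[str]:
    """Seed genes plus their direct interaction partners."""
    seed = frozenset(seed)
    partners: set[str] = set()
    for s in seed & g.nodes:
        partners.update(g.graph.neighbors(s))
    return seed | partners


def coexpression_expansion(
    seed: Iterable[str],
    pairs: pd.DataFrame,
    alpha: float = 0.05,
    genome_n: int = 20183,
) -> frozenset[str]:
    """Seed genes plus partners co-expressed below the Bonferroni threshold.

    The threshold is ``alpha / genome_n`` (0.05 / 20183 ≈ 2.5e-06 at the
    default genome size). A partner joins when a pair linking it to a seed
    gene, in either column order, has p strictly below the threshold.
    """
    if genome_n <= 0:
        raise ValueError("genome_n must be positive")
    threshold = coexpression_threshold(alpha, genome_n)
    seed = frozenset(seed)
    hits = pairs[pairs["p"] < threshold]
    partners: set[str] = set()
    for a, b in zip(hits["gene_a"], hits["gene_b"]):
        if a in seed:
            partners.add(b)
        if b in seed:
            partners.add(a)
    return seed | partners


def coexpression_threshold(alpha: float = 0.05, genome_n: int = 20183) -> float:
    """Bonferroni-corrected co-expression significance threshold."""
    if genome_n <= 0:
        raise ValueError("genome_n must be positive")
    return alpha / genome_n


@dataclass(frozen=True)
class DegreeNull:
    """Empirical null of mean degree for random same-sized node sets."""

    samples: np.ndarray

    def percentile(self, value: float) -> float:
        """Fraction of null draws with mean degree <= value."""
        return float(np.mean(self.samples <= value))


def random_set_degree_null(
    size: int, g: InteractionGraph, draws: int = 1000, seed: int = 0
) -> DegreeNull:
    """Mean-degree null from uniformly drawn node subsets (no replacement)."""
    nodes = sorted(g.nodes)
    if size > len(nodes):
        raise ValueError(f"size {size} exceeds node count {len(nodes)}")
    if draws < 1:
        raise ValueError("draws must be >= 1")
    rng = np.random.default_rng(seed)
    deg = np.array([g.degree(x) for x in nodes], dtype=float)
    samples = np.empty(draws)
    for i in range(draws):
        idx = rng.choice(len(nodes), size=size, replace=False)
        samples[i] = deg[idx].mean()
    return DegreeNull(samples=samples)


def pub_degree_correlation(
    pub_count: Mapping[str, int], g: InteractionGraph
) -> float:
    """Spearman correlation between publication count and degree.

    Computed over genes present both in the graph and in the publication
    table; average-rank tie handling (scipy).
    """
    common = sorted(g.nodes & set(pub_count))
    if len(common) < 3:
        raise ValueError("need >= 3 genes common to the graph and publication table")
    pubs = [pub_count[x] for x in common]
    degs = [g.degree(x) for x in common]
    rho = spearmanr(pubs, degs).statistic
    return float(rho)
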