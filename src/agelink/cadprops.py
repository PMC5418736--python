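"""Properties of genes shared between aging sets and disease sets.

Covers three characterizations: how many disease sets each shared gene
recurs in, whether shared genes are network hubs, and whether gene groups
differ in molecular evolutionary rate (dN/dS).
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.stats import mannwhitneyu

from .catalog import DiseaseCatalog
from .network import InteractionGraph
from .types import GeneUniverse


@dataclass(frozen=True)
class CadFrequencyProfile:
    """Per-gene count of disease sets (at one level) containing the gene."""

    level: str  # "class" or "individual"
    counts: Mapping[str, int]  # every aging-set gene, 0 when in no disease set
    n_targets: int  # number of disease sets tested at this level

    @property
    def cad_genes(self) -> frozenset[str]:
        return frozenset(g for g, c in self.counts.items() if c > 0)

    def histogram(self) -> dict[int, int]:
        """count-value -> number of shared genes with that count (count >= 1)."""
        return dict(sorted(Counter(c for c in self.counts.values() if c > 0).items()))

    def fraction_at_most(self, k: int = 3) -> float:
        """Fraction of shared genes found in at most ``k`` disease sets."""
        cad = [c for c in self.counts.values() if c > 0]
        if not cad:
            return 0.0
        return sum(1 for c in cad if c <= k) / len(cad)

    def top_genes(self, n: int = 10) -> list[tuple[str, int]]:
        ranked = sorted(self.counts.items(), key=lambda kv: (-kv[1], kv[0]))
        return [(g, c) for g, c in ranked[:n] if c > 0]


def cad_frequency_profile(
    aging_set: Iterable[str], catalog: DiseaseCatalog, level: str = "class"
) -> CadFrequencyProfile:
    """Count, per aging-set gene, the disease sets at ``level`` containing it."""
    aging = frozenset(aging_set)
    if level == "class":
        targets = list(catalog.class_sets().values())
    elif level == "individual":
        targets = [catalog.diseases[d] for d in catalog.individual_diseases()]
    else:
        raise ValueError(f"unknown level {level!r}")
    counts = {g: sum(1 for t in targets if g in t) for g in sorted(aging)}
    return CadFrequencyProfile(level=level, counts=counts, n_targets=len(targets))


@dataclass(frozen=True)
class GroupComparison:
    group_a_values: tuple[float, ...]
    group_b_values: tuple[float, ...]
    median_a: float
    median_b: float
    statistic: float
    p_value: float
    corrected_p: float


def mann_whitney(
    a: Sequence[float], b: Sequence[float], exact_max_n: int = 8
) -> tuple[float, float]:
    """Two-sided Mann-Whitney U: exact for small tie-free samples, else
    normal approximation with tie correction."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    no_ties = len(np.unique(pooled)) == len(pooled)
    method = "exact" if (max(len(a), len(b)) <= exact_max_n and no_ties) else "asymptotic"
    res = mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def bonferroni(p: float, m: int) -> float:
    """Bonferroni-corrected p: min(1, p * m)."""
    if m < 1:
        raise ValueError("m must be >= 1")
    return min(1.0, p * m)


def _compare(a_vals: Sequence[float], b_vals: Sequence[float], m_tests: int) -> GroupComparison:
    stat, p = mann_whitney(a_vals, b_vals)
    return GroupComparison(
        group_a_values=tuple(a_vals),
        group_b_values=tuple(b_vals),
        median_a=float(np.median(a_vals)),
        median_b=float(np.median(b_vals)),
        statistic=stat,
        p_value=p,
        corrected_p=bonferroni(p, m_tests),
    )


def hub_degree_comparison(
    cad: Iterable[str],
    control: Iterable[str],
    g: InteractionGraph,
    m_tests: int = 1,
) -> GroupComparison:
    """Compare node degrees of shared genes vs a control group."""
    cad_in = sorted(frozenset(cad) & g.nodes)
    ctl_in = sorted(frozenset(control) & g.nodes)
    if not cad_in or not ctl_in:
        raise ValueError("a group is entirely absent from the graph")
    return _compare(
        [float(g.degree(x)) for x in cad_in],
        [float(g.degree(x)) for x in ctl_in],
        m_tests,
    )


def dnds_ratio(dn: float, ds: float) -> float | None:
    """dN/dS; None (excluded) when dS is zero."""
    if dn < 0 or ds < 0:
        raise ValueError("dN and dS must be non-negative")
    if ds == 0:
        return None
    return dn / ds


def dnds_ratios(genes: Iterable[str], universe: GeneUniverse) -> list[float]:
    """Defined dN/dS ratios for genes in the universe (undefined excluded)."""
    out = []
    for g in sorted(frozenset(genes) & universe.genes):
        if g in universe.dn and g in universe.ds:
            r = dnds_ratio(universe.dn[g], universe.ds[g])
            if r is not None:
                out.append(r)
    return out


def compare_dnds(
    group: Iterable[str],
    complement: Iterable[str],
    universe: GeneUniverse,
    m_tests: int = 1,
) -> GroupComparison:
    """Two-sided Mann-Whitney on dN/dS ratios of two gene groups."""
    a_vals = dnds_ratios(group, universe)
    b_vals = dnds_ratios(complement, universe)
    if len(a_vals) < 2 or len(b_vals) < 2:
        raise ValueError("need >= 2 genes with defined dN/dS in each group")
    return _compare(a_vals, b_vals, m_tests)


def escore_from_p(p: float) -> float:
    """Enrichment score of a p-value: -log10(p)."""
    if not 0 < p <= 1:
        raise ValueError("p must be in (0, 1]")
    return -math.log10(p)


def p_from_escore(escore: float) -> float:
    """p-value of an enrichment score: 10 ** (-score)."""
    return 10.0 ** (-escore)
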