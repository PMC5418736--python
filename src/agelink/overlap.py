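"""Gene-set overlap engine.

One aging set is tested against one disease set over an explicit background:
the observed intersection is compared with its chance expectation and with
the hypergeometric upper tail. A pair is called significant only when BOTH
(i) the observed intersection exceeds the expected one and (ii) the tail
p-value is below alpha.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .catalog import DiseaseCatalog
from .types import GeneUniverse, LabeledGeneSet

log = logging.getLogger(__name__)

ALPHA_DEFAULT = 0.05


class BackgroundPolicy(str, enum.Enum):
    """How the background gene universe for the test is chosen."""

    GENOME = "genome"
    INTERACTOME = "interactome"
    #: interactome + seed set + disease genes (first-order-expansion runs)
    SEED_UNION = "seed_union"
    #: interactome + seed set only (narrower variant)
    SEED_INTERACTOME = "seed_interactome"


def hypergeometric_tail(k, K, n, N):
    """Upper-tail P(X >= k) for X ~ Hypergeometric(N, K, n).

    ``N`` is the background size, ``K`` the size of one set, ``n`` the size
    of the other, ``k`` the observed intersection. Accepts scalars or
    equally-shaped arrays; evaluated via the survival function in log-space
    internally (scipy), stable for large N.
    """
    k = np.asarray(k, dtype=np.int64)
    K = np.asarray(K, dtype=np.int64)
    n = np.asarray(n, dtype=np.int64)
    N = np.asarray(N, dtype=np.int64)
    if np.any(k < 0) or np.any(k > n) or np.any(n > N):
        raise ValueError("require 0 <= k <= n <= N")
    if np.any(K < 0) or np.any(K > N):
        raise ValueError("require 0 <= K <= N")
    out = hypergeom.sf(k - 1, N, K, n)
    out = np.minimum(out, 1.0)
    if out.ndim == 0:
        return float(out)
    return out


@dataclass(frozen=True)
class OverlapResult:
    """One aging-set x disease-set test over a fixed background."""

    aging_set: str
    disease_set: str
    background_size: int
    n_aging: int
    n_disease: int
    observed: int
    expected: float
    p_value: float
    significant: bool
    cad_genes: frozenset[str]


def overlap_test(
    a: LabeledGeneSet,
    b: Iterable[str],
    background: Iterable[str],
    disease_name: str = "disease",
    alpha: float = ALPHA_DEFAULT,
    two_sided: bool = False,
) -> OverlapResult:
    """Test set ``a`` against gene collection ``b`` over ``background``.

    Both sets are intersected with the background first. Significance uses
    the dual rule (observed strictly above expected AND p < alpha); ties
    observed == expected are not significant. ``two_sided`` replaces the
    upper-tail p with Fisher's two-sided p, the direction rule unchanged.
    """
    bg = frozenset(background)
    if not bg:
        raise ValueError("empty background")
    a_bg = a.members & bg
    b_bg = frozenset(b) & bg
    cad = frozenset(a_bg & b_bg)
    N, nA, nB, k = len(bg), len(a_bg), len(b_bg), len(cad)
    if nA == 0 or nB == 0:
        log.warning(
            "overlap %s x %s: one side empty after background restriction",
            a.name,
            disease_name,
        )
        return OverlapResult(
            aging_set=a.name,
            disease_set=disease_name,
            background_size=N,
            n_aging=nA,
            n_disease=nB,
            observed=0,
            expected=0.0,
            p_value=1.0,
            significant=False,
            cad_genes=frozenset(),
        )
    expected = nA * nB / N
    if two_sided:
        from scipy.stats import fisher_exact

        table = [[k, nA - k], [nB - k, N - nA - nB + k]]
        p = float(fisher_exact(table, alternative="two-sided")[1])
    else:
        p = hypergeometric_tail(k, nA, nB, N)
    significant = (k > expected) and (p < alpha)
    return OverlapResult(
        aging_set=a.name,
        disease_set=disease_name,
        background_size=N,
        n_aging=nA,
        n_disease=nB,
        observed=k,
        expected=expected,
        p_value=p,
        significant=significant,
        cad_genes=cad,
    )


def resolve_background(
    policy: BackgroundPolicy | str,
    universe: GeneUniverse,
    seed: Iterable[str] = (),
    disease_genes: Iterable[str] = (),
) -> frozenset[str]:
    """Materialize a background per policy (seed policies vary per aging set)."""
    policy = BackgroundPolicy(policy)
    if policy is BackgroundPolicy.GENOME:
        return universe.genes
    if policy is BackgroundPolicy.INTERACTOME:
        return universe.interactome
    if policy is BackgroundPolicy.SEED_UNION:
        return (universe.interactome | frozenset(seed) | frozenset(disease_genes)) & universe.genes
    if policy is BackgroundPolicy.SEED_INTERACTOME:
        return (universe.interactome | frozenset(seed)) & universe.genes
    raise ValueError(f"unknown background policy {policy!r}")


def run_overlap_grid(
    aging_sets: Sequence[LabeledGeneSet],
    catalog: DiseaseCatalog,
    universe: GeneUniverse,
    background_policy: BackgroundPolicy | str = BackgroundPolicy.GENOME,
    level: str = "individual",
    alpha: float = ALPHA_DEFAULT,
    two_sided: bool = False,
    include_unions: bool = True,
) -> pd.DataFrame:
    """Run every aging set against every disease set at the chosen level.

    ``level`` is ``"individual"`` (per disease) or ``"class"`` (per disease
    class). Union rows (``all_diseases``, ``all_classes``) are appended when
    ``include_unions``. A Benjamini-Hochberg column is emitted for reference
    but the ``significant`` flag follows the per-test dual rule.
    """
    if level == "individual":
        targets = [(d, catalog.diseases[d]) for d in catalog.individual_diseases()]
    elif level == "class":
        targets = [(c.value, genes) for c, genes in catalog.class_sets().items()]
    else:
        raise ValueError(f"unknown level {level!r}")
    if include_unions:
        targets = targets + [
            ("all_diseases", catalog.all_diseases),
            ("all_classes", catalog.all_classes),
        ]

    all_disease_genes = catalog.all_classes | catalog.all_diseases
    rows = []
    for a in aging_sets:
        bg = resolve_background(
            background_policy, universe, seed=a.members, disease_genes=all_disease_genes
        )
        for name, genes in targets:
            r = overlap_test(a, genes, bg, disease_name=name, alpha=alpha, two_sided=two_sided)
            rows.append(
                {
                    "aging_set": r.aging_set,
                    "disease_set": r.disease_set,
                    "level": level,
                    "background_policy": BackgroundPolicy(background_policy).value,
                    "background_size": r.background_size,
                    "n_aging": r.n_aging,
                    "n_disease": r.n_disease,
                    "observed": r.observed,
                    "expected": r.expected,
                    "p_value": r.p_value,
                    "significant": r.significant,
                    "cad_genes": ";".join(sorted(r.cad_genes)),
                }
            )
    df = pd.DataFrame(rows)
    if not df.empty:
        df["bh_q"] = multipletests(df["p_value"].to_numpy(), method="fdr_bh")[1]
    return df


def summarize_grid(grid: pd.DataFrame, exclude_unions: bool = True) -> pd.DataFrame:
    """Count significant disease sets per aging set (the bar-chart summary)."""
    df = grid
    if exclude_unions:
        df = df[~df["disease_set"].isin(["all_diseases", "all_classes"])]
    out = (
        df.groupby("aging_set", sort=True)["significant"]
        .agg(n_tested="count", n_significant="sum")
        .reset_index()
    )
    out["n_significant"] = out["n_significant"].astype(int)
    return out


def extract_cad_genes(grid: pd.DataFrame) -> dict[tuple[str, str], frozenset[str]]:
    """Recover the per-pair shared-gene sets from a grid table."""
    out: dict[tuple[str, str], frozenset[str]] = {}
    for row in grid.itertuples(index=False):
        genes = frozenset(g for g in str(row.cad_genes).split(";") if g) if row.cad_genes else frozenset()
        out[(row.aging_set, row.disease_set)] = genes
    return out
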