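"""Direction-aware drug ranking from drug-gene interaction tables.

Each interaction type is classified as Anti (decreases target expression or
activity), Pro (increases it) or Neither. A drug acting in the Anti
direction is scored for enrichment of its targets among anti-longevity
genes — knocking those genes down is expected to extend lifespan — and
symmetrically for Pro drugs and pro-longevity genes. Scoring uses the
one-tailed hypergeometric test and drugs are ranked by ascending p-value
with a Bonferroni-significance flag.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .overlap import hypergeometric_tail

log = logging.getLogger(__name__)


class Direction(str, enum.Enum):
    ANTI = "Anti"
    PRO = "Pro"
    NEITHER = "Neither"


#: Default interaction-type -> direction classification (44 common types).
#: User-replaceable via a two-column TSV (interaction_type, direction).
DEFAULT_DIRECTION_MAP: dict[str, Direction] = {
    "inhibitor": Direction.ANTI,
    "antagonist": Direction.ANTI,
    "blocker": Direction.ANTI,
    "channel blocker": Direction.ANTI,
    "gating inhibitor": Direction.ANTI,
    "suppressor": Direction.ANTI,
    "inverse agonist": Direction.ANTI,
    "negative modulator": Direction.ANTI,
    "antisense": Direction.ANTI,
    "antisense oligonucleotide": Direction.ANTI,
    "antibody": Direction.ANTI,
    "cleavage": Direction.ANTI,
    "competitive inhibitor": Direction.ANTI,
    "inhibitory allosteric modulator": Direction.ANTI,
    "inhibitor, competitive": Direction.ANTI,
    "partial antagonist": Direction.ANTI,
    "sirna drug": Direction.ANTI,
    "conjugate inhibitor": Direction.ANTI,
    "downregulator": Direction.ANTI,
    "repressor": Direction.ANTI,
    "agonist": Direction.PRO,
    "partial agonist": Direction.PRO,
    "activator": Direction.PRO,
    "inducer": Direction.PRO,
    "positive allosteric modulator": Direction.PRO,
    "positive modulator": Direction.PRO,
    "stimulator": Direction.PRO,
    "potentiator": Direction.PRO,
    "cofactor": Direction.PRO,
    "chaperone": Direction.PRO,
    "upregulator": Direction.PRO,
    "vaccine": Direction.PRO,
    "inducer, substrate": Direction.PRO,
    "binder": Direction.NEITHER,
    "ligand": Direction.NEITHER,
    "substrate": Direction.NEITHER,
    "modulator": Direction.NEITHER,
    "allosteric modulator": Direction.NEITHER,
    "cross-linking agent": Direction.NEITHER,
    "adduct": Direction.NEITHER,
    "multitarget": Direction.NEITHER,
    "product of": Direction.NEITHER,
    "na": Direction.NEITHER,
    "other/unknown": Direction.NEITHER,
}


def read_direction_map(path: str | Path) -> dict[str, Direction]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"interaction_type", "direction"} <= set(df.columns):
        raise ValueError(f"{path}: expected columns interaction_type, direction")
    return {
        t.strip().lower(): Direction(d.strip().capitalize())
        for t, d in zip(df["interaction_type"], df["direction"])
    }


def write_direction_map(mapping: Mapping[str, Direction], path: str | Path) -> None:
    rows = sorted((t, d.value) for t, d in mapping.items())
    pd.DataFrame(rows, columns=["interaction_type", "direction"]).to_csv(
        path, sep="\t", index=False
    )


def classify_interactions(
    table: pd.DataFrame,
    direction_map: Mapping[str, Direction] | None = None,
) -> pd.DataFrame:
    """Append a ``direction`` column to a (drug, gene, interaction_type) table.

    Unmapped interaction-type strings default to Neither with a warning.
    """
    direction_map = DEFAULT_DIRECTION_MAP if direction_map is None else direction_map
    if not {"drug", "gene", "interaction_type"} <= set(table.columns):
        raise ValueError("expected columns drug, gene, interaction_type")
    out = table.copy()
    types = out["interaction_type"].astype(str).str.strip().str.lower()
    unknown = sorted(set(types) - set(direction_map))
    if unknown:
        log.warning("unmapped interaction types -> Neither: %s", unknown)
    out["direction"] = [
        direction_map.get(t, Direction.NEITHER).value for t in types
    ]
    return out


@dataclass(frozen=True)
class DrugScore:
    drug: str
    direction: Direction
    k: int  # targets in the matching longevity set
    n: int  # scored targets of the drug in the universe
    K: int  # matching longevity-set size within the universe
    N: int  # scoring universe size
    p_value: float
    bonferroni_p: float = 1.0
    significant: bool = False


def score_drug(
    drug: str,
    direction: Direction,
    targets: Iterable[str],
    anti: Iterable[str],
    pro: Iterable[str],
    universe: Iterable[str],
) -> DrugScore:
    """Hypergeometric upper-tail score of one (drug, direction) entry."""
    uni = frozenset(universe)
    if not uni:
        raise ValueError("empty scoring universe")
    matching = frozenset(anti) if direction is Direction.ANTI else frozenset(pro)
    if direction is Direction.NEITHER:
        raise ValueError("Neither-direction entries are not scored")
    K_set = matching & uni
    t = frozenset(targets) & uni
    k = len(t & K_set)
    p = hypergeometric_tail(k, len(K_set), len(t), len(uni)) if t else 1.0
    return DrugScore(
        drug=drug, direction=direction, k=k, n=len(t), K=len(K_set), N=len(uni), p_value=p
    )


def rank_drugs(scores: Iterable[DrugScore], alpha: float = 0.05) -> pd.DataFrame:
    """Order scores by ascending p (ties broken by drug name), apply
    Bonferroni over the number of scored entries, and flag significance."""
    scores = list(scores)
    m = len(scores)
    rows = []
    for s in sorted(scores, key=lambda s: (s.p_value, s.drug, s.direction.value)):
        bp = min(1.0, s.p_value * m)
        rows.append(
            {
                "drug": s.drug,
                "direction": s.direction.value,
                "k": s.k,
                "n": s.n,
                "K": s.K,
                "N": s.N,
                "p_value": s.p_value,
                "bonferroni_p": bp,
                "significant": bp < alpha,
            }
        )
    df = pd.DataFrame(rows)
    if not df.empty:
        df.insert(0, "rank", range(1, len(df) + 1))
    return df


def run_drug_ranking(
    interactions: pd.DataFrame,
    anti: Iterable[str],
    pro: Iterable[str],
    gene_universe: Iterable[str],
    direction_map: Mapping[str, Direction] | None = None,
    scoring_universe: str = "drug_annotated",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Classify, score and rank every drug in an interaction table.

    The scoring universe is the set of genes with at least one interaction
    in the table, intersected with ``gene_universe``; pass
    ``scoring_universe="genome"`` to use the whole gene universe instead.
    A drug with rows in both directions is scored once per direction.
    """
    classified = classify_interactions(interactions, direction_map)
    scored_rows = classified[classified["direction"] != Direction.NEITHER.value]
    gene_universe = frozenset(gene_universe)
    if scoring_universe == "drug_annotated":
        uni = frozenset(classified["gene"]) & gene_universe
    elif scoring_universe == "genome":
        uni = gene_universe
    else:
        raise ValueError(f"unknown scoring_universe {scoring_universe!r}")
    scores = []
    for (drug, direction), grp in scored_rows.groupby(["drug", "direction"], sort=True):
        scores.append(
            score_drug(
                drug,
                Direction(direction),
                set(grp["gene"]),
                anti,
                pro,
                uni,
            )
        )
    log.info("scored %d (drug, direction) entries; Bonferroni m=%d", len(scores), len(scores))
    return rank_drugs(scores, alpha=alpha)
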