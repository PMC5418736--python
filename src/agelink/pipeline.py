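"""End-to-end pipeline: baseline grid, publication-bias-corrected grid,
interactome-restricted grid, first-order and co-expression expansion grids,
shared-gene properties, dN/dS comparisons and drug ranking, all driven by a
single config and fully deterministic."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import cadprops, drugrank, network, overlap, pbc
from .catalog import (
    filter_disease_catalog,
    load_universe,
    read_disease_catalog,
    read_edge_list,
    read_gene_sets,
    read_pair_table,
    restrict_to_universe,
)
from .network import InteractionGraph
from .overlap import BackgroundPolicy
from .types import LongevityClass, MODEL_ORGANISMS, Organism

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Paths and knobs for a full pipeline run."""

    universe: str
    ppi: str
    pubs: str
    aging: str
    diseases: str
    coexpr: str
    drugs: str
    dnds: str
    output_dir: str
    pbc_threshold: int = 10
    alpha: float = 0.05
    background_policy: str = "genome"
    min_disease_genes: int = 20
    genome_n: int | None = None  # Bonferroni denominator; defaults to |universe|

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        return cls(**raw)

    @classmethod
    def from_bundle(cls, bundle_dir: str | Path, output_dir: str | Path, **kwargs) -> "RunConfig":
        b = Path(bundle_dir)
        return cls(
            universe=str(b / "universe.tsv"),
            ppi=str(b / "ppi.tsv"),
            pubs=str(b / "pubs.tsv"),
            aging=str(b / "aging.gmt"),
            diseases=str(b / "diseases.tsv"),
            coexpr=str(b / "coexpr.tsv"),
            drugs=str(b / "drugs.tsv"),
            dnds=str(b / "dnds.tsv"),
            output_dir=str(output_dir),
            **kwargs,
        )


def _write(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def run_all(cfg: RunConfig) -> dict:
    """Run every stage, write per-stage TSVs plus a JSON summary.

    Returns the summary dict. A stage failure raises with the stage name;
    outputs of completed stages are retained.
    """
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"stages": {}, "defaults": {"pbc_threshold": cfg.pbc_threshold, "alpha": cfg.alpha}}

    stage = "load"
    try:
        edges = read_edge_list(cfg.ppi)
        universe = load_universe(cfg.universe, cfg.pubs, cfg.dnds, edges)
        graph = InteractionGraph.from_edges(edges)
        aging_sets = [restrict_to_universe(s, universe) for s in read_gene_sets(cfg.aging)]
        catalog = filter_disease_catalog(
            read_disease_catalog(cfg.diseases), min_genes=cfg.min_disease_genes
        )
        coexpr_pairs = read_pair_table(cfg.coexpr)
        drug_table = pd.read_csv(cfg.drugs, sep="\t", dtype=str)
        genome_n = cfg.genome_n or len(universe.genes)

        stage = "baseline_grid"
        for level in ("class", "individual"):
            grid = overlap.run_overlap_grid(
                aging_sets, catalog, universe, cfg.background_policy, level=level, alpha=cfg.alpha
            )
            _write(grid, out / f"baseline_{level}.tsv")
            _write(overlap.summarize_grid(grid), out / f"baseline_{level}_summary.tsv")
            summary["stages"][f"baseline_{level}"] = _sig_counts(grid)

        stage = "pbc_grid"
        pbc_sets = [
            pbc.apply_publication_filter(s, universe.pub_count, cfg.pbc_threshold)
            for s in aging_sets
        ]
        pbc_sets = [s for s in pbc_sets if s.members]
        for level in ("class", "individual"):
            grid = overlap.run_overlap_grid(
                pbc_sets, catalog, universe, cfg.background_policy, level=level, alpha=cfg.alpha
            )
            _write(grid, out / f"pbc_{level}.tsv")
            _write(overlap.summarize_grid(grid), out / f"pbc_{level}_summary.tsv")
            summary["stages"][f"pbc_{level}"] = _sig_counts(grid)

        stage = "interactome_grid"
        grid = overlap.run_overlap_grid(
            pbc_sets, catalog, universe, BackgroundPolicy.INTERACTOME, level="class", alpha=cfg.alpha
        )
        _write(grid, out / "interactome_class.tsv")
        summary["stages"]["interactome_class"] = _sig_counts(grid)

        stage = "first_order_grid"
        expanded = [
            s.replace_members(network.first_order_expansion(s.members, graph))
            for s in pbc_sets
        ]
        grid = overlap.run_overlap_grid(
            expanded, catalog, universe, BackgroundPolicy.SEED_UNION, level="class", alpha=cfg.alpha
        )
        _write(grid, out / "first_order_class.tsv")
        summary["stages"]["first_order_class"] = _sig_counts(grid)

        stage = "coexpression_grid"
        co_expanded = [
            s.replace_members(
                network.coexpression_expansion(
                    s.members, coexpr_pairs, alpha=cfg.alpha, genome_n=genome_n
                )
                & universe.genes
            )
            for s in pbc_sets
        ]
        grid = overlap.run_overlap_grid(
            co_expanded, catalog, universe, BackgroundPolicy.GENOME, level="class", alpha=cfg.alpha
        )
        _write(grid, out / "coexpression_class.tsv")
        summary["stages"]["coexpression_class"] = _sig_counts(grid)

        stage = "cad_properties"
        human = [s for s in pbc_sets if s.organism is Organism.HUMAN] or pbc_sets[:1]
        freq_rows = []
        for level in ("class", "individual"):
            profile = cadprops.cad_frequency_profile(human[0].members, catalog, level=level)
            for gene, count in sorted(profile.counts.items()):
                if count > 0:
                    freq_rows.append({"gene": gene, "level": level, "count": count})
            summary["stages"][f"cad_frequency_{level}"] = {
                "n_cad": len(profile.cad_genes),
                "fraction_at_most_3": profile.fraction_at_most(3),
            }
        _write(pd.DataFrame(freq_rows, columns=["gene", "level", "count"]), out / "cad_frequency.tsv")
        cad = cadprops.cad_frequency_profile(human[0].members, catalog, "class").cad_genes
        control = (human[0].members | catalog.all_classes) - cad
        comp_rows = []
        if cad & graph.nodes and control & graph.nodes:
            hub = cadprops.hub_degree_comparison(cad, control, graph)
            comp_rows.append(_comp_row("hub_degree", "cad", "non_common", hub))

        stage = "dnds"
        aging_union = frozenset().union(*(s.members for s in aging_sets))
        disease_union = catalog.all_classes | catalog.all_diseases
        comp_rows.append(
            _comp_row(
                "dnds", "disease", "rest",
                cadprops.compare_dnds(disease_union, universe.genes - disease_union, universe),
            )
        )
        comp_rows.append(
            _comp_row(
                "dnds", "aging", "rest",
                cadprops.compare_dnds(aging_union, universe.genes - aging_union, universe),
            )
        )
        organisms = [o for o in MODEL_ORGANISMS]
        for org in organisms:
            anti = [s for s in aging_sets if s.organism is org and s.longevity_class is LongevityClass.ANTI]
            pro = [s for s in aging_sets if s.organism is org and s.longevity_class is LongevityClass.PRO]
            if anti and pro and anti[0].members and pro[0].members:
                try:
                    comp = cadprops.compare_dnds(
                        anti[0].members, pro[0].members, universe, m_tests=len(organisms)
                    )
                except ValueError:
                    continue
                comp_rows.append(_comp_row("dnds", f"{org.value}_anti", f"{org.value}_pro", comp))
        _write(
            pd.DataFrame(
                comp_rows,
                columns=["comparison", "group_a", "group_b", "median_a", "median_b",
                         "statistic", "p_value", "corrected_p"],
            ),
            out / "group_comparisons.tsv",
        )

        stage = "drugs"
        anti_all = frozenset().union(
            *(s.members for s in aging_sets if s.longevity_class is LongevityClass.ANTI),
            frozenset(),
        )
        pro_all = frozenset().union(
            *(s.members for s in aging_sets if s.longevity_class is LongevityClass.PRO),
            frozenset(),
        )
        ranking = drugrank.run_drug_ranking(
            drug_table, anti_all, pro_all, universe.genes, alpha=cfg.alpha
        )
        _write(ranking, out / "drug_ranking.tsv")
        summary["stages"]["drugs"] = {
            "n_scored": int(len(ranking)),
            "n_significant": int(ranking["significant"].sum()) if not ranking.empty else 0,
        }
    except Exception as exc:  # annotate with the failing stage, keep partials
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
    return summary


def _sig_counts(grid: pd.DataFrame) -> dict:
    per_set = overlap.summarize_grid(grid)
    return {
        "n_tests": int(len(grid)),
        "n_significant": int(grid["significant"].sum()),
        "per_set": {
            r.aging_set: int(r.n_significant) for r in per_set.itertuples(index=False)
        },
    }


def _comp_row(kind: str, a: str, b: str, comp: cadprops.GroupComparison) -> dict:
    return {
        "comparison": kind,
        "group_a": a,
        "group_b": b,
        "median_a": comp.median_a,
        "median_b": comp.median_b,
        "statistic": comp.statistic,
        "p_value": comp.p_value,
        "corrected_p": comp.corrected_p,
    }
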