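"""Deterministic synthetic benchmark generator.

Emulates the structure of the real inputs — a gene universe with a
heavy-tailed interaction network, publication counts rank-correlated with
degree, aging and disease gene sets with overlap planted at a controlled
odds ratio, sparse small-p co-expression pairs, drug-target tables with
direction-matched drugs, and dN/dS values with a location shift for disease
genes — so that every pipeline stage can be exercised and scored offline.

A single global seed drives independent per-component generators (each
component derives its own child seed from a stable name hash), so adding a
component never perturbs the others.
"""

from __future__ import annotations

import dataclasses
import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd
import yaml

from .catalog import DiseaseCatalog, write_disease_catalog, write_gene_sets
from .network import InteractionGraph
from .types import (
    DiseaseClass,
    GeneUniverse,
    LabeledGeneSet,
    LongevityClass,
    MODEL_ORGANISMS,
    Organism,
)


def component_rng(seed: int, name: str) -> np.random.Generator:
    """Independent generator for one named component of the benchmark."""
    return np.random.default_rng(np.random.SeedSequence([seed, zlib.crc32(name.encode())]))


@dataclass(frozen=True)
class AgingSetSpec:
    name: str
    organism: str
    longevity_class: str
    size: int


@dataclass(frozen=True)
class DiseaseSpec:
    name: str
    disease_class: str
    size: int
    planted_or: float = 1.0  # odds ratio of containing an aging gene


@dataclass(frozen=True)
class DrugSpec:
    name: str
    direction: str  # Anti | Pro
    n_targets: int
    frac_matched: float = 0.0  # fraction of targets drawn from the matching set


@dataclass(frozen=True)
class SimConfig:
    seed: int = 0
    n_genes: int = 5000
    ppi_attachment: int = 2
    ppi_fraction: float = 0.74  # fraction of the universe placed in the network
    pubs_scale: float = 4.0  # publication mean = baseline + scale * degree^exponent
    pubs_degree_exponent: float = 1.2
    pubs_dispersion: float = 4.0  # negative-binomial dispersion (smaller = noisier)
    pubs_baseline: float = 1.0
    aging_sets: tuple[AgingSetSpec, ...] = ()
    disease_sets: tuple[DiseaseSpec, ...] = ()
    coexpr_density: float = 2.0  # background pairs per gene
    coexpr_planted_pairs: int = 200
    drugs: tuple[DrugSpec, ...] = ()
    dnds_lognormal_mu: float = -2.4  # median ratio exp(mu) ~ 0.09
    dnds_lognormal_sigma: float = 0.6
    disease_shift: float = 0.5  # multiplicative dN/dS shift for disease genes

    def validate(self) -> None:
        if self.n_genes <= self.ppi_attachment:
            raise ValueError("n_genes must exceed ppi_attachment")
        if self.ppi_attachment < 1:
            raise ValueError("ppi_attachment must be >= 1")
        for s in self.aging_sets:
            if s.size > self.n_genes:
                raise ValueError(f"aging set {s.name} larger than the universe")
        for d in self.disease_sets:
            if d.size > self.n_genes:
                raise ValueError(f"disease set {d.name} larger than the universe")
            if d.planted_or < 1:
                raise ValueError(f"disease set {d.name}: planted_or must be >= 1")
        if not 0 < self.ppi_fraction <= 1:
            raise ValueError("ppi_fraction must be in (0, 1]")


def default_config(seed: int = 0, n_genes: int = 5000) -> SimConfig:
    """Benchmark mirroring the real inputs at roughly quarter scale."""
    scale = n_genes / 20183
    aging = (
        AgingSetSpec("human_candidates", "human", "human_candidate", max(10, round(298 * scale))),
        AgingSetSpec("mouse_anti", "mouse", "anti", max(5, round(23 * scale))),
        AgingSetSpec("mouse_pro", "mouse", "pro", max(5, round(59 * scale))),
        AgingSetSpec("fly_anti", "fly", "anti", max(5, round(48 * scale))),
        AgingSetSpec("fly_pro", "fly", "pro", max(5, round(87 * scale))),
        AgingSetSpec("worm_anti", "worm", "anti", max(5, round(381 * scale))),
        AgingSetSpec("worm_pro", "worm", "pro", max(5, round(290 * scale))),
        AgingSetSpec("yeast_anti", "yeast", "anti", max(4, round(41 * scale))),
        AgingSetSpec("yeast_pro", "yeast", "pro", max(4, round(13 * scale))),
    )
    classes = [
        ("neoplasms", 4.0),
        ("nutritional_metabolic", 3.0),
        ("nervous", 3.0),
        ("cardiovascular", 2.5),
        ("musculoskeletal", 2.0),
        ("immune", 1.5),
        ("respiratory", 1.0),  # negative control: nothing planted
        ("eye", 1.5),
    ]
    diseases = []
    i = 0
    for cls, or_ in classes:
        for j in range(3):
            size = max(20, round((30 + 15 * j) * scale * 4))
            diseases.append(DiseaseSpec(f"{cls}_{j}", cls, size, or_ if j < 2 else 1.0))
            i += 1
    drugs = []
    for d in range(12):
        direction = "Anti" if d % 2 == 0 else "Pro"
        frac = 0.6 if d < 2 else 0.0  # two planted direction-matched drugs
        drugs.append(DrugSpec(f"drug_{d:02d}", direction, 10, frac))
    return SimConfig(
        seed=seed,
        n_genes=n_genes,
        aging_sets=aging,
        disease_sets=tuple(diseases),
        drugs=tuple(drugs),
    )


def config_from_yaml(path: str | Path) -> SimConfig:
    raw = yaml.safe_load(Path(path).read_text())
    raw["aging_sets"] = tuple(AgingSetSpec(**s) for s in raw.get("aging_sets", []))
    raw["disease_sets"] = tuple(DiseaseSpec(**s) for s in raw.get("disease_sets", []))
    raw["drugs"] = tuple(DrugSpec(**s) for s in raw.get("drugs", []))
    return SimConfig(**raw)


def config_to_yaml(cfg: SimConfig, path: str | Path) -> None:
    d = dataclasses.asdict(cfg)
    Path(path).write_text(yaml.safe_dump(d, sort_keys=True))


# ---------------------------------------------------------------------------
# Component generators
# ---------------------------------------------------------------------------

def gene_names(n: int) -> list[str]:
    return [f"G{i:05d}" for i in range(n)]


def generate_ppi(n: int, attachment: int, seed: int) -> InteractionGraph:
    """Preferential-attachment (heavy-tailed) interaction graph on n genes."""
    if attachment < 1:
        raise ValueError("attachment must be >= 1")
    if n <= attachment:
        raise ValueError("n must exceed attachment")
    g = nx.barabasi_albert_graph(n, attachment, seed=seed)
    names = gene_names(n)
    g = nx.relabel_nodes(g, {i: names[i] for i in range(n)})
    return InteractionGraph(graph=g)


def plant_overlap(
    universe: Sequence[str],
    base: Iterable[str],
    size: int,
    or_: float,
    rng: np.random.Generator,
) -> frozenset[str]:
    """Weighted sample without replacement: membership odds for genes in
    ``base`` are ``or_`` times those outside (Efraimidis–Spirakis keys)."""
    universe = sorted(universe)
    if size > len(universe):
        raise ValueError("size exceeds universe")
    base = frozenset(base)
    w = np.array([or_ if g in base else 1.0 for g in universe])
    keys = rng.random(len(universe)) ** (1.0 / w)
    idx = np.argsort(keys)[::-1][:size]
    return frozenset(universe[i] for i in idx)


@dataclass
class Benchmark:
    """In-memory benchmark bundle plus the planted-truth manifest."""

    config: SimConfig
    universe: GeneUniverse
    graph: InteractionGraph
    aging_sets: list[LabeledGeneSet]
    catalog: DiseaseCatalog
    coexpr: pd.DataFrame
    drugs: pd.DataFrame
    manifest: dict = field(default_factory=dict)

    def aging_set(self, name: str) -> LabeledGeneSet:
        for s in self.aging_sets:
            if s.name == name:
                return s
        raise KeyError(name)

    def write(self, out_dir: str | Path) -> None:
        """Write the full bundle as plain-text files (deterministic bytes)."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        genes = sorted(self.universe.genes)
        pd.DataFrame({"gene": genes}).to_csv(out / "universe.tsv", sep="\t", index=False)
        pd.DataFrame(
            {"gene": genes, "publications": [self.universe.publications(g) for g in genes]}
        ).to_csv(out / "pubs.tsv", sep="\t", index=False)
        pd.DataFrame(
            {
                "gene": genes,
                "dn": [self.universe.dn.get(g, 0.0) for g in genes],
                "ds": [self.universe.ds.get(g, 0.0) for g in genes],
            }
        ).to_csv(out / "dnds.tsv", sep="\t", index=False, float_format="%.8g")
        self.graph.to_tsv(out / "ppi.tsv")
        write_gene_sets(self.aging_sets, out / "aging.gmt")
        write_disease_catalog(self.catalog, out / "diseases.tsv")
        self.coexpr.sort_values(["gene_a", "gene_b"]).to_csv(
            out / "coexpr.tsv", sep="\t", index=False, float_format="%.8g"
        )
        self.drugs.sort_values(["drug", "gene"]).to_csv(
            out / "drugs.tsv", sep="\t", index=False
        )
        (out / "manifest.json").write_text(json.dumps(self.manifest, indent=2, sort_keys=True) + "\n")


def generate_benchmark(cfg: SimConfig) -> Benchmark:
    """Generate the full synthetic bundle from a validated config."""
    cfg.validate()
    genes = gene_names(cfg.n_genes)
    seed = cfg.seed

    # Interaction network over a subset of the universe (the "interactome").
    n_net = max(cfg.ppi_attachment + 1, int(round(cfg.ppi_fraction * cfg.n_genes)))
    net_rng = component_rng(seed, "ppi")
    member_idx = np.sort(net_rng.choice(cfg.n_genes, size=n_net, replace=False))
    graph_full = generate_ppi(n_net, cfg.ppi_attachment, int(net_rng.integers(2**31)))
    relabel = {f"G{i:05d}": genes[member_idx[i]] for i in range(n_net)}
    graph = InteractionGraph(graph=nx.relabel_nodes(graph_full.graph, relabel))

    # Publication counts: negative binomial, mean scaling with degree.
    pub_rng = component_rng(seed, "pubs")
    deg = np.array([graph.degree(g) for g in genes], dtype=float)
    mu = cfg.pubs_baseline + cfg.pubs_scale * deg**cfg.pubs_degree_exponent
    r = cfg.pubs_dispersion
    pubs = pub_rng.negative_binomial(r, r / (r + mu))
    pub_count = {g: int(c) for g, c in zip(genes, pubs)}

    # Aging sets: uniform draws; anti/pro disjoint within an organism.
    aging_rng = component_rng(seed, "aging")
    aging_sets: list[LabeledGeneSet] = []
    taken_by_org: dict[str, set[str]] = {}
    for spec in cfg.aging_sets:
        pool = sorted(set(genes) - taken_by_org.get(spec.organism, set()))
        members = frozenset(
            np.array(pool)[aging_rng.choice(len(pool), size=spec.size, replace=False)]
        )
        taken_by_org.setdefault(spec.organism, set()).update(members)
        aging_sets.append(
            LabeledGeneSet(
                name=spec.name,
                members=members,
                organism=Organism(spec.organism),
                longevity_class=LongevityClass(spec.longevity_class),
            )
        )
    pooled: dict[LongevityClass, set[str]] = {LongevityClass.ANTI: set(), LongevityClass.PRO: set()}
    for s in aging_sets:
        if s.organism in MODEL_ORGANISMS and s.longevity_class in pooled:
            pooled[s.longevity_class] |= s.members
    for cls in (LongevityClass.ANTI, LongevityClass.PRO):
        if pooled[cls]:
            aging_sets.append(
                LabeledGeneSet(
                    name=f"all_orthologs_{cls.value}",
                    members=frozenset(pooled[cls]),
                    organism=Organism.ALL_ORTHOLOGS,
                    longevity_class=cls,
                )
            )
    aging_union = frozenset().union(*(s.members for s in aging_sets)) if aging_sets else frozenset()

    # Disease sets with overlap planted against the aging union.
    dis_rng = component_rng(seed, "diseases")
    diseases: dict[str, frozenset[str]] = {}
    disease_class: dict[str, DiseaseClass] = {}
    for spec in cfg.disease_sets:
        diseases[spec.name] = plant_overlap(
            genes, aging_union, spec.size, spec.planted_or, dis_rng
        )
        disease_class[spec.name] = DiseaseClass(spec.disease_class)
    catalog = DiseaseCatalog(diseases=diseases, disease_class=disease_class)

    # Co-expression pairs: uniform background p, planted small-p pairs.
    co_rng = component_rng(seed, "coexpr")
    n_bg = int(cfg.coexpr_density * cfg.n_genes)
    a_idx = co_rng.integers(0, cfg.n_genes, size=n_bg)
    b_idx = co_rng.integers(0, cfg.n_genes, size=n_bg)
    keep = a_idx != b_idx
    rows = {
        "gene_a": [genes[i] for i in a_idx[keep]],
        "gene_b": [genes[i] for i in b_idx[keep]],
        "p": co_rng.uniform(size=int(keep.sum())),
    }
    coexpr = pd.DataFrame(rows)
    threshold = 0.05 / cfg.n_genes
    planted_partners: dict[str, list[str]] = {}
    if cfg.coexpr_planted_pairs and aging_union:
        seeds = sorted(aging_union)
        outside = sorted(set(genes) - aging_union)
        sel_seed = co_rng.choice(len(seeds), size=cfg.coexpr_planted_pairs, replace=True)
        sel_out = co_rng.choice(len(outside), size=cfg.coexpr_planted_pairs, replace=True)
        planted = pd.DataFrame(
            {
                "gene_a": [seeds[i] for i in sel_seed],
                "gene_b": [outside[i] for i in sel_out],
                "p": co_rng.uniform(0, threshold / 2, size=cfg.coexpr_planted_pairs),
            }
        )
        coexpr = pd.concat([coexpr, planted], ignore_index=True)
        for s, o in zip(planted["gene_a"], planted["gene_b"]):
            planted_partners.setdefault(s, []).append(o)
    coexpr = coexpr.drop_duplicates(["gene_a", "gene_b"]).reset_index(drop=True)

    # Drug-gene interaction table.
    drug_rng = component_rng(seed, "drugs")
    anti_pool = sorted(pooled[LongevityClass.ANTI])
    pro_pool = sorted(pooled[LongevityClass.PRO])
    drug_rows = []
    for spec in cfg.drugs:
        matching = anti_pool if spec.direction == "Anti" else pro_pool
        n_match = min(int(round(spec.frac_matched * spec.n_targets)), len(matching))
        targets: set[str] = set()
        if n_match:
            targets |= {
                matching[i]
                for i in drug_rng.choice(len(matching), size=n_match, replace=False)
            }
        pool = sorted(set(genes) - targets)
        need = spec.n_targets - len(targets)
        targets |= {pool[i] for i in drug_rng.choice(len(pool), size=need, replace=False)}
        itype = "inhibitor" if spec.direction == "Anti" else "agonist"
        for t in sorted(targets):
            drug_rows.append({"drug": spec.name, "gene": t, "interaction_type": itype})
    drugs = pd.DataFrame(drug_rows, columns=["drug", "gene", "interaction_type"])

    # dN/dS with a multiplicative shift for disease genes.
    ev_rng = component_rng(seed, "dnds")
    disease_union = catalog.all_classes | catalog.all_diseases
    ratio = ev_rng.lognormal(cfg.dnds_lognormal_mu, cfg.dnds_lognormal_sigma, size=cfg.n_genes)
    ds_vals = ev_rng.lognormal(0.0, 0.3, size=cfg.n_genes)
    dn, ds = {}, {}
    for i, g in enumerate(genes):
        r_i = ratio[i] * (1.0 + cfg.disease_shift) if g in disease_union else ratio[i]
        ds[g] = float(ds_vals[i])
        dn[g] = float(r_i * ds_vals[i])

    universe = GeneUniverse(
        genes=frozenset(genes),
        pub_count=pub_count,
        dn=dn,
        ds=ds,
        in_interactome={g: True for g in graph.nodes},
    )

    manifest = {
        "seed": seed,
        "n_genes": cfg.n_genes,
        "coexpr_threshold": threshold,
        "disease_shift": cfg.disease_shift,
        "aging_sets": {s.name: len(s.members) for s in aging_sets},
        "diseases": {
            spec.name: {
                "class": spec.disease_class,
                "size": spec.size,
                "planted_or": spec.planted_or,
            }
            for spec in cfg.disease_sets
        },
        "drugs": {
            spec.name: {
                "direction": spec.direction,
                "n_targets": spec.n_targets,
                "frac_matched": spec.frac_matched,
            }
            for spec in cfg.drugs
        },
        "coexpr_planted_partners": {k: sorted(v) for k, v in sorted(planted_partners.items())},
    }
    return Benchmark(
        config=cfg,
        universe=universe,
        graph=graph,
        aging_sets=aging_sets,
        catalog=catalog,
        coexpr=coexpr,
        drugs=drugs,
        manifest=manifest,
    )
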