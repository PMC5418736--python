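"""Input parsing and gene-set / disease-catalog assembly.

File formats (all plain text, tab-separated):

* gene sets: GMT (``name<TAB>description<TAB>gene...``)
* disease catalog: TSV with columns ``disease_id``, ``class``, ``gene``
* interaction edges: TSV ``gene_a``, ``gene_b`` and optional
  ``interaction_type``
* gene-pair tables (co-expression): TSV ``gene_a``, ``gene_b``, ``p``
* annotation tables: TSV ``gene`` plus one or more value columns
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .types import (
    AGE_RELATED_CLASSES,
    CLASS_LEVEL_ONLY,
    MODEL_ORGANISMS,
    NEGATIVE_CONTROL_CLASSES,
    DiseaseClass,
    GeneUniverse,
    LabeledGeneSet,
    LongevityClass,
    Organism,
    normalize_gene,
)

log = logging.getLogger(__name__)

#: Interaction-type strings kept by default when the edge table carries types.
DEFAULT_EDGE_TYPES = frozenset({"physical association", "direct interaction"})

_ORGANISM_TOKENS = {
    "human": Organism.HUMAN,
    "mouse": Organism.MOUSE,
    "fly": Organism.FLY,
    "worm": Organism.WORM,
    "yeast": Organism.YEAST,
    "all": Organism.ALL_ORTHOLOGS,
    "all_orthologs": Organism.ALL_ORTHOLOGS,
    "orthologs": Organism.ALL_ORTHOLOGS,
}

_CLASS_TOKENS = {
    "pro": LongevityClass.PRO,
    "anti": LongevityClass.ANTI,
    "candidate": LongevityClass.HUMAN_CANDIDATE,
    "candidates": LongevityClass.HUMAN_CANDIDATE,
}


class ParseError(ValueError):
    """Malformed input file."""


class ValidationError(ValueError):
    """Input parses but violates a content contract."""


# ---------------------------------------------------------------------------
# Gene sets (GMT)
# ---------------------------------------------------------------------------

def parse_set_name(name: str) -> tuple[Organism, LongevityClass]:
    """Infer (organism, longevity class) labels from a set name.

    Recognizes underscore-separated tokens such as ``worm_pro`` or
    ``all_orthologs_anti``; unknown tokens leave the label at its default.
    """
    organism = Organism.HUMAN
    cls = LongevityClass.UNSET
    tokens = [t.lower() for t in name.split("_")]
    joined = name.lower()
    if joined.startswith("all_orthologs") or joined.startswith("orthologs"):
        organism = Organism.ALL_ORTHOLOGS
    else:
        for t in tokens:
            if t in _ORGANISM_TOKENS:
                organism = _ORGANISM_TOKENS[t]
                break
    for t in tokens:
        if t in _CLASS_TOKENS:
            cls = _CLASS_TOKENS[t]
            break
    return organism, cls


def read_gene_sets(
    path: str | Path,
    label_policy: Mapping[str, tuple[Organism, LongevityClass]] | None = None,
) -> list[LabeledGeneSet]:
    """Read a GMT file into labeled gene sets.

    ``label_policy`` maps set names to explicit (organism, class) labels;
    names not covered fall back to :func:`parse_set_name`. Member symbols
    are upper-cased and deduplicated.
    """
    path = Path(path)
    sets: list[LabeledGeneSet] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"{path}:{lineno}: expected >= 3 tab-separated fields "
                    f"(name, description, genes...), got {len(fields)}"
                )
            name = fields[0]
            members = frozenset(
                normalize_gene(g) for g in fields[2:] if g.strip()
            )
            if not members:
                raise ValidationError(f"{path}:{lineno}: set {name!r} has no members")
            if label_policy and name in label_policy:
                organism, cls = label_policy[name]
            else:
                organism, cls = parse_set_name(name)
            sets.append(
                LabeledGeneSet(
                    name=name, members=members, organism=organism, longevity_class=cls
                )
            )
    return sets


def write_gene_sets(sets: Iterable[LabeledGeneSet], path: str | Path) -> None:
    """Write gene sets as GMT, members sorted for reproducible output."""
    with Path(path).open("w") as fh:
        for s in sets:
            desc = f"{s.organism.value}|{s.longevity_class.value}"
            fh.write("\t".join([s.name, desc, *sorted(s.members)]) + "\n")


def assemble_longevity_sets(
    raw: Iterable[tuple[str, str, str]],
) -> list[LabeledGeneSet]:
    """Build per-organism anti/pro sets from (gene, organism, annotation) rows.

    Genes annotated with both classes in the same organism are excluded from
    both sets; genes whose annotation is neither ``pro`` nor ``anti`` are
    excluded. Pooled ``all_orthologs`` anti/pro sets union the four model
    organisms.
    """
    per_org: dict[Organism, dict[LongevityClass, set[str]]] = {}
    for gene, org_token, annotation in raw:
        org_token = org_token.strip().lower()
        if org_token not in _ORGANISM_TOKENS:
            raise ValidationError(f"unknown organism token {org_token!r}")
        organism = _ORGANISM_TOKENS[org_token]
        gene = normalize_gene(gene)
        per_org.setdefault(organism, {LongevityClass.ANTI: set(), LongevityClass.PRO: set()})
        cls = _CLASS_TOKENS.get(annotation.strip().lower())
        if cls not in (LongevityClass.PRO, LongevityClass.ANTI):
            continue  # unclassified genes are excluded
        per_org[organism][cls].add(gene)

    out: list[LabeledGeneSet] = []
    pooled: dict[LongevityClass, set[str]] = {
        LongevityClass.ANTI: set(),
        LongevityClass.PRO: set(),
    }
    for organism in sorted(per_org, key=lambda o: o.value):
        anti = per_org[organism][LongevityClass.ANTI]
        pro = per_org[organism][LongevityClass.PRO]
        both = anti & pro
        if both:
            log.info(
                "%s: excluding %d genes annotated both anti and pro", organism.value, len(both)
            )
        anti, pro = anti - both, pro - both
        for cls, members in ((LongevityClass.ANTI, anti), (LongevityClass.PRO, pro)):
            out.append(
                LabeledGeneSet(
                    name=f"{organism.value}_{cls.value}",
                    members=frozenset(members),
                    organism=organism,
                    longevity_class=cls,
                )
            )
            if organism in MODEL_ORGANISMS:
                pooled[cls] |= members
    for cls in (LongevityClass.ANTI, LongevityClass.PRO):
        out.append(
            LabeledGeneSet(
                name=f"all_orthologs_{cls.value}",
                members=frozenset(pooled[cls]),
                organism=Organism.ALL_ORTHOLOGS,
                longevity_class=cls,
            )
        )
    return out


# ---------------------------------------------------------------------------
# Disease catalog
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DiseaseCatalog:
    """Disease -> gene-set mapping with class labels and inclusion flags.

    ``included_class`` marks diseases contributing to class-level unions;
    ``included_individual`` marks diseases tested one by one (class-level-only
    classes such as eye diseases stay in the former but not the latter).
    """

    diseases: Mapping[str, frozenset[str]]
    disease_class: Mapping[str, DiseaseClass]
    included_individual: Mapping[str, bool] = field(default_factory=dict)
    included_class: Mapping[str, bool] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = set(self.diseases) ^ set(self.disease_class)
        if missing:
            raise ValidationError(f"diseases without class label (or vice versa): {sorted(missing)[:5]}")
        if not self.included_individual:
            object.__setattr__(
                self, "included_individual", {d: True for d in self.diseases}
            )
        if not self.included_class:
            object.__setattr__(self, "included_class", {d: True for d in self.diseases})

    def individual_diseases(self) -> list[str]:
        return sorted(d for d in self.diseases if self.included_individual[d])

    def class_sets(self) -> dict[DiseaseClass, frozenset[str]]:
        """Per-class gene unions over class-included diseases."""
        out: dict[DiseaseClass, set[str]] = {}
        for d, genes in self.diseases.items():
            if not self.included_class[d]:
                continue
            out.setdefault(self.disease_class[d], set()).update(genes)
        return {c: frozenset(g) for c, g in sorted(out.items(), key=lambda kv: kv[0].value)}

    @property
    def all_diseases(self) -> frozenset[str]:
        """Union of genes over individually analysed diseases."""
        out: set[str] = set()
        for d in self.individual_diseases():
            out |= self.diseases[d]
        return frozenset(out)

    @property
    def all_classes(self) -> frozenset[str]:
        """Union of genes over class-level sets."""
        out: set[str] = set()
        for genes in self.class_sets().values():
            out |= genes
        return frozenset(out)

    def is_negative_control(self, disease_id: str) -> bool:
        return self.disease_class[disease_id] in NEGATIVE_CONTROL_CLASSES


def read_disease_catalog(path: str | Path) -> DiseaseCatalog:
    """Read a TSV with columns disease_id, class, gene."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"disease_id", "class", "gene"}
    if not required <= set(df.columns):
        raise ParseError(f"{path}: expected columns {sorted(required)}, got {list(df.columns)}")
    diseases: dict[str, set[str]] = {}
    classes: dict[str, DiseaseClass] = {}
    for did, cls_token, gene in zip(df["disease_id"], df["class"], df["gene"]):
        did = str(did)
        cls = DiseaseClass(cls_token)
        if did in classes and classes[did] is not cls:
            raise ValidationError(f"{path}: disease {did!r} listed with two classes")
        classes[did] = cls
        diseases.setdefault(did, set()).add(normalize_gene(gene))
    return DiseaseCatalog(
        diseases={d: frozenset(g) for d, g in diseases.items()},
        disease_class=classes,
    )


def write_disease_catalog(catalog: DiseaseCatalog, path: str | Path) -> None:
    rows = [
        (d, catalog.disease_class[d].value, g)
        for d in sorted(catalog.diseases)
        for g in sorted(catalog.diseases[d])
    ]
    pd.DataFrame(rows, columns=["disease_id", "class", "gene"]).to_csv(
        path, sep="\t", index=False
    )


def filter_disease_catalog(
    catalog: DiseaseCatalog,
    min_genes: int = 20,
    allowed_classes: frozenset[DiseaseClass] = AGE_RELATED_CLASSES,
    class_level_only: frozenset[DiseaseClass] = CLASS_LEVEL_ONLY,
) -> DiseaseCatalog:
    """Apply the inclusion rules for age-related disease analysis.

    Diseases with fewer than ``min_genes`` genes or from a class outside
    ``allowed_classes`` are excluded entirely. Diseases from
    ``class_level_only`` classes are kept at class level but excluded from
    per-disease testing.
    """
    if min_genes < 1:
        raise ValueError("min_genes must be >= 1")
    included_class = {
        d: (len(genes) >= min_genes and catalog.disease_class[d] in allowed_classes)
        for d, genes in catalog.diseases.items()
    }
    included_individual = {
        d: included_class[d] and catalog.disease_class[d] not in class_level_only
        for d in catalog.diseases
    }
    if not any(included_individual.values()):
        log.warning("disease filter left no individually analysable disease")
    return DiseaseCatalog(
        diseases=dict(catalog.diseases),
        disease_class=dict(catalog.disease_class),
        included_individual=included_individual,
        included_class=included_class,
    )


# ---------------------------------------------------------------------------
# Tables: edges, pairs, annotations
# ---------------------------------------------------------------------------

def read_edge_list(
    path: str | Path,
    allowed_types: frozenset[str] | None = DEFAULT_EDGE_TYPES,
) -> list[tuple[str, str]]:
    """Read a TSV edge list into deduplicated, self-loop-free unordered pairs.

    If the table carries an ``interaction_type`` column, rows whose type is
    not in ``allowed_types`` are dropped (pass ``None`` to keep all rows).
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"gene_a", "gene_b"} <= set(df.columns):
        raise ParseError(f"{path}: expected columns gene_a, gene_b")
    if "interaction_type" in df.columns and allowed_types is not None:
        df = df[df["interaction_type"].isin(allowed_types)]
    edges: set[tuple[str, str]] = set()
    for a, b in zip(df["gene_a"], df["gene_b"]):
        a, b = normalize_gene(a), normalize_gene(b)
        if not a or not b:
            raise ParseError(f"{path}: empty gene field in edge row")
        if a == b:
            continue
        edges.add((min(a, b), max(a, b)))
    return sorted(edges)


def write_edge_list(edges: Iterable[tuple[str, str]], path: str | Path) -> None:
    rows = sorted({(min(a, b), max(a, b)) for a, b in edges})
    pd.DataFrame(rows, columns=["gene_a", "gene_b"]).to_csv(path, sep="\t", index=False)


def read_pair_table(path: str | Path) -> pd.DataFrame:
    """Read a gene-pair p-value table (columns gene_a, gene_b, p)."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_a": str, "gene_b": str, "p": float})
    if not {"gene_a", "gene_b", "p"} <= set(df.columns):
        raise ParseError(f"{path}: expected columns gene_a, gene_b, p")
    df["gene_a"] = df["gene_a"].map(normalize_gene)
    df["gene_b"] = df["gene_b"].map(normalize_gene)
    if ((df["p"] < 0) | (df["p"] > 1)).any():
        raise ValidationError(f"{path}: p values outside [0, 1]")
    return df


def read_annotation_table(
    path: str | Path, value_columns: Sequence[str] = ("value",)
) -> dict[str, float] | dict[str, tuple[float, ...]]:
    """Read a per-gene annotation TSV keyed uniquely by gene.

    With one value column returns gene -> value; with several, gene -> tuple.
    Duplicate rows with conflicting values raise :class:`ValidationError`.
    """
    df = pd.read_csv(path, sep="\t", dtype={"gene": str})
    needed = {"gene", *value_columns}
    if not needed <= set(df.columns):
        raise ParseError(f"{path}: expected columns {sorted(needed)}")
    df["gene"] = df["gene"].map(normalize_gene)
    dup = df[df.duplicated("gene", keep=False)]
    if not dup.empty:
        conflicting = [
            g for g, grp in dup.groupby("gene")
            if grp[list(value_columns)].drop_duplicates().shape[0] > 1
        ]
        if conflicting:
            raise ValidationError(
                f"{path}: conflicting duplicate annotations for {sorted(conflicting)}"
            )
        df = df.drop_duplicates("gene")
    if len(value_columns) == 1:
        col = value_columns[0]
        return dict(zip(df["gene"], df[col].astype(float)))
    return {
        g: tuple(float(v) for v in vals)
        for g, *vals in df[["gene", *value_columns]].itertuples(index=False)
    }


def restrict_to_universe(
    s: LabeledGeneSet, universe: GeneUniverse
) -> LabeledGeneSet:
    """Drop set members absent from the universe (with a warning, not an error)."""
    outside = s.members - universe.genes
    if outside:
        warnings.warn(
            f"set {s.name!r}: dropping {len(outside)} genes absent from the universe",
            stacklevel=2,
        )
    return s.replace_members(s.members & universe.genes)


def load_universe(
    universe_path: str | Path,
    pubs_path: str | Path | None = None,
    dnds_path: str | Path | None = None,
    edges: Iterable[tuple[str, str]] | None = None,
) -> GeneUniverse:
    """Assemble a :class:`GeneUniverse` from the standard annotation files.

    ``universe_path`` is a one-column TSV of gene symbols; publication counts
    and dN/dS come from optional annotation tables; interactome membership is
    derived from the edge list.
    """
    df = pd.read_csv(universe_path, sep="\t", dtype=str)
    if "gene" not in df.columns:
        raise ParseError(f"{universe_path}: expected a 'gene' column")
    genes = frozenset(normalize_gene(g) for g in df["gene"])
    pub_count: dict[str, int] = {}
    if pubs_path is not None:
        raw = read_annotation_table(pubs_path, ("publications",))
        pub_count = {g: int(v) for g, v in raw.items() if g in genes}
    dn: dict[str, float] = {}
    ds: dict[str, float] = {}
    if dnds_path is not None:
        raw = read_annotation_table(dnds_path, ("dn", "ds"))
        for g, (a, b) in raw.items():
            if g in genes:
                dn[g], ds[g] = a, b
    in_inter: dict[str, bool] = {}
    if edges is not None:
        touched = {g for e in edges for g in e}
        in_inter = {g: True for g in touched & genes}
    return GeneUniverse(
        genes=genes, pub_count=pub_count, dn=dn, ds=ds, in_interactome=in_inter
    )
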