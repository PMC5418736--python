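"""Core domain types shared across the analysis modules."""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Mapping


class Organism(str, enum.Enum):
    """Source organism of a longevity gene set (human-symbol space)."""

    HUMAN = "human"
    MOUSE = "mouse"
    FLY = "fly"
    WORM = "worm"
    YEAST = "yeast"
    ALL_ORTHOLOGS = "all_orthologs"


#: Model organisms whose pro/anti sets are pooled into the all-ortholog sets.
MODEL_ORGANISMS = (Organism.MOUSE, Organism.FLY, Organism.WORM, Organism.YEAST)


class LongevityClass(str, enum.Enum):
    PRO = "pro"
    ANTI = "anti"
    HUMAN_CANDIDATE = "human_candidate"
    UNSET = "unset"


class DiseaseClass(str, enum.Enum):
    NEOPLASMS = "neoplasms"
    NUTRITIONAL_METABOLIC = "nutritional_metabolic"
    NERVOUS = "nervous"
    CARDIOVASCULAR = "cardiovascular"
    MUSCULOSKELETAL = "musculoskeletal"
    RESPIRATORY = "respiratory"
    IMMUNE = "immune"
    EYE = "eye"
    OTHER = "other"


#: Disease classes treated as age-related and kept in the analysis.
AGE_RELATED_CLASSES = frozenset(
    {
        DiseaseClass.NEOPLASMS,
        DiseaseClass.NUTRITIONAL_METABOLIC,
        DiseaseClass.NERVOUS,
        DiseaseClass.CARDIOVASCULAR,
        DiseaseClass.MUSCULOSKELETAL,
        DiseaseClass.RESPIRATORY,
        DiseaseClass.IMMUNE,
        DiseaseClass.EYE,
    }
)

#: Classes kept at the class level but excluded from per-disease testing.
CLASS_LEVEL_ONLY = frozenset({DiseaseClass.EYE})

#: Classes expected a priori NOT to overlap with longevity genes.
NEGATIVE_CONTROL_CLASSES = frozenset({DiseaseClass.RESPIRATORY})


def normalize_gene(symbol: str) -> str:
    """Case-normalize a gene symbol (upper-case, stripped)."""
    return symbol.strip().upper()


@dataclass(frozen=True)
class GeneUniverse:
    """Background gene catalog with per-gene annotations.

    All mapping keys must be members of ``genes``; symbols are assumed
    case-normalized by the readers.
    """

    genes: frozenset[str]
    pub_count: Mapping[str, int] = field(default_factory=dict)
    dn: Mapping[str, float] = field(default_factory=dict)
    ds: Mapping[str, float] = field(default_factory=dict)
    in_interactome: Mapping[str, bool] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for label, mapping in (
            ("pub_count", self.pub_count),
            ("dn", self.dn),
            ("ds", self.ds),
            ("in_interactome", self.in_interactome),
        ):
            stray = set(mapping) - self.genes
            if stray:
                raise ValueError(
                    f"{label} has {len(stray)} keys outside the universe, "
                    f"e.g. {sorted(stray)[:5]}"
                )
        bad = [g for g, c in self.pub_count.items() if c < 0]
        if bad:
            raise ValueError(f"negative publication counts for {sorted(bad)[:5]}")

    def __len__(self) -> int:
        return len(self.genes)

    @property
    def interactome(self) -> frozenset[str]:
        """Genes with at least one annotated protein interaction."""
        return frozenset(g for g, v in self.in_interactome.items() if v)

    def publications(self, gene: str) -> int:
        """Publication count for ``gene``; missing means unstudied (0)."""
        return int(self.pub_count.get(gene, 0))


@dataclass(frozen=True)
class LabeledGeneSet:
    """A named gene set with organism and longevity-class labels."""

    name: str
    members: frozenset[str]
    organism: Organism = Organism.HUMAN
    longevity_class: LongevityClass = LongevityClass.UNSET

    def __len__(self) -> int:
        return len(self.members)

    def __iter__(self):
        return iter(self.members)

    def replace_members(self, members: Iterable[str]) -> "LabeledGeneSet":
        """New set with the same labels and different members."""
        return LabeledGeneSet(
            name=self.name,
            members=frozenset(members),
            organism=self.organism,
            longevity_class=self.longevity_class,
        )

    def intersect(self, other: Iterable[str]) -> "LabeledGeneSet":
        return self.replace_members(self.members & frozenset(other))
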