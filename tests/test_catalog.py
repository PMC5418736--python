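from __future__ import annotations

import pandas as pd
import pytest

import agelink as al
from agelink.catalog import (
    DEFAULT_EDGE_TYPES,
    ParseError,
    ValidationError,
    parse_set_name,
    read_annotation_table,
)


# ---------------------------------------------------------------------------
# GMT reading
# ---------------------------------------------------------------------------

class TestReadGeneSets:
    def test_dedup_and_case_normalization(self, tmp_path):
        p = tmp_path / "s.gmt"
        p.write_text("worm_pro\tdesc\tDAF16\tdaf16\n")
        (s,) = al.read_gene_sets(p)
        assert s.members == frozenset({"DAF16"})
        assert s.organism is al.Organism.WORM
        assert s.longevity_class is al.LongevityClass.PRO

    def test_two_field_line_is_parse_error_with_line_number(self, tmp_path):
        p = tmp_path / "s.gmt"
        p.write_text("ok\tdesc\tA\nbad\tdesc\n")
        with pytest.raises(ParseError, match=":2"):
            al.read_gene_sets(p)

    def test_empty_member_list_is_validation_error(self, tmp_path):
        p = tmp_path / "s.gmt"
        p.write_text("empty\tdesc\t\t\n")
        with pytest.raises(ValidationError):
            al.read_gene_sets(p)

    def test_eleven_standard_sets(self, tmp_path):
        names = ["human_candidates"] + [
            f"{org}_{cls}"
            for org in ("mouse", "fly", "worm", "yeast", "all_orthologs")
            for cls in ("anti", "pro")
        ]
        p = tmp_path / "s.gmt"
        p.write_text("".join(f"{n}\tdesc\tA{i}\n" for i, n in enumerate(names)))
        sets = al.read_gene_sets(p)
        assert len(sets) == 11
        assert {s.name for s in sets} == set(names)

    def test_label_policy_override(self, tmp_path):
        p = tmp_path / "s.gmt"
        p.write_text("mystery\tdesc\tA\n")
        (s,) = al.read_gene_sets(
            p, label_policy={"mystery": (al.Organism.YEAST, al.LongevityClass.ANTI)}
        )
        assert s.organism is al.Organism.YEAST
        assert s.longevity_class is al.LongevityClass.ANTI

    def test_gmt_round_trip(self, tmp_path):
        sets = [
            al.LabeledGeneSet("worm_pro", frozenset({"A", "B"}), al.Organism.WORM, al.LongevityClass.PRO),
            al.LabeledGeneSet("mouse_anti", frozenset({"C"}), al.Organism.MOUSE, al.LongevityClass.ANTI),
        ]
        p = tmp_path / "out.gmt"
        al.write_gene_sets(sets, p)
        back = al.read_gene_sets(p)
        assert {(s.name, s.members, s.organism, s.longevity_class) for s in back} == {
            (s.name, s.members, s.organism, s.longevity_class) for s in sets
        }


@pytest.mark.parametrize(
    "name,org,cls",
    [
        ("worm_pro", al.Organism.WORM, al.LongevityClass.PRO),
        ("all_orthologs_anti", al.Organism.ALL_ORTHOLOGS, al.LongevityClass.ANTI),
        ("human_candidates", al.Organism.HUMAN, al.LongevityClass.HUMAN_CANDIDATE),
        ("unlabeled", al.Organism.HUMAN, al.LongevityClass.UNSET),
    ],
)
def test_parse_set_name(name, org, cls):
    assert parse_set_name(name) == (org, cls)


# ---------------------------------------------------------------------------
# Longevity-set assembly
# ---------------------------------------------------------------------------

class TestAssembleLongevitySets:
    def test_dual_annotation_excluded_from_both(self):
        raw = [("g1", "worm", "pro"), ("g1", "worm", "anti"), ("g2", "worm", "pro")]
        sets = {s.name: s for s in al.assemble_longevity_sets(raw)}
        assert sets["worm_pro"].members == frozenset({"G2"})
        assert sets["worm_anti"].members == frozenset()

    def test_unclassified_excluded(self):
        sets = {s.name: s for s in al.assemble_longevity_sets([("g1", "mouse", "unclear")])}
        assert sets["mouse_pro"].members == frozenset()
        assert sets["mouse_anti"].members == frozenset()

    def test_all_orthologs_union(self):
        raw = [
            ("g1", "mouse", "pro"),
            ("g2", "fly", "pro"),
            ("g2", "worm", "pro"),
            ("g3", "yeast", "pro"),
            ("g4", "worm", "anti"),
        ]
        sets = {s.name: s for s in al.assemble_longevity_sets(raw)}
        assert sets["all_orthologs_pro"].members == frozenset({"G1", "G2", "G3"})
        assert sets["all_orthologs_anti"].members == frozenset({"G4"})

    def test_anti_pro_disjoint_within_organism(self):
        raw = [(f"g{i}", "fly", "pro" if i % 2 else "anti") for i in range(10)]
        raw += [("g0", "fly", "pro")]  # g0 now dual
        sets = {s.name: s for s in al.assemble_longevity_sets(raw)}
        assert not sets["fly_pro"].members & sets["fly_anti"].members

    def test_unknown_organism_raises(self):
        with pytest.raises(ValidationError):
            al.assemble_longevity_sets([("g1", "axolotl", "pro")])


# ---------------------------------------------------------------------------
# Disease catalog
# ---------------------------------------------------------------------------

class TestFilterDiseaseCatalog:
    def _catalog(self, sizes: dict[str, tuple[int, al.DiseaseClass]]) -> al.DiseaseCatalog:
        return al.DiseaseCatalog(
            diseases={
                d: frozenset(f"{d}_g{i}" for i in range(n)) for d, (n, _) in sizes.items()
            },
            disease_class={d: c for d, (_, c) in sizes.items()},
        )

    def test_min_genes_boundary(self):
        cat = self._catalog(
            {
                "small": (19, al.DiseaseClass.NEOPLASMS),
                "exact": (20, al.DiseaseClass.NEOPLASMS),
            }
        )
        filtered = al.filter_disease_catalog(cat)
        assert not filtered.included_individual["small"]
        assert not filtered.included_class["small"]
        assert filtered.included_individual["exact"]

    def test_eye_class_level_only(self):
        cat = self._catalog({"glaucoma": (25, al.DiseaseClass.EYE)})
        filtered = al.filter_disease_catalog(cat)
        assert not filtered.included_individual["glaucoma"]
        assert filtered.included_class["glaucoma"]
        assert al.DiseaseClass.EYE in filtered.class_sets()

    def test_respiratory_retained_and_negative_control(self):
        cat = self._catalog({"asthma": (30, al.DiseaseClass.RESPIRATORY)})
        filtered = al.filter_disease_catalog(cat)
        assert filtered.included_individual["asthma"]
        assert filtered.is_negative_control("asthma")

    def test_non_age_related_class_excluded(self):
        cat = self._catalog({"misc": (40, al.DiseaseClass.OTHER)})
        filtered = al.filter_disease_catalog(cat)
        assert not filtered.included_class["misc"]
        assert filtered.all_classes == frozenset()

    def test_union_identities(self, small_benchmark):
        cat = al.filter_disease_catalog(small_benchmark.catalog)
        expected = frozenset().union(
            *(cat.diseases[d] for d in cat.individual_diseases()), frozenset()
        )
        assert cat.all_diseases == expected
        class_union = frozenset().union(*cat.class_sets().values(), frozenset())
        assert cat.all_classes == class_union
        assert len(cat.all_diseases) <= sum(len(g) for g in cat.diseases.values())

    def test_catalog_round_trip(self, tiny_catalog, tmp_path):
        p = tmp_path / "d.tsv"
        al.write_disease_catalog(tiny_catalog, p)
        back = al.read_disease_catalog(p)
        assert back.diseases == dict(tiny_catalog.diseases)
        assert back.disease_class == dict(tiny_catalog.disease_class)


# ---------------------------------------------------------------------------
# Edge / pair / annotation tables
# ---------------------------------------------------------------------------

class TestTables:
    def test_edge_dedup_and_self_loop(self, tmp_path):
        p = tmp_path / "e.tsv"
        p.write_text("gene_a\tgene_b\na\tb\nb\ta\na\ta\n")
        assert al.read_edge_list(p) == [("A", "B")]

    def test_interaction_type_filter(self, tmp_path):
        p = tmp_path / "e.tsv"
        p.write_text(
            "gene_a\tgene_b\tinteraction_type\n"
            "a\tb\tphysical association\n"
            "a\tc\tdirect interaction\n"
            "a\td\tcolocalization\n"
        )
        assert al.read_edge_list(p) == [("A", "B"), ("A", "C")]
        assert len(al.read_edge_list(p, allowed_types=None)) == 3
        assert "colocalization" not in DEFAULT_EDGE_TYPES

    def test_edge_round_trip(self, tmp_path):
        edges = [("A", "B"), ("B", "C"), ("A", "C")]
        p = tmp_path / "e.tsv"
        al.write_edge_list(edges, p)
        assert al.read_edge_list(p, allowed_types=None) == sorted(edges)

    def test_annotation_identity(self, tmp_path):
        p = tmp_path / "a.tsv"
        p.write_text("gene\tpublications\ng1\t12\n")
        assert read_annotation_table(p, ("publications",)) == {"G1": 12.0}

    def test_conflicting_duplicate_annotation_raises(self, tmp_path):
        p = tmp_path / "a.tsv"
        p.write_text("gene\tvalue\ng1\t1\ng1\t2\n")
        with pytest.raises(ValidationError, match="G1"):
            read_annotation_table(p)

    def test_pair_table_validates_p(self, tmp_path):
        p = tmp_path / "pairs.tsv"
        p.write_text("gene_a\tgene_b\tp\na\tb\t1.5\n")
        with pytest.raises(ValidationError):
            al.read_pair_table(p)


def test_restrict_to_universe_warns(tiny_universe):
    s = al.LabeledGeneSet("x", frozenset({"G1", "NOT_THERE"}))
    with pytest.warns(UserWarning, match="absent"):
        out = al.restrict_to_universe(s, tiny_universe)
    assert out.members == frozenset({"G1"})


def test_universe_rejects_stray_annotation_keys():
    with pytest.raises(ValueError, match="pub_count"):
        al.GeneUniverse(genes=frozenset({"A"}), pub_count={"B": 1})
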