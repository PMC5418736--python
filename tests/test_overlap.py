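from __future__ import annotations

from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import agelink as al
from agelink.overlap import BackgroundPolicy, resolve_background, summarize_grid

from _oracles import hypergeom_tail_exact, hypergeom_tail_suffix


class TestHypergeometricTail:
    def test_enumeration_fixture(self):
        # oracle: sum_{i>=3} C(5,i) C(15,4-i) / C(20,4) = 155/4845
        assert hypergeom_tail_exact(3, 5, 4, 20) == Fraction(155, 4845)
        assert al.hypergeometric_tail(3, 5, 4, 20) == pytest.approx(155 / 4845, abs=1e-12)

    def test_k_zero_is_one(self):
        for K, n, N in [(0, 0, 1), (5, 3, 10), (10, 10, 10)]:
            assert al.hypergeometric_tail(0, K, n, N) == 1.0

    def test_forced_overlap(self):
        assert al.hypergeometric_tail(3, 10, 3, 10) == pytest.approx(1.0)

    @pytest.mark.parametrize(
        "k,K,n,N",
        [(-1, 5, 4, 20), (5, 5, 4, 20), (3, 25, 4, 20), (3, 5, 21, 20)],
    )
    def test_parameter_violations(self, k, K, n, N):
        with pytest.raises(ValueError):
            al.hypergeometric_tail(k, K, n, N)

    @given(
        N=st.integers(1, 40),
        data=st.data(),
    )
    @settings(max_examples=60, deadline=None)
    def test_matches_exact_enumeration(self, N, data):
        K = data.draw(st.integers(0, N))
        n = data.draw(st.integers(0, N))
        tails = hypergeom_tail_suffix(K, n, N)
        ks = np.arange(n + 1)
        got = np.atleast_1d(al.hypergeometric_tail(ks, K, n, N))
        for k in range(n + 1):
            assert got[k] == pytest.approx(float(tails[k]), abs=1e-10)

    def test_vectorized_matches_scalar(self):
        ks = np.array([0, 1, 2, 3])
        vec = al.hypergeometric_tail(ks, 5, 4, 20)
        for k, v in zip(ks, vec):
            assert v == al.hypergeometric_tail(int(k), 5, 4, 20)


def _mk(name, members, **kw):
    return al.LabeledGeneSet(name, frozenset(members), **kw)


class TestOverlapTest:
    def test_derived_fixture(self):
        bg = {f"g{i}" for i in range(20)}
        a = _mk("a", {"g0", "g1", "g2", "g3", "g4"})
        b = {"g0", "g1", "g2", "g10"}
        r = al.overlap_test(a, b, bg)
        assert r.observed == 3
        assert r.expected == pytest.approx(1.0)
        assert r.p_value == pytest.approx(155 / 4845, rel=1e-9)
        assert r.significant
        assert r.cad_genes == frozenset({"g0", "g1", "g2"})

    def test_zero_observed_not_significant(self):
        bg = {f"g{i}" for i in range(20)}
        r = al.overlap_test(_mk("a", {"g0", "g1"}), {"g2", "g3"}, bg)
        assert r.observed == 0 and not r.significant

    def test_observed_below_expected_never_significant(self):
        bg = {f"g{i}" for i in range(20)}
        a = _mk("a", {f"g{i}" for i in range(10)})
        b = {f"g{i}" for i in range(8, 18)}
        r = al.overlap_test(a, b, bg)
        assert r.observed == 2 and r.expected == pytest.approx(5.0)
        assert not r.significant

    def test_empty_side_warns_into_null_result(self):
        bg = {"g1", "g2"}
        r = al.overlap_test(_mk("a", {"zz"}), {"g1"}, bg)
        assert (r.observed, r.p_value, r.significant) == (0, 1.0, False)

    def test_symmetry_of_p(self):
        bg = {f"g{i}" for i in range(30)}
        a = {f"g{i}" for i in range(7)}
        b = {f"g{i}" for i in range(4, 16)}
        p1 = al.overlap_test(_mk("a", a), b, bg).p_value
        p2 = al.overlap_test(_mk("b", b), a, bg).p_value
        assert p1 == pytest.approx(p2, rel=1e-12)

    def test_two_sided_flag(self):
        bg = {f"g{i}" for i in range(20)}
        a = _mk("a", {"g0", "g1", "g2", "g3", "g4"})
        b = {"g0", "g1", "g2", "g10"}
        r2 = al.overlap_test(a, b, bg, two_sided=True)
        assert r2.p_value >= al.overlap_test(a, b, bg).p_value - 1e-12

    def test_expected_invariant(self):
        bg = {f"g{i}" for i in range(25)}
        a = _mk("a", {f"g{i}" for i in range(6)})
        b = {f"g{i}" for i in range(3, 12)}
        r = al.overlap_test(a, b, bg)
        assert r.observed <= min(r.n_aging, r.n_disease)
        assert r.expected <= min(r.n_aging, r.n_disease)
        assert len(r.cad_genes) == r.observed


class TestBackgroundsAndGrid:
    @pytest.fixture()
    def universe(self):
        genes = frozenset(f"g{i}" for i in range(40))
        inter = {f"g{i}": True for i in range(20)}
        return al.GeneUniverse(genes=genes, in_interactome=inter)

    def test_genome_policy(self, universe):
        assert resolve_background(BackgroundPolicy.GENOME, universe) == universe.genes

    def test_interactome_policy(self, universe):
        assert resolve_background("interactome", universe) == universe.interactome

    def test_seed_union_policy(self, universe):
        bg = resolve_background(
            BackgroundPolicy.SEED_UNION, universe, seed={"g30"}, disease_genes={"g35"}
        )
        assert bg == universe.interactome | {"g30", "g35"}

    def test_seed_interactome_policy_narrower(self, universe):
        wide = resolve_background(BackgroundPolicy.SEED_UNION, universe, {"g30"}, {"g35"})
        narrow = resolve_background(BackgroundPolicy.SEED_INTERACTOME, universe, {"g30"}, {"g35"})
        assert narrow <= wide
        assert "g35" not in narrow

    def test_unknown_policy_raises(self, universe):
        with pytest.raises(ValueError):
            resolve_background("nonsense", universe)

    def test_grid_row_count(self, universe):
        catalog = al.DiseaseCatalog(
            diseases={
                "d1": frozenset({"g1", "g2"}),
                "d2": frozenset({"g3"}),
                "d3": frozenset({"g4", "g5"}),
            },
            disease_class={
                "d1": al.DiseaseClass.NEOPLASMS,
                "d2": al.DiseaseClass.NERVOUS,
                "d3": al.DiseaseClass.NEOPLASMS,
            },
        )
        aging = [_mk("a1", {"g1"}), _mk("a2", {"g2"})]
        grid = al.run_overlap_grid(aging, catalog, universe, "genome", level="individual")
        # 2 aging sets x (3 diseases + all_diseases + all_classes)
        assert len(grid) == 2 * 5

    def test_background_shrink_keeps_observed(self, small_benchmark):
        b = small_benchmark
        cat = al.filter_disease_catalog(b.catalog)
        aging = [s for s in b.aging_sets if len(s) >= 10][:3]
        g1 = al.run_overlap_grid(aging, cat, b.universe, "genome", level="class")
        g2 = al.run_overlap_grid(aging, cat, b.universe, "interactome", level="class")
        m1 = {(r.aging_set, r.disease_set): r for r in g1.itertuples()}
        m2 = {(r.aging_set, r.disease_set): r for r in g2.itertuples()}
        for key in m1:
            assert m2[key].background_size <= m1[key].background_size
            assert m2[key].observed <= m1[key].observed
            # intersection with a smaller background can only drop genes
            assert m2[key].n_aging <= m1[key].n_aging

    def test_summarize_and_extract(self, universe):
        catalog = al.DiseaseCatalog(
            diseases={"d1": frozenset({"g1", "g2"})},
            disease_class={"d1": al.DiseaseClass.NEOPLASMS},
        )
        grid = al.run_overlap_grid([_mk("a1", {"g1", "g9"})], catalog, universe, "genome")
        summ = summarize_grid(grid)
        assert list(summ["aging_set"]) == ["a1"]
        cads = al.extract_cad_genes(grid)
        assert cads[("a1", "d1")] == frozenset({"g1"})
        for row in grid.itertuples(index=False):
            assert len(cads[(row.aging_set, row.disease_set)]) == row.observed


class TestCalibration:
    def test_null_calibration_small(self):
        """~5% raw positives under a planted null; dual rule never exceeds it."""
        rng = np.random.default_rng(11)
        genes = [f"g{i}" for i in range(2000)]
        bg = frozenset(genes)
        n_sig_raw = 0
        n_sig_dual = 0
        trials = 300
        for _ in range(trials):
            a = frozenset(rng.choice(genes, size=60, replace=False))
            b = frozenset(rng.choice(genes, size=120, replace=False))
            r = al.overlap_test(_mk("a", a), b, bg)
            n_sig_raw += r.p_value < 0.05
            n_sig_dual += r.significant
        assert n_sig_dual <= n_sig_raw
        assert n_sig_raw / trials == pytest.approx(0.05, abs=0.035)

    def test_power_with_planted_or(self):
        # At |A|=400 the dual rule is near-certain to fire under OR=5;
        # smaller seeds (|A|=100) top out near 80% power at this alpha.
        rng = np.random.default_rng(5)
        genes = [f"g{i}" for i in range(20000)]
        hits = 0
        trials = 40
        for i in range(trials):
            a = frozenset(rng.choice(genes, size=400, replace=False))
            b = al.plant_overlap(genes, a, 200, 5.0, rng)
            r = al.overlap_test(_mk("a", a), b, frozenset(genes))
            hits += r.significant
        assert hits / trials > 0.9
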