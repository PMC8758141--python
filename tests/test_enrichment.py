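"""enrichment_core: hypergeometric tail vs independent oracles, BH
adjustment, downregulated-gene selection, screen assembly and ranking."""

import itertools
import random

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from mirnet import (
    bh_adjust,
    hypergeom_tail,
    mirna_enrichment,
    rank_mirnas,
    select_downregulated,
)
from mirnet.io import GeneSet, TargetMap

from .conftest import bh_by_hand, hypergeom_tail_by_enumeration, make_de


class TestHypergeomTail:
    def test_zero_overlap_sums_all_mass(self):
        assert hypergeom_tail(100, 30, 20, 0) == 1.0

    def test_small_case_matches_enumeration(self):
        # N=10, M=4, D=3, O=2: (C(3,2)C(7,2) + C(3,3)C(7,1)) / C(10,4) = 70/210
        assert hypergeom_tail(10, 4, 3, 2) == pytest.approx(70 / 210, abs=1e-12)
        assert hypergeom_tail_by_enumeration(10, 4, 3, 2) == pytest.approx(70 / 210)

    def test_targets_cover_universe_force_full_overlap(self):
        assert hypergeom_tail(5, 5, 2, 2) == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("n", [6, 8, 10])
    def test_exhaustive_oracle_equivalence_small_universes(self, n):
        for m in range(0, n + 1):
            for d in range(0, n + 1):
                for o in range(0, min(m, d) + 1):
                    expected = hypergeom_tail_by_enumeration(n, m, d, o)
                    assert hypergeom_tail(n, m, d, o) == pytest.approx(
                        expected, abs=1e-12
                    ), (n, m, d, o)

    def test_agrees_with_scipy_survival_function_at_scale(self):
        # independent cross-check: sf(O-1) is the same upper tail
        for m in (10, 200, 2000):
            for o in range(0, min(m, 17) + 1):
                ours = hypergeom_tail(16010, m, 17, o)
                ref = stats.hypergeom.sf(o - 1, 16010, 17, m)
                assert ours == pytest.approx(ref, rel=1e-10, abs=1e-300)

    def test_monotone_nonincreasing_in_overlap(self):
        vals = [hypergeom_tail(16010, 200, 17, o) for o in range(18)]
        assert all(np.isfinite(vals)) and all(0 <= v <= 1 for v in vals)
        assert all(a >= b - 1e-15 for a, b in zip(vals, vals[1:]))

    def test_pmf_from_tail_differences_normalizes(self):
        for n, m, d in [(16010, 200, 17), (16010, 2000, 17), (50, 10, 7)]:
            hi = min(m, d)
            tail = [hypergeom_tail(n, m, d, o) for o in range(hi + 1)] + [0.0]
            pmf = [tail[o] - tail[o + 1] for o in range(hi + 1)]
            assert sum(pmf) == pytest.approx(1.0, abs=1e-10)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            hypergeom_tail(10, 4, 3, 4)  # O > min(M, D)
        with pytest.raises(ValueError):
            hypergeom_tail(10, 11, 3, 1)  # M > N
        with pytest.raises(ValueError):
            hypergeom_tail(10, 4, 11, 1)  # D > N

    @given(st.data())
    @settings(max_examples=100, deadline=None)
    def test_property_matches_enumeration(self, data):
        n = data.draw(st.integers(1, 9))
        m = data.draw(st.integers(0, n))
        d = data.draw(st.integers(0, n))
        o = data.draw(st.integers(0, min(m, d)))
        assert hypergeom_tail(n, m, d, o) == pytest.approx(
            hypergeom_tail_by_enumeration(n, m, d, o), abs=1e-12
        )


class TestBhAdjust:
    def test_single_value_identity(self):
        assert bh_adjust([0.05]).tolist() == [0.05]

    def test_step_up_hand_example(self):
        assert bh_adjust([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)

    def test_equal_inputs_unchanged(self):
        assert bh_adjust([0.3, 0.3, 0.3]) == pytest.approx([0.3, 0.3, 0.3])

    def test_matches_hand_rule_on_random_vectors(self):
        rng = random.Random(42)
        for _ in range(50):
            p = [rng.random() for _ in range(rng.randint(1, 40))]
            assert bh_adjust(p) == pytest.approx(bh_by_hand(p), abs=1e-12)

    def test_adjusted_at_least_raw_and_at_most_one(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            p = rng.random(rng.integers(1, 200))
            adj = bh_adjust(p)
            assert (adj >= p - 1e-15).all() and (adj <= 1.0 + 1e-15).all()

    def test_order_invariance(self):
        p = [0.9, 0.001, 0.5, 0.03, 0.03]
        perm = [1, 3, 4, 2, 0]
        adj = bh_adjust(p)
        adj_perm = bh_adjust([p[i] for i in perm])
        assert [adj[i] for i in perm] == pytest.approx(list(adj_perm))

    def test_alternative_methods(self):
        assert bh_adjust([0.01, 0.04], method="bonferroni") == pytest.approx([0.02, 0.08])
        with pytest.raises(ValueError):
            bh_adjust([0.5], method="nope")

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])


class TestSelectDownregulated:
    def test_threshold_and_sign(self):
        de = make_de(
            {
                "g1": (-1.0, 0.001, 0.01),
                "g2": (1.0, 0.001, 0.01),
                "g3": (-1.0, 0.1, 0.2),
                "g4": (-0.1, 0.05, 0.09),
                "g5": (0.0, 0.5, 0.5),
            }
        )
        pathway = GeneSet("p", frozenset({"G1", "G2", "G3", "G4"}))
        down = select_downregulated(de, pathway, alpha_select=0.1)
        assert down.genes == frozenset({"G1", "G4"})

    def test_strict_inequality_at_alpha(self):
        de = make_de({"g1": (-1.0, 0.05, 0.1)})
        pathway = GeneSet("p", frozenset({"G1"}))
        assert select_downregulated(de, pathway, 0.1).genes == frozenset()

    def test_empty_pathway_warns_not_raises(self):
        de = make_de({"g1": (-1.0, 0.001, 0.01)})
        down = select_downregulated(de, GeneSet("p", frozenset({"ZZZ"})), 0.1)
        assert down.genes == frozenset()


class TestMirnaEnrichment:
    def test_toy_screen_counts_and_pvalues(self, toy_de, toy_targets, toy_pathway):
        records = {r.mirna_id: r for r in mirna_enrichment(toy_de, toy_targets, toy_pathway)}
        a = records["MIR-A"]
        assert (a.n_universe, a.m_targets, a.d_down, a.o_overlap) == (10, 3, 2, 2)
        assert a.overlap_genes == frozenset({"G01", "G02"})
        assert a.p_value == pytest.approx(8 / 120, abs=1e-12)
        b = records["MIR-B"]
        assert (b.m_targets, b.o_overlap) == (4, 1)
        assert b.p_value == pytest.approx(2 / 3, abs=1e-12)
        c = records["MIR-C"]
        assert c.o_overlap == 0 and c.p_value == 1.0
        # BH over [1/15, 2/3, 1]
        assert a.p_adjusted == pytest.approx(0.2, abs=1e-12)
        assert b.p_adjusted == pytest.approx(1.0, abs=1e-12)

    def test_targets_outside_universe_ignored_for_m_and_o(self, toy_de, toy_pathway):
        tmap = TargetMap({"m1": frozenset({"G01", "G02", "NOT_IN_DE"})})
        rec = mirna_enrichment(toy_de, tmap, toy_pathway)[0]
        assert rec.m_targets == 2 and rec.o_overlap == 2

    def test_no_downregulated_gene_is_instructive_error(self, toy_de, toy_targets, toy_pathway):
        with pytest.raises(ValueError, match="alpha_select"):
            mirna_enrichment(toy_de, toy_targets, toy_pathway, alpha_select=0.001)


class TestRankMirnas:
    def _rec(self, mirna_id, p, padj, o=1):
        from mirnet import EnrichmentRecord

        return EnrichmentRecord(
            mirna_id=mirna_id, n_universe=100, m_targets=10, d_down=5,
            o_overlap=o, overlap_genes=frozenset(), p_value=p, p_adjusted=padj,
        )

    def test_orders_by_adjusted_then_raw_then_overlap_then_id(self):
        recs = [
            self._rec("d", 0.02, 0.05),
            self._rec("c", 0.01, 0.05, o=3),
            self._rec("b", 0.01, 0.05, o=5),
            self._rec("a2", 0.01, 0.01),
        ]
        assert [r.mirna_id for r in rank_mirnas(recs)] == ["a2", "b", "c", "d"]

    def test_permutation_invariant(self):
        recs = [self._rec(f"m{i}", 0.01 * i + 0.001, 0.05) for i in range(6)]
        ranked = rank_mirnas(recs)
        for perm in itertools.permutations(recs, 6):
            assert rank_mirnas(list(perm)) == ranked
            break
        random.Random(1).shuffle(recs)
        assert rank_mirnas(recs) == ranked
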