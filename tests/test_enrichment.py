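"""Over-representation, BH, ortholog mapping, target partition, redundancy filter."""

import itertools
import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest

from pairmir import (
    AnnotationCollection,
    OrthologMap,
    TargetMap,
    Term,
    ValidationError,
    best_per_parent,
    bh_adjust,
    build_target_sets,
    collapse_family,
    map_orthologs,
    ora,
    random_set_calibration,
)
from pairmir.enrichment import EnrichmentResult


def hypergeom_tail_exact(M: int, K: int, s: int, k: int) -> Fraction:
    """Exhaustive-enumeration upper tail P(X >= k), exact rational arithmetic."""
    total = math.comb(M, s)
    acc = 0
    for j in range(k, min(K, s) + 1):
        if s - j <= M - K:
            acc += math.comb(K, j) * math.comb(M - K, s - j)
    return Fraction(acc, total)


class TestOrthologs:
    def test_table_entry_wins(self):
        om = OrthologMap({"rno-miR-1-3p": "hsa-miR-1-3p"})
        mapped, unmapped = map_orthologs({"rno-miR-1-3p"}, om, prefix_fallback=False)
        assert mapped == {"hsa-miR-1-3p"} and unmapped == []

    def test_prefix_fallback(self):
        mapped, unmapped = map_orthologs({"rno-miR-423-5p"})
        assert mapped == {"hsa-miR-423-5p"} and unmapped == []

    def test_unmapped_reported(self):
        mapped, unmapped = map_orthologs({"mmu-miR-5"}, prefix_fallback=True)
        assert mapped == set() and unmapped == ["mmu-miR-5"]

    def test_many_to_one_dedup(self):
        om = OrthologMap({"rno-miR-a": "hsa-miR-x", "rno-miR-b": "hsa-miR-x"})
        mapped, _ = map_orthologs({"rno-miR-a", "rno-miR-b"}, om)
        assert mapped == {"hsa-miR-x"}

    def test_family_collapse(self):
        assert collapse_family("hsa-miR-125b-5p") == "hsa-miR-125b"
        assert collapse_family("hsa-miR-207") == "hsa-miR-207"


class TestOra:
    def _annotation(self, member_sets):
        return AnnotationCollection(
            [
                Term(f"T{i}", f"t{i}", "function", frozenset(m))
                for i, m in enumerate(member_sets)
            ]
        )

    def test_worked_example_66_252(self):
        # M=10, K=4, s=5, overlap 3: P(X>=3) = 66/252
        uni = [f"g{i}" for i in range(10)]
        ann = self._annotation([uni[:4]])
        query = set(uni[1:4]) | {uni[5], uni[6]}  # 3 of the 4 term members
        (res,) = ora(query, ann, universe=uni, return_all=True)
        assert res.raw_p == pytest.approx(float(Fraction(66, 252)), abs=1e-12)
        assert res.contributing_members == frozenset(uni[1:4])

    def test_zero_overlap_p_one(self):
        uni = [f"g{i}" for i in range(10)]
        ann = self._annotation([uni[:4]])
        (res,) = ora(set(uni[4:6]), ann, universe=uni, return_all=True)
        assert res.raw_p == 1.0

    def test_query_equals_term_equals_universe(self):
        uni = ["a", "b", "c"]
        ann = self._annotation([uni])
        (res,) = ora(set(uni), ann, universe=uni, return_all=True)
        assert res.raw_p == 1.0

    def test_empty_universe_rejected(self):
        ann = self._annotation([["a"]])
        with pytest.raises(ValidationError):
            ora({"a"}, ann, universe=[])

    def test_empty_query_empty_result(self):
        ann = self._annotation([["a", "b"]])
        assert ora(set(), ann, universe=["a", "b"]) == []

    def test_exhaustive_enumeration_all_small_universes(self):
        # every (M, K, s, k) with M <= 12 plus random instances up to M = 20
        rng = np.random.default_rng(0)
        checked = 0
        for M in range(2, 13):
            for K in range(1, M + 1):
                for s in range(1, M + 1):
                    for k in range(max(0, s + K - M), min(s, K) + 1):
                        from scipy import stats

                        got = float(stats.hypergeom.sf(k - 1, M, K, s))
                        exact = float(hypergeom_tail_exact(M, K, s, k))
                        assert abs(got - exact) <= 1e-12, (M, K, s, k)
                        checked += 1
        assert checked > 1000
        uni20 = [f"g{i}" for i in range(20)]
        for _ in range(200):
            K = int(rng.integers(1, 21))
            s = int(rng.integers(1, 21))
            term = list(rng.choice(uni20, size=K, replace=False))
            query = set(rng.choice(uni20, size=s, replace=False))
            (res,) = ora(query, self._annotation([term]), universe=uni20, return_all=True)
            k = len(query & set(term))
            assert res.raw_p == pytest.approx(
                float(hypergeom_tail_exact(20, K, s, k)), abs=1e-12
            )

    def test_significant_sorted_ascending(self):
        uni = [f"g{i}" for i in range(30)]
        ann = self._annotation([uni[:5], uni[:10], uni[10:20]])
        res = ora(set(uni[:10]), ann, universe=uni, alpha=1.1, return_all=True)
        assert [r.raw_p for r in res] == sorted(r.raw_p for r in res)


class TestBH:
    def test_hand_example(self):
        assert bh_adjust([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])

    def test_singleton_identity(self):
        assert bh_adjust([0.5]) == [0.5]

    def test_output_at_least_input_and_capped(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(1e-6, 1.0, size=40)
        adj = np.array(bh_adjust(list(p)))
        assert (adj >= p - 1e-15).all()
        assert (adj <= 1.0).all()

    def test_order_invariance(self):
        rng = np.random.default_rng(2)
        p = list(rng.uniform(1e-6, 1.0, size=25))
        adj = bh_adjust(p)
        perm = rng.permutation(25)
        adj_perm = bh_adjust([p[i] for i in perm])
        for j, i in enumerate(perm):
            assert adj_perm[j] == pytest.approx(adj[i])

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(3)
        for _ in range(20):
            p = rng.uniform(1e-8, 1.0, size=int(rng.integers(1, 50)))
            ref = multipletests(p, method="fdr_bh")[1]
            assert np.allclose(bh_adjust(list(p)), ref, atol=1e-12)

    def test_invalid_values_rejected(self):
        with pytest.raises(ValidationError):
            bh_adjust([0.0, 0.5])
        with pytest.raises(ValidationError):
            bh_adjust([1.5])


class TestRandomSetCalibration:
    def _uniform_annotation(self, seed=0, n_terms=10, M=100):
        from pairmir import generate_annotation

        uni = [f"g{i}" for i in range(M)]
        ann, _ = generate_annotation(n_terms, uni, seed=seed, term_size_range=(5, 40))
        return ann, uni

    def test_impossible_term_count_zero(self):
        # a term too small to ever reach significance for this query size
        uni = [f"g{i}" for i in range(100)]
        ann = AnnotationCollection(
            [Term("T0", "t", "function", frozenset(uni[:2]))], universe=frozenset(uni)
        )
        obs = [
            EnrichmentResult("T0", "t", "function", 1.0, frozenset())
        ]
        out = random_set_calibration(
            obs, set_size=5, annotation=ann, alpha=1e-9, n_sets=50, seed=1
        )
        assert out[0].random_hit_count == 0
        assert out[0].empirical_p == pytest.approx(1 / 51)

    def test_seed_determinism(self):
        ann, uni = self._uniform_annotation()
        obs = ora(set(uni[:12]), ann, universe=uni, alpha=1.1, return_all=True)
        a = random_set_calibration(obs, 12, ann, universe=uni, alpha=0.05, n_sets=100, seed=2)
        b = random_set_calibration(obs, 12, ann, universe=uni, alpha=0.05, n_sets=100, seed=2)
        assert [r.random_hit_count for r in a] == [r.random_hit_count for r in b]

    def test_empirical_p_add_one_rule(self):
        ann, uni = self._uniform_annotation(seed=4)
        obs = ora(set(uni[:10]), ann, universe=uni, alpha=1.1, return_all=True)
        out = random_set_calibration(obs, 10, ann, universe=uni, alpha=0.05, n_sets=99, seed=5)
        for r in out:
            assert r.empirical_p == pytest.approx((r.random_hit_count + 1) / 100)
            assert r.empirical_p > 0

    def test_hit_frequency_matches_analytic_tail_mass(self):
        # small version of the convergence property: MC frequency vs the
        # hypergeometric probability of reaching the per-term critical overlap
        from scipy import stats

        ann, uni = self._uniform_annotation(seed=6, n_terms=5, M=80)
        alpha, s, n_sets = 0.05, 10, 2000
        obs = ora(set(uni[:s]), ann, universe=uni, alpha=1.1, return_all=True)
        out = random_set_calibration(obs, s, ann, universe=uni, alpha=alpha, n_sets=n_sets, seed=7)
        M = len(uni)
        violations = 0
        for r in out:
            K = len(ann.get(r.term_id).members)
            ks = np.arange(0, min(K, s) + 1)
            tails = stats.hypergeom.sf(ks - 1, M, K, s)
            crit = ks[tails < alpha]
            p_sig = float(stats.hypergeom.sf(crit[0] - 1, M, K, s)) if len(crit) else 0.0
            freq = r.random_hit_count / n_sets
            se = np.sqrt(max(p_sig * (1 - p_sig), 1e-12) / n_sets)
            violations += abs(freq - p_sig) > 3 * max(se, 1e-12)
        assert violations <= 1

    def test_n_sets_validated(self):
        ann, uni = self._uniform_annotation()
        with pytest.raises(ValidationError):
            random_set_calibration([], 5, ann, universe=uni, n_sets=0)


class TestTargetSets:
    def _map(self, rows):
        return TargetMap(
            pd.DataFrame(rows, columns=["mirna", "target", "validated", "n_predictions"])
        )

    def test_evidence_filter_boundaries(self):
        tm = self._map(
            [
                ("mA", "g_weak", False, 2),  # fails filter
                ("mA", "g_pred", False, 3),  # passes on predictions
                ("mA", "g_val", True, 0),  # passes on validation
            ]
        )
        sets = build_target_sets({"mA"}, {"mV"}, tm)
        assert sets.arterial_exclusive == frozenset({"g_pred", "g_val"})

    def test_hand_partition(self):
        tm = self._map(
            [
                ("miR-A", "g1", True, 0),
                ("miR-A", "g2", True, 0),
                ("miR-V", "g2", True, 0),
                ("miR-V", "g3", True, 0),
            ]
        )
        sets = build_target_sets({"miR-A"}, {"miR-V"}, tm)
        assert sets.arterial_exclusive == frozenset({"g1"})
        assert sets.venous_exclusive == frozenset({"g3"})
        assert sets.shared == frozenset({"g2"})

    def test_overlapping_groups_rejected(self):
        tm = self._map([("mA", "g1", True, 0)])
        with pytest.raises(ValidationError):
            build_target_sets({"mA"}, {"mA"}, tm)

    def test_partition_is_disjoint_and_complete(self):
        rng = np.random.default_rng(8)
        rows = []
        for mir in [f"a{i}" for i in range(5)] + [f"v{i}" for i in range(5)]:
            for g in rng.choice([f"g{j}" for j in range(60)], size=20, replace=False):
                rows.append((mir, g, bool(rng.random() < 0.4), int(rng.integers(0, 6))))
        tm = TargetMap(
            pd.DataFrame(rows, columns=["mirna", "target", "validated", "n_predictions"])
        )
        art = {f"a{i}" for i in range(5)}
        ven = {f"v{i}" for i in range(5)}
        sets = build_target_sets(art, ven, tm)
        union = sets.arterial_exclusive | sets.venous_exclusive | sets.shared
        assert union == tm.targets_of(art) | tm.targets_of(ven)
        assert len(union) == (
            len(sets.arterial_exclusive) + len(sets.venous_exclusive) + len(sets.shared)
        )


class TestBestPerParent:
    def _res(self, term_id, p):
        return EnrichmentResult(term_id, term_id, "gene_function", p, frozenset())

    def test_sibling_with_smaller_p_survives(self):
        results = [self._res("A", 0.001), self._res("B", 0.01)]
        out = best_per_parent(results, {"A": frozenset({"P"}), "B": frozenset({"P"})})
        assert [r.term_id for r in out] == ["A"]

    def test_distinct_parents_all_retained(self):
        results = [self._res("A", 0.001), self._res("B", 0.01)]
        out = best_per_parent(results, {"A": frozenset({"P1"}), "B": frozenset({"P2"})})
        assert {r.term_id for r in out} == {"A", "B"}

    def test_parentless_always_retained(self):
        results = [self._res("A", 0.5), self._res("B", 0.001)]
        out = best_per_parent(results, {"B": frozenset({"P"})})
        assert {r.term_id for r in out} == {"A", "B"}

    def test_three_level_ontology_matches_brute_force(self):
        rng = np.random.default_rng(9)
        # three-level random DAG: level0 roots, level1, level2 leaves
        parent_map = {}
        for i in range(6):
            parent_map[f"L1_{i}"] = frozenset({f"L0_{i % 2}"})
        for i in range(12):
            parents = set(
                rng.choice([f"L1_{j}" for j in range(6)], size=rng.integers(1, 3), replace=False)
            )
            parent_map[f"L2_{i}"] = frozenset(parents)
        results = [
            self._res(t, float(rng.uniform(1e-4, 0.05)))
            for t in list(parent_map) + ["L0_0", "L0_1"]
        ]
        out = {r.term_id for r in best_per_parent(results, parent_map)}
        # brute force: keep parentless terms and any term winning one of its groups
        by_id = {r.term_id: r for r in results}
        expected = {t for t in by_id if not parent_map.get(t)}
        groups = {}
        for t in by_id:
            for p in parent_map.get(t, ()):  # noqa: B905
                groups.setdefault(p, []).append(t)
        for members in groups.values():
            best = min(members, key=lambda t: (by_id[t].raw_p, t))
            expected.add(best)
        assert out == expected

    def test_cycle_rejected(self):
        results = [self._res("A", 0.01)]
        with pytest.raises(ValidationError, match="cycle"):
            best_per_parent(
                results, {"A": frozenset({"B"}), "B": frozenset({"A"})}
            )

    def test_no_parent_map_is_identity(self):
        results = [self._res("A", 0.5)]
        assert best_per_parent(results, None) == results
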