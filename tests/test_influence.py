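"""Influence score s_k and the overlap-preserving permutation null."""

import numpy as np
import pytest

from brelax import (
    PathwayCollection,
    b_relaxation,
    build_permutation_graph,
    influence_profile,
    influence_score,
    pathway_overlap,
    permutation_significance,
    permute_memberships,
)
from brelax.synthetic import planted_influence_bundle

from conftest import make_random_hypergraph


@pytest.fixture
def toy_pathways(toy1):
    return PathwayCollection({"PS": {"a", "b"}, "PT": {"d", "e"}}, toy1)


class TestPathwayCollection:
    def test_restricted_to_hypergraph_nodes(self, toy1):
        p = PathwayCollection({"P": {"a", "ghost"}}, toy1)
        assert p.members("P") == {"a"}

    def test_empty_pathway_rejected(self, toy1):
        with pytest.raises(ValueError):
            PathwayCollection({"P": {"ghost"}}, toy1)

    def test_unknown_pathway_lookup(self, toy_pathways):
        with pytest.raises(KeyError):
            toy_pathways.members("nope")


class TestOverlapMatrix:
    def test_asymmetric_normalization(self):
        p = PathwayCollection({"S": {"a", "b"}, "T": {"b", "c", "d"}})
        m = pathway_overlap(p)
        assert m.loc["S", "T"] == 0.5
        assert m.loc["T", "S"] == pytest.approx(1 / 3)
        assert (np.diag(m.to_numpy()) == 1).all()

    def test_disjoint_and_identical(self):
        p = PathwayCollection({"A": {"x"}, "B": {"y"}, "C": {"x"}})
        m = pathway_overlap(p)
        assert m.loc["A", "B"] == 0 and m.loc["A", "C"] == 1


class TestInfluenceScore:
    def test_toy1_worked_values(self, toy1, toy_pathways):
        relax = b_relaxation(toy1, {"a", "b"})
        ps, pt = toy_pathways.members("PS"), toy_pathways.members("PT")
        assert influence_score(relax, ps, pt, 0) == 0.25
        assert influence_score(relax, ps, pt, 1) == 0.4

    def test_zero_when_target_only_in_overlap(self, toy1):
        relax = b_relaxation(toy1, {"a", "b"})
        # target inside the source: numerator empty
        assert influence_score(relax, {"a", "b"}, {"a"}, 5) == 0.0

    def test_zero_denominator_convention(self, toy1):
        relax = b_relaxation(toy1, {"f"})
        # source reaches only itself; discounting the overlap empties the denominator
        assert influence_score(relax, {"f"}, {"f"}, 0) == 0.0

    def test_negative_k_rejected(self, toy1):
        relax = b_relaxation(toy1, {"a"})
        with pytest.raises(ValueError):
            influence_score(relax, {"a"}, {"e"}, -1)

    def test_bounded_and_label_invariant(self, toy1):
        relax = b_relaxation(toy1, {"a", "b"})
        for k in range(4):
            s = influence_score(relax, {"a", "b"}, {"d", "e"}, k)
            assert 0.0 <= s <= 1.0


class TestInfluenceProfile:
    def test_matches_single_scores(self, toy1, toy_pathways):
        df = influence_profile(toy1, toy_pathways, "PS", k_max=1)
        got = df.set_index(["target", "k"])["score"]
        assert got.loc[("PT", 0)] == 0.25 and got.loc[("PT", 1)] == 0.4
        sizes = df.set_index(["target", "k"])["b_leq_k_size"]
        assert sizes.loc[("PT", 0)] == 4 and sizes.loc[("PT", 1)] == 5

    def test_kmax_zero_single_column(self, toy1, toy_pathways):
        df = influence_profile(toy1, toy_pathways, "PS", k_max=0)
        assert set(df["k"]) == {0}

    def test_unknown_source_rejected(self, toy1, toy_pathways):
        with pytest.raises(KeyError):
            influence_profile(toy1, toy_pathways, "nope", k_max=1)


def overlap_counts(p: PathwayCollection):
    return {
        (s, t): len(p.members(s) & p.members(t))
        for s in p.names
        for t in p.names
    }


class TestPermutationGraph:
    def test_disjoint_pathways_two_regions(self):
        p = PathwayCollection({"A": {"a", "b"}, "B": {"c", "d"}})
        pg = build_permutation_graph(p)
        assert len(pg.regions) == 2 and len(pg.molecules) == 4

    def test_regions_bounded_by_venn_cells(self):
        p = PathwayCollection(
            {"A": {"1", "2", "3"}, "B": {"2", "4"}, "C": {"3", "4", "5"}}
        )
        pg = build_permutation_graph(p)
        assert 1 <= len(pg.regions) <= 2**3 - 1
        # every molecule assigned to the region matching its memberships
        rebuilt = pg.to_collection()
        assert overlap_counts(rebuilt) == overlap_counts(p)

    def test_single_pathway_single_region(self):
        pg = build_permutation_graph(PathwayCollection({"A": {"x", "y"}}))
        assert len(pg.regions) == 1


class TestPermuteMemberships:
    def test_zero_swaps_identity(self):
        p = PathwayCollection({"A": {"a", "b"}, "B": {"b", "c", "d"}})
        pg = build_permutation_graph(p)
        q = permute_memberships(pg, 0, seed=5)
        assert {n: q.members(n) for n in q.names} == {n: p.members(n) for n in p.names}

    def test_overlaps_invariant_under_any_swaps(self):
        p = PathwayCollection(
            {"A": {"a", "b", "c"}, "B": {"c", "d"}, "C": {"e", "f", "a"}}
        )
        pg = build_permutation_graph(p)
        base = overlap_counts(p)
        for seed in range(10):
            q = permute_memberships(pg, 500, seed=seed)
            assert overlap_counts(q) == base

    def test_deterministic_under_seed(self):
        p = PathwayCollection({"A": {"a", "b", "c"}, "B": {"d", "e"}})
        pg = build_permutation_graph(p)
        q1 = permute_memberships(pg, 10_000, seed=42)
        q2 = permute_memberships(pg, 10_000, seed=42)
        assert {n: q1.members(n) for n in q1.names} == {n: q2.members(n) for n in q2.names}

    def test_swaps_actually_shuffle(self):
        p = PathwayCollection({"A": {"a", "b", "c"}, "B": {"d", "e", "f"}})
        pg = build_permutation_graph(p)
        results = {frozenset(permute_memberships(pg, 100, seed=s).members("A")) for s in range(20)}
        assert len(results) > 1


class TestPermutationSignificance:
    def test_degenerate_null_single_region(self, toy1):
        # one pathway only: every permutation is identical, so n_ge = n_perm
        p = PathwayCollection({"A": {"a", "b"}, "B": {"a", "b"}}, toy1)
        rec = permutation_significance(toy1, p, "A", "B", k=0, n_perm=20, n_swaps=100, seed=1)
        assert rec.n_ge == rec.n_perm and not rec.significant

    def test_observed_zero_never_significant(self, toy1):
        p = PathwayCollection({"A": {"f"}, "B": {"a"}}, toy1)
        rec = permutation_significance(toy1, p, "A", "B", k=0, n_perm=10, n_swaps=50, seed=1)
        assert rec.score == 0.0 and rec.n_ge == rec.n_perm

    def test_planted_pair_detected(self):
        h, p, src, tgt, k = planted_influence_bundle(seed=3)
        rec = permutation_significance(h, p, src, tgt, k, n_perm=50, n_swaps=2000, seed=3)
        assert rec.score > 0.8
        assert rec.n_ge == 0 and rec.significant

    def test_power_monotone_in_signal(self):
        """Weakening the planted signal (fewer exclusive target members
        downstream) cannot decrease n_ge at a fixed seed set."""
        h, p, src, tgt, k = planted_influence_bundle(seed=7, branch_width=4)
        strong = permutation_significance(h, p, src, tgt, k, n_perm=30, n_swaps=1000, seed=7)
        h2, p2, src2, tgt2, k2 = planted_influence_bundle(seed=7, branch_width=1)
        weak = permutation_significance(h2, p2, src2, tgt2, k2, n_perm=30, n_swaps=1000, seed=7)
        assert strong.n_ge <= weak.n_ge
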