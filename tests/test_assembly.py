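"""Phase edges, block assembly and configuration search."""

import random

import numpy as np
import pytest

from haplophase.assembly import (
    build_blocks,
    build_edges,
    enumerate_configuration,
    is_conflict_free,
    phase_all,
    phase_subblocks,
    resolve_block,
    split_subblocks,
)
from haplophase.noise import NoiseModel
from haplophase.reads import AlleleObservation

from conftest import (
    brute_force_best_support,
    make_edge,
    make_variant,
    random_consistent_block,
)


def pair_observations(pairs, variant_a, variant_b):
    """Observations for fragments covering two variants.

    ``pairs`` is a list of (class_a, class_b) per fragment.
    """
    out = []
    for i, (ca, cb) in enumerate(pairs):
        out.append(AlleleObservation(f"f{i}", variant_a.id, ca, 30))
        out.append(AlleleObservation(f"f{i}", variant_b.id, cb, 30))
    return out


class TestBuildEdges:
    va, vb = make_variant(100), make_variant(200)
    vmap = {va.id: va, vb.id: vb}
    noise = NoiseModel(0.01)

    def test_no_shared_fragment_no_edge(self):
        observations = [
            AlleleObservation("f1", self.va.id, "ref", 30),
            AlleleObservation("f2", self.vb.id, "ref", 30),
        ]
        assert build_edges(observations, self.vmap, self.noise) == []

    def test_unanimous_cis_edge_passes(self):
        observations = pair_observations([("ref", "ref")] * 4 + [("alt", "alt")] * 4,
                                         self.va, self.vb)
        (edge,) = build_edges(observations, self.vmap, self.noise)
        assert (edge.chosen, edge.n_supporting, edge.n_total) == ("cis", 8, 8)
        assert edge.p_value == pytest.approx(1.0)
        assert edge.passed

    def test_tied_edge_discarded(self):
        observations = pair_observations(
            [("ref", "ref")] * 5 + [("ref", "alt")] * 5, self.va, self.vb
        )
        assert build_edges(observations, self.vmap, self.noise) == []

    def test_conflicted_edge_fails_threshold(self):
        observations = pair_observations(
            [("ref", "ref")] * 6 + [("ref", "alt")] * 4, self.va, self.vb
        )
        (edge,) = build_edges(observations, self.vmap, self.noise, threshold=0.01)
        assert edge.chosen == "cis" and not edge.passed

    def test_other_alleles_not_informative(self):
        observations = pair_observations(
            [("other", "ref")] * 3 + [("ref", "ref")] * 2, self.va, self.vb
        )
        (edge,) = build_edges(observations, self.vmap, self.noise)
        assert edge.n_total == 2


class TestBuildBlocks:
    def test_transitive_connection(self):
        edges = [make_edge("A", "B"), make_edge("B", "C")]
        assert build_blocks(edges) == [["A", "B", "C"]]

    def test_disjoint_components(self):
        edges = [make_edge("A", "B"), make_edge("C", "D")]
        assert build_blocks(edges) == [["A", "B"], ["C", "D"]]

    def test_failed_edges_excluded(self):
        edges = [make_edge("A", "B"), make_edge("B", "C", passed=False)]
        assert build_blocks(edges) == [["A", "B"]]

    def test_matches_union_find_oracle(self):
        rng = np.random.default_rng(42)
        nodes = [f"v{i}" for i in range(400)]
        edges = [
            make_edge(*sorted(rng.choice(nodes, size=2, replace=False)))
            for _ in range(1000)
        ]
        parent = {n: n for n in nodes}

        def find(x):
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for e in edges:
            parent[find(e.variant_a)] = find(e.variant_b)
        oracle = {}
        for n in nodes:
            oracle.setdefault(find(n), set()).add(n)
        expected = sorted(
            (sorted(c) for c in oracle.values() if len(c) >= 2),
            key=lambda c: c[0],
        )
        assert build_blocks(edges) == expected


class TestConflictFree:
    def test_consistent_cis_chain(self):
        edges = [make_edge("A", "B", "cis"), make_edge("B", "C", "cis")]
        free, parity = is_conflict_free(["A", "B", "C"], edges)
        assert free
        assert parity["A"] == parity["B"] == parity["C"]

    def test_odd_cycle_not_conflict_free(self):
        edges = [
            make_edge("A", "B", "cis"),
            make_edge("B", "C", "cis"),
            make_edge("A", "C", "trans"),
        ]
        free, parity = is_conflict_free(["A", "B", "C"], edges)
        assert not free and parity is None

    def test_agrees_with_enumeration_when_free(self):
        rng = np.random.default_rng(7)
        for _ in range(30):
            n = int(rng.integers(2, 11))
            vids, vmap, edges, truth = random_consistent_block(
                rng, n, fidelity=1.0, extra_edge_prob=0.3
            )
            free, parity = is_conflict_free(vids, edges)
            assert free
            enum_parity, support, ambiguous = enumerate_configuration(
                vids, edges, vmap
            )
            assert support == len(edges)
            rel = {v: parity[v] ^ parity[vids[0]] for v in vids}
            rel_enum = {v: enum_parity[v] ^ enum_parity[vids[0]] for v in vids}
            assert rel == rel_enum


class TestEnumerateConfiguration:
    def test_single_cis_edge_block(self):
        va, vb = make_variant(100), make_variant(200)
        vmap = {va.id: va, vb.id: vb}
        parity, support, ambiguous = enumerate_configuration(
            [va.id, vb.id], [make_edge(va.id, vb.id, "cis")], vmap
        )
        assert parity[va.id] == parity[vb.id]
        assert support == 1 and not ambiguous

    def test_triangle_majority_two_of_three(self):
        va, vb, vc = (make_variant(p) for p in (100, 200, 300))
        vmap = {v.id: v for v in (va, vb, vc)}
        edges = [
            make_edge(va.id, vb.id, "cis"),
            make_edge(vb.id, vc.id, "cis"),
            make_edge(va.id, vc.id, "trans"),
        ]
        parity, support, ambiguous = enumerate_configuration(
            [va.id, vb.id, vc.id], edges, vmap
        )
        assert support == 2
        # three assignments tie at 2; the lexicographic tie-break selects
        # the all-cis configuration (haplotype string AAA < AAT < ATT)
        assert ambiguous
        assert parity[va.id] == parity[vb.id] == parity[vc.id]

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(40):
            n = int(rng.integers(2, 9))
            vids, vmap, edges, _ = random_consistent_block(
                rng, n, fidelity=0.75, extra_edge_prob=0.4
            )
            _, support, _ = enumerate_configuration(vids, edges, vmap)
            assert support == brute_force_best_support(vids, edges)

    def test_haplotype_swap_symmetry(self):
        # scoring all 2^(n-1) distinct assignments loses nothing relative
        # to the full 2^n space, which double-covers by label swap
        rng = np.random.default_rng(3)
        vids, vmap, edges, _ = random_consistent_block(rng, 7, 0.7, 0.5)
        _, support, _ = enumerate_configuration(vids, edges, vmap)
        assert support == brute_force_best_support(vids, edges)


class TestSplitSubblocks:
    @staticmethod
    def chain(n, extra=()):
        variants = [make_variant(100 * (i + 1)) for i in range(n)]
        vids = [v.id for v in variants]
        vmap = {v.id: v for v in variants}
        edges = [make_edge(vids[i], vids[i + 1]) for i in range(n - 1)]
        edges += [make_edge(vids[i], vids[j]) for i, j in extra]
        return vids, vmap, edges

    def test_under_threshold_identity(self):
        vids, vmap, edges = self.chain(12)
        assert split_subblocks(vids, edges, vmap, max_size=15) == [vids]

    def test_cut_at_minimal_span_boundary(self):
        # every boundary spanned by >=2 edges except between variants 9|10
        extra = [(i, i + 2) for i in range(18) if i not in (8, 9)]
        vids, vmap, edges = self.chain(20, extra)
        subblocks = split_subblocks(vids, edges, vmap, max_size=15)
        assert subblocks == [vids[:10], vids[10:]]

    def test_equal_spans_cut_leftmost(self):
        vids, vmap, edges = self.chain(20)
        subblocks = split_subblocks(vids, edges, vmap, max_size=15)
        assert subblocks[0] == [vids[0]]

    def test_all_subblocks_within_bound(self):
        rng = np.random.default_rng(5)
        vids, vmap, edges, _ = random_consistent_block(rng, 40, 0.95, 0.2)
        for sub in split_subblocks(vids, edges, vmap, max_size=15):
            assert 1 <= len(sub) <= 15


class TestPhaseSubblocks:
    def test_concordant_edges_merge_units(self):
        vids, vmap, edges = TestSplitSubblocks.chain(6)
        edges += [
            make_edge(vids[2], vids[3]),
            make_edge(vids[1], vids[4]),
        ]
        blocks = phase_subblocks([vids[:3], vids[3:]], edges, vmap)
        assert len(blocks) == 1
        parity = blocks[0].parity
        assert len(set(parity.values())) == 1  # all-cis chain

    def test_no_connecting_edges_stay_separate(self):
        variants = [make_variant(100 * (i + 1)) for i in range(6)]
        vids = [v.id for v in variants]
        vmap = {v.id: v for v in variants}
        edges = [
            make_edge(vids[0], vids[1]), make_edge(vids[1], vids[2]),
            make_edge(vids[3], vids[4]), make_edge(vids[4], vids[5]),
        ]
        blocks = phase_subblocks([vids[:3], vids[3:]], edges, vmap)
        assert len(blocks) == 2

    def test_split_then_merge_matches_full_enumeration(self):
        rng = np.random.default_rng(17)
        for _ in range(10):
            n = int(rng.integers(16, 19))
            vids, vmap, edges, _ = random_consistent_block(rng, n, 0.95, 0.5)
            subblocks = split_subblocks(vids, edges, vmap, max_size=15)
            assert len(subblocks) > 1
            merged = phase_subblocks(subblocks, edges, vmap)
            assert len(merged) == 1
            _, full_support, _ = enumerate_configuration(vids, edges, vmap)
            assert merged[0].n_supporting_edges == full_support


class TestResolveAndDeterminism:
    def test_conflict_free_large_block_bypasses_splitting(self):
        rng = np.random.default_rng(23)
        vids, vmap, edges, truth = random_consistent_block(rng, 30, 1.0, 0.2)
        (block,) = resolve_block(vids, edges, vmap, max_size=15)
        assert block.conflict_free
        assert block.n_supporting_edges == block.n_total_edges == len(edges)
        rel = {v: block.parity[v] ^ block.parity[vids[0]] for v in vids}
        true_rel = {v: truth[v] ^ truth[vids[0]] for v in vids}
        assert rel == true_rel

    def test_each_variant_in_exactly_one_block(self):
        rng = np.random.default_rng(29)
        vids, vmap, edges, _ = random_consistent_block(rng, 25, 0.9, 0.3)
        blocks = phase_all(edges, vmap)
        seen = [v for b in blocks for v in b.variants]
        assert len(seen) == len(set(seen))

    def test_edge_order_invariance(self):
        rng = np.random.default_rng(31)
        vids, vmap, edges, _ = random_consistent_block(rng, 20, 0.9, 0.3)
        blocks_a = phase_all(edges, vmap)
        shuffled = list(edges)
        random.Random(0).shuffle(shuffled)
        blocks_b = phase_all(shuffled, vmap)
        assert [(b.variants, b.parity) for b in blocks_a] == [
            (b.variants, b.parity) for b in blocks_b
        ]
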