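"""Haplotypic counts, gene-level aggregation and allelic imbalance."""

import numpy as np
import pytest

from haplophase.anchoring import AnchoredBlock
from haplophase.expression import (
    Gene,
    allelic_imbalance_test,
    bh_adjust,
    gene_level_ae,
    haplotypic_counts,
)
from haplophase.reads import AlleleObservation

from conftest import make_block, make_variant


def hap_obs(fragment_id, block, variants, haplotype, subset=None):
    """Observations of ``fragment_id`` consistent with haplotype A (0) or B (1)."""
    out = []
    for v in variants:
        if subset is not None and v.id not in subset:
            continue
        p = block.parity[v.id]
        klass = ("ref" if p == 0 else "alt") if haplotype == 0 else (
            "alt" if p == 0 else "ref")
        out.append(AlleleObservation(fragment_id, v.id, klass, 30))
    return out


@pytest.fixture
def simple_block():
    variants = [make_variant(p, "A", "G") for p in (100, 200, 300)]
    parity = {variants[0].id: 0, variants[1].id: 1, variants[2].id: 0}
    return make_block(variants, parity), variants


class TestHaplotypicCounts:
    def test_multi_variant_fragment_counts_once(self, simple_block):
        block, variants = simple_block
        observations = hap_obs("f1", block, variants, haplotype=0)
        hc = haplotypic_counts(block, observations)
        assert (hc.count_a, hc.count_b, hc.n_discarded) == (1, 0, 0)

    def test_internal_conflict_discarded(self, simple_block):
        block, variants = simple_block
        observations = (
            hap_obs("f1", block, variants[:1], 0) + hap_obs("f1", block, variants[1:2], 1)
        )
        hc = haplotypic_counts(block, observations)
        assert (hc.count_a, hc.count_b, hc.n_discarded) == (0, 0, 1)

    def test_other_allele_discarded(self, simple_block):
        block, variants = simple_block
        observations = [AlleleObservation("f1", variants[0].id, "other", 30)]
        hc = haplotypic_counts(block, observations)
        assert (hc.count_a, hc.count_b, hc.n_discarded) == (0, 0, 1)

    def test_mixed_fragment_population(self, simple_block):
        block, variants = simple_block
        observations = []
        for i in range(10):
            observations += hap_obs(f"a{i}", block, variants[:2], 0)
        for i in range(4):
            observations += hap_obs(f"b{i}", block, variants, 1)
        observations += (
            hap_obs("c0", block, variants[:1], 0) + hap_obs("c0", block, variants[2:], 1)
        )
        hc = haplotypic_counts(block, observations)
        assert (hc.count_a, hc.count_b, hc.n_discarded) == (10, 4, 1)


def two_block_gene(orientation2="config1"):
    """Gene with two blocks: counts (6,2) and (4,1) in block-local labels."""
    v1 = [make_variant(p, "A", "G") for p in (100, 200)]
    v2 = [make_variant(p, "C", "T") for p in (500, 600)]
    b1 = make_block(v1, {v.id: 0 for v in v1})
    b2 = make_block(v2, {v.id: 0 for v in v2})
    observations = []
    for i in range(6):
        observations += hap_obs(f"x{i}", b1, v1, 0)
    for i in range(2):
        observations += hap_obs(f"y{i}", b1, v1, 1)
    for i in range(4):
        observations += hap_obs(f"p{i}", b2, v2, 0)
    for i in range(1):
        observations += hap_obs(f"q{i}", b2, v2, 1)
    ab1 = AnchoredBlock(b1, 0.4, 0.0, "config1", 1.0)
    ab2 = AnchoredBlock(b2, 0.4, 0.0, orientation2, 1.0)
    gene = Gene("GENE1", "chr1", 0, 1000)
    vmap = {v.id: v for v in v1 + v2}
    return gene, [ab1, ab2], observations, vmap


class TestGeneLevelAE:
    def test_single_block_identity(self):
        gene, blocks, observations, vmap = two_block_gene()
        (res,) = gene_level_ae([gene], blocks[:1], observations, vmap)
        assert (res.count_a, res.count_b) == (6, 2)

    def test_same_orientation_sums(self):
        gene, blocks, observations, vmap = two_block_gene("config1")
        (res,) = gene_level_ae([gene], blocks, observations, vmap)
        assert (res.count_a, res.count_b) == (10, 3)
        assert res.n_blocks == 2 and res.anchored

    def test_opposite_orientation_flips_before_summing(self):
        gene, blocks, observations, vmap = two_block_gene("config2")
        (res,) = gene_level_ae([gene], blocks, observations, vmap)
        assert (res.count_a, res.count_b) == (7, 6)

    def test_unanchored_gene_uses_best_supported_block_only(self):
        gene, blocks, observations, vmap = two_block_gene()
        unanchored = [
            AnchoredBlock(ab.block, 0.0, 0.0, "unanchored", 0.5) for ab in blocks
        ]
        (res,) = gene_level_ae([gene], unanchored, observations, vmap)
        assert (res.count_a, res.count_b) == (6, 2)
        assert res.n_blocks == 1 and not res.anchored

    def test_gene_without_phased_variants_absent(self):
        gene, blocks, observations, vmap = two_block_gene()
        empty_gene = Gene("EMPTY", "chr1", 5000, 6000)
        results = gene_level_ae([gene, empty_gene], blocks, observations, vmap)
        assert [r.gene_id for r in results] == ["GENE1"]

    def test_fragment_spanning_two_blocks_counted_once(self):
        gene, blocks, observations, vmap = two_block_gene()
        b1, b2 = blocks[0].block, blocks[1].block
        v1 = [vmap[v] for v in b1.variants]
        v2 = [vmap[v] for v in b2.variants]
        observations = observations + hap_obs("span", b1, v1, 0) + hap_obs(
            "span", b2, v2, 0)
        (res,) = gene_level_ae([gene], blocks, observations, vmap)
        assert (res.count_a, res.count_b) == (11, 3)

    def test_anti_double_counting_vs_naive_per_variant_sum(self):
        # every fragment spans both variants of its block: the gene count
        # equals the distinct-fragment count while naive per-variant
        # summation is strictly larger
        gene, blocks, observations, vmap = two_block_gene()
        (res,) = gene_level_ae([gene], blocks, observations, vmap)
        n_distinct = len({o.fragment_id for o in observations})
        assert res.count_a + res.count_b == n_distinct == 13
        naive = len(observations)  # one count per variant per fragment
        assert naive > res.count_a + res.count_b

    def test_flip_consistency(self):
        flip = {"config1": "config2", "config2": "config1"}
        gene, blocks, observations, vmap = two_block_gene("config2")
        flipped = [
            AnchoredBlock(ab.block, ab.beta, ab.alpha, flip[ab.orientation],
                          ab.confidence)
            for ab in blocks
        ]
        (res,) = gene_level_ae([gene], blocks, observations, vmap)
        (res_f,) = gene_level_ae([gene], flipped, observations, vmap)
        assert (res.count_a, res.count_b) == (res_f.count_b, res_f.count_a)


class TestImbalanceTest:
    def test_perfect_balance(self):
        assert allelic_imbalance_test(5, 5) == pytest.approx(1.0)

    def test_extreme_outcome_closed_form(self):
        assert allelic_imbalance_test(10, 0) == pytest.approx(1 / 512, rel=1e-12)
        assert allelic_imbalance_test(0, 10) == pytest.approx(1 / 512, rel=1e-12)

    def test_zero_total_excluded(self):
        with pytest.raises(ValueError):
            allelic_imbalance_test(0, 0)

    def test_bh_matches_step_up_oracle(self):
        pvals = [0.001, 0.02, 0.9]
        # step-up: p(i) * m / i with monotonicity enforcement
        assert bh_adjust(pvals) == pytest.approx([0.003, 0.03, 0.9])


def test_deep_coverage_recovers_allelic_ratio():
    """With true allelic ratio r, count_a/(count_a+count_b) -> r."""
    from haplophase.reads import FilterSettings, extract_observations
    from haplophase.simulate import simulate_diploid, simulate_fragments

    r = 0.7
    truth = simulate_diploid(40, 6000, seed=5)
    sim = simulate_fragments(truth, coverage=60, epsilon=0.0,
                             allelic_ratio=r, seed=6)
    import tempfile, pathlib
    with tempfile.TemporaryDirectory() as tmp:
        sam = sim.write_sam(pathlib.Path(tmp) / "x.sam")
        observations, _ = extract_observations(
            sam, truth.variants, FilterSettings(min_mapq=40))
    block = make_block(truth.variants, truth.parity)
    hc = haplotypic_counts(block, observations)
    n = hc.count_a + hc.count_b
    se = np.sqrt(r * (1 - r) / n)
    assert hc.count_a / n == pytest.approx(r, abs=3 * se)
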