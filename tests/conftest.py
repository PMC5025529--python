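"""Shared fixtures: in-memory SAM records, variants, and edge builders."""

from __future__ import annotations

import itertools
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pysam
import pytest

from haplophase.assembly import HaplotypeBlock, PhaseEdge
from haplophase.variants import HetVariant


@pytest.fixture
def sam_header() -> pysam.AlignmentHeader:
    return pysam.AlignmentHeader.from_dict(
        {"HD": {"VN": "1.6"}, "SQ": [{"SN": "chr1", "LN": 1_000_000},
                                     {"SN": "chr2", "LN": 1_000_000}]}
    )


def make_read(
    header: pysam.AlignmentHeader,
    name: str = "r1",
    pos: int = 100,
    seq: str = "ACGT",
    cigar: Optional[List[Tuple[int, int]]] = None,
    mapq: int = 60,
    baseq: int = 30,
    flag: int = 0,
    tlen: int = 0,
    align_score: int = 100,
    chrom: str = "chr1",
) -> pysam.AlignedSegment:
    a = pysam.AlignedSegment(header)
    a.query_name = name
    a.flag = flag
    a.reference_id = header.get_tid(chrom)
    a.reference_start = pos
    a.mapping_quality = mapq
    a.cigartuples = cigar or [(0, len(seq))]
    a.query_sequence = seq
    a.query_qualities = pysam.qualitystring_to_array(chr(baseq + 33) * len(seq))
    a.template_length = tlen
    a.set_tag("AS", align_score)
    return a


def make_variant(
    pos: int, ref: str = "A", alt: str = "T", chrom: str = "chr1",
    pop_phase: Optional[str] = None, maf: Optional[float] = None,
    is_indel: bool = False,
) -> HetVariant:
    return HetVariant(
        id=HetVariant.make_id(chrom, pos, ref, alt),
        chrom=chrom, pos=pos, ref=ref, alt=alt,
        pop_phase=pop_phase, maf=maf, is_indel=is_indel,
    )


def make_edge(
    a: str, b: str, chosen: str = "cis",
    n_majority: int = 5, n_minority: int = 0,
    p_value: float = 1.0, passed: bool = True,
) -> PhaseEdge:
    n_cis, n_trans = (
        (n_majority, n_minority) if chosen == "cis" else (n_minority, n_majority)
    )
    return PhaseEdge(a, b, n_cis, n_trans, chosen, p_value, passed)


def make_block(
    variants: Sequence[HetVariant], parity: Dict[str, int],
    conflict_free: bool = True,
) -> HaplotypeBlock:
    ordered = sorted(variants, key=lambda v: (v.chrom, v.pos))
    return HaplotypeBlock(
        variants=tuple(v.id for v in ordered),
        parity=dict(parity),
        alleles_a="".join(v.ref if parity[v.id] == 0 else v.alt for v in ordered),
        alleles_b="".join(v.alt if parity[v.id] == 0 else v.ref for v in ordered),
        chrom=ordered[0].chrom,
        conflict_free=conflict_free,
        n_supporting_edges=0,
        n_total_edges=0,
    )


def brute_force_best_support(
    block: Sequence[str], edges: Sequence[PhaseEdge]
) -> int:
    """Independent exhaustive search over all 2^n allele assignments."""
    best = -1
    rest = list(block[1:])
    for bits in itertools.product((0, 1), repeat=len(rest)):
        parity = {block[0]: 0}
        parity.update(zip(rest, bits))
        score = sum(
            1 for e in edges
            if (parity[e.variant_a] ^ parity[e.variant_b]) == e.is_trans
        )
        best = max(best, score)
    return best


def random_consistent_block(
    rng: np.random.Generator,
    n: int,
    fidelity: float,
    extra_edge_prob: float,
) -> Tuple[List[str], Dict[str, HetVariant], List[PhaseEdge], Dict[str, int]]:
    """A connected block with edges drawn around a random true configuration.

    A chain keeps the block connected; every other pair joins with
    ``extra_edge_prob``. Each edge's orientation matches the truth with
    probability ``fidelity``.
    """
    variants = [make_variant(100 * (i + 1), "A", "C") for i in range(n)]
    vids = [v.id for v in variants]
    vmap = {v.id: v for v in variants}
    truth = {vid: int(rng.integers(0, 2)) for vid in vids}
    pairs = [(i, i + 1) for i in range(n - 1)]
    for i in range(n):
        for j in range(i + 2, n):
            if rng.random() < extra_edge_prob:
                pairs.append((i, j))
    edges = []
    for i, j in sorted(set(pairs)):
        rel = truth[vids[i]] ^ truth[vids[j]]
        if rng.random() > fidelity:
            rel ^= 1
        edges.append(make_edge(vids[i], vids[j], "trans" if rel else "cis"))
    return vids, vmap, edges, truth
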