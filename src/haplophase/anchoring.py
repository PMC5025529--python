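"""Genome-wide phase anchoring of read-backed blocks.

Population phasing is accurate for common variants and unreliable for
rare ones, so each block variant that carries a population phase votes
for one of the two genome-wide orientations of the block, weighted by
its minor allele frequency:

    α = Σ MAF of variants supporting configuration 1
    β = Σ MAF of variants supporting configuration 2

Configuration 1 means read-backed haplotype A equals population
haplotype 1. The orientation with the larger sum wins, with

    anchor phase confidence = max(α, β) / (α + β).

Blocks with α = β (including no voting variants at all) stay
unanchored and keep only their block-local phase.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Mapping, Optional

from .assembly import HaplotypeBlock
from .variants import HetVariant

__all__ = ["AnchoredBlock", "anchor_block"]


@dataclass(frozen=True)
class AnchoredBlock:
    block: HaplotypeBlock
    alpha: float
    beta: float
    orientation: str  # "config1" | "config2" | "unanchored"
    confidence: float

    @property
    def anchored(self) -> bool:
        return self.orientation != "unanchored"

    def genome_parity(self, variant_id: str) -> int:
        """Parity of a member variant in the genome-wide orientation.

        0: genome haplotype 1 carries the ref allele. For unanchored
        blocks this is the block-local parity.
        """
        flip = 1 if self.orientation == "config2" else 0
        return self.block.parity[variant_id] ^ flip


def anchor_block(
    block: HaplotypeBlock,
    variant_map: Mapping[str, HetVariant],
) -> AnchoredBlock:
    """MAF-weighted vote of the block's population-phased variants.

    Variants without a population phase or without a MAF contribute
    weight 0. A variant supports configuration 1 when its read-backed
    haplotype-A allele matches its population haplotype-1 allele.
    """
    alpha = 0.0
    beta = 0.0
    for vid in block.variants:
        v = variant_map[vid]
        pop = v.pop_parity
        if pop is None or v.maf is None:
            continue
        if block.parity[vid] == pop:
            alpha += v.maf
        else:
            beta += v.maf
    if alpha > beta:
        orientation = "config1"
    elif beta > alpha:
        orientation = "config2"
    else:
        orientation = "unanchored"
    total = alpha + beta
    confidence = max(alpha, beta) / total if total > 0 else 0.5
    return AnchoredBlock(block, alpha, beta, orientation, confidence)
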