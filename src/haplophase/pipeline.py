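"""End-to-end driver: BAM + VCF → phased, anchored haplotype blocks."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import pandas as pd

from . import anchoring, assembly, noise, reads, variants

log = logging.getLogger(__name__)

__all__ = ["PhasingConfig", "PhasingResult", "run_phasing", "run_phasing_files", "blocks_table"]


@dataclass(frozen=True)
class PhasingConfig:
    """Tunable settings for one phasing run.

    ``filters`` holds the per-library read filters (see
    ``reads.LIBRARY_PRESETS`` for the RNA/exome/genome presets);
    ``conflict_p`` is the edge-removal threshold of the conflicting-
    phase test; ``max_block_size`` bounds the exhaustive configuration
    search; ``default_epsilon`` is used when the substitution rate
    cannot be estimated from the data.
    """

    filters: reads.FilterSettings = field(default_factory=reads.FilterSettings)
    conflict_p: float = assembly.DEFAULT_CONFLICT_P
    max_block_size: int = assembly.DEFAULT_MAX_BLOCK
    default_epsilon: float = noise.DEFAULT_EPSILON
    include_indels: bool = False

    @classmethod
    def preset(cls, library: str, **overrides) -> "PhasingConfig":
        return cls(filters=reads.LIBRARY_PRESETS[library], **overrides)


@dataclass
class PhasingResult:
    variants: List[variants.HetVariant]
    variant_map: Dict[str, variants.HetVariant]
    observations: List[reads.AlleleObservation]
    noise_model: noise.NoiseModel
    edges: List[assembly.PhaseEdge]
    blocks: List[assembly.HaplotypeBlock]
    anchored_blocks: List[anchoring.AnchoredBlock]
    stats: Dict[str, object]


def run_phasing(
    bam_path: str | Path,
    het_variants: Sequence[variants.HetVariant],
    config: Optional[PhasingConfig] = None,
) -> PhasingResult:
    """Run the full read-backed phasing pipeline on in-memory variants."""
    config = config or PhasingConfig()
    variant_map = {v.id: v for v in het_variants}
    observations, stats = reads.extract_observations(
        bam_path, het_variants, config.filters
    )
    model = noise.estimate_epsilon(observations, config.default_epsilon)
    edges = assembly.build_edges(
        observations, variant_map, model, config.conflict_p
    )
    blocks = assembly.phase_all(edges, variant_map, config.max_block_size)
    anchored = [anchoring.anchor_block(b, variant_map) for b in blocks]
    stats.update(
        epsilon=model.epsilon,
        n_edges=len(edges),
        n_edges_passed=sum(e.passed for e in edges),
        n_blocks=len(blocks),
        n_variants_phased=sum(len(b) for b in blocks),
    )
    log.info("phasing summary: %s", stats)
    return PhasingResult(
        list(het_variants), variant_map, observations, model, edges,
        blocks, anchored, stats,
    )


def run_phasing_files(
    bam_path: str | Path,
    vcf_path: str | Path,
    sample: str,
    config: Optional[PhasingConfig] = None,
    blacklist_path: Optional[str | Path] = None,
) -> PhasingResult:
    """File-based entry point: load variants from VCF, then phase."""
    config = config or PhasingConfig()
    blacklist = (
        variants.load_blacklist(blacklist_path) if blacklist_path else None
    )
    hets = variants.load_het_variants(
        vcf_path, sample, include_indels=config.include_indels,
        blacklist=blacklist,
    )
    return run_phasing(bam_path, hets, config)


def blocks_table(result: PhasingResult) -> pd.DataFrame:
    """Tabular block report (one row per phased haplotype block)."""
    rows = []
    for i, ab in enumerate(result.anchored_blocks):
        b = ab.block
        start, end = b.span
        rows.append(
            {
                "block_id": f"block_{i}",
                "chrom": b.chrom,
                "start": start,
                "end": end,
                "n_variants": len(b),
                "variants": ",".join(b.variants),
                "haplotype_a": b.alleles_a,
                "haplotype_b": b.alleles_b,
                "conflict_free": b.conflict_free,
                "ambiguous": b.ambiguous,
                "n_supporting_edges": b.n_supporting_edges,
                "n_total_edges": b.n_total_edges,
                "anchor_orientation": ab.orientation,
                "anchor_confidence": ab.confidence,
                "alpha": ab.alpha,
                "beta": ab.beta,
            }
        )
    return pd.DataFrame(rows)
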