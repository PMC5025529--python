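"""Per-fragment allele observation extraction from aligned reads.

A *fragment* (read pair, or a single read for single-end libraries) is
the unit of phase evidence. Reads are filtered on duplicate/secondary/
supplementary flags, mapping quality, insert size and a per-library
alignment-score quantile cutoff; bases are filtered on base quality.
Overlapping mates that agree at a variant yield one observation; mates
that disagree yield none.
"""

from __future__ import annotations

import logging
import math
from bisect import bisect_left, bisect_right
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, NamedTuple, Optional, Sequence, Tuple

import pysam

from .variants import HetVariant

log = logging.getLogger(__name__)

__all__ = [
    "FilterSettings",
    "Fragment",
    "AlleleObservation",
    "compute_alignment_score_cutoff",
    "filter_fragment",
    "assign_alleles",
    "extract_observations",
    "LIBRARY_PRESETS",
]


@dataclass(frozen=True)
class FilterSettings:
    """Read/fragment quality filters for one library.

    Defaults follow short-read DNA-seq conventions (exome preset);
    RNA-seq libraries typically use ``min_mapq=255`` (STAR's unique-
    mapper value) and no insert-size cap because of splicing.
    """

    min_mapq: int = 40
    min_baseq: int = 10
    max_insert_size: Optional[int] = 500
    as_quantile: float = 0.05


#: The per-library settings used throughout: RNA-seq (STAR unique MAPQ 255,
#: unbounded inserts), exome (MAPQ 40, 500 bp), whole genome (MAPQ 40, 1 kb).
LIBRARY_PRESETS: Dict[str, FilterSettings] = {
    "rna": FilterSettings(min_mapq=255, max_insert_size=None),
    "wes": FilterSettings(min_mapq=40, max_insert_size=500),
    "wgs": FilterSettings(min_mapq=40, max_insert_size=1000),
}


@dataclass
class Fragment:
    """One sequencing fragment: a read pair or a single read."""

    fragment_id: str
    mapq: int = 0
    alignment_score: Optional[int] = None
    insert_size: int = 0
    is_duplicate: bool = False
    is_secondary: bool = False
    is_supplementary: bool = False
    reads: List[pysam.AlignedSegment] = field(default_factory=list)

    def add_read(self, read: pysam.AlignedSegment) -> None:
        self.reads.append(read)
        mapqs = [r.mapping_quality for r in self.reads]
        self.mapq = min(mapqs)
        scores = [r.get_tag("AS") for r in self.reads if r.has_tag("AS")]
        # worst mate governs the fragment score
        self.alignment_score = min(scores) if scores else None
        if read.is_paired and read.template_length:
            self.insert_size = abs(read.template_length)
        self.is_duplicate = self.is_duplicate or read.is_duplicate


class AlleleObservation(NamedTuple):
    fragment_id: str
    variant_id: str
    allele_class: str  # "ref" | "alt" | "other"
    base_quality: int


def compute_alignment_score_cutoff(
    scores: Sequence[float], quantile: float
) -> Optional[float]:
    """Nearest-rank empirical quantile of the per-fragment alignment scores.

    Fragments scoring strictly below the returned threshold are dropped
    downstream. Returns ``None`` (filter disabled) when no scores are
    available or the quantile is 0.
    """
    scores = [s for s in scores if s is not None]
    if not scores:
        log.warning("no alignment scores available; score filter disabled")
        return None
    if quantile <= 0:
        return None
    k = math.ceil(quantile * len(scores))
    return sorted(scores)[max(k, 1) - 1]


def filter_fragment(
    fragment: Fragment,
    settings: FilterSettings,
    as_threshold: Optional[float] = None,
) -> bool:
    """Return True when the fragment passes all library-level filters."""
    if fragment.is_duplicate or fragment.is_secondary or fragment.is_supplementary:
        return False
    if fragment.mapq < settings.min_mapq:
        return False
    if (
        settings.max_insert_size is not None
        and fragment.insert_size > settings.max_insert_size
    ):
        return False
    if (
        as_threshold is not None
        and fragment.alignment_score is not None
        and fragment.alignment_score < as_threshold
    ):
        return False
    return True


VariantIndex = Dict[str, Tuple[List[int], List[HetVariant]]]


def index_variants(variants: Sequence[HetVariant]) -> VariantIndex:
    """Per-chromosome position-sorted index for overlap queries."""
    by_chrom: Dict[str, List[HetVariant]] = {}
    for v in variants:
        by_chrom.setdefault(v.chrom, []).append(v)
    index: VariantIndex = {}
    for chrom, vs in by_chrom.items():
        vs.sort(key=lambda v: v.pos)
        index[chrom] = ([v.pos - 1 for v in vs], vs)  # 0-based positions
    return index


def _read_alleles(
    read: pysam.AlignedSegment,
    index: VariantIndex,
    min_baseq: int,
) -> List[Tuple[HetVariant, str, int]]:
    """Alleles observed by one read at indexed SNV positions.

    Variants under N-skips (introns), deletions or clipped bases yield
    nothing; so do bases below ``min_baseq``.
    """
    entry = index.get(read.reference_name)
    if entry is None:
        return []
    positions, variants = entry
    lo = bisect_left(positions, read.reference_start)
    hi = bisect_right(positions, read.reference_end - 1)
    if lo >= hi:
        return []
    wanted = {positions[i]: variants[i] for i in range(lo, hi)}
    seq = read.query_sequence
    quals = read.query_qualities
    out: List[Tuple[HetVariant, str, int]] = []
    try:
        pairs = read.get_aligned_pairs(matches_only=True)
    except (ValueError, SystemError) as exc:
        log.warning("skipping read %s with inconsistent CIGAR: %s",
                    read.query_name, exc)
        return []
    for qpos, rpos in pairs:
        v = wanted.get(rpos)
        if v is None or v.is_indel:
            continue
        bq = quals[qpos] if quals is not None else 0
        if bq < min_baseq:
            continue
        base = seq[qpos].upper()
        if base == v.ref:
            klass = "ref"
        elif base == v.alt:
            klass = "alt"
        else:
            klass = "other"
        out.append((v, klass, bq))
    return out


def assign_alleles(
    fragment: Fragment,
    index: VariantIndex,
    min_baseq: int = 10,
) -> List[AlleleObservation]:
    """Reconcile the fragment's reads into one observation per variant.

    When both mates cover a variant: agreement keeps a single
    observation (highest base quality); disagreement discards the
    (fragment, variant) observation entirely.
    """
    per_variant: Dict[str, List[Tuple[str, int]]] = {}
    for read in fragment.reads:
        for v, klass, bq in _read_alleles(read, index, min_baseq):
            per_variant.setdefault(v.id, []).append((klass, bq))
    observations: List[AlleleObservation] = []
    for vid, calls in per_variant.items():
        classes = {c for c, _ in calls}
        if len(classes) > 1:
            continue  # mate disagreement
        klass, bq = max(calls, key=lambda cb: cb[1])
        observations.append(
            AlleleObservation(fragment.fragment_id, vid, klass, bq)
        )
    return observations


def collect_fragments(alignments) -> Dict[str, Fragment]:
    """Group mapped primary reads by query name into fragments."""
    fragments: Dict[str, Fragment] = {}
    for read in alignments:
        if read.is_unmapped or read.is_secondary or read.is_supplementary:
            continue
        frag = fragments.get(read.query_name)
        if frag is None:
            frag = fragments[read.query_name] = Fragment(read.query_name)
        frag.add_read(read)
    return fragments


def extract_observations(
    bam_path: str | Path,
    variants: Sequence[HetVariant],
    settings: FilterSettings = FilterSettings(),
) -> Tuple[List[AlleleObservation], Dict[str, int]]:
    """Run the full read-filtering and allele-assignment stage on a SAM/BAM.

    The alignment-score quantile cutoff is computed over fragments that
    already pass the MAPQ/flag/insert filters, then applied. Returns the
    observation list plus summary counts.
    """
    index = index_variants(variants)
    with pysam.AlignmentFile(str(bam_path), check_sq=False) as bam:
        fragments = collect_fragments(bam)
    prefiltered = [
        f for f in fragments.values() if filter_fragment(f, settings, None)
    ]
    cutoff = compute_alignment_score_cutoff(
        [f.alignment_score for f in prefiltered], settings.as_quantile
    )
    kept = [f for f in prefiltered if filter_fragment(f, settings, cutoff)]
    observations: List[AlleleObservation] = []
    for frag in sorted(kept, key=lambda f: f.fragment_id):
        observations.extend(assign_alleles(frag, index, settings.min_baseq))
    stats = {
        "n_fragments": len(fragments),
        "n_pass_prefilter": len(prefiltered),
        "n_pass_all": len(kept),
        "n_observations": len(observations),
        "as_cutoff": cutoff,
    }
    return observations, stats
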