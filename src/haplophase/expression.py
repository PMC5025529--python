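"""Haplotypic expression: unique-fragment counts per haplotype.

Summing per-variant allele counts across a phased region double-counts
any fragment that covers more than one variant. Here each distinct
fragment is assigned at most once per scope: to haplotype A or B when
every one of its observations matches that haplotype's alleles, or
discarded when it matches neither. Block counts aggregate to gene level
after flipping each anchored block to the common genome-wide
orientation; allelic imbalance is assessed with a two-sided exact
binomial test against 0.5 and Benjamini–Hochberg FDR across genes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import pandas as pd
from scipy.stats import binomtest
from statsmodels.stats.multitest import multipletests

from .anchoring import AnchoredBlock
from .assembly import HaplotypeBlock
from .reads import AlleleObservation

log = logging.getLogger(__name__)

__all__ = [
    "Gene",
    "HaplotypicCount",
    "GeneAEResult",
    "haplotypic_counts",
    "gene_level_ae",
    "allelic_imbalance_test",
    "bh_adjust",
    "load_genes_bed",
    "load_genes_gff3",
]


@dataclass(frozen=True)
class Gene:
    """Gene span in 0-based half-open genomic coordinates."""

    gene_id: str
    chrom: str
    start: int
    end: int

    def contains(self, chrom: str, pos_1based: int) -> bool:
        return chrom == self.chrom and self.start <= pos_1based - 1 < self.end


@dataclass(frozen=True)
class HaplotypicCount:
    """Unique-fragment counts for the two haplotypes of one scope."""

    scope: str
    count_a: int
    count_b: int
    n_discarded: int
    fragments_a: frozenset = frozenset()
    fragments_b: frozenset = frozenset()

    @property
    def total(self) -> int:
        return self.count_a + self.count_b

    def flipped(self) -> "HaplotypicCount":
        return HaplotypicCount(
            self.scope, self.count_b, self.count_a, self.n_discarded,
            self.fragments_b, self.fragments_a,
        )


@dataclass(frozen=True)
class GeneAEResult:
    gene_id: str
    count_a: int
    count_b: int
    n_discarded: int
    n_variants: int
    n_blocks: int
    anchored: bool
    anchor_confidence: Optional[float]
    imbalance_p: Optional[float] = None
    imbalance_fdr: Optional[float] = None


def haplotypic_counts(
    block: HaplotypeBlock,
    observations: Iterable[AlleleObservation],
    variant_subset: Optional[Sequence[str]] = None,
    scope: Optional[str] = None,
) -> HaplotypicCount:
    """Count unique fragments consistent with each haplotype of a block.

    A fragment overlapping one or more block variants counts once for
    haplotype A (resp. B) iff all of its observations at those variants
    match A's (resp. B's) alleles; fragments with conflicting or
    other-allele observations are discarded and reported.
    """
    members = set(variant_subset) if variant_subset is not None else set(block.variants)
    members &= set(block.variants)
    per_fragment: Dict[str, List[AlleleObservation]] = {}
    for obs in observations:
        if obs.variant_id in members:
            per_fragment.setdefault(obs.fragment_id, []).append(obs)
    frags_a, frags_b = set(), set()
    n_discarded = 0
    for fid, obs_list in per_fragment.items():
        matches_a = matches_b = True
        for obs in obs_list:
            if obs.allele_class == "other":
                matches_a = matches_b = False
                break
            p = block.parity[obs.variant_id]
            is_ref = obs.allele_class == "ref"
            # parity 0: haplotype A carries ref
            if is_ref != (p == 0):
                matches_a = False
            if is_ref != (p == 1):
                matches_b = False
        if matches_a and not matches_b:
            frags_a.add(fid)
        elif matches_b and not matches_a:
            frags_b.add(fid)
        else:
            n_discarded += 1
    return HaplotypicCount(
        scope=scope or f"{block.chrom}:{block.span[0]}-{block.span[1]}",
        count_a=len(frags_a),
        count_b=len(frags_b),
        n_discarded=n_discarded,
        fragments_a=frozenset(frags_a),
        fragments_b=frozenset(frags_b),
    )


def allelic_imbalance_test(count_a: int, count_b: int) -> float:
    """Two-sided exact binomial p-value against a balanced 0.5 null."""
    n = count_a + count_b
    if n < 1:
        raise ValueError("allelic imbalance test needs at least one fragment")
    return float(binomtest(count_a, n, 0.5).pvalue)


def bh_adjust(pvalues: Sequence[float]) -> List[float]:
    """Benjamini–Hochberg step-up adjusted p-values."""
    if len(pvalues) == 0:
        return []
    return list(multipletests(pvalues, method="fdr_bh")[1])


def gene_level_ae(
    genes: Sequence[Gene],
    anchored_blocks: Sequence[AnchoredBlock],
    observations: Sequence[AlleleObservation],
    variant_map: Mapping[str, "HetVariant"],
) -> List[GeneAEResult]:
    """Aggregate haplotypic counts to gene level.

    Within a gene, counts are recomputed over each block's variants
    falling inside the gene span, each anchored block is flipped to the
    common genome-wide orientation, and fragment sets are unioned so a
    fragment spanning two blocks still counts once. When a gene has no
    anchored block, only its single best-supported block contributes
    (guessing relative orientation would manufacture spurious imbalance).
    Genes with no phased variants are absent from the output.
    """
    results: List[GeneAEResult] = []
    for gene in genes:
        entries: List[Tuple[AnchoredBlock, HaplotypicCount, int]] = []
        for ab in anchored_blocks:
            inside = [
                vid for vid in ab.block.variants
                if gene.contains(variant_map[vid].chrom, variant_map[vid].pos)
            ]
            if not inside:
                continue
            hc = haplotypic_counts(ab.block, observations, inside, scope=gene.gene_id)
            if ab.orientation == "config2":
                hc = hc.flipped()
            entries.append((ab, hc, len(inside)))
        if not entries:
            continue
        anchored_entries = [e for e in entries if e[0].anchored]
        if anchored_entries:
            used = anchored_entries
            confidence = min(e[0].confidence for e in used)
            anchored = True
        else:
            used = [max(entries, key=lambda e: e[1].total)]
            confidence = None
            anchored = False
        set_a = frozenset().union(*(e[1].fragments_a for e in used))
        set_b = frozenset().union(*(e[1].fragments_b for e in used))
        conflict = set_a & set_b  # disagreeing assignment across blocks
        set_a, set_b = set_a - conflict, set_b - conflict
        n_discarded = sum(e[1].n_discarded for e in used) + len(conflict)
        results.append(
            GeneAEResult(
                gene_id=gene.gene_id,
                count_a=len(set_a),
                count_b=len(set_b),
                n_discarded=n_discarded,
                n_variants=sum(e[2] for e in used),
                n_blocks=len(used),
                anchored=anchored,
                anchor_confidence=confidence,
            )
        )
    tested = [r for r in results if r.count_a + r.count_b >= 1]
    pvals = [allelic_imbalance_test(r.count_a, r.count_b) for r in tested]
    fdrs = bh_adjust(pvals)
    by_gene = {r.gene_id: (p, q) for r, p, q in zip(tested, pvals, fdrs)}
    final: List[GeneAEResult] = []
    for r in results:
        p, q = by_gene.get(r.gene_id, (None, None))
        final.append(
            GeneAEResult(
                r.gene_id, r.count_a, r.count_b, r.n_discarded, r.n_variants,
                r.n_blocks, r.anchored, r.anchor_confidence, p, q,
            )
        )
    return final


def gene_ae_frame(results: Sequence[GeneAEResult]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in results])


def load_genes_bed(path) -> List[Gene]:
    """Gene spans from BED (0-based half-open; column 4 as gene id)."""
    genes: List[Gene] = []
    with open(path) as fh:
        for i, line in enumerate(fh):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            name = f[3] if len(f) > 3 else f"gene_{i}"
            genes.append(Gene(name, f[0], int(f[1]), int(f[2])))
    return genes


def load_genes_gff3(path) -> List[Gene]:
    """Gene spans from GFF3 ``gene`` features (1-based inclusive input)."""
    genes: List[Gene] = []
    with open(path) as fh:
        for i, line in enumerate(fh):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) < 9 or f[2] != "gene":
                continue
            attrs = dict(
                kv.split("=", 1) for kv in f[8].split(";") if "=" in kv
            )
            name = attrs.get("ID", attrs.get("gene_id", f"gene_{i}"))
            genes.append(Gene(name, f[0], int(f[3]) - 1, int(f[4])))
    return genes
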