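"""Heterozygous-variant I/O.

Reads heterozygous sites (with optional population phase and allele
frequency) from a VCF, and writes phased output VCF with phase-set and
anchor-confidence tags.

Coordinate conventions: VCF positions are 1-based; BED blacklists are
0-based half-open. Internally ``HetVariant.pos`` keeps the 1-based VCF
position and conversion happens only at the I/O boundary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence

import pysam
from intervaltree import IntervalTree

log = logging.getLogger(__name__)

__all__ = [
    "HetVariant",
    "load_blacklist",
    "load_het_variants",
    "write_phased_vcf",
]


@dataclass(frozen=True)
class HetVariant:
    """A single heterozygous biallelic SNV (or indel, when requested).

    ``pop_phase`` is the population-phasing orientation of the genotype
    ("0|1", "1|0") or ``None`` when the input genotype is unphased.
    ``maf`` is the folded minor allele frequency in [0, 0.5], ``None``
    when the input VCF carries no frequency.
    """

    id: str
    chrom: str
    pos: int  # 1-based, as in VCF
    ref: str
    alt: str
    pop_phase: Optional[str] = None
    maf: Optional[float] = None
    is_indel: bool = False

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise ValueError(f"ref == alt at {self.chrom}:{self.pos}")
        if self.maf is not None and not (0.0 <= self.maf <= 0.5):
            raise ValueError(f"folded MAF out of range: {self.maf}")

    @staticmethod
    def make_id(chrom: str, pos: int, ref: str, alt: str) -> str:
        return f"{chrom}:{pos}:{ref}:{alt}"

    @property
    def pop_parity(self) -> Optional[int]:
        """0 when population haplotype 1 carries the ref allele, 1 for alt."""
        if self.pop_phase == "0|1":
            return 0
        if self.pop_phase == "1|0":
            return 1
        return None


def fold_maf(af: Optional[float]) -> Optional[float]:
    """Fold an alternate-allele frequency to minor allele frequency."""
    if af is None:
        return None
    return min(float(af), 1.0 - float(af))


def load_blacklist(bed_path: str | Path) -> Dict[str, IntervalTree]:
    """Load a BED file (0-based half-open) into per-chromosome interval trees."""
    trees: Dict[str, IntervalTree] = {}
    with open(bed_path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            if end > start:
                trees.setdefault(chrom, IntervalTree()).addi(start, end)
    return trees


def _record_maf(rec: pysam.VariantRecord) -> Optional[float]:
    try:
        af = rec.info.get("AF")
    except (KeyError, ValueError):  # AF not declared in the header
        return None
    if af is None:
        return None
    if isinstance(af, (tuple, list)):
        af = af[0]
    return fold_maf(af)


def load_het_variants(
    vcf_path: str | Path,
    sample: str,
    include_indels: bool = False,
    blacklist: Optional[Mapping[str, IntervalTree]] = None,
) -> List[HetVariant]:
    """Read heterozygous variants for one sample from a VCF.

    Only biallelic heterozygous genotypes are returned. Indels are
    excluded unless ``include_indels``; sites falling inside
    ``blacklist`` regions (e.g. HLA genes) are removed. Population phase
    and folded MAF are populated when present in the record. Malformed
    records are skipped with a logged count.
    """
    vcf = pysam.VariantFile(str(vcf_path))
    if sample not in vcf.header.samples:
        raise ValueError(f"sample {sample!r} not present in {vcf_path}")

    variants: List[HetVariant] = []
    n_skipped = {"malformed": 0, "multiallelic": 0, "not_het": 0,
                 "indel": 0, "blacklisted": 0}
    for rec in vcf:
        try:
            alts = rec.alts
            if alts is None or len(alts) != 1:
                n_skipped["multiallelic"] += 1
                continue
            ref, alt = rec.ref, alts[0]
            call = rec.samples[sample]
            gt = call.get("GT")
            if gt is None or len(gt) != 2 or set(gt) != {0, 1}:
                n_skipped["not_het"] += 1
                continue
            is_indel = len(ref) != 1 or len(alt) != 1
            if is_indel and not include_indels:
                n_skipped["indel"] += 1
                continue
            if blacklist is not None:
                tree = blacklist.get(rec.chrom)
                if tree is not None and tree.overlaps(rec.pos - 1):
                    n_skipped["blacklisted"] += 1
                    continue
            pop_phase = None
            if call.phased:
                pop_phase = "0|1" if gt == (0, 1) else "1|0"
            variants.append(
                HetVariant(
                    id=HetVariant.make_id(rec.chrom, rec.pos, ref, alt),
                    chrom=rec.chrom,
                    pos=rec.pos,
                    ref=ref,
                    alt=alt,
                    pop_phase=pop_phase,
                    maf=_record_maf(rec),
                    is_indel=is_indel,
                )
            )
        except (ValueError, KeyError, TypeError) as exc:  # malformed record
            n_skipped["malformed"] += 1
            log.warning("skipping malformed VCF record: %s", exc)
    vcf.close()
    log.info("loaded %d het variants from %s (skipped: %s)",
             len(variants), vcf_path, n_skipped)
    return variants


def _build_header(variants: Sequence[HetVariant], sample: str) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    header.add_line('##INFO=<ID=AF,Number=A,Type=Float,Description="Allele frequency">')
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    header.add_line('##FORMAT=<ID=PS,Number=1,Type=Integer,Description="Phase set (read-backed block)">')
    header.add_line('##FORMAT=<ID=PC,Number=1,Type=Float,Description="Anchor phase confidence">')
    max_pos: Dict[str, int] = {}
    for v in variants:
        max_pos[v.chrom] = max(max_pos.get(v.chrom, 0), v.pos)
    for chrom, mp in max_pos.items():
        header.contigs.add(chrom, length=mp + 1000)
    header.add_sample(sample)
    return header


def write_phased_vcf(
    variants: Sequence[HetVariant],
    anchored_blocks: Iterable = (),
    out_path: str | Path = "phased.vcf",
    sample: str = "SAMPLE",
) -> Path:
    """Write variants with phased genotypes for block members.

    Each resolved block gets one phase set (``PS`` = smallest member
    position); anchored blocks additionally carry their anchor
    confidence in ``PC`` and are flipped to the genome-wide orientation.
    Variants in no block keep their input genotype representation.
    """
    # variant id -> (parity in genome orientation, phase set id, confidence)
    phased: Dict[str, tuple] = {}
    for ab in anchored_blocks:
        block = getattr(ab, "block", ab)
        orientation = getattr(ab, "orientation", None)
        confidence = getattr(ab, "confidence", None)
        flip = 1 if orientation == "config2" else 0
        ps = min(int(vid.split(":")[1]) for vid in block.variants)
        for vid in block.variants:
            conf = confidence if orientation in ("config1", "config2") else None
            phased[vid] = (block.parity[vid] ^ flip, ps, conf)

    out_path = Path(out_path)
    header = _build_header(variants, sample)
    with pysam.VariantFile(str(out_path), "w", header=header) as out:
        for v in sorted(variants, key=lambda v: (v.chrom, v.pos)):
            rec = out.new_record(
                contig=v.chrom, start=v.pos - 1, stop=v.pos - 1 + len(v.ref),
                alleles=(v.ref, v.alt),
            )
            if v.maf is not None:
                rec.info["AF"] = v.maf
            call = rec.samples[sample]
            if v.id in phased:
                parity, ps, conf = phased[v.id]
                call["GT"] = (0, 1) if parity == 0 else (1, 0)
                call.phased = True
                call["PS"] = ps
                if conf is not None:
                    call["PC"] = float(conf)
            elif v.pop_phase is not None:
                call["GT"] = (0, 1) if v.pop_phase == "0|1" else (1, 0)
                call.phased = True
            else:
                call["GT"] = (0, 1)
                call.phased = False
            out.write(rec)
    return out_path


def with_pop_phase(variant: HetVariant, parity: Optional[int],
                   maf: Optional[float] = None) -> HetVariant:
    """Return a copy of ``variant`` with population phase (and optionally MAF) set."""
    phase = None if parity is None else ("0|1" if parity == 0 else "1|0")
    kwargs = {"pop_phase": phase}
    if maf is not None:
        kwargs["maf"] = maf
    return replace(variant, **kwargs)
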