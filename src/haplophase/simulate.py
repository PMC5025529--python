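"""Synthetic diploid truth sets, error-bearing fragments and scoring.

Generates everything the phasing pipeline consumes — a random diploid
genome with heterozygous SNVs, paired (optionally spliced) sequencing
fragments carrying uniform substitution noise at rate ε, and a
population-phase reference with MAF-dependent switch error — together
with the ground truth needed to score phasing output. All randomness
flows through one numpy Generator seeded per call, so fixtures are
bit-reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Dict, List, Optional, Sequence, Set, Tuple

import numpy as np
import pysam

from .assembly import HaplotypeBlock
from .variants import HetVariant, with_pop_phase

__all__ = [
    "TruthSet",
    "SimulatedReads",
    "Concordance",
    "simulate_diploid",
    "simulate_fragments",
    "simulate_population_phase",
    "score_concordance",
    "default_switch_error",
]

_BASES = np.array(list("ACGT"))


@dataclass
class TruthSet:
    """Ground truth for one simulated diploid chromosome."""

    chrom: str
    length: int
    reference: str
    variants: List[HetVariant]
    parity: Dict[str, int]  # 0: haplotype 1 carries ref
    pop_parity: Optional[Dict[str, int]] = None
    switch_errors: Optional[Set[str]] = None
    genes: Optional[list] = None

    @property
    def variant_map(self) -> Dict[str, HetVariant]:
        return {v.id: v for v in self.variants}

    def haplotype(self, which: int) -> str:
        """Sequence of haplotype 0 or 1 (alt substituted where it belongs)."""
        seq = list(self.reference)
        for v in self.variants:
            carries_alt = self.parity[v.id] == 1 if which == 0 else self.parity[v.id] == 0
            if carries_alt:
                seq[v.pos - 1] = v.alt
        return "".join(seq)


def _draw_mafs(rng: np.random.Generator, n: int, maf_distribution) -> np.ndarray:
    if callable(maf_distribution):
        mafs = np.asarray(maf_distribution(rng, n), dtype=float)
    elif maf_distribution == "uniform":
        mafs = rng.uniform(0.01, 0.5, size=n)
    else:
        raise ValueError(f"unknown MAF distribution: {maf_distribution!r}")
    if np.any((mafs < 0) | (mafs > 0.5)):
        raise ValueError("MAFs must lie in [0, 0.5]")
    return mafs


def simulate_diploid(
    n_variants: int,
    chrom_length: int,
    maf_distribution="uniform",
    seed: int = 0,
    chrom: str = "chr1",
    positions: Optional[Sequence[int]] = None,
) -> TruthSet:
    """Random reference plus ``n_variants`` phased heterozygous SNVs.

    Positions are distinct (drawn uniformly unless given explicitly,
    1-based); each variant's haplotype-1 allele is a fair coin flip.
    """
    if n_variants > chrom_length:
        raise ValueError("more variants than positions available")
    rng = np.random.default_rng(seed)
    reference = "".join(rng.choice(_BASES, size=chrom_length))
    if positions is None:
        positions = np.sort(
            rng.choice(chrom_length, size=n_variants, replace=False)
        ) + 1
    else:
        positions = sorted(positions)
        if len(positions) != n_variants or len(set(positions)) != n_variants:
            raise ValueError("positions must be distinct and match n_variants")
    mafs = _draw_mafs(rng, n_variants, maf_distribution)
    variants: List[HetVariant] = []
    parity: Dict[str, int] = {}
    for i, pos in enumerate(positions):
        ref = reference[pos - 1]
        alt = rng.choice([b for b in "ACGT" if b != ref])
        v = HetVariant(
            id=HetVariant.make_id(chrom, int(pos), ref, alt),
            chrom=chrom, pos=int(pos), ref=ref, alt=str(alt),
            maf=float(mafs[i]),
        )
        variants.append(v)
        parity[v.id] = int(rng.integers(0, 2))
    return TruthSet(chrom, chrom_length, reference, variants, parity)


@dataclass
class _SimRead:
    qname: str
    flag: int
    pos: int  # 0-based genomic
    cigar: List[Tuple[int, int]]
    seq: str
    tlen: int
    mate_pos: int
    alignment_score: int
    mapq: int = 60
    base_quality: int = 30


@dataclass
class SimulatedReads:
    """Simulated alignment records plus fragment-origin truth labels."""

    reads: List[_SimRead]
    origins: Dict[str, int]  # fragment id -> originating haplotype (0/1)
    epsilon: float
    truth: TruthSet

    def write_sam(self, path: str | Path) -> Path:
        path = Path(path)
        header = {
            "HD": {"VN": "1.6", "SO": "coordinate"},
            "SQ": [{"SN": self.truth.chrom, "LN": self.truth.length}],
        }
        mode = "wb" if path.suffix == ".bam" else "w"
        with pysam.AlignmentFile(str(path), mode, header=header) as out:
            for r in sorted(self.reads, key=lambda r: (r.pos, r.qname, r.flag)):
                a = pysam.AlignedSegment(out.header)
                a.query_name = r.qname
                a.flag = r.flag
                a.reference_id = 0
                a.reference_start = r.pos
                a.mapping_quality = r.mapq
                a.cigartuples = r.cigar
                a.query_sequence = r.seq
                a.query_qualities = pysam.qualitystring_to_array(
                    chr(r.base_quality + 33) * len(r.seq)
                )
                a.next_reference_id = 0
                a.next_reference_start = r.mate_pos
                a.template_length = r.tlen
                a.set_tag("AS", r.alignment_score)
                out.write(a)
        return path


class _Transcript:
    """Maps transcript coordinates onto genomic exon blocks."""

    def __init__(self, exons: Sequence[Tuple[int, int]]):
        exons = sorted(exons)
        for (s1, e1), (s2, e2) in zip(exons, exons[1:]):
            if e1 > s2:
                raise ValueError("exons must not overlap")
        if any(e <= s for s, e in exons):
            raise ValueError("empty exon")
        self.exons = exons
        self.length = sum(e - s for s, e in exons)
        self._offsets = np.cumsum([0] + [e - s for s, e in exons])

    def blocks(self, t0: int, t1: int) -> List[Tuple[int, int]]:
        """Genomic (start, end) blocks covered by transcript interval [t0, t1)."""
        out: List[Tuple[int, int]] = []
        for (gs, ge), off in zip(self.exons, self._offsets):
            lo = max(t0, off)
            hi = min(t1, off + (ge - gs))
            if lo < hi:
                out.append((gs + (lo - off), gs + (hi - off)))
        return out


def _noisy_base(base: str, rng: np.random.Generator, epsilon: float) -> str:
    if epsilon > 0 and rng.random() < 3.0 * epsilon:
        return rng.choice([b for b in "ACGT" if b != base])
    return base


def _blocks_to_cigar(blocks: Sequence[Tuple[int, int]]) -> List[Tuple[int, int]]:
    cigar: List[Tuple[int, int]] = []
    for i, (s, e) in enumerate(blocks):
        if i > 0:
            gap = s - blocks[i - 1][1]
            cigar.append((3, gap))  # N: skipped region (intron)
        cigar.append((0, e - s))  # M
    return cigar


def simulate_fragments(
    truth: TruthSet,
    read_length: int = 75,
    mean_insert: int = 300,
    sd_insert: float = 30.0,
    coverage: float = 30.0,
    epsilon: float = 0.005,
    splice_model: Optional[Sequence[Tuple[int, int]]] = None,
    paired: bool = True,
    allelic_ratio: float = 0.5,
    seed: int = 0,
) -> SimulatedReads:
    """Sample fragments from the two haplotypes with substitution noise.

    ``coverage`` is the expected fragment (insert-span) depth per
    position. Each emitted base is substituted to each of the other
    three nucleotides with probability ε. With ``splice_model`` (a list
    of genomic exon intervals, 0-based half-open) fragments are sampled
    in transcript space and written with N-gapped CIGARs, so mates and
    spliced segments can connect variants across introns.
    ``allelic_ratio`` is the probability a fragment originates from
    haplotype 0 (for simulating allelic imbalance).
    """
    if not 0 <= epsilon < 1.0 / 3.0:
        raise ValueError("epsilon must lie in [0, 1/3)")
    rng = np.random.default_rng(seed)
    haps = [truth.haplotype(0), truth.haplotype(1)]
    tx = _Transcript(splice_model) if splice_model is not None else None
    space = tx.length if tx is not None else truth.length
    min_len = 2 * read_length if paired else read_length
    mean_insert = max(mean_insert, min_len)
    n_fragments = max(1, int(round(coverage * space / mean_insert)))
    reads: List[_SimRead] = []
    origins: Dict[str, int] = {}

    for i in range(n_fragments):
        fid = f"frag{i:07d}"
        hap = 0 if rng.random() < allelic_ratio else 1
        origins[fid] = hap
        insert = int(np.clip(round(rng.normal(mean_insert, sd_insert)),
                             min_len, space))
        start = int(rng.integers(0, space - insert + 1))
        if paired:
            intervals = [(start, start + read_length),
                         (start + insert - read_length, start + insert)]
        else:
            intervals = [(start, start + read_length)]
        score = int(np.clip(round(rng.normal(100, 5)), 60, 110))
        mate_info: List[Tuple[int, List[Tuple[int, int]]]] = []
        for t0, t1 in intervals:
            blocks = tx.blocks(t0, t1) if tx is not None else [(t0, t1)]
            mate_info.append((blocks[0][0], blocks))
        span = (mate_info[-1][1][-1][1]) - mate_info[0][0]
        for mate_idx, (gpos, blocks) in enumerate(mate_info):
            bases = []
            for gs, ge in blocks:
                for g in range(gs, ge):
                    bases.append(_noisy_base(haps[hap][g], rng, epsilon))
            if paired:
                flag = 0x1 | 0x2 | (0x40 if mate_idx == 0 else 0x80)
                flag |= 0x20 if mate_idx == 0 else 0x10
                tlen = span if mate_idx == 0 else -span
                mate_pos = mate_info[1 - mate_idx][0]
            else:
                flag, tlen, mate_pos = 0, 0, -1
            reads.append(
                _SimRead(fid, flag, gpos, _blocks_to_cigar(blocks),
                         "".join(bases), tlen, mate_pos, score)
            )
    return SimulatedReads(reads, origins, epsilon, truth)


def default_switch_error(maf: float) -> float:
    """Population-phasing switch-error probability as a function of MAF.

    Rare variants are phased nearly at random (error → 0.5), common
    variants nearly perfectly: 0.5·exp(−8·MAF).
    """
    return 0.5 * math.exp(-8.0 * maf)


def simulate_population_phase(
    truth: TruthSet,
    switch_error_fn: Callable[[float], float] = default_switch_error,
    seed: int = 0,
) -> TruthSet:
    """Attach a population phase to every variant, with MAF-dependent error.

    Each variant's population phase equals the truth with probability
    1 − switch_error_fn(MAF); flipped variants are recorded in
    ``switch_errors``. Returns a new TruthSet whose variants carry the
    population phase (ready to be written to VCF).
    """
    rng = np.random.default_rng(seed)
    pop_parity: Dict[str, int] = {}
    switch_errors: Set[str] = set()
    new_variants: List[HetVariant] = []
    for v in truth.variants:
        err = switch_error_fn(v.maf if v.maf is not None else 0.0)
        if not 0.0 <= err <= 0.5:
            raise ValueError("switch error must lie in [0, 0.5]")
        flipped = bool(rng.random() < err)
        p = truth.parity[v.id] ^ int(flipped)
        pop_parity[v.id] = p
        if flipped:
            switch_errors.add(v.id)
        new_variants.append(with_pop_phase(v, p))
    return replace(
        truth, variants=new_variants,
        pop_parity=pop_parity, switch_errors=switch_errors,
    )


@dataclass(frozen=True)
class Concordance:
    """Pair-event phasing concordance against simulation truth."""

    n_pairs: int
    n_correct: int
    per_variant: Dict[str, float]

    @property
    def fraction(self) -> float:
        return self.n_correct / self.n_pairs if self.n_pairs else float("nan")


def score_concordance(
    truth: TruthSet, blocks: Sequence[HaplotypeBlock]
) -> Concordance:
    """Score every within-block variant pair against the true relative phase.

    A pair event is correct when the inferred relative phase
    (parity XOR) matches the truth; swapping a whole block's haplotype
    labels therefore never changes the score. Per-variant concordance
    is each variant's fraction of correct pair events.
    """
    n_pairs = 0
    n_correct = 0
    per_var_total: Dict[str, int] = {}
    per_var_correct: Dict[str, int] = {}
    for block in blocks:
        vids = [v for v in block.variants if v in truth.parity]
        for i in range(len(vids)):
            for j in range(i + 1, len(vids)):
                u, w = vids[i], vids[j]
                inferred = block.parity[u] ^ block.parity[w]
                true_rel = truth.parity[u] ^ truth.parity[w]
                ok = inferred == true_rel
                n_pairs += 1
                n_correct += ok
                for vid in (u, w):
                    per_var_total[vid] = per_var_total.get(vid, 0) + 1
                    per_var_correct[vid] = per_var_correct.get(vid, 0) + ok
    per_variant = {
        vid: per_var_correct[vid] / per_var_total[vid] for vid in per_var_total
    }
    return Concordance(n_pairs, n_correct, per_variant)
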