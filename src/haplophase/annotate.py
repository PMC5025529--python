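"""Allele-interaction annotation: cis/trans calls and compound-het triage.

Two heterozygous variants in the same gene are *trans* when their
alternate alleles sit on different haplotypes (a candidate compound
heterozygote, both gene copies hit) and *cis* when they share a
haplotype. Evidence classes, strongest first: ``read_backed`` (same
phase set), ``anchored`` (different phase sets joined by genome-wide
anchoring), ``population`` (population phasing only — reported but
flagged, since it is unreliable exactly for the rare variants this
workflow targets).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import pandas as pd

from .expression import Gene

__all__ = [
    "PhasedVariant",
    "AlleleInteraction",
    "classify_interactions",
    "prioritize_compound_hets",
    "FILTER_STEPS",
]


@dataclass(frozen=True)
class PhasedVariant:
    """One phased heterozygous variant with annotations, for one sample.

    ``alt_hap`` gives the haplotype (0 or 1) carrying the alternate
    allele within ``phase_set``; ``anchor_alt_hap`` the genome-wide
    haplotype when the variant's block was anchored; ``pop_alt_hap``
    the population-phasing assignment. ``af`` is the alternate allele
    frequency; ``score`` a deleteriousness score (e.g. a scaled CADD);
    ``effect`` an effect class such as LoF/probably_damaging.
    """

    id: str
    chrom: str
    pos: int
    sample: str = "sample"
    phase_set: Optional[str] = None
    alt_hap: Optional[int] = None
    anchor_alt_hap: Optional[int] = None
    pop_alt_hap: Optional[int] = None
    af: Optional[float] = None
    score: Optional[float] = None
    effect: str = "other"


@dataclass(frozen=True)
class AlleleInteraction:
    variant_a: PhasedVariant
    variant_b: PhasedVariant
    gene_id: str
    relationship: str  # "cis" | "trans"
    evidence: str  # "read_backed" | "anchored" | "population"

    @property
    def sample(self) -> str:
        return self.variant_a.sample


def _pair_relationship(a: PhasedVariant, b: PhasedVariant) -> Optional[Tuple[str, str]]:
    if (
        a.phase_set is not None
        and a.phase_set == b.phase_set
        and a.alt_hap is not None
        and b.alt_hap is not None
    ):
        rel = "cis" if a.alt_hap == b.alt_hap else "trans"
        return rel, "read_backed"
    if a.anchor_alt_hap is not None and b.anchor_alt_hap is not None:
        rel = "cis" if a.anchor_alt_hap == b.anchor_alt_hap else "trans"
        return rel, "anchored"
    if a.pop_alt_hap is not None and b.pop_alt_hap is not None:
        rel = "cis" if a.pop_alt_hap == b.pop_alt_hap else "trans"
        return rel, "population"
    return None


def classify_interactions(
    variants: Sequence[PhasedVariant],
    genes: Sequence[Gene],
) -> List[AlleleInteraction]:
    """Classify every same-gene, same-sample heterozygous pair as cis/trans.

    Pairs whose relative phase cannot be established from any evidence
    class are omitted (unknown phase). Each phased pair is classified
    exactly once, with the strongest available evidence.
    """
    interactions: List[AlleleInteraction] = []
    by_sample: Dict[str, List[PhasedVariant]] = {}
    for v in variants:
        by_sample.setdefault(v.sample, []).append(v)
    for sample in sorted(by_sample):
        vs = sorted(by_sample[sample], key=lambda v: (v.chrom, v.pos, v.id))
        for gene in genes:
            members = [v for v in vs if gene.contains(v.chrom, v.pos)]
            for i in range(len(members)):
                for j in range(i + 1, len(members)):
                    call = _pair_relationship(members[i], members[j])
                    if call is None:
                        continue
                    rel, evidence = call
                    interactions.append(
                        AlleleInteraction(members[i], members[j], gene.gene_id, rel, evidence)
                    )
    return interactions


FILTER_STEPS = ("all", "rare", "deleterious", "expressed", "phased", "trans", "cis")


def prioritize_compound_hets(
    interactions: Sequence[AlleleInteraction],
    max_af: float = 0.01,
    min_score: float = 15.0,
    expressed_genes: Optional[Set[str]] = None,
    allow_population_evidence: bool = False,
) -> Tuple[List[AlleleInteraction], List[AlleleInteraction], pd.DataFrame]:
    """Successive filter cascade for candidate compound heterozygotes.

    Steps: rare (both alternate AFs < ``max_af``), deleterious (both
    scores ≥ ``min_score``), expressed (gene in ``expressed_genes``),
    phased (read-backed or anchored evidence, unless population-only
    evidence is explicitly allowed), then the split into trans
    (candidate compound hets) and cis (deprioritized). Pairs missing an
    annotation needed by a filter drop out at that filter. Returns
    (trans pairs, cis pairs, per-sample counts at each step).
    """
    surviving = list(interactions)
    step_sets: Dict[str, List[AlleleInteraction]] = {"all": list(surviving)}

    def both(pair: AlleleInteraction, pred) -> bool:
        return pred(pair.variant_a) and pred(pair.variant_b)

    surviving = [
        p for p in surviving
        if both(p, lambda v: v.af is not None and v.af < max_af)
    ]
    step_sets["rare"] = list(surviving)
    surviving = [
        p for p in surviving
        if both(p, lambda v: v.score is not None and v.score >= min_score)
    ]
    step_sets["deleterious"] = list(surviving)
    if expressed_genes is not None:
        surviving = [p for p in surviving if p.gene_id in expressed_genes]
    step_sets["expressed"] = list(surviving)
    allowed = {"read_backed", "anchored"}
    if allow_population_evidence:
        allowed.add("population")
    surviving = [p for p in surviving if p.evidence in allowed]
    step_sets["phased"] = list(surviving)
    step_sets["trans"] = [p for p in surviving if p.relationship == "trans"]
    step_sets["cis"] = [p for p in surviving if p.relationship == "cis"]

    samples = sorted({p.sample for p in interactions})
    counts = pd.DataFrame(
        {
            step: [sum(1 for p in step_sets[step] if p.sample == s) for s in samples]
            for step in FILTER_STEPS
        },
        index=pd.Index(samples, name="sample"),
    )
    return step_sets["trans"], step_sets["cis"], counts
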