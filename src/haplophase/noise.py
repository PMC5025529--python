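"""Sequencing-noise model and the conflicting-phase binomial test.

The error model is uniform: a true nucleotide is misread as any given
other nucleotide with pairwise probability ε, so all 12 substitutions
are equally likely. At a heterozygous SNV the chance of observing one
of the two non-ref, non-alt bases is then 2ε, which gives the
library-wide estimator ε̂ = mismatching bases / (2 × total bases),
taken over sites that look cleanly biallelic (>50% of observations
being ref or alt, guarding against genotyping errors inflating ε̂).

For a variant pair with a chosen phase, a fragment drawn from either
haplotype supports that phase with probability

    p_s = (1 − 3ε)² + ε²

(neither site misread, or both sites misread into the opposite
alleles). With ``n`` informative fragments of which ``n_s`` support the
chosen phase, the conflict p-value is P(X ≤ n_s) for X ~ Binomial(n,
p_s): a small value means more conflicting fragments than noise alone
explains.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Iterable, List, Tuple

from scipy.stats import binom

from .reads import AlleleObservation

log = logging.getLogger(__name__)

__all__ = [
    "NoiseModel",
    "estimate_epsilon",
    "supporting_probability",
    "conflict_pvalue",
]

DEFAULT_EPSILON = 1e-3


@dataclass(frozen=True)
class NoiseModel:
    epsilon: float
    n_mismatch_bases: int = 0
    n_total_bases: int = 0
    n_sites_used: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.epsilon < 1.0 / 3.0:
            raise ValueError(f"epsilon must lie in [0, 1/3): {self.epsilon}")

    @property
    def p_supporting(self) -> float:
        return supporting_probability(self.epsilon)


def estimate_epsilon(
    observations: Iterable[AlleleObservation],
    default_epsilon: float = DEFAULT_EPSILON,
) -> NoiseModel:
    """Estimate ε from base observations pooled over qualifying sites.

    A site qualifies when more than half of its observations carry the
    ref or alt allele. ε̂ = other-base observations / (2 × total
    observations) over qualifying sites; with no qualifying site the
    configured default is returned (and logged).
    """
    per_site: Dict[str, List[str]] = {}
    for obs in observations:
        per_site.setdefault(obs.variant_id, []).append(obs.allele_class)
    n_other = 0
    n_total = 0
    n_sites = 0
    for classes in per_site.values():
        total = len(classes)
        refalt = sum(1 for c in classes if c in ("ref", "alt"))
        if refalt <= 0.5 * total:
            continue
        n_sites += 1
        n_total += total
        n_other += total - refalt
    if n_total == 0:
        log.warning(
            "no qualifying sites for substitution-rate estimation; "
            "using default epsilon=%g", default_epsilon,
        )
        return NoiseModel(default_epsilon)
    return NoiseModel(
        epsilon=n_other / (2.0 * n_total),
        n_mismatch_bases=n_other,
        n_total_bases=n_total,
        n_sites_used=n_sites,
    )


def supporting_probability(epsilon: float) -> float:
    """Probability p_s = (1 − 3ε)² + ε² that a fragment supports the true phase."""
    if not 0.0 <= epsilon < 1.0 / 3.0:
        raise ValueError(f"epsilon must lie in [0, 1/3): {epsilon}")
    return (1.0 - 3.0 * epsilon) ** 2 + epsilon**2


def conflict_pvalue(n_supporting: int, n_total: int, epsilon: float) -> float:
    """P(X ≤ n_supporting) with X ~ Binomial(n_total, p_s(ε)).

    Small values indicate significant evidence of a conflicting phase.
    """
    if n_total < 1 or not 0 <= n_supporting <= n_total:
        raise ValueError(
            f"invalid counts: n_supporting={n_supporting}, n_total={n_total}"
        )
    return float(binom.cdf(n_supporting, n_total, supporting_probability(epsilon)))
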