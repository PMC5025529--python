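"""Self-contained simulate → phase → score round trip.

Used by the ``selftest`` CLI command and by the reproducibility script:
simulates a diploid truth set and noisy paired-end fragments, runs the
complete pipeline with default settings, and scores pair-event
concordance against the truth.
"""

from __future__ import annotations

import tempfile
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

from .pipeline import PhasingConfig, PhasingResult, run_phasing
from .simulate import (
    Concordance,
    TruthSet,
    score_concordance,
    simulate_diploid,
    simulate_fragments,
    simulate_population_phase,
)

__all__ = ["SelftestReport", "run_selftest"]


@dataclass
class SelftestReport:
    truth: TruthSet
    result: PhasingResult
    concordance: Concordance
    epsilon_true: float
    epsilon_hat: float

    @property
    def summary(self) -> dict:
        return {
            "n_variants": len(self.truth.variants),
            "n_variants_phased": self.result.stats["n_variants_phased"],
            "n_blocks": len(self.result.blocks),
            "n_pair_events": self.concordance.n_pairs,
            "pair_concordance_pct": 100.0 * self.concordance.fraction,
            "epsilon_true": self.epsilon_true,
            "epsilon_hat": self.epsilon_hat,
        }


def run_selftest(
    seed: int = 1,
    n_variants: int = 400,
    chrom_length: int = 40_000,
    coverage: float = 30.0,
    epsilon: float = 0.005,
    read_length: int = 75,
    mean_insert: int = 300,
    sd_insert: float = 30.0,
    config: Optional[PhasingConfig] = None,
    workdir: Optional[Path] = None,
) -> SelftestReport:
    """Simulate a diploid library and phase it back with default settings.

    The default problem size — 400 heterozygous SNVs at ~100 bp mean
    spacing on a 40 kb contig, 2×75 bp pairs at 30× fragment coverage,
    ε = 0.005 — yields well over 1,000 scored pair events in a few
    seconds while exercising edge testing, block assembly, enumeration
    and sub-block splitting.
    """
    truth = simulate_diploid(n_variants, chrom_length, seed=seed)
    truth = simulate_population_phase(truth, seed=seed + 1)
    sim = simulate_fragments(
        truth,
        read_length=read_length,
        mean_insert=mean_insert,
        sd_insert=sd_insert,
        coverage=coverage,
        epsilon=epsilon,
        seed=seed + 2,
    )

    def _run(dirpath: Path) -> PhasingResult:
        sam = sim.write_sam(dirpath / "simulated.sam")
        return run_phasing(sam, truth.variants, config or PhasingConfig())

    if workdir is not None:
        result = _run(Path(workdir))
    else:
        with tempfile.TemporaryDirectory() as tmp:
            result = _run(Path(tmp))
    concordance = score_concordance(truth, result.blocks)
    return SelftestReport(
        truth=truth,
        result=result,
        concordance=concordance,
        epsilon_true=epsilon,
        epsilon_hat=result.noise_model.epsilon,
    )
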