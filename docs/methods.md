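# Methods

This note documents the models, parameter choices, numerical conventions
and known limitations of `haplophase`, in the order the pipeline runs.

## Noise model and the conflicting-phase test

Sequencing noise is modelled as a uniform substitution process: a true
nucleotide is misread as any *given* other nucleotide with pairwise
probability ε, so the total per-base error rate is 3ε and all twelve
substitutions are equally likely. At a heterozygous SNV the probability of
observing one of the two non-ref, non-alt bases is 2ε, which yields the
library-wide estimator

    ε̂ = (non-ref, non-alt base observations) / (2 × total base observations),

pooled over sites where more than half of the observations are ref or alt.
That majority rule guards against genotyping errors: a site whose "het"
call is wrong produces a pile of apparent mismatches that would inflate ε̂,
and such sites are excluded rather than down-weighted. When no site
qualifies (tiny inputs), a configurable default ε = 0.001 is used and logged.
The estimator is unbiased under the model; the >50% exclusion rule is
deliberately strict (`≤ 0.5` excluded).

For a variant pair with a chosen phase, a fragment drawn from either
haplotype supports that phase with probability p_s = (1 − 3ε)² + ε²: either
neither site is misread, or both sites are misread into exactly the
opposite alleles. With n informative fragments (ref/alt observed at both
sites) of which n_s support the chosen orientation, the conflict p-value is
the binomial lower tail P(X ≤ n_s), X ~ Binomial(n, p_s). Conditioning on
informativeness makes the true support probability slightly larger than
p_s, so the test is conservative; type-I calibration is verified by
simulation in the test suite. Edges with p below the threshold (default
0.01) are removed before block construction. The p_s parabola has an
interior minimum of 0.1 at ε = 0.3; the model domain is 0 ≤ ε < 1/3 and the
estimator cannot exceed 0.25 because of the majority rule.

## Allele extraction

The evidence unit is the *fragment* (read pair), not the read. Reads are
dropped if unmapped, secondary, supplementary or duplicate; fragments are
dropped below the library MAPQ, above the library insert-size cap, or below
the alignment-score cutoff. Library presets follow common practice: RNA-seq
MAPQ 255 (STAR's unique-mapper value) with no insert cap (splicing makes
genomic "inserts" arbitrarily long), exome MAPQ 40 with a 500 bp cap, whole
genome MAPQ 40 with 1000 bp. Fragment MAPQ and alignment score are the
minimum over mates (the worst mate governs). The alignment-score cutoff is
the nearest-rank empirical quantile (default 0.05) of per-fragment scores,
computed after the MAPQ/flag/insert filters so that the score distribution
reflects the library actually being used; fragments strictly below the
cutoff are removed. With no score tags or quantile 0 the filter is
disabled.

Base-level rules: bases below BASEQ 10 yield no observation; variants under
N-skips (introns), deletions or clipped segments yield none. When both
mates cover a variant, agreement yields one observation (highest base
quality kept) and disagreement discards the (fragment, variant)
observation — the conservative choice, since such a fragment carries
self-contradictory evidence. Observations of a base that is neither ref
nor alt are retained for ε estimation but are never phase-informative.

## Edge construction, blocks and configuration search

One candidate edge per variant pair sharing at least one informative
fragment; orientation is the majority of cis (ref·ref/alt·alt) versus
trans (ref·alt/alt·ref) fragments. A tied pair is discarded: it carries no
net phase signal. Each passed edge then counts once — with weight 1,
regardless of read depth — in all downstream scoring; depth influences only
the conflict test.

Blocks are connected components of the passed-edge graph (singletons are
not blocks). A variant's *parity* is 0 when haplotype A carries its ref
allele. If propagating every edge's orientation 2-colours the block
consistently, the block is conflict-free and that assignment is reported
directly, at any block size. Otherwise all 2^(n−1) distinct configurations
(haplotype-label swap halves the 2^n space) are scored by satisfied edge
count, vectorized over a numpy integer range so n = 15 costs 2^14 array
operations. Score ties are resolved deterministically by the
lexicographically smallest haplotype-A allele string and flagged
`ambiguous` in the output.

Blocks larger than the enumeration bound (default 15) are split
recursively at the inter-variant boundary (in genome order) crossed by the
fewest passed edges, leftmost on ties. Each sub-block's internal connected
components are phased exhaustively and become two-state units; every edge
crossing two units votes, given the units' internal assignments, for one
relative unit orientation, and the unit-orientation configuration is chosen
by the same exhaustive search one level up (recursing hierarchically while
the problem shrinks; if reduction ever stalls the current partition is
accepted). A final deterministic refinement sweep flips single variants
while that strictly increases the satisfied-edge count; it terminates, can
only raise support, and recovers optima the hierarchical merge can miss
when a variant's best assignment depends on edges crossing its sub-block
boundary. On dense, mostly-consistent blocks of 16–18 variants this
split-then-merge procedure reproduces the full-enumeration support exactly
in the test suite; it is a heuristic, not a guarantee, for adversarial
edge sets. Phasing is chromosome-wide with no cap on pair distance.

## Phase anchoring

Population phasing is trusted in proportion to how common a variant is, so
each block variant with a population phase votes for one of the two
genome-wide orientations with weight equal to its folded minor allele
frequency: α = Σ MAF voting configuration 1 (read-backed haplotype A equals
population haplotype 1), β likewise for configuration 2; the larger sum
wins and the anchor confidence is max(α, β)/(α + β) ∈ [0.5, 1]. MAF is
folded from the VCF alternate-allele frequency as min(AF, 1 − AF), because
the rationale concerns minor-allele rarity. Variants without a population
phase or without a frequency contribute weight 0. α = β (including the
no-vote case) leaves the block unanchored with only its local phase; the
orientation rule is only defined for strict inequality, so equality is
reported rather than guessed. A minimum-confidence filter is available but
off by default: confidence is reported, not thresholded.

## Haplotypic expression

A fragment overlapping one or more block variants is assigned to haplotype
A (or B) iff *all* of its observations match that haplotype's alleles, and
it is counted exactly once per scope however many variants it spans —
summing per-variant allele counts would double-count exactly those
fragments that make read-backed phasing possible. Fragments matching
neither haplotype (internal conflict or a non-allelic base) are discarded
and reported. At gene level, counts are recomputed over each block's
variants inside the gene span, anchored blocks are flipped to the common
genome-wide orientation and their fragment sets unioned (a fragment
spanning two blocks still counts once; cross-block disagreements are
discarded). A gene with no anchored block uses only its single
best-supported block: guessing the relative orientation of unanchored
blocks would manufacture spurious imbalance in either direction. A variant
inside two overlapping genes contributes to both, and a fragment spanning
two genes counts in both — genes are independent scopes. Imbalance uses
the two-sided exact binomial test against 0.5 with Benjamini–Hochberg FDR
across genes; this is a convenience statistic, not an overdispersion-aware
allelic-expression model.

## Interaction annotation

Within a gene, two phased heterozygous variants are *trans* when their
alternate alleles sit on different haplotypes and *cis* otherwise, with
evidence graded read_backed (same phase set) > anchored (different blocks
joined genome-wide) > population (population phasing only). Population-only
calls are excluded from the compound-het cascade by default because that
evidence class is unreliable precisely for the rare variants the workflow
targets. The prioritization cascade filters pairs by frequency (both
alternate AFs below a cutoff, default 0.01), deleteriousness (both scores
at or above a cutoff, default 15 on a CADD-like scale), gene expression
(membership in a user-supplied expressed-gene set — expression calling is
out of scope), and phasing evidence, then splits survivors into trans
(candidate compound heterozygotes) and cis (deprioritized). Annotation
fields are consumed generically; pairs missing a field drop out at the
filter that needs it, with per-sample counts reported at every step.

## Synthetic data

The simulator generates what the pipeline consumes and nothing more: a
random reference with biallelic het SNVs at distinct positions (MAFs
uniform on [0.01, 0.5] by default, or any caller-supplied sampler), a fair
random assignment of alleles to the two haplotypes, paired or single-end
fragments sampled uniformly (per-fragment origin haplotype Bernoulli with
configurable allelic ratio), per-base substitution to each other
nucleotide with probability ε, optional exon-structured sampling that
emits N-gapped CIGARs across introns, plausible MAPQ/AS/base-quality
fields so every filter is exercisable, and a population phase whose
per-variant switch error decreases with MAF (0.5·exp(−8·MAF) by default).
All randomness flows through one numpy Generator per call.

What it does **not** emulate: allelic mapping bias, reference bias,
non-uniform coverage, transcript-abundance structure, indel errors, or
quality-score miscalibration. Passing tests therefore demonstrate
correctness of the algorithms under the stated noise model, not robustness
to alignment artefacts — for mapping-bias handling the package defers to
dedicated upstream QC.

## Problem sizes and numerical choices

The standard self-test and the reproduction script use 400 SNVs uniform on
40 kb (≈100 bp spacing, so ≈300 bp inserts of 2×75 bp pairs connect
neighbours), 30× fragment coverage, ε = 0.005 and default settings; this
yields several thousand scored pair events and exercises conflict testing,
enumeration, splitting and merging, while completing in seconds. Binomial
tails come from scipy; the configuration search verifies against direct
pmf summation to 1e-12 in tests. All tie rules (edge ties discarded,
enumeration ties lexicographic, α = β unanchored, boundary ties leftmost)
are deterministic, making the pipeline's output independent of input
ordering.

## Known limitations

- Reads are loaded per file into memory before fragment grouping;
  chromosome-streaming would be needed for very deep whole-genome BAMs.
- Indels can be loaded (`include_indels`) and phased via co-occurring SNV
  observations, but bases are only compared at single-nucleotide sites;
  there is no indel-allele matching.
- Multiallelic sites are skipped (the pair model is biallelic).
- The sub-block merge is exact on the regimes tested but heuristic in the
  worst case, as is any bounded search over an exponential space.
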