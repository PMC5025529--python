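"""Haplotype block assembly from fragment co-observations.

Pipeline: every variant pair co-observed on a fragment defines a
candidate *phase edge* whose cis/trans orientation is the majority vote
of its fragments; each edge gets a conflicting-phase binomial p-value
and edges failing the threshold are removed. Blocks are the connected
components of the surviving edge graph. Within a block the assignment
of alleles to the two haplotypes is either read off directly when the
edges are mutually consistent (conflict-free 2-colouring), or chosen by
scoring all 2^(n−1) distinct configurations by the number of edges each
satisfies. Blocks larger than the enumeration bound are split at the
inter-variant boundary spanned by the fewest edges, phased per
sub-block, and the sub-blocks re-joined by majority vote of the edges
between them.

A variant's *parity* is 0 when haplotype A carries its ref allele and 1
when it carries the alt; an edge is satisfied when
``parity_a XOR parity_b`` equals 1 for trans and 0 for cis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import networkx as nx
import numpy as np

from .noise import NoiseModel, conflict_pvalue
from .reads import AlleleObservation
from .variants import HetVariant

log = logging.getLogger(__name__)

__all__ = [
    "PhaseEdge",
    "HaplotypeBlock",
    "build_edges",
    "build_blocks",
    "is_conflict_free",
    "enumerate_configuration",
    "split_subblocks",
    "phase_subblocks",
    "resolve_block",
    "phase_all",
]

DEFAULT_CONFLICT_P = 0.01
DEFAULT_MAX_BLOCK = 15
_HARD_ENUM_CAP = 22  # 2^21 configurations; guards accidental blow-ups


@dataclass(frozen=True)
class PhaseEdge:
    """Phase evidence between two variants (ids ordered by genome position).

    ``n_cis`` counts fragments carrying ref·ref or alt·alt across the
    pair, ``n_trans`` those carrying ref·alt or alt·ref. ``chosen`` is
    the majority orientation (ties never produce an edge); ``p_value``
    is the conflicting-phase test result and ``passed`` its verdict at
    the configured threshold.
    """

    variant_a: str
    variant_b: str
    n_cis: int
    n_trans: int
    chosen: str  # "cis" | "trans"
    p_value: float
    passed: bool

    @property
    def n_supporting(self) -> int:
        return max(self.n_cis, self.n_trans)

    @property
    def n_total(self) -> int:
        return self.n_cis + self.n_trans

    @property
    def is_trans(self) -> int:
        return 1 if self.chosen == "trans" else 0


@dataclass
class HaplotypeBlock:
    """A set of ≥2 variants with a resolved two-haplotype assignment."""

    variants: Tuple[str, ...]  # ordered by genome position
    parity: Dict[str, int]  # 0: haplotype A carries ref; 1: carries alt
    alleles_a: str
    alleles_b: str
    chrom: str
    conflict_free: bool
    n_supporting_edges: int
    n_total_edges: int
    ambiguous: bool = False  # configuration-score tie broken lexicographically

    def __len__(self) -> int:
        return len(self.variants)

    @property
    def span(self) -> Tuple[int, int]:
        positions = [int(v.split(":")[1]) for v in self.variants]
        return min(positions), max(positions)


def _order_key(variant_map: Mapping[str, HetVariant]):
    return lambda vid: (variant_map[vid].chrom, variant_map[vid].pos, vid)


def build_edges(
    observations: Iterable[AlleleObservation],
    variant_map: Mapping[str, HetVariant],
    noise: NoiseModel,
    threshold: float = DEFAULT_CONFLICT_P,
) -> List[PhaseEdge]:
    """Build conflict-tested phase edges from reconciled observations.

    Only ref/alt observations are informative. One edge per variant pair
    sharing at least one informative fragment; pairs whose cis and trans
    counts tie are dropped as carrying no net phase signal. Edges with
    ``p_value < threshold`` are kept in the list but marked failed.
    """
    key = _order_key(variant_map)
    by_fragment: Dict[str, Dict[str, str]] = {}
    for obs in observations:
        if obs.allele_class not in ("ref", "alt"):
            continue
        by_fragment.setdefault(obs.fragment_id, {})[obs.variant_id] = obs.allele_class
    counts: Dict[Tuple[str, str], List[int]] = {}
    for alleles in by_fragment.values():
        if len(alleles) < 2:
            continue
        vids = sorted(alleles, key=key)
        for a, b in combinations(vids, 2):
            pair = counts.setdefault((a, b), [0, 0])
            pair[0 if alleles[a] == alleles[b] else 1] += 1
    edges: List[PhaseEdge] = []
    n_ties = 0
    for (a, b), (n_cis, n_trans) in sorted(counts.items()):
        if n_cis == n_trans:
            n_ties += 1
            continue
        chosen = "cis" if n_cis > n_trans else "trans"
        p = conflict_pvalue(max(n_cis, n_trans), n_cis + n_trans, noise.epsilon)
        edges.append(
            PhaseEdge(a, b, n_cis, n_trans, chosen, p, passed=p >= threshold)
        )
    if n_ties:
        log.info("discarded %d tied (uninformative) candidate edges", n_ties)
    return edges


def build_blocks(edges: Iterable[PhaseEdge]) -> List[List[str]]:
    """Connected components of the passed-edge graph; singletons excluded."""
    graph = nx.Graph()
    for e in edges:
        if e.passed:
            graph.add_edge(e.variant_a, e.variant_b)
    components = [sorted(c) for c in nx.connected_components(graph)]
    components.sort(key=lambda c: c[0])
    return [c for c in components if len(c) >= 2]


def _edges_within(
    block: Sequence[str], edges: Iterable[PhaseEdge]
) -> List[PhaseEdge]:
    members = set(block)
    return [
        e for e in edges
        if e.passed and e.variant_a in members and e.variant_b in members
    ]


def is_conflict_free(
    block: Sequence[str], edges: Iterable[PhaseEdge]
) -> Tuple[bool, Optional[Dict[str, int]]]:
    """Check whether the block's edges 2-colour consistently.

    Propagates each edge's chosen orientation from an arbitrary root;
    returns (True, parity assignment) when every edge is satisfied,
    else (False, None).
    """
    within = _edges_within(block, edges)
    adj: Dict[str, List[Tuple[str, int]]] = {v: [] for v in block}
    for e in within:
        adj[e.variant_a].append((e.variant_b, e.is_trans))
        adj[e.variant_b].append((e.variant_a, e.is_trans))
    parity: Dict[str, int] = {}
    for start in block:
        if start in parity:
            continue
        parity[start] = 0
        stack = [start]
        while stack:
            u = stack.pop()
            for v, rel in adj[u]:
                want = parity[u] ^ rel
                if v not in parity:
                    parity[v] = want
                    stack.append(v)
                elif parity[v] != want:
                    return False, None
    return True, parity


def _support_vector(
    block: Sequence[str], edges: Sequence[PhaseEdge]
) -> np.ndarray:
    """Edge-support score of every distinct configuration of ``block``.

    Configuration ``c`` assigns variant 0 parity 0 and variant ``i>0``
    parity bit ``i−1`` of ``c``; the haplotype-label swap symmetry makes
    these 2^(n−1) assignments exhaustive.
    """
    n = len(block)
    if n > _HARD_ENUM_CAP:
        raise ValueError(f"block of {n} variants exceeds enumeration cap")
    idx = {vid: i for i, vid in enumerate(block)}
    configs = np.arange(1 << (n - 1), dtype=np.int64)
    support = np.zeros(len(configs), dtype=np.int32)
    for e in edges:
        ia, ib = idx[e.variant_a], idx[e.variant_b]
        pa = 0 if ia == 0 else (configs >> (ia - 1)) & 1
        pb = 0 if ib == 0 else (configs >> (ib - 1)) & 1
        support += ((pa ^ pb) == e.is_trans)
    return support


def _config_parity(block: Sequence[str], config: int) -> Dict[str, int]:
    parity = {block[0]: 0}
    for i, vid in enumerate(block[1:], start=1):
        parity[vid] = (config >> (i - 1)) & 1
    return parity


def _canonical_string(
    block: Sequence[str], parity: Mapping[str, int],
    variant_map: Mapping[str, HetVariant],
) -> str:
    s1 = "".join(
        variant_map[v].ref if parity[v] == 0 else variant_map[v].alt for v in block
    )
    s2 = "".join(
        variant_map[v].alt if parity[v] == 0 else variant_map[v].ref for v in block
    )
    return min(s1, s2)


def enumerate_configuration(
    block: Sequence[str],
    edges: Iterable[PhaseEdge],
    variant_map: Mapping[str, HetVariant],
) -> Tuple[Dict[str, int], int, bool]:
    """Exhaustively score all configurations; return the best assignment.

    Returns (parity, support, ambiguous) where ``support`` is the number
    of satisfied edges and ``ambiguous`` flags a score tie resolved by
    taking the lexicographically smallest haplotype-A allele string.
    """
    block = sorted(block, key=_order_key(variant_map))
    within = _edges_within(block, edges)
    support = _support_vector(block, within)
    best = int(support.max()) if len(support) else 0
    winners = np.flatnonzero(support == best)
    if len(winners) == 1:
        return _config_parity(block, int(winners[0])), best, False
    candidates = [_config_parity(block, int(c)) for c in winners]
    chosen = min(
        candidates, key=lambda p: _canonical_string(block, p, variant_map)
    )
    return chosen, best, True


def split_subblocks(
    block: Sequence[str],
    edges: Iterable[PhaseEdge],
    variant_map: Mapping[str, HetVariant],
    max_size: int = DEFAULT_MAX_BLOCK,
) -> List[List[str]]:
    """Recursively cut a block at boundaries spanned by the fewest edges.

    The block is kept in genome order; a boundary sits between
    consecutive variants, its span being the number of passed edges
    crossing it. The minimum-span boundary is cut (leftmost on ties)
    until every sub-block holds at most ``max_size`` variants.
    """
    ordered = sorted(block, key=_order_key(variant_map))
    within = _edges_within(ordered, edges)

    def split(vars_: List[str]) -> List[List[str]]:
        if len(vars_) <= max_size:
            return [vars_]
        idx = {v: i for i, v in enumerate(vars_)}
        members = set(vars_)
        spans = np.zeros(len(vars_) - 1, dtype=np.int64)
        for e in within:
            if e.variant_a in members and e.variant_b in members:
                i, j = sorted((idx[e.variant_a], idx[e.variant_b]))
                spans[i:j] += 1
        cut = int(np.argmin(spans))  # leftmost minimum
        return split(vars_[: cut + 1]) + split(vars_[cut + 1 :])

    return split(ordered)


def _meta_problem(
    units: Sequence[Tuple[List[str], Dict[str, int]]],
    edges: Sequence[PhaseEdge],
) -> Tuple[List[str], Dict[str, HetVariant], List[PhaseEdge], Dict[str, int]]:
    """Reduce inter-unit phasing to another two-state configuration search.

    Each internally phased unit becomes a pseudo-variant; each passed
    edge crossing two units implies (given the units' internal
    assignments) a cis or trans relation between the pseudo-variants.
    Parallel meta-edges are kept: each original edge votes once.
    """
    unit_of: Dict[str, int] = {}
    for k, (vids, _) in enumerate(units):
        for v in vids:
            unit_of[v] = k
    meta_ids = [f"_unit:{k + 1}:A:T" for k in range(len(units))]
    meta_map = {
        mid: HetVariant(id=mid, chrom="_unit", pos=k + 1, ref="A", alt="T")
        for k, mid in enumerate(meta_ids)
    }
    meta_edges: List[PhaseEdge] = []
    members = set(unit_of)
    for e in edges:
        if not e.passed or e.variant_a not in members or e.variant_b not in members:
            continue
        ka, kb = unit_of[e.variant_a], unit_of[e.variant_b]
        if ka == kb:
            continue
        rel = units[ka][1][e.variant_a] ^ units[kb][1][e.variant_b] ^ e.is_trans
        a, b = sorted((ka, kb))
        meta_edges.append(
            PhaseEdge(meta_ids[a], meta_ids[b], 1 - rel, rel,
                      "trans" if rel else "cis", 1.0, True)
        )
    return meta_ids, meta_map, meta_edges, unit_of


def _resolve_connected(
    ordered: List[str],
    edges: List[PhaseEdge],
    variant_map: Mapping[str, HetVariant],
    max_size: int,
) -> List[Tuple[List[str], Dict[str, int], bool]]:
    """Resolve a connected variant set into one or more parity assignments.

    Fast path: a consistent edge set is read off directly. Small
    conflicted sets are enumerated exhaustively. Oversized sets are
    split at minimum-span boundaries; each sub-block's internal
    connected components become two-state units, and the units are
    phased relative to one another by the same configuration search one
    level up (recursing while the problem keeps shrinking).
    """
    free, parity = is_conflict_free(ordered, edges)
    if free:
        return [(ordered, parity, False)]
    if len(ordered) <= max_size:
        parity, _, amb = enumerate_configuration(ordered, edges, variant_map)
        return [(list(parity), parity, amb)]

    subblocks = split_subblocks(ordered, edges, variant_map, max_size)
    units: List[Tuple[List[str], Dict[str, int]]] = []
    ambiguous = False
    for sub in subblocks:
        sub_edges = _edges_within(sub, edges)
        graph = nx.Graph()
        graph.add_nodes_from(sub)
        for e in sub_edges:
            graph.add_edge(e.variant_a, e.variant_b)
        for comp in sorted(nx.connected_components(graph), key=min):
            comp_ordered = sorted(comp, key=_order_key(variant_map))
            if len(comp_ordered) == 1:
                units.append((comp_ordered, {comp_ordered[0]: 0}))
                continue
            free, parity = is_conflict_free(comp_ordered, edges)
            if not free:
                parity, _, amb = enumerate_configuration(
                    comp_ordered, edges, variant_map
                )
                ambiguous = ambiguous or amb
            units.append((comp_ordered, parity))

    meta_ids, meta_map, meta_edges, _ = _meta_problem(units, edges)
    if len(meta_ids) >= len(ordered):
        # no reduction (fully fragmented sub-blocks): enumeration at the
        # meta level would recurse forever, so stop splitting here
        meta_results = [
            (list(p), p, False)
            for p in [is_conflict_free(meta_ids, meta_edges)[1] or
                      {m: 0 for m in meta_ids}]
        ]
    else:
        graph = nx.Graph()
        graph.add_nodes_from(meta_ids)
        for e in meta_edges:
            graph.add_edge(e.variant_a, e.variant_b)
        meta_results = []
        for comp in sorted(nx.connected_components(graph), key=min):
            comp_ordered = sorted(comp, key=_order_key(meta_map))
            meta_results.extend(
                _resolve_connected(comp_ordered, meta_edges, meta_map, max_size)
            )

    unit_index = {mid: k for k, mid in enumerate(meta_ids)}
    results: List[Tuple[List[str], Dict[str, int], bool]] = []
    for meta_vids, meta_parity, meta_amb in meta_results:
        merged: Dict[str, int] = {}
        for mid in meta_vids:
            vids, unit_parity = units[unit_index[mid]]
            for vid in vids:
                merged[vid] = unit_parity[vid] ^ meta_parity[mid]
        ordered_merged = sorted(merged, key=_order_key(variant_map))
        merged = _refine_parity(ordered_merged, merged, edges)
        results.append((ordered_merged, merged, ambiguous or meta_amb))
    return results


def _refine_parity(
    vids: Sequence[str], parity: Dict[str, int], edges: Sequence[PhaseEdge]
) -> Dict[str, int]:
    """Greedy post-pass after sub-block merging.

    Flips single variants while doing so strictly increases the number
    of satisfied edges (deterministic sweep order, strict improvement
    only, so it terminates and never decreases support). Recovers
    optima the hierarchical merge can miss when a variant's best
    assignment depends on edges crossing its sub-block boundary.
    """
    adj: Dict[str, List[Tuple[str, int]]] = {v: [] for v in vids}
    for e in edges:
        if e.variant_a in adj and e.variant_b in adj:
            adj[e.variant_a].append((e.variant_b, e.is_trans))
            adj[e.variant_b].append((e.variant_a, e.is_trans))
    parity = dict(parity)
    for _ in range(len(vids)):
        changed = False
        for v in vids:
            gain = 0
            for u, rel in adj[v]:
                sat_now = (parity[v] ^ parity[u]) == rel
                gain += (not sat_now) - sat_now
            if gain > 0:
                parity[v] ^= 1
                changed = True
        if not changed:
            break
    return parity


def phase_subblocks(
    subblocks: Sequence[Sequence[str]],
    edges: Iterable[PhaseEdge],
    variant_map: Mapping[str, HetVariant],
    max_size: int = DEFAULT_MAX_BLOCK,
) -> List[HaplotypeBlock]:
    """Phase sub-blocks internally, then relative to one another.

    Each phased sub-block is a two-state unit; every passed edge
    between two units votes for one relative orientation, and the
    unit-orientation configuration satisfying the most edges is chosen
    by the same exhaustive search used within sub-blocks. Units with no
    connecting passed edges remain separate blocks.
    """
    edges = [e for e in edges if e.passed]
    units: List[Tuple[List[str], Dict[str, int]]] = []
    ambiguous = False
    for sub in subblocks:
        p, _, amb = enumerate_configuration(sub, edges, variant_map)
        ambiguous = ambiguous or amb
        units.append((sorted(sub, key=_order_key(variant_map)), p))

    meta_ids, meta_map, meta_edges, _ = _meta_problem(units, edges)
    graph = nx.Graph()
    graph.add_nodes_from(meta_ids)
    for e in meta_edges:
        graph.add_edge(e.variant_a, e.variant_b)
    unit_index = {mid: k for k, mid in enumerate(meta_ids)}
    blocks: List[HaplotypeBlock] = []
    for comp in sorted(nx.connected_components(graph), key=min):
        comp_ordered = sorted(comp, key=_order_key(meta_map))
        for meta_vids, meta_parity, meta_amb in _resolve_connected(
            comp_ordered, meta_edges, meta_map, max_size
        ):
            merged: Dict[str, int] = {}
            for mid in meta_vids:
                vids, unit_parity = units[unit_index[mid]]
                for vid in vids:
                    merged[vid] = unit_parity[vid] ^ meta_parity[mid]
            if len(merged) < 2:
                continue
            ordered_merged = sorted(merged, key=_order_key(variant_map))
            merged = _refine_parity(ordered_merged, merged, edges)
            blocks.append(
                _make_block(ordered_merged, merged, edges, variant_map,
                            conflict_free=False,
                            ambiguous=ambiguous or meta_amb)
            )
    blocks.sort(key=lambda b: (b.chrom, b.span[0]))
    return blocks


def _make_block(
    ordered: Sequence[str],
    parity: Mapping[str, int],
    edges: Iterable[PhaseEdge],
    variant_map: Mapping[str, HetVariant],
    conflict_free: bool,
    ambiguous: bool = False,
) -> HaplotypeBlock:
    within = _edges_within(ordered, edges)
    supported = sum(
        1 for e in within
        if (parity[e.variant_a] ^ parity[e.variant_b]) == e.is_trans
    )
    alleles_a = "".join(
        variant_map[v].ref if parity[v] == 0 else variant_map[v].alt
        for v in ordered
    )
    alleles_b = "".join(
        variant_map[v].alt if parity[v] == 0 else variant_map[v].ref
        for v in ordered
    )
    return HaplotypeBlock(
        variants=tuple(ordered),
        parity=dict(parity),
        alleles_a=alleles_a,
        alleles_b=alleles_b,
        chrom=variant_map[ordered[0]].chrom,
        conflict_free=conflict_free,
        n_supporting_edges=supported,
        n_total_edges=len(within),
        ambiguous=ambiguous,
    )


def resolve_block(
    block: Sequence[str],
    edges: Iterable[PhaseEdge],
    variant_map: Mapping[str, HetVariant],
    max_size: int = DEFAULT_MAX_BLOCK,
) -> List[HaplotypeBlock]:
    """Resolve one connected component into phased block(s).

    Conflict-free components of any size are read off directly; small
    conflicted ones are enumerated; oversized conflicted ones go through
    sub-block splitting and re-joining (which may yield several blocks
    when sub-blocks end up unlinked).
    """
    edges = [e for e in edges if e.passed]
    ordered = sorted(block, key=_order_key(variant_map))
    free, parity = is_conflict_free(ordered, edges)
    if free:
        return [_make_block(ordered, parity, edges, variant_map, conflict_free=True)]
    blocks = [
        _make_block(vids, parity, edges, variant_map,
                    conflict_free=False, ambiguous=amb)
        for vids, parity, amb in _resolve_connected(
            ordered, edges, variant_map, max_size)
        if len(vids) >= 2
    ]
    blocks.sort(key=lambda b: (b.chrom, b.span[0]))
    return blocks


def phase_all(
    edges: Iterable[PhaseEdge],
    variant_map: Mapping[str, HetVariant],
    max_size: int = DEFAULT_MAX_BLOCK,
) -> List[HaplotypeBlock]:
    """Assemble and resolve every haplotype block from the edge set."""
    edges = list(edges)
    blocks: List[HaplotypeBlock] = []
    for component in build_blocks(edges):
        blocks.extend(resolve_block(component, edges, variant_map, max_size))
    blocks.sort(key=lambda b: (b.chrom, b.span[0]))
    return blocks
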