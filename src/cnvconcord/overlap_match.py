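"""Reciprocal overlap, same-event grouping, and between-sample call matching.

Two calls x and y overlap reciprocally at threshold t when the intersection
length L covers at least t of EACH call:

    O_A = L / (x_end - x_start + 1),   O_B = L / (y_end - y_start + 1)

and a pair "passes" (is the same event) when both fractions reach the
threshold (default 50%, boundary inclusive) AND the gain/loss statuses match.
Event groups are connected components of the passing-pair graph, so a chain
of partially overlapping calls forms one event even when its extremes do not
overlap each other directly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
from intervaltree import IntervalTree
from scipy.optimize import linear_sum_assignment

from .calls_io import CallSet, CNVCall, _chrom_sort_key
from .errors import ValidationError

DEFAULT_RO_THRESHOLD = 0.50


def overlap_length(x: CNVCall, y: CNVCall) -> int:
    """Intersection length L in base pairs (0 for different chromosomes)."""
    if x.chrom != y.chrom:
        return 0
    return max(0, min(x.end, y.end) - max(x.start, y.start) + 1)


@dataclass(frozen=True)
class OverlapResult:
    """Reciprocal overlap of an ordered pair (x, y)."""

    L: int
    O_a: float
    O_b: float
    passes: bool


def reciprocal_overlap(
    x: CNVCall, y: CNVCall, threshold: float = DEFAULT_RO_THRESHOLD
) -> OverlapResult:
    """Evaluate the reciprocal-overlap criterion for a pair of calls.

    ``passes`` is true iff both O_a and O_b are >= threshold and the calls
    share gain/loss status (copy states are binarized before comparison).
    """
    L = overlap_length(x, y)
    o_a = L / x.length
    o_b = L / y.length
    passes = o_a >= threshold and o_b >= threshold and x.status is y.status
    return OverlapResult(L=L, O_a=o_a, O_b=o_b, passes=passes)


def _interval_index(calls: Sequence[CNVCall]) -> dict[str, IntervalTree]:
    """Per-chromosome interval index over call indices.

    Intervals are stored half-open on [start, end + 1) so that the inclusive
    endpoint participates in queries.
    """
    trees: dict[str, IntervalTree] = {}
    for i, c in enumerate(calls):
        trees.setdefault(c.chrom, IntervalTree()).addi(c.start, c.end + 1, i)
    return trees


def candidate_pairs(
    calls_a: Sequence[CNVCall],
    calls_b: Sequence[CNVCall],
    threshold: float = DEFAULT_RO_THRESHOLD,
) -> list[tuple[int, int, OverlapResult]]:
    """Index-accelerated passing pairs between two call collections.

    Returns (i, j, overlap) triples for every pair calls_a[i], calls_b[j]
    whose reciprocal overlap passes.  Equivalent to exhaustive all-pairs
    checking; the interval index only prunes non-intersecting pairs, which
    can never pass at any positive threshold.
    """
    trees = _interval_index(calls_b)
    out: list[tuple[int, int, OverlapResult]] = []
    for i, x in enumerate(calls_a):
        tree = trees.get(x.chrom)
        if tree is None:
            continue
        for iv in sorted(tree.overlap(x.start, x.end + 1), key=lambda v: v.data):
            j = iv.data
            res = reciprocal_overlap(x, calls_b[j], threshold)
            if res.passes:
                out.append((i, j, res))
    return out


@dataclass(frozen=True)
class EventGroup:
    """Calls connected through chains of passing reciprocal overlaps.

    The unit of cross-program (and cross-sample) comparison: one biological
    CNV event as seen by possibly many programs and samples.
    """

    member_calls: tuple[CNVCall, ...]
    chrom: str
    start: int
    end: int

    @property
    def programs(self) -> frozenset[str]:
        return frozenset(c.program_id for c in self.member_calls)

    @property
    def samples(self) -> frozenset[str]:
        return frozenset(c.sample_id for c in self.member_calls)

    def __len__(self) -> int:
        return len(self.member_calls)


def build_event_groups(
    callsets: Iterable[CallSet],
    threshold: float = DEFAULT_RO_THRESHOLD,
) -> list[EventGroup]:
    """Group calls from many call sets into same-event connected components.

    Builds a graph with one node per call and an edge wherever the reciprocal
    overlap passes, then returns each connected component as an EventGroup,
    ordered by genomic span.  Every input call lands in exactly one group
    (singletons included).
    """
    calls: list[CNVCall] = [c for cs in callsets for c in cs]
    graph = nx.Graph()
    graph.add_nodes_from(range(len(calls)))
    for i, j, _res in candidate_pairs(calls, calls, threshold):
        if i < j:
            graph.add_edge(i, j)
    groups: list[EventGroup] = []
    for component in nx.connected_components(graph):
        members = tuple(sorted((calls[i] for i in component), key=CNVCall.sort_key))
        groups.append(
            EventGroup(
                member_calls=members,
                chrom=members[0].chrom,
                start=min(c.start for c in members),
                end=max(c.end for c in members),
            )
        )
    groups.sort(key=lambda g: (_chrom_sort_key(g.chrom), g.start, g.end, len(g)))
    return groups


@dataclass(frozen=True)
class MatchedPair:
    call_a: CNVCall
    call_b: CNVCall
    overlap: OverlapResult


def match_pairwise(
    A: CallSet,
    B: CallSet,
    threshold: float = DEFAULT_RO_THRESHOLD,
) -> list[MatchedPair]:
    """One-to-one matching of shared calls between two samples, one program.

    Candidate pairs are those passing reciprocal overlap; among candidates a
    maximum-cardinality matching is chosen so a call is never counted as
    shared twice, with ties broken in favor of larger min(O_a, O_b) and then
    genomic order.  Comparing call sets from different programs is refused:
    between-individual comparisons are within-program by design.
    """
    if A.program_id != B.program_id:
        raise ValidationError(
            f"between-sample matching requires one program; got "
            f"{A.program_id!r} vs {B.program_id!r}"
        )
    cands = candidate_pairs(A.calls, B.calls, threshold)
    if not cands:
        return []
    n_a, n_b = len(A), len(B)
    # Profit BIG + quality per candidate edge: BIG dominates any sum of
    # qualities, so linear assignment maximizes cardinality first, then total
    # min(O_a, O_b); a tiny genomic-order nudge keeps ties deterministic.
    big = float(n_a + n_b + 1)
    profit = np.zeros((n_a, n_b))
    passes = np.zeros((n_a, n_b), dtype=bool)
    results: dict[tuple[int, int], OverlapResult] = {}
    for i, j, res in cands:
        quality = min(res.O_a, res.O_b)
        profit[i, j] = big + quality - 1e-9 * (i + j)
        passes[i, j] = True
        results[(i, j)] = res
    rows, cols = linear_sum_assignment(profit, maximize=True)
    matched = [
        MatchedPair(call_a=A.calls[i], call_b=B.calls[j], overlap=results[(i, j)])
        for i, j in zip(rows, cols)
        if passes[i, j]
    ]
    matched.sort(key=lambda m: m.call_a.sort_key())
    return matched
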