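"""Merging of adjacent same-status calls within one (sample, program).

Two calls A and C with an intervening uncalled gap B are merged when (1) they
are adjacent on the same chromosome with no other call between them, (2) they
share gain/loss status, and (3) the gap fraction len(B) / len(A+B+C) is at
most 20%.  Chains of consecutive same-status calls are merged whenever the
cumulative gap fraction — the sum of all internal gaps divided by the full
chain span — stays within the threshold at each extension step; the scan is
iterated to a fixed point so that no two output neighbors still satisfy the
criteria.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .calls_io import CallSet, CNVCall, Status
from .errors import ValidationError

DEFAULT_MAX_GAP_FRACTION = 0.20


@dataclass(frozen=True)
class MergeDecision:
    """Gap geometry for one candidate pair of adjacent calls."""

    left_call: CNVCall
    right_call: CNVCall
    gap_bp: int
    span_bp: int
    gap_fraction: float
    merged: bool = False


@dataclass
class MergeResult:
    """Merged call set plus the per-pair decisions taken during the scan."""

    callset: CallSet
    decisions: list[MergeDecision] = field(default_factory=list)

    def __iter__(self):
        return iter(self.callset)

    def __len__(self) -> int:
        return len(self.callset)


def gap_fraction(a: CNVCall, c: CNVCall) -> MergeDecision:
    """Compute the gap geometry between two ordered, non-overlapping calls.

    With A the left call, C the right call and B the uncalled gap between
    them: ``gap_bp = c.start - a.end - 1``, ``span_bp = c.end - a.start + 1``
    and ``gap_fraction = gap_bp / span_bp``.  The merge decision itself
    belongs to :func:`merge_adjacent`.
    """
    if a.chrom != c.chrom:
        raise ValidationError(
            f"calls on different chromosomes: {a.chrom} vs {c.chrom}"
        )
    if a.end >= c.start:
        raise ValidationError(
            f"left call must end before right call starts "
            f"(a.end={a.end}, c.start={c.start})"
        )
    gap_bp = c.start - a.end - 1
    span_bp = c.end - a.start + 1
    return MergeDecision(
        left_call=a,
        right_call=c,
        gap_bp=gap_bp,
        span_bp=span_bp,
        gap_fraction=gap_bp / span_bp,
    )


def _merge_chain(chain: list[CNVCall]) -> CNVCall:
    """Collapse a chain of same-status calls into one call.

    The merged call spans min start to max end; its copy state is that of the
    largest constituent (dominant evidence — downstream comparisons use
    gain/loss status only); marker counts are summed when known.
    """
    if len(chain) == 1:
        return chain[0]
    start = min(c.start for c in chain)
    end = max(c.end for c in chain)
    dominant = max(chain, key=lambda c: (c.length, -c.start))
    markers = (
        sum(c.n_markers for c in chain)
        if all(c.n_markers is not None for c in chain)
        else None
    )
    return CNVCall(
        sample_id=chain[0].sample_id,
        program_id=chain[0].program_id,
        chrom=chain[0].chrom,
        start=start,
        end=end,
        copy_state=dominant.copy_state,
        n_markers=markers,
        merged_from=sum(c.merged_from for c in chain),
    )


def _scan_once(
    calls: list[CNVCall],
    max_gap_fraction: float,
    decisions: list[MergeDecision],
) -> list[CNVCall]:
    """One left-to-right chained merge pass over one chromosome."""
    out: list[CNVCall] = []
    chain: list[CNVCall] = []
    chain_start = chain_end = 0
    cum_gap = 0

    def flush() -> None:
        if chain:
            out.append(_merge_chain(chain))

    for call in calls:
        if not chain:
            chain = [call]
            chain_start, chain_end = call.start, call.end
            cum_gap = 0
            continue
        if call.status is chain[0].status:
            gap = max(0, call.start - chain_end - 1)
            new_end = max(chain_end, call.end)
            span = new_end - chain_start + 1
            frac = (cum_gap + gap) / span
            merged = frac <= max_gap_fraction
            if gap > 0:
                decisions.append(
                    MergeDecision(
                        left_call=chain[-1],
                        right_call=call,
                        gap_bp=gap,
                        span_bp=span,
                        gap_fraction=frac,
                        merged=merged,
                    )
                )
            if merged:
                chain.append(call)
                chain_end = new_end
                cum_gap += gap
                continue
        flush()
        chain = [call]
        chain_start, chain_end = call.start, call.end
        cum_gap = 0
    flush()
    return out


def merge_adjacent(
    cs: CallSet,
    max_gap_fraction: float = DEFAULT_MAX_GAP_FRACTION,
) -> MergeResult:
    """Merge adjacent same-status calls within one call set.

    Scans each chromosome left to right, growing chains of consecutive
    same-status calls while the cumulative gap fraction over the chain span
    stays at or below ``max_gap_fraction``; overlapping same-status calls
    merge unconditionally (gap 0).  A call of the other status terminates the
    chain (criterion 1: nothing may lie between merge partners).  The scan
    repeats until no further merge applies, so the output is a fixed point:
    ``merge_adjacent(merge_adjacent(cs)) == merge_adjacent(cs)``.
    """
    if not 0 <= max_gap_fraction < 1:
        raise ValidationError(
            f"max_gap_fraction must be in [0, 1), got {max_gap_fraction}"
        )
    decisions: list[MergeDecision] = []
    by_chrom: dict[str, list[CNVCall]] = {}
    for call in cs:
        by_chrom.setdefault(call.chrom, []).append(call)

    merged_calls: list[CNVCall] = []
    for chrom in by_chrom:
        calls = by_chrom[chrom]
        while True:
            merged = _scan_once(calls, max_gap_fraction, decisions)
            if len(merged) == len(calls):
                break
            calls = sorted(merged, key=CNVCall.sort_key)
        merged_calls.extend(calls)

    return MergeResult(
        callset=CallSet(cs.sample_id, cs.program_id, merged_calls),
        decisions=decisions,
    )
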