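"""Headline summaries: cross-program Venn partition, the pairwise difference
statistic d, relatedness-group summaries, and size/chromosome distributions.

The difference statistic for a pair of individuals compared within one
program is

    d = unshared / total

where ``total`` is the number of calls across both individuals and
``unshared = total - 2 * shared_pairs`` with shared pairs determined by
one-to-one >=50% reciprocal-overlap matching.  d = 0 means identical call
sets, d = 1 fully discordant; under purely inherited variation its
expectation tracks genetic relatedness (MZ twins 0, parent-child 0.5,
unrelated 1).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .calls_io import AUTOSOMES, CallSet, CNVCall, Relation, RelatednessPair
from .errors import ConfigurationError, UndefinedStatisticError, ValidationError
from .overlap_match import DEFAULT_RO_THRESHOLD, EventGroup, match_pairwise

#: right-closed size-bin edges in bp: (1 kb, 100 kb], (100 kb, 1 Mb],
#: (1 Mb, 10 Mb], > 10 Mb
DEFAULT_SIZE_BIN_EDGES: tuple[int, ...] = (1_000, 100_000, 1_000_000, 10_000_000)


@dataclass(frozen=True)
class DifferenceStat:
    """Unshared/total call difference for one sample pair, one program."""

    sample_a: str
    sample_b: str
    program_id: str
    shared_pairs: int
    unshared: int
    total: int

    @property
    def d(self) -> float:
        return self.unshared / self.total


def pairwise_difference(
    A: CallSet,
    B: CallSet,
    threshold: float = DEFAULT_RO_THRESHOLD,
) -> DifferenceStat:
    """Compute d between two individuals' call sets from one program."""
    total = len(A) + len(B)
    if total == 0:
        raise UndefinedStatisticError(
            f"d is undefined: no calls for {A.sample_id} or {B.sample_id} "
            f"({A.program_id})"
        )
    shared = len(match_pairwise(A, B, threshold))
    return DifferenceStat(
        sample_a=A.sample_id,
        sample_b=B.sample_id,
        program_id=A.program_id,
        shared_pairs=shared,
        unshared=total - 2 * shared,
        total=total,
    )


@dataclass(frozen=True)
class GroupSummary:
    """Mean/SD/SEM of d over the pairs of one relatedness group, one program."""

    relation: Relation
    program_id: str
    n_pairs: int
    mean_d: float
    sd_d: float
    sem_d: float


def group_difference_summary(
    stats: Iterable[DifferenceStat],
    pairs: Iterable[RelatednessPair],
) -> list[GroupSummary]:
    """Aggregate pair-level d values per (relation, program).

    Every stat's sample pair must appear in the declared pairs.  Dispersion
    is the sample standard deviation (ddof=1) and SEM = sd / sqrt(n); a group
    with a single pair reports sd = sem = 0 by convention (flagged by
    n_pairs = 1).
    """
    relation_of: dict[frozenset[str], Relation] = {
        p.unordered: p.relation for p in pairs
    }
    grouped: dict[tuple[Relation, str], list[float]] = {}
    for st in stats:
        key = frozenset((st.sample_a, st.sample_b))
        if key not in relation_of:
            raise ValidationError(
                f"pair ({st.sample_a}, {st.sample_b}) has no declared relation"
            )
        grouped.setdefault((relation_of[key], st.program_id), []).append(st.d)

    order = {Relation.MZ: 0, Relation.PARENT_CHILD: 1, Relation.UNRELATED: 2}
    summaries: list[GroupSummary] = []
    for (relation, program), values in sorted(
        grouped.items(), key=lambda kv: (order[kv[0][0]], kv[0][1])
    ):
        n = len(values)
        mean = float(np.mean(values))
        sd = float(np.std(values, ddof=1)) if n > 1 else 0.0
        summaries.append(
            GroupSummary(
                relation=relation,
                program_id=program,
                n_pairs=n,
                mean_d=mean,
                sd_d=sd,
                sem_d=sd / math.sqrt(n),
            )
        )
    return summaries


@dataclass(frozen=True)
class SubsetCounts:
    event_group_count: int
    call_count: int


@dataclass
class VennPartition:
    """Event groups and constituent calls per program-membership subset.

    A group containing calls from programs {PC, AGC} contributes one event
    and all its member calls to the {PC, AGC} cell.  Call counts over all
    cells partition the total post-merge call count, which is how a printed
    "12 calls shared by all four programs" coexists with "3 shared events":
    3 events x 4 programs = 12 constituent calls.
    """

    subsets: dict[frozenset[str], SubsetCounts]
    total_calls: int

    def cell(self, *programs: str) -> SubsetCounts:
        return self.subsets.get(frozenset(programs), SubsetCounts(0, 0))

    @property
    def shared_by_all(self) -> SubsetCounts:
        if not self.subsets:
            return SubsetCounts(0, 0)
        universe = frozenset().union(*self.subsets)
        return self.cell(*universe)


def venn_partition(
    groups: Sequence[EventGroup],
    programs: Iterable[str] | None = None,
) -> VennPartition:
    """Partition event groups by the set of programs that called them."""
    allowed = frozenset(programs) if programs is not None else None
    cells: dict[frozenset[str], list[int]] = {}
    total = 0
    for g in groups:
        progs = g.programs
        if allowed is not None:
            if not progs <= allowed:
                raise ValidationError(
                    f"event group has program(s) {sorted(progs - allowed)} "
                    "outside the declared program set"
                )
        counts = cells.setdefault(progs, [0, 0])
        counts[0] += 1
        counts[1] += len(g)
        total += len(g)
    return VennPartition(
        subsets={
            k: SubsetCounts(event_group_count=v[0], call_count=v[1])
            for k, v in cells.items()
        },
        total_calls=total,
    )


def size_distribution(
    calls: Iterable[CNVCall],
    bin_edges: Sequence[int] = DEFAULT_SIZE_BIN_EDGES,
) -> pd.DataFrame:
    """Count calls per size bin per program.

    Bins are right-closed: (1 kb, 100 kb], (100 kb, 1 Mb], (1 Mb, 10 Mb],
    > 10 Mb by default, with an extra leading "<=1kb" bin so that counts
    always sum to the input size even for unfiltered calls.
    """
    edges = list(bin_edges)
    if edges != sorted(edges) or len(set(edges)) != len(edges):
        raise ConfigurationError(f"bin edges must be strictly increasing: {edges}")

    def label(lo: float, hi: float) -> str:
        def fmt(v: float) -> str:
            if v >= 1_000_000:
                return f"{v / 1_000_000:g}Mb"
            if v >= 1_000:
                return f"{v / 1_000:g}kb"
            return f"{v:g}bp"

        if hi == math.inf:
            return f">{fmt(lo)}"
        return f"{fmt(lo)}-{fmt(hi)}"

    labels = [f"<={edges[0] / 1000:g}kb"]
    full_edges = [0, *edges, math.inf]
    for lo, hi in zip(edges, edges[1:] + [math.inf]):
        labels.append(label(lo, hi))

    calls = list(calls)
    programs = sorted({c.program_id for c in calls})
    table = pd.DataFrame(0, index=programs, columns=labels, dtype=int)
    if calls:
        df = pd.DataFrame(
            {
                "program_id": [c.program_id for c in calls],
                "length": [c.length for c in calls],
            }
        )
        df["bin"] = pd.cut(df["length"], bins=full_edges, right=True, labels=labels)
        counts = df.groupby(["program_id", "bin"], observed=False).size()
        for (prog, bin_label), n in counts.items():
            table.loc[prog, bin_label] = int(n)
    table.index.name = "program_id"
    return table


def chromosome_distribution(calls: Iterable[CNVCall]) -> pd.DataFrame:
    """Count calls per autosome per program (all 22 columns, zeros kept)."""
    calls = list(calls)
    programs = sorted({c.program_id for c in calls})
    table = pd.DataFrame(0, index=programs, columns=list(AUTOSOMES), dtype=int)
    for c in calls:
        table.loc[c.program_id, c.chrom] += 1
    table.index.name = "program_id"
    return table
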