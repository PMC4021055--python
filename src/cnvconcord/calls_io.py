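"""Reading, filtering and writing CNV call tables and relatedness pair files.

A *call* is one copy-number segment reported by one calling program for one
sample, on 1-based inclusive genomic coordinates.  Copy-number states are the
discrete HMM states 0..4, where 4 stands for "4 or more copies"; states 0 and 1
are losses, 3 and 4 gains, and 2 is copy-neutral.  Only the 22 autosomes are
analyzed: rows on other chromosomes are excluded (and counted) at ingestion.

The standard inclusion filters are: at least 10 consecutive supporting array
markers, length strictly greater than 1 kb, and a non-neutral state.
"""

from __future__ import annotations

import io
from collections import Counter
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import pandas as pd

from .errors import ConfigurationError, ParseError, ValidationError

AUTOSOMES: tuple[str, ...] = tuple(str(i) for i in range(1, 23))

#: canonical field -> default column header in call tables
DEFAULT_COLUMNS: dict[str, str] = {
    "sample_id": "sample_id",
    "program_id": "program_id",
    "chrom": "chrom",
    "start": "start",
    "end": "end",
    "state": "state",
    "n_markers": "n_markers",
}

_MANDATORY_FIELDS = ("sample_id", "program_id", "chrom", "start", "end", "state")


class Status(str, Enum):
    """Gain/loss binarization of the copy-number state."""

    GAIN = "GAIN"
    LOSS = "LOSS"
    NEUTRAL = "NEUTRAL"


def status_from_state(copy_state: int) -> Status:
    """Map a discrete copy-number state (0..4) to gain/loss status."""
    if copy_state in (0, 1):
        return Status.LOSS
    if copy_state == 2:
        return Status.NEUTRAL
    if copy_state in (3, 4):
        return Status.GAIN
    raise ValidationError(
        f"copy_state must be in 0..4 (4 encodes '4+'), got {copy_state!r}"
    )


def _chrom_sort_key(chrom: str) -> int:
    try:
        return int(chrom)
    except ValueError:
        return 1_000  # non-numeric labels sort last; ingestion excludes them anyway


@dataclass(frozen=True)
class CNVCall:
    """One called copy-number segment for one sample from one program.

    Coordinates are 1-based inclusive, so ``length = end - start + 1``.
    ``merged_from`` counts how many original calls were combined into this one
    (1 for an unmerged call).
    """

    sample_id: str
    program_id: str
    chrom: str
    start: int
    end: int
    copy_state: int
    n_markers: int | None = None
    merged_from: int = 1

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ValidationError(f"start must be >= 1, got {self.start}")
        if self.end < self.start:
            raise ValidationError(
                f"end ({self.end}) must be >= start ({self.start})"
            )
        if self.merged_from < 1:
            raise ValidationError("merged_from must be >= 1")
        status_from_state(self.copy_state)  # validates the state domain

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def status(self) -> Status:
        return status_from_state(self.copy_state)

    def sort_key(self) -> tuple:
        return (_chrom_sort_key(self.chrom), self.start, self.end, self.status.value)


@dataclass
class CallSet:
    """All calls for one (sample, program), kept sorted by (chrom, start, end)."""

    sample_id: str
    program_id: str
    calls: list[CNVCall] = field(default_factory=list)

    def __post_init__(self) -> None:
        for c in self.calls:
            if c.sample_id != self.sample_id or c.program_id != self.program_id:
                raise ValidationError(
                    f"call {c.chrom}:{c.start}-{c.end} belongs to "
                    f"({c.sample_id}, {c.program_id}), not "
                    f"({self.sample_id}, {self.program_id})"
                )
        self.calls = sorted(self.calls, key=CNVCall.sort_key)

    def __len__(self) -> int:
        return len(self.calls)

    def __iter__(self) -> Iterator[CNVCall]:
        return iter(self.calls)

    @property
    def key(self) -> tuple[str, str]:
        return (self.sample_id, self.program_id)


class Relation(str, Enum):
    MZ = "MZ"
    PARENT_CHILD = "parent_child"
    UNRELATED = "unrelated"


_EXPECTED_SHARING = {
    Relation.MZ: 1.0,
    Relation.PARENT_CHILD: 0.5,
    Relation.UNRELATED: 0.0,
}


@dataclass(frozen=True)
class RelatednessPair:
    """A declared sample pair with its degree of genetic relatedness.

    MZ twins share 100% of their genome, parent and child 50%, and unrelated
    individuals 0%; ``expected_sharing`` is derived from the relation.
    """

    sample_a: str
    sample_b: str
    relation: Relation

    def __post_init__(self) -> None:
        if self.sample_a == self.sample_b:
            raise ValidationError(f"self-pair not allowed: {self.sample_a!r}")

    @property
    def expected_sharing(self) -> float:
        return _EXPECTED_SHARING[self.relation]

    @property
    def unordered(self) -> frozenset[str]:
        return frozenset((self.sample_a, self.sample_b))


@dataclass
class TableReadResult:
    """Call sets parsed from a table, plus the count of non-autosomal rows."""

    callsets: list[CallSet]
    excluded_chrom_rows: int

    def __iter__(self) -> Iterator[CallSet]:
        return iter(self.callsets)


@dataclass
class FilterResult:
    """A filtered call set and per-reason drop counts."""

    callset: CallSet
    dropped: dict[str, int]

    @property
    def n_dropped(self) -> int:
        return sum(self.dropped.values())


def read_call_table(
    source,
    dialect: Mapping[str, str] | None = None,
) -> TableReadResult:
    """Read a TSV/CSV call table into one CallSet per (sample, program).

    Parameters
    ----------
    source:
        Path or text stream.  The delimiter is sniffed (TSV or CSV).
    dialect:
        Optional mapping from canonical field names (``sample_id``,
        ``program_id``, ``chrom``, ``start``, ``end``, ``state``,
        ``n_markers``) to the column headers actually present, for ingesting
        exports whose headers differ between callers.

    Rows on chromosomes outside "1".."22" are excluded and counted in the
    result.  Non-integer coordinates/states and end < start raise row-level
    errors that name the offending line.
    """
    columns = dict(DEFAULT_COLUMNS)
    if dialect:
        unknown = set(dialect) - set(DEFAULT_COLUMNS)
        if unknown:
            raise ConfigurationError(
                f"unknown dialect field(s): {sorted(unknown)}; "
                f"allowed: {sorted(DEFAULT_COLUMNS)}"
            )
        columns.update(dialect)

    df = pd.read_csv(source, sep=None, engine="python", dtype=str)
    for fld in _MANDATORY_FIELDS:
        if columns[fld] not in df.columns:
            raise ConfigurationError(
                f"mandatory column {columns[fld]!r} (field {fld!r}) "
                f"missing from call table; found {list(df.columns)}"
            )
    has_markers = columns["n_markers"] in df.columns

    callsets: dict[tuple[str, str], list[CNVCall]] = {}
    excluded = 0
    for idx, row in enumerate(df.itertuples(index=False)):
        rec = dict(zip(df.columns, row))
        line_no = idx + 2  # 1-based, after the header line
        chrom = str(rec[columns["chrom"]]).removeprefix("chr")
        if chrom not in AUTOSOMES:
            excluded += 1
            continue
        try:
            start = int(rec[columns["start"]])
            end = int(rec[columns["end"]])
            state = int(rec[columns["state"]])
        except (TypeError, ValueError) as exc:
            raise ParseError(
                f"line {line_no}: non-integer coordinate or state: {exc}"
            ) from None
        n_markers: int | None = None
        if has_markers:
            raw = rec[columns["n_markers"]]
            if raw is not None and not pd.isna(raw) and str(raw) != "":
                try:
                    n_markers = int(raw)
                except ValueError:
                    raise ParseError(
                        f"line {line_no}: non-integer marker count {raw!r}"
                    ) from None
        try:
            call = CNVCall(
                sample_id=str(rec[columns["sample_id"]]),
                program_id=str(rec[columns["program_id"]]),
                chrom=chrom,
                start=start,
                end=end,
                copy_state=state,
                n_markers=n_markers,
            )
        except ValidationError as exc:
            raise ParseError(f"line {line_no}: {exc}") from None
        callsets.setdefault((call.sample_id, call.program_id), []).append(call)

    result = [
        CallSet(sample_id=s, program_id=p, calls=calls)
        for (s, p), calls in sorted(callsets.items())
    ]
    return TableReadResult(callsets=result, excluded_chrom_rows=excluded)


def filter_calls(
    cs: CallSet,
    min_markers: int = 10,
    min_length_bp: int = 1000,
    exclude_neutral: bool = True,
) -> FilterResult:
    """Apply the standard inclusion filters to one call set.

    Retains exactly the calls with ``n_markers >= min_markers`` (inclusive),
    length strictly greater than ``min_length_bp``, and, when
    ``exclude_neutral``, a non-neutral (gain or loss) state.  Drop counts are
    reported per reason, with precedence markers > length > neutral, so the
    counts plus the retained count partition the input.
    """
    kept: list[CNVCall] = []
    dropped: Counter[str] = Counter({"markers": 0, "length": 0, "neutral": 0})
    for call in cs:
        if min_markers > 0:
            if call.n_markers is None:
                raise ValidationError(
                    f"call {call.chrom}:{call.start}-{call.end} lacks a marker "
                    "count; supply n_markers or disable the filter with "
                    "min_markers=0"
                )
            if call.n_markers < min_markers:
                dropped["markers"] += 1
                continue
        if call.length <= min_length_bp:
            dropped["length"] += 1
            continue
        if exclude_neutral and call.status is Status.NEUTRAL:
            dropped["neutral"] += 1
            continue
        kept.append(call)
    return FilterResult(
        callset=CallSet(cs.sample_id, cs.program_id, kept),
        dropped=dict(dropped),
    )


def read_pairs(source) -> list[RelatednessPair]:
    """Read a pairs file (sample_a, sample_b, relation) into validated pairs.

    Relation keywords are MZ, parent_child, unrelated (case-insensitive).
    Duplicate unordered pairs and self-pairs are rejected.
    """
    df = pd.read_csv(source, sep=None, engine="python", dtype=str)
    required = ("sample_a", "sample_b", "relation")
    for col in required:
        if col not in df.columns:
            raise ConfigurationError(
                f"pairs file missing column {col!r}; found {list(df.columns)}"
            )
    keyword_map = {r.value.lower(): r for r in Relation}
    keyword_map["mz"] = Relation.MZ
    pairs: list[RelatednessPair] = []
    seen: set[frozenset[str]] = set()
    for idx, row in df.iterrows():
        raw_rel = str(row["relation"]).strip().lower()
        if raw_rel not in keyword_map:
            raise ConfigurationError(
                f"line {idx + 2}: unknown relation {row['relation']!r}; "
                f"allowed: {[r.value for r in Relation]}"
            )
        pair = RelatednessPair(
            sample_a=str(row["sample_a"]),
            sample_b=str(row["sample_b"]),
            relation=keyword_map[raw_rel],
        )
        if pair.unordered in seen:
            raise ValidationError(
                f"line {idx + 2}: duplicate pair "
                f"({pair.sample_a}, {pair.sample_b})"
            )
        seen.add(pair.unordered)
        pairs.append(pair)
    return pairs


def callsets_to_frame(callsets: Iterable[CallSet]) -> pd.DataFrame:
    """Flatten call sets to a tidy table (canonical column names)."""
    rows = [
        {
            "sample_id": c.sample_id,
            "program_id": c.program_id,
            "chrom": c.chrom,
            "start": c.start,
            "end": c.end,
            "state": c.copy_state,
            "n_markers": c.n_markers if c.n_markers is not None else "",
            "status": c.status.value,
            "merged_from": c.merged_from,
        }
        for cs in callsets
        for c in cs
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "sample_id", "program_id", "chrom", "start", "end",
            "state", "n_markers", "status", "merged_from",
        ],
    )


def write_call_table(callsets: Iterable[CallSet], dest) -> None:
    """Write call sets as a TSV in the canonical table format."""
    callsets_to_frame(callsets).to_csv(dest, sep="\t", index=False)


def write_pairs(pairs: Iterable[RelatednessPair], dest) -> None:
    df = pd.DataFrame(
        [
            {
                "sample_a": p.sample_a,
                "sample_b": p.sample_b,
                "relation": p.relation.value,
            }
            for p in pairs
        ],
        columns=["sample_a", "sample_b", "relation"],
    )
    df.to_csv(dest, sep="\t", index=False)


def write_bed(callsets: Iterable[CallSet], dest) -> None:
    """Export calls as BED (0-based half-open).

    Columns: chrom, start, end, name (sample|program|status|state),
    score (n_markers, 0 when unknown).
    """
    rows = [
        {
            "chrom": c.chrom,
            "start": c.start - 1,
            "end": c.end,
            "name": f"{c.sample_id}|{c.program_id}|{c.status.value}|{c.copy_state}",
            "score": c.n_markers or 0,
        }
        for cs in callsets
        for c in cs
    ]
    pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "score"]).to_csv(
        dest, sep="\t", index=False, header=False
    )


def read_bed(source) -> TableReadResult:
    """Import a BED written by :func:`write_bed` back to call sets."""
    df = pd.read_csv(
        source,
        sep="\t",
        header=None,
        names=["chrom", "start", "end", "name", "score"],
        dtype=str,
    )
    callsets: dict[tuple[str, str], list[CNVCall]] = {}
    excluded = 0
    for idx, row in df.iterrows():
        chrom = str(row["chrom"]).removeprefix("chr")
        if chrom not in AUTOSOMES:
            excluded += 1
            continue
        try:
            sample_id, program_id, _status, state = str(row["name"]).split("|")
        except ValueError:
            raise ParseError(
                f"line {idx + 1}: BED name field must be "
                "sample|program|status|state"
            ) from None
        n_markers = int(row["score"]) if int(row["score"]) > 0 else None
        call = CNVCall(
            sample_id=sample_id,
            program_id=program_id,
            chrom=chrom,
            start=int(row["start"]) + 1,  # back to 1-based inclusive
            end=int(row["end"]),
            copy_state=int(state),
            n_markers=n_markers,
        )
        callsets.setdefault((sample_id, program_id), []).append(call)
    result = [
        CallSet(sample_id=s, program_id=p, calls=calls)
        for (s, p), calls in sorted(callsets.items())
    ]
    return TableReadResult(callsets=result, excluded_chrom_rows=excluded)
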