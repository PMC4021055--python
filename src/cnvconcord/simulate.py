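"""Synthetic multi-caller CNV call sets over a pedigree of known relatedness.

The truth model is a rare-variant one: each founder genome carries a fixed
number of non-overlapping heterozygous CNVs (loss = state 1, gain = state 3)
placed uniformly on a 22-autosome genome, with lengths drawn log-uniformly so
all size decades are populated.  Monozygotic (MZ) twins carry identical truth
sets; a child inherits each parental CNV independently with probability 1/2.
An optional fraction of loci is shared by every founder, emulating common
copy-number polymorphisms.

Callers are emulated by an error profile: per-CNV detection probability,
Gaussian breakpoint jitter, a chance of emitting a detected CNV as two
fragments separated by a small gap (at most 15% of the span, so the default
20% adjacent-merge rule can re-join them), a status-flip probability, and a
Poisson number of false-positive calls per genome.  Marker counts are
synthesized at one marker per kb (minimum 10), a convenience density rather
than a claim about any particular array.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .calls_io import (
    CallSet,
    CNVCall,
    Relation,
    RelatednessPair,
    write_call_table,
    write_pairs,
)
from .errors import SimulationError, ValidationError

TRUTH_PROGRAM = "TRUTH"
DEFAULT_LENGTH_RANGE: tuple[int, int] = (2_000, 5_000_000)
_SEED_BOUND = 2**31


@dataclass(frozen=True)
class GenomeModel:
    """Autosome lengths in bp (22 chromosomes, each > 10 Mb)."""

    lengths: dict[str, int]

    def __post_init__(self) -> None:
        if len(self.lengths) != 22:
            raise ValidationError("genome model must have exactly 22 autosomes")
        if any(v <= 10_000_000 for v in self.lengths.values()):
            raise ValidationError("all autosome lengths must exceed 10 Mb")

    @classmethod
    def default(cls) -> "GenomeModel":
        # linear descent from 250 Mb (chr1) to ~50 Mb (chr22)
        return cls(
            lengths={
                str(i): 250_000_000 - (i - 1) * 9_500_000 for i in range(1, 23)
            }
        )

    @property
    def total_bp(self) -> int:
        return sum(self.lengths.values())


@dataclass(frozen=True)
class CallerProfile:
    """Error model for one emulated calling program."""

    program_id: str
    sensitivity: float = 1.0
    fp_rate: float = 0.0
    jitter_sd: float = 0.0
    frag_prob: float = 0.0
    state_flip_prob: float = 0.0

    def __post_init__(self) -> None:
        for name in ("sensitivity", "frag_prob", "state_flip_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must be in [0, 1], got {v}")
        if self.jitter_sd < 0 or self.fp_rate < 0:
            raise ValidationError("jitter_sd and fp_rate must be >= 0")


def perfect_profile(program_id: str) -> CallerProfile:
    """A caller that reproduces the truth exactly."""
    return CallerProfile(program_id=program_id)


def default_profiles() -> list[CallerProfile]:
    """Four contrasting caller profiles.

    Three agree broadly (moderate noise); the fourth is permissive with many
    genome-wide false calls, so its output overlaps the others poorly —
    mimicking the qualitative behavior differences seen between HMM callers
    and an aggressive segmentation caller.  Values are chosen for test power,
    not fidelity to any real program.
    """
    return [
        CallerProfile("AGC", sensitivity=0.90, fp_rate=5, jitter_sd=2_000,
                      frag_prob=0.10, state_flip_prob=0.01),
        CallerProfile("PGS", sensitivity=0.85, fp_rate=5, jitter_sd=3_000,
                      frag_prob=0.10, state_flip_prob=0.01),
        CallerProfile("PC", sensitivity=0.90, fp_rate=5, jitter_sd=2_000,
                      frag_prob=0.15, state_flip_prob=0.01),
        CallerProfile("GH", sensitivity=0.95, fp_rate=40, jitter_sd=10_000,
                      frag_prob=0.20, state_flip_prob=0.05),
    ]


@dataclass(frozen=True)
class Individual:
    """A pedigree member: founder, child of two members, or MZ co-twin."""

    sample_id: str
    father: str | None = None
    mother: str | None = None
    twin_of: str | None = None

    def __post_init__(self) -> None:
        if self.twin_of is not None and (self.father or self.mother):
            raise ValidationError(
                "an MZ co-twin copies its twin; declare parents on the twin "
                "it points to"
            )
        if (self.father is None) != (self.mother is None):
            raise ValidationError("declare both parents or neither")


def twin_study_pedigree(
    n_twin_pairs: int = 6, n_parent_couples: int = 2
) -> list[Individual]:
    """The study-shaped cohort: MZ twin pairs, parents for the first couples.

    Defaults give 6 twin pairs plus 2 parent couples = 16 individuals.
    """
    if n_parent_couples > n_twin_pairs:
        raise ValidationError("cannot have more parent couples than twin pairs")
    ped: list[Individual] = []
    for j in range(1, n_parent_couples + 1):
        ped.append(Individual(f"F{j}"))
        ped.append(Individual(f"M{j}"))
    for k in range(1, n_twin_pairs + 1):
        if k <= n_parent_couples:
            ped.append(Individual(f"T{k}a", father=f"F{k}", mother=f"M{k}"))
        else:
            ped.append(Individual(f"T{k}a"))
        ped.append(Individual(f"T{k}b", twin_of=f"T{k}a"))
    return ped


def trio_pedigree(n_trios: int) -> list[Individual]:
    """n independent father-mother-child trios (2n parent-child pairs)."""
    ped: list[Individual] = []
    for i in range(1, n_trios + 1):
        ped.append(Individual(f"F{i}"))
        ped.append(Individual(f"M{i}"))
        ped.append(Individual(f"C{i}", father=f"F{i}", mother=f"M{i}"))
    return ped


@dataclass
class SimConfig:
    """Cohort design, truth model and caller profiles for one simulation."""

    genome: GenomeModel = field(default_factory=GenomeModel.default)
    pedigree: list[Individual] = field(default_factory=twin_study_pedigree)
    n_cnvs_per_founder: int = 80
    length_range: tuple[int, int] = DEFAULT_LENGTH_RANGE
    population_shared_fraction: float = 0.0
    de_novo_per_twin: int = 0
    caller_profiles: list[CallerProfile] = field(default_factory=default_profiles)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.population_shared_fraction <= 1.0:
            raise ValidationError("population_shared_fraction must be in [0, 1]")
        lo, hi = self.length_range
        if not (0 < lo <= hi):
            raise ValidationError(f"bad length range {self.length_range}")
        ids = [ind.sample_id for ind in self.pedigree]
        if len(set(ids)) != len(ids):
            raise ValidationError("duplicate sample ids in pedigree")


def _draw_length(rng: np.random.Generator, length_range: tuple[int, int]) -> int:
    lo, hi = length_range
    return int(round(math.exp(rng.uniform(math.log(lo), math.log(hi)))))


def _overlaps(existing: dict[str, list[tuple[int, int]]], chrom: str,
              start: int, end: int) -> bool:
    return any(s <= end and start <= e for s, e in existing.get(chrom, ()))


def _draw_locus(
    rng: np.random.Generator,
    genome: GenomeModel,
    length_range: tuple[int, int],
    existing: dict[str, list[tuple[int, int]]],
    max_tries: int = 1_000,
) -> tuple[str, int, int]:
    """One uniformly placed locus rejected against overlap with `existing`."""
    chroms = list(genome.lengths)
    weights = np.array([genome.lengths[c] for c in chroms], dtype=float)
    weights /= weights.sum()
    for _ in range(max_tries):
        length = _draw_length(rng, length_range)
        chrom = chroms[rng.choice(len(chroms), p=weights)]
        chrom_len = genome.lengths[chrom]
        if length >= chrom_len:
            continue
        start = int(rng.integers(1, chrom_len - length + 2))
        end = start + length - 1
        if not _overlaps(existing, chrom, start, end):
            return chrom, start, end
    raise SimulationError(
        "could not place a CNV without overlap; genome too small for the "
        "requested number/size of CNVs"
    )


def _markers_for(length: int) -> int:
    return max(10, length // 1_000)


def _truth_call(sample_id: str, chrom: str, start: int, end: int,
                copy_state: int) -> CNVCall:
    return CNVCall(
        sample_id=sample_id,
        program_id=TRUTH_PROGRAM,
        chrom=chrom,
        start=start,
        end=end,
        copy_state=copy_state,
        n_markers=_markers_for(end - start + 1),
    )


def simulate_truth_cohort(cfg: SimConfig) -> dict[str, list[CNVCall]]:
    """Generate the true CNV set for every pedigree member.

    Founders draw ``n_cnvs_per_founder`` non-overlapping loci (a
    ``population_shared_fraction`` of which is drawn once and carried by all
    founders); children inherit each parental CNV with probability 1/2; MZ
    co-twins copy their twin exactly, plus ``de_novo_per_twin`` private
    events each.  Deterministic for a fixed config (including seed).
    """
    rng = np.random.default_rng(cfg.seed)
    n_shared = int(round(cfg.population_shared_fraction * cfg.n_cnvs_per_founder))

    shared_loci: list[tuple[str, int, int, int]] = []
    shared_existing: dict[str, list[tuple[int, int]]] = {}
    for _ in range(n_shared):
        chrom, start, end = _draw_locus(
            rng, cfg.genome, cfg.length_range, shared_existing
        )
        shared_existing.setdefault(chrom, []).append((start, end))
        state = 1 if rng.random() < 0.5 else 3
        shared_loci.append((chrom, start, end, state))

    truth: dict[str, list[CNVCall]] = {}

    def add_private(sample_id: str, n: int,
                    existing: dict[str, list[tuple[int, int]]]) -> list[CNVCall]:
        out = []
        for _ in range(n):
            chrom, start, end = _draw_locus(
                rng, cfg.genome, cfg.length_range, existing
            )
            existing.setdefault(chrom, []).append((start, end))
            state = 1 if rng.random() < 0.5 else 3
            out.append(_truth_call(sample_id, chrom, start, end, state))
        return out

    # founders first, then children (parents resolved), then co-twins
    founders = [i for i in cfg.pedigree if not i.father and not i.twin_of]
    children = [i for i in cfg.pedigree if i.father]
    twins = [i for i in cfg.pedigree if i.twin_of]

    for ind in founders:
        existing = {c: list(v) for c, v in shared_existing.items()}
        calls = [
            _truth_call(ind.sample_id, *locus[:3], locus[3])
            for locus in shared_loci
        ]
        calls += add_private(
            ind.sample_id, cfg.n_cnvs_per_founder - n_shared, existing
        )
        truth[ind.sample_id] = sorted(calls, key=CNVCall.sort_key)

    for ind in children:
        if ind.father not in truth or ind.mother not in truth:
            raise ValidationError(
                f"parents of {ind.sample_id} must precede it in the pedigree"
            )
        calls: list[CNVCall] = []
        existing: dict[str, list[tuple[int, int]]] = {}
        for parent in (ind.father, ind.mother):
            for call in truth[parent]:
                if rng.random() < 0.5:
                    if _overlaps(existing, call.chrom, call.start, call.end):
                        continue  # rare collision between parental haplotypes
                    existing.setdefault(call.chrom, []).append(
                        (call.start, call.end)
                    )
                    calls.append(replace(call, sample_id=ind.sample_id))
        truth[ind.sample_id] = sorted(calls, key=CNVCall.sort_key)

    for ind in twins:
        if ind.twin_of not in truth:
            raise ValidationError(
                f"co-twin {ind.twin_of} of {ind.sample_id} must precede it"
            )
        calls = [
            replace(c, sample_id=ind.sample_id) for c in truth[ind.twin_of]
        ]
        if cfg.de_novo_per_twin:
            existing = {}
            for c in calls:
                existing.setdefault(c.chrom, []).append((c.start, c.end))
            calls += add_private(ind.sample_id, cfg.de_novo_per_twin, existing)
        truth[ind.sample_id] = sorted(calls, key=CNVCall.sort_key)

    return truth


def _flip_state(state: int) -> int:
    return 3 if state in (0, 1) else 1


def _emit(
    truth: Sequence[CNVCall],
    profile: CallerProfile,
    genome: GenomeModel,
    rng: np.random.Generator,
    sample_id: str,
) -> tuple[list[CNVCall], list[tuple[CNVCall, CNVCall]]]:
    """Emit noisy calls for one individual; also return fragment pairs."""
    calls: list[CNVCall] = []
    fragment_pairs: list[tuple[CNVCall, CNVCall]] = []

    def make(chrom: str, start: int, end: int, state: int) -> CNVCall:
        return CNVCall(
            sample_id=sample_id,
            program_id=profile.program_id,
            chrom=chrom,
            start=start,
            end=end,
            copy_state=state,
            n_markers=_markers_for(end - start + 1),
        )

    for t in truth:
        if rng.random() >= profile.sensitivity:
            continue
        start, end = t.start, t.end
        if profile.jitter_sd > 0:
            start += int(round(rng.normal(0, profile.jitter_sd)))
            end += int(round(rng.normal(0, profile.jitter_sd)))
        chrom_len = genome.lengths[t.chrom]
        start = max(1, min(start, chrom_len - 1_000))
        end = min(chrom_len, end)
        if end - start + 1 < 1_001:  # keep every emission past the >1 kb filter
            end = min(chrom_len, start + 1_000)
        state = t.copy_state
        if profile.state_flip_prob and rng.random() < profile.state_flip_prob:
            state = _flip_state(state)
        span = end - start + 1
        fragmented = False
        if profile.frag_prob and span >= 5_000 and rng.random() < profile.frag_prob:
            gap = int(round(span * rng.uniform(0.02, 0.15)))
            avail = span - gap
            left_len = int(round(avail * rng.uniform(0.35, 0.65)))
            right_len = avail - left_len
            if min(left_len, right_len) > 1_200:
                left = make(t.chrom, start, start + left_len - 1, state)
                right = make(t.chrom, end - right_len + 1, end, state)
                calls += [left, right]
                fragment_pairs.append((left, right))
                fragmented = True
        if not fragmented:
            calls.append(make(t.chrom, start, end, state))

    n_fp = rng.poisson(profile.fp_rate)
    for _ in range(int(n_fp)):
        chrom, start, end = _draw_locus(rng, genome, DEFAULT_LENGTH_RANGE, {})
        state = 1 if rng.random() < 0.5 else 3
        calls.append(make(chrom, start, end, state))

    return calls, fragment_pairs


def apply_caller(
    truth: Sequence[CNVCall],
    profile: CallerProfile,
    genome: GenomeModel,
    seed: int,
    sample_id: str | None = None,
) -> CallSet:
    """Run one caller error model over one individual's true CNV set."""
    if sample_id is None:
        if not truth:
            raise ValidationError("sample_id required when truth is empty")
        sample_id = truth[0].sample_id
    rng = np.random.default_rng(seed)
    calls, _pairs = _emit(truth, profile, genome, rng, sample_id)
    return CallSet(sample_id=sample_id, program_id=profile.program_id, calls=calls)


def apply_caller_traced(
    truth: Sequence[CNVCall],
    profile: CallerProfile,
    genome: GenomeModel,
    seed: int,
    sample_id: str | None = None,
) -> tuple[CallSet, list[tuple[CNVCall, CNVCall]]]:
    """Like :func:`apply_caller` but also returns the emitted fragment pairs."""
    if sample_id is None:
        if not truth:
            raise ValidationError("sample_id required when truth is empty")
        sample_id = truth[0].sample_id
    rng = np.random.default_rng(seed)
    calls, pairs = _emit(truth, profile, genome, rng, sample_id)
    cs = CallSet(sample_id=sample_id, program_id=profile.program_id, calls=calls)
    return cs, pairs


def relatedness_pairs(pedigree: Sequence[Individual]) -> list[RelatednessPair]:
    """Enumerate MZ, parent-child and cross-family (unrelated) sample pairs.

    Unrelated pairs are formed by pairing one representative per family
    (families = connected components of the parent/twin graph) into disjoint
    consecutive couples.
    """
    by_id = {i.sample_id: i for i in pedigree}
    pairs: list[RelatednessPair] = []
    for ind in pedigree:
        if ind.twin_of:
            pairs.append(
                RelatednessPair(ind.twin_of, ind.sample_id, Relation.MZ)
            )
        if ind.father:
            pairs.append(
                RelatednessPair(ind.father, ind.sample_id, Relation.PARENT_CHILD)
            )
            pairs.append(
                RelatednessPair(ind.mother, ind.sample_id, Relation.PARENT_CHILD)
            )

    # union-find over family edges
    parent_of: dict[str, str] = {i.sample_id: i.sample_id for i in pedigree}

    def find(x: str) -> str:
        while parent_of[x] != x:
            parent_of[x] = parent_of[parent_of[x]]
            x = parent_of[x]
        return x

    def union(a: str, b: str) -> None:
        parent_of[find(a)] = find(b)

    for ind in pedigree:
        for other in (ind.father, ind.mother, ind.twin_of):
            if other is not None and other in by_id:
                union(ind.sample_id, other)

    reps: list[str] = []
    seen: set[str] = set()
    for ind in pedigree:
        root = find(ind.sample_id)
        if root not in seen:
            seen.add(root)
            reps.append(ind.sample_id)
    for a, b in zip(reps[0::2], reps[1::2]):
        pairs.append(RelatednessPair(a, b, Relation.UNRELATED))
    return pairs


@dataclass
class SimulatedDataset:
    """Truth sets, per-(individual, program) call sets and declared pairs."""

    truth: dict[str, list[CNVCall]]
    callsets: list[CallSet]
    pairs: list[RelatednessPair]
    fragment_pairs: list[tuple[CNVCall, CNVCall]] = field(default_factory=list)


def simulate_dataset(cfg: SimConfig) -> SimulatedDataset:
    """Simulate truth and run every caller profile over every individual."""
    truth = simulate_truth_cohort(cfg)
    rng = np.random.default_rng(cfg.seed)
    callsets: list[CallSet] = []
    fragment_pairs: list[tuple[CNVCall, CNVCall]] = []
    for ind in cfg.pedigree:
        for profile in cfg.caller_profiles:
            sub_seed = int(rng.integers(_SEED_BOUND))
            cs, pairs = apply_caller_traced(
                truth[ind.sample_id], profile, cfg.genome, sub_seed,
                sample_id=ind.sample_id,
            )
            callsets.append(cs)
            fragment_pairs.extend(pairs)
    return SimulatedDataset(
        truth=truth,
        callsets=callsets,
        pairs=relatedness_pairs(cfg.pedigree),
        fragment_pairs=fragment_pairs,
    )


def write_dataset(ds: SimulatedDataset, outdir) -> dict[str, Path]:
    """Write calls.tsv, pairs.tsv and truth.tsv under `outdir`."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "calls": outdir / "calls.tsv",
        "pairs": outdir / "pairs.tsv",
        "truth": outdir / "truth.tsv",
    }
    write_call_table(ds.callsets, paths["calls"])
    write_pairs(ds.pairs, paths["pairs"])
    truth_sets = [
        CallSet(sample_id=sid, program_id=TRUTH_PROGRAM, calls=calls)
        for sid, calls in sorted(ds.truth.items())
    ]
    write_call_table(truth_sets, paths["truth"])
    return paths
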