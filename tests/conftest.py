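import numpy as np
import pytest

from cnvconcord import CallSet, CNVCall


def make_call(
    start,
    end,
    state=1,
    chrom="1",
    sample="S1",
    program="PC",
    n_markers=50,
):
    return CNVCall(
        sample_id=sample,
        program_id=program,
        chrom=chrom,
        start=start,
        end=end,
        copy_state=state,
        n_markers=n_markers,
    )


def make_callset(intervals, sample="S1", program="PC", chrom="1"):
    """Build a CallSet from (start, end, state) triples."""
    return CallSet(
        sample_id=sample,
        program_id=program,
        calls=[
            make_call(s, e, state=st, chrom=chrom, sample=sample, program=program)
            for s, e, st in intervals
        ],
    )


def random_callset(rng: np.random.Generator, n_max=30, sample="S1", program="PC"):
    """Random non-degenerate call set on a couple of chromosomes."""
    n = int(rng.integers(0, n_max + 1))
    calls = []
    for _ in range(n):
        chrom = str(rng.integers(1, 4))
        start = int(rng.integers(1, 500_000))
        length = int(rng.integers(1, 50_000))
        state = int(rng.choice([0, 1, 3, 4]))
        calls.append(
            make_call(start, start + length - 1, state=state, chrom=chrom,
                      sample=sample, program=program)
        )
    return CallSet(sample_id=sample, program_id=program, calls=calls)


@pytest.fixture
def rng():
    return np.random.default_rng(20260922)
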