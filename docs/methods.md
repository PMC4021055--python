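# Methods

## The problem and the model

Different CNV-calling algorithms applied to the same SNP-array data produce
call sets that differ in number, size, boundaries and even gain/loss
direction. `cnvconcord` integrates such call sets and scores callers against
genetics: because CNVs are overwhelmingly inherited, two monozygotic (MZ)
twins should show near-identical call sets, a parent and child should share
about half, and two unrelated individuals (absent common polymorphisms)
should share essentially none. A caller whose between-individual differences
do not follow this gradient is, to that extent, calling noise.

The workflow has four stages, each with one tunable threshold:

| stage | parameter | default | meaning |
|---|---|---|---|
| filter | `min_markers` | 10 | minimum consecutive array markers (inclusive) |
| filter | `min_length_bp` | 1000 | retained calls must be strictly longer (bp) |
| merge | `max_gap_fraction` | 0.20 | max gap/span for adjacent same-status calls |
| match | `ro_threshold` | 0.50 | reciprocal-overlap fraction, boundary inclusive |

Coordinates are 1-based inclusive throughout, so `length = end − start + 1`
and the RO denominators are exactly those lengths; BED import/export converts
to and from 0-based half-open at the boundary. Copy states are the discrete
HMM states 0..4 with 4 meaning "4 or more"; all comparisons binarize states
to gain (3, 4) versus loss (0, 1), since merged events carry only a
gain/loss label. Sex chromosomes are excluded at ingestion (counted, not
silent): the analysis is defined over the 22 autosomes.

## Adjacent-call merging

For ordered same-status calls A, C with uncalled gap B, the merge criterion
is `len(B)/len(A+B+C) ≤ 0.20`, applied only when no other call of any status
lies between A and C. Chains extend under the cumulative form: a chain is
grown call by call while (sum of internal gaps)/(full chain span) stays
within the threshold at every extension step. The phrase "20% or less length
between one and all of the others" is ambiguous between this cumulative
reading and an all-pairwise one; the cumulative reading was chosen as the
direct extension of the two-call formula to "merge all of the CNVs into one
event". A single left-to-right scan under this rule is not a fixed point: a
chain can grow to the point where its gap to a previously rejected neighbor
falls under 20% of the now-larger span. `merge_adjacent` therefore iterates
the scan to convergence, which guarantees idempotence and leaves no pair of
output neighbors that still satisfies the criteria (both are property-tested
on random call sets).

Merged calls keep the shared status; a concrete copy state must still be
stored, and the state of the largest constituent is used (dominant
evidence). Marker counts are summed; `merged_from` counts constituents, so
its total is conserved through merging. Overlapping same-status calls from
one program — degenerate input, since per-program segmentations are
non-overlapping — merge unconditionally (gap 0). Merging never crosses
programs or samples; cross-program unification is the matching stage's job.

## Reciprocal overlap, events, and matching

The pair predicate is symmetric and boundary-inclusive: exactly half-covering
each other passes at the 0.50 default. Same-event grouping across programs
(and, where requested, samples) takes connected components of the
passing-pair graph rather than cliques, so chains of partially overlapping
calls form one event; this mirrors merged-event behavior of graph-based
CNV-consensus tools. Candidate pairs are generated with a per-chromosome
interval index, which only prunes non-intersecting pairs and is therefore
exactly equivalent to exhaustive all-pairs checking (tested against that
oracle on 1,000 random instances).

Between two individuals, shared calls are counted by a one-to-one
maximum-cardinality matching over passing pairs (solved as a linear
assignment with a large constant plus min(O_A, O_B) as profit, so
cardinality dominates and overlap quality breaks ties; a tiny genomic-order
term makes ties deterministic). One-to-one matching is a design choice —
the multiplicity handling of between-individual comparison is otherwise
unspecified — and guarantees no call is ever counted as shared twice.
Matching maximality is tested against an independent augmenting-path oracle.

The difference statistic for a pair compared within one program is
`d = unshared / total` with `total` the two call-set sizes summed and
`unshared = total − 2·shared`. d is undefined (an explicit error, never a
silent 0) when both call sets are empty. Group summaries report mean, sample
SD (ddof = 1) and SEM = SD/√n per (relatedness class, program); a
single-pair group reports SD = SEM = 0, flagged by n = 1. d is deliberately
per-program; a pooled-across-programs d is not defined.

The Venn partition assigns each event group to the subset of programs that
contributed calls to it, and reports both event-group counts and
constituent-call counts, because the two are easily conflated: k events each
seen by all four programs contribute 4k constituent calls to the four-way
cell. Call counts over all cells partition the total post-merge call count
exactly.

Size distributions use right-closed bins ((1 kb, 100 kb], (100 kb, 1 Mb],
(1 Mb, 10 Mb], > 10 Mb) so the conventional decade labels partition cleanly;
an underflow bin keeps the counts summing to the input size for unfiltered
calls. The boundary convention is a package choice; nothing downstream
depends on it.

## The simulator

The simulator exists to make every stage testable at desk scale with known
truth. Its defaults describe a study-shaped cohort: six MZ twin pairs plus
parents for the first two pairs (16 individuals), 80 true CNVs per founder
genome, lengths log-uniform on [2 kb, 5 Mb] (populating all size decades;
no generative length model is claimed), placed uniformly without overlap on
a 22-autosome genome with lengths descending linearly 250 Mb → 50.5 Mb.
True CNVs are heterozygous (loss = state 1, gain = state 3, equiprobable).
MZ twins copy their co-twin exactly — somatic mosaicism between twins is
available as an optional per-twin de novo count, default 0; a child inherits
each parental CNV independently with probability 1/2 (the rare collision of
two parental CNVs in the child is resolved by dropping the later one).
`population_shared_fraction` (default 0.0, a rare-variant model) makes a
fraction of loci common to all founders, emulating copy-number
polymorphisms.

Caller error profiles apply, in order: Bernoulli detection (sensitivity);
Gaussian breakpoint jitter (clamped to chromosome bounds, minimum emitted
length 1001 bp so every emission clears the strict >1 kb filter); a status
flip with small probability; fragmentation with probability `frag_prob`
for spans ≥ 5 kb into two pieces ≥ 1.2 kb separated by a gap of 2–15% of
the span — below the 20% merge rule by construction, so the merge stage can
re-join them; and Poisson(`fp_rate`) uniformly placed false calls. Marker
counts are synthesized at 1 per kb (minimum 10), a convenience density, not
a claim about any array. The four default profiles are three broadly
concordant moderate-noise callers and one permissive caller with many
genome-wide false calls (low cross-program overlap, relatedness-blind d) —
chosen for test power and qualitative contrast, not as calibrated estimates
of any real program's error rates. All randomness flows from a single
integer seed through `numpy.random.default_rng`; fixed configs give
byte-identical outputs.

What passing simulator-based tests shows — and does not. The simulator
omits probe-level intensity, locus-dependent marker density, genuine
breakpoint uncertainty structure, homozygous and multi-allelic states, and
correlated errors between callers at hard loci. Pipeline correctness
(filters, merging, RO matching, d arithmetic) transfers to real data;
quantitative d levels do not.

## Problem sizes and numerical choices

The shipped checks use: 1,000 random instances (≤ 50 calls per side) for the
index-vs-exhaustive RO equivalence; 1,000 random call sets for the merge
fixed point; one perfect-caller 16-individual cohort plus 100 trio families
(200 parent–child pairs, mean d within 0.05 of 0.5) for noise-free
relatedness recovery; 100 replicate noisy cohorts (sensitivity 0.9, 5 kb
jitter, 20% fragmentation, 10 false positives per genome) for the
d-ordering check; and one 16-individual cohort at 50% fragmentation for the
fragment re-join rate. These sizes give stable statistics while keeping a
full run in seconds.

Known limitations: the cumulative-gap chain rule is one defensible reading
of an ambiguous prescription (the all-pairwise alternative is stricter);
event grouping by connected components can chain distinct loci through
bridging calls at permissive thresholds; the d statistic ignores call size,
so one large discordant call and one small one weigh equally; and unrelated
simulated pairs can in principle share a locus by chance placement, so
d(unrelated) = 1 is exact only with rare-variant truth and finite cohorts.
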