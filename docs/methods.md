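# Methods

This note documents the models, parameters and numerical choices behind
`fem`, what the synthetic-data generator does and does not emulate, and the
known limitations.

## Problem statement

Given a reference genome G (sequences over {A,C,G,T,N}), reads R and an
error threshold e (absolute, or a fraction of read length, budget
⌊rate·|R|⌋), report every substring of G within edit distance e of each
read, on either strand. Coordinates are 0-based, intervals half-open.

## Succinct hash index

- `Lu` has 4^k + 1 entries; `Occ` stores only start positions p with
  p mod l_step = 0, *measured within each sequence*. Anchoring the
  sampling per sequence (not on a concatenation) means no recorded window
  can span a sequence boundary, so cross-chromosome phantom matches are
  impossible by construction.
- Windows containing a non-ACGT base are skipped: the 2-bit hash has no
  code for N, and a seed containing N can never match exactly anyway.
- Construction is sort-based: (code, position) pairs are collected into an
  auxiliary table (partitioned across workers), sorted by (code,
  position), and flattened. Because global positions are unique the sort
  key is total and the result — and its serialization — is byte-identical
  for any worker count.
- Positions are stored as 4-byte unsigned integers (`SOI = 4`); genomes
  with ≥ 2^32 total bases are rejected. Model size:
  `SOI · (4^k + ⌈(|G| − k + 1)/l_step⌉)` bytes.
- Defaults: k = 12 (the practical sweet spot for mammalian-scale genomes;
  Lu is then 64 MB), l_step = 2.

## Group seeding (Hamming guarantee)

For position group P_i the serving seed group is j = (l_step − i) mod
l_step. The relation is implemented modularly because i = 0 must pair with
j = 0 (a read aligned at a recorded position is found by seeds at offsets
0, l_step, 2·l_step, …).

Within each group, OPS selects the m = e + 2 non-overlapping length-k
seeds minimizing the summed *recorded* occurrence counts (a DP over the
sorted allowed starts; ties resolved toward leftmost starts). With ≤ e
substitutions at least two of the e + 2 disjoint seeds are error-free and
— substitutions causing no diagonal drift — vote for the exact true
diagonal, so requiring support ≥ 2 keeps the guarantee while discarding
most random single-seed hits. Seeds whose k-mer contains N receive a huge
frequency penalty so OPS avoids them; if a group cannot supply e + 2 clean
seeds it degrades to however many fit with support threshold 1
(sensitivity preserved, more candidates verified). Group seeding makes no
promise under indels; that is variable-length seeding's job.

## Variable-length seeding (edit-distance guarantee)

k' = k + l_step − 1 is the minimal seed length whose length-k windows
cover all l_step congruence classes of offsets; whichever class lines up
with the recorded reference position retrieves an error-free seed. The
pipeline: estimate Est[i] as the sum of the l_step sub-seed counts of the
seed at offset i (N-containing sub-seeds contribute the penalty); OPS over
Est with m = e + 2 and seed length k'; extend the first seed to offset 0
and the last to the read end; award each inter-seed gap to the
higher-frequency neighbour (ties to the earlier seed, matching a single
left-to-right pass); within each extended span keep the cheapest window
per congruence class (ties to the smallest offset); then *phase* trailing
bases unused by any chosen sub-seed into the next span before its classes
are formed.

Correctness of the support filter under edits: the final spans partition
the read, so ≤ e edits leave ≥ 2 spans untouched; each clean span yields a
vote whose diagonal differs from the true read start only by the
cumulative indel drift, bounded by e. Votes on one sequence are therefore
clustered with ±e tolerance, support counts distinct seeds, and clusters
need ≥ 2 supporters (threshold 1 when fewer than e + 2 seeds could be
selected — short-read fallback).

Configuration guard: e + 2 disjoint seeds cap the seed length at
k_max = ⌊|R|/(e+2)⌋ and hence l_step at l_max = k_max − k + 1; mapping
refuses, per read, configurations with l_step > l_max (for 100-bp reads,
e = 4, k = 12 this enforces l_step ≤ 5).

## Verification

Semi-global edit distance (pattern consumed fully, text ends free) is
computed with the Myers bit-vector recurrence; the DP column lives in two
arbitrary-precision integers, so one code path serves all pattern lengths
(this subsumes the blocked multi-word formulation). A plain quadratic DP
(`dp_oracle`, vectorized with a running-minimum trick for the horizontal
dependency) is kept as the independent ground truth; the property suite
asserts equality on thousands of random and adversarial pairs.

Banding is realized by windowing: a candidate cluster with diagonals
[d_min, d_max] is verified on the reference window
[d_min − (e + l_step), d_max + |R| + e + l_step). The half-width e + l_step
covers sampling offset plus indel drift; a triangle bound (an alignment
starting a bases right of d_max needs ≥ a insertions, leaving ≤ e − 2a net
deletions) shows every alignment within the budget lies strictly inside,
so the banded minimum equals the unbanded one — asserted on simulations.

Match identity: among all alignments achieving the window-minimal
distance, the *leftmost start* is reported (computed exactly via a
reversed-pattern global DP row per candidate end), then one CIGAR is
produced by traceback with the fixed move preference diagonal > D > I.
Matches are deduplicated on (sequence, strand, start), keeping the lowest
distance.

## Mapping workflow and SAM conventions

Both strands are mapped (candidates generated independently for the read
and its reverse complement; minus-strand matches are reported on forward
coordinates). SAM output: one primary line per mapped read (lowest edit
distance, then leftmost, then + before −), all other locations secondary
(flag 0x100), `NM` = edit distance, MAPQ = 255 (no mapping-quality model),
unmapped reads emitted with flag 0x4. Reads are dispatched to a worker
pool but emitted in input order, so output is byte-identical for any
thread count. Per-stage counters (candidates, verifications, matches) are
returned for filtration-efficiency bookkeeping.

## Synthetic data and evaluation

The generator emulates Illumina-like resequencing at desk scale: uniform
i.i.d. ACGT genomes (optionally one copied block to exercise
multi-mapping), reads of fixed length from uniform loci and strands, edit
counts uniform in [0, max_edits], each edit an indel with probability
`indel_fraction` (split evenly insertion/deletion, positions uniform
without collision). Defaults — 1 Mb genome, 10,000 reads of 100 bp,
max_edits = 4 (the 4% threshold on 100-bp reads), indel_fraction = 0.15 —
are a desk-scale proxy for a 100k-read human-genome experiment. Not
emulated: base-quality profiles, platform-specific error spectra, GC bias,
real repeat structure. A green sensitivity test therefore establishes the
algorithmic guarantee on this stated world, not performance on real
genomes.

The gold standard contains, per read, every location within edit distance
e on both strands with its minimal distance. Two provably equivalent
builders exist: a literal full-genome DP scan, and a pigeonhole-anchored
scan (the e + 1 disjoint exact read pieces are located on a
full-resolution sorted k-mer table — no sampling, no OPS, none of the
mapper's machinery — and the unbanded DP runs around every hit). The two
are asserted equal on simulations; the fast path makes the 1 Mb × 10k-read
benchmark feasible on one CPU. Location identity uses the same
leftmost-start normalization as the mapper (an approximation of
interval-based benchmark semantics, so evaluator matching can be exact on
starts). Accuracy categories: *all* (fraction of gold locations found),
*all-best* (fraction of minimal-distance locations found), *any-best*
(fraction of reads with ≥ 1 minimal-distance location found), per edit
distance and total, printed to two decimals.

## Numerical/degenerate-input choices

- Ambiguous (N) windows: skipped at build; penalized (2^40) at selection;
  N in the pattern matches nothing during verification.
- Reads shorter than (e+2)·k (group) or (e+2)·k' (vl): seed count
  degrades toward 1 with support threshold 1; a read with no usable seeds
  is reported unmapped.
- Empty lookup slices, empty candidate lists, clamped windows at sequence
  edges all return empty results rather than raising.
- All randomness flows through explicit integer seeds
  (`numpy.random.default_rng`); identical seeds give identical genomes,
  reads, indexes and SAM bytes.

## Known limitations

- One locus can yield two reported matches at nearby distinct starts (or,
  conversely, two pathologically overlapping loci a single match); exact
  dedup is by start only. On uniform synthetic genomes this is
  vanishingly rare; on tandem-repeat-rich real genomes an interval-based
  dedup would be preferable.
- Group seeding with indels is not guaranteed (documented Hamming-only);
  the mapper defaults to variable-length seeding.
- No paired-end mode, no BAM/CRAM, no affine-gap scoring, no
  base-quality-aware verification, no mapping-quality model.
- Throughput is desk-scale (pure Python seeding over numpy tables, numba
  DP kernels): ~500 reads/s on a 1 Mb genome, not a hg19-scale tool.
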