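"""Variable-length seeding: full sensitivity under edit distance.

Group seeding's guarantee breaks once indels shift the alignment frame.
Variable-length seeding instead works with seeds of length at least
k' = k + l_step - 1.  Any error-free seed of length k' spans l_step
consecutive reference positions p, p+1, ..., p+l_step-1 with its length-k
windows (*sub-seeds*), and exactly one of those positions is recorded by
the sampled index — so at least one sub-seed always retrieves the
occurrence (the retrieval lemma tested exhaustively in the suite).

The selection pipeline:

1. estimate the frequency of every length-k' seed as the sum of its l_step
   sub-seed occurrence counts;
2. OPS-select e + 2 non-overlapping seeds on those estimates;
3. extend the selected seeds so their spans partition the whole read
   (boundary extension, then gaps awarded to the higher-frequency
   neighbour);
4. within each extended span, bucket every length-k window by offset mod
   l_step (*sub-seed groups*) and keep the least frequent window per
   bucket; trailing bases unused by any chosen sub-seed are phased over to
   the next seed before its buckets are formed.

With <= e edits, at least two of the e + 2 spans are error-free; each
error-free span contributes a vote whose diagonal is within +-e of the true
read start (indel drift), so votes are merged with +-e tolerance and
clusters need support from >= 2 distinct seeds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError, ParameterError
from .index import SuccinctHashIndex, encode_bases, kmer_codes, lookup, occurrence_counts
from .seeding_group import (
    AMBIG_PENALTY,
    CandidateLocation,
    resolve_occurrences,
    select_with_fallback,
)


@dataclass
class Seed:
    """A selected seed: inclusive read span [start, end], estimated
    frequency f, and its sequence s."""

    start: int
    end: int
    f: int
    s: str = ""


@dataclass(frozen=True)
class SubSeed:
    """A chosen length-k window: read offset ``loc`` and recorded count ``f``."""

    loc: int
    f: int


def min_guaranteed_seed_len(k: int, l_step: int) -> int:
    """Minimal seed length k' = k + l_step - 1 for guaranteed retrieval."""
    if k < 1 or l_step < 1:
        raise ParameterError("k and l_step must be >= 1")
    return k + l_step - 1


def sub_seeds_of(seed_len: int, k: int, l_step: int) -> list[int]:
    """The l_step sub-seed offsets 0..l_step-1 of a length->=k' seed."""
    if seed_len < min_guaranteed_seed_len(k, l_step):
        raise ParameterError(
            f"seed length {seed_len} below minimum {min_guaranteed_seed_len(k, l_step)}"
        )
    return list(range(l_step))


def sub_seed_group(x: int, l_step: int) -> int:
    """Sub-seed group of a window at offset x within its seed: x mod l_step."""
    if x < 0:
        raise ParameterError("offset must be non-negative")
    return x % l_step


def max_seed_len(read_len: int, e: int) -> int:
    """Upper bound on seed length when e + 2 disjoint seeds must fit."""
    if e < 0 or read_len < e + 2:
        raise ConfigurationError(f"read length {read_len} cannot host e+2={e + 2} seeds")
    return read_len // (e + 2)


def max_step(k_max: int, k: int) -> int:
    """Largest admissible l_step for a given k and seed-length bound."""
    l_max = k_max - k + 1
    if l_max < 1:
        raise ConfigurationError(f"k={k} exceeds the maximal seed length {k_max}")
    return l_max


def validate_step(read_len: int, e: int, k: int, l_step: int) -> None:
    """Refuse configurations with l_step > l_max (per-read runtime guard)."""
    l_max = max_step(max_seed_len(read_len, e), k)
    if l_step > l_max:
        raise ConfigurationError(
            f"l_step={l_step} exceeds l_max={l_max} for read length {read_len}, e={e}, k={k}"
        )


def estimate_frequencies(
    read: str | np.ndarray, index: SuccinctHashIndex
) -> np.ndarray:
    """Est[i]: summed recorded counts of the l_step sub-seeds of the
    length-k' seed starting at read offset i.

    Sub-seeds containing a non-ACGT base contribute ``AMBIG_PENALTY``.
    Offsets whose window would overrun the read are not represented.
    """
    enc = encode_bases(read) if isinstance(read, str) else read
    k, l_step = index.k, index.l_step
    codes, valid = kmer_codes(enc, k)
    if len(codes) < l_step:
        return np.empty(0, np.int64)
    counts = occurrence_counts(index, codes)
    counts[~valid] = AMBIG_PENALTY
    cs = np.concatenate([[0], np.cumsum(counts)])
    return cs[l_step:] - cs[:-l_step]


def select_and_extend(
    read: str | np.ndarray,
    Est: np.ndarray,
    e: int,
    index: SuccinctHashIndex,
) -> tuple[list[Seed], list[list[SubSeed]]]:
    """Select e + 2 seeds, extend them to a partition of the read, and pick
    the least frequent sub-seed per sub-seed group.

    Returns the final (trimmed) seed spans and, per seed, the chosen
    sub-seeds (at most l_step each).
    """
    enc = encode_bases(read) if isinstance(read, str) else read
    k, l_step = index.k, index.l_step
    kp = min_guaranteed_seed_len(k, l_step)
    n = len(enc)
    codes, valid = kmer_codes(enc, k)
    counts = occurrence_counts(index, codes)
    counts[~valid] = AMBIG_PENALTY

    freqs = {i: int(Est[i]) for i in range(len(Est))}
    sel = select_with_fallback(freqs, m=e + 2, k=kp)
    if not sel:
        return [], []
    sel.sort()
    seeds = [Seed(start=s, end=s + kp - 1, f=int(Est[s])) for s in sel]

    # Boundary extension: cover the read's prefix and suffix.
    seeds[0].start = 0
    seeds[-1].end = n - 1
    # Gap assignment: the more frequent neighbour absorbs the gap (ties go
    # to the earlier seed), after which the spans partition [0, n).
    for i in range(1, len(seeds)):
        prev, cur = seeds[i - 1], seeds[i]
        if cur.f > prev.f:
            cur.start = prev.end + 1
        else:
            prev.end = cur.start - 1

    bsets: list[list[SubSeed]] = []
    for i, seed in enumerate(seeds):
        span_len = seed.end - seed.start + 1
        best: dict[int, SubSeed] = {}
        for x in range(span_len - k + 1):
            o = seed.start + x
            g = x % l_step
            f = int(counts[o])
            if g not in best or f < best[g].f:
                best[g] = SubSeed(loc=o, f=f)
        chosen = [best[g] for g in sorted(best)]
        bsets.append(chosen)
        # Phasing: trailing bases unused by any chosen sub-seed are handed
        # to the next seed before its buckets are formed.
        if chosen and i + 1 < len(seeds):
            used_end = max(ss.loc + k - 1 for ss in chosen)
            if used_end < seed.end:
                seeds[i + 1].start = used_end + 1
                seed.end = used_end
    return seeds, bsets


def candidates_vl(
    read: str | np.ndarray,
    index: SuccinctHashIndex,
    e: int,
    min_support: int = 2,
) -> list[CandidateLocation]:
    """Candidate diagonals for a read via variable-length seeding.

    Chosen sub-seeds vote with diagonal (occurrence - read offset); votes on
    one sequence within +-e of each other are merged (indel drift) and
    clusters supported by >= ``min_support`` distinct seeds are returned.
    The threshold drops to 1 when fewer than e + 2 seeds could be selected.
    """
    enc = encode_bases(read) if isinstance(read, str) else read
    Est = estimate_frequencies(enc, index)
    if len(Est) == 0:
        return []
    seeds, bsets = select_and_extend(enc, Est, e, index)
    if not seeds:
        return []
    codes, valid = kmer_codes(enc, index.k)
    threshold = min_support if len(seeds) >= e + 2 else 1

    votes: list[tuple[int, int, int]] = []  # (seq, diag, seed_id)
    for sid, chosen in enumerate(bsets):
        for ss in chosen:
            if not valid[ss.loc]:
                continue
            ps = lookup(index, int(codes[ss.loc]))
            if len(ps) == 0:
                continue
            si, lp = resolve_occurrences(index, ps)
            for s, p in zip(si, lp):
                votes.append((int(s), int(p) - ss.loc, sid))
    if not votes:
        return []

    votes.sort()
    out: list[CandidateLocation] = []
    cl_seq, cl_min, cl_max, cl_sids = votes[0][0], votes[0][1], votes[0][1], {votes[0][2]}
    for s, d, sid in votes[1:]:
        if s == cl_seq and d - cl_max <= e:
            cl_max = d
            cl_sids.add(sid)
        else:
            if len(cl_sids) >= threshold:
                out.append(
                    CandidateLocation(
                        index.seq_boundaries[cl_seq][0], cl_min, len(cl_sids), cl_max
                    )
                )
            cl_seq, cl_min, cl_max, cl_sids = s, d, d, {sid}
    if len(cl_sids) >= threshold:
        out.append(
            CandidateLocation(index.seq_boundaries[cl_seq][0], cl_min, len(cl_sids), cl_max)
        )
    return out
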