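"""Group seeding: full-sensitivity candidate generation under Hamming distance.

The sampled index only records reference positions p with p mod l_step == 0.
Partition reference positions into *position groups* P_i (p mod l_step == i)
and read seed starts into *seed groups* S_j (offset mod l_step == j).  For a
substitution-only match starting at p in P_i, a seed at read offset o lines
up with reference position p + o, which is recorded exactly when
o == (l_step - i) mod l_step.  Each position group is therefore served by
exactly one seed group, and running a pigeonhole selection inside every seed
group restores full sensitivity on the sampled index.

Seed selection inside a group is OPS (optimal prefix selection): the set of
m mutually non-overlapping seeds minimizing the summed recorded-occurrence
frequency, found by dynamic programming.  Following the additional-prefix
filter, m = e + 2 seeds are selected and only diagonals supported by at
least two distinct seeds survive; with <= e substitutions at least two of
the e + 2 disjoint seeds are error-free, so the guarantee is preserved.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import SelectionError
from .index import (
    AMBIGUOUS,
    SuccinctHashIndex,
    encode_bases,
    kmer_codes,
    lookup,
    occurrence_counts,
)

#: Frequency assigned to seeds whose k-mer contains a non-ACGT base, so that
#: OPS avoids them whenever a clean alternative exists.
AMBIG_PENALTY = 1 << 40


@dataclass(frozen=True)
class SeedGroupAssignment:
    """The pairing (position group i -> seed group j) for a step size."""

    l_step: int

    @property
    def pairs(self) -> list[tuple[int, int]]:
        return [(i, matching_seed_group(i, self.l_step)) for i in range(self.l_step)]


@dataclass
class CandidateLocation:
    """A putative read-start diagonal on one reference sequence.

    ``diag`` may be negative before clamping (clamped at verification).
    ``diag_max`` >= ``diag`` spans the merged vote diagonals (equal to
    ``diag`` for group seeding, where substitutions cause no drift).
    """

    seq_name: str
    diag: int
    support: int
    diag_max: int | None = None

    def __post_init__(self):
        if self.diag_max is None:
            self.diag_max = self.diag


def position_group(p: int, l_step: int) -> int:
    """Position group index of reference position p: p mod l_step."""
    return p % l_step


def matching_seed_group(i: int, l_step: int) -> int:
    """The unique seed group serving position group i: (l_step - i) mod l_step."""
    return (l_step - i) % l_step


def ops_select(freqs, m: int, k: int) -> list[int]:
    """OPS: m non-overlapping seed starts with minimal total frequency.

    ``freqs`` maps allowed start positions to occurrence counts.  Seeds are
    length k, so selected starts must be pairwise >= k apart.  Among
    minimal-cost selections the leftmost (lexicographically smallest) start
    tuple is returned.  Raises :class:`SelectionError` if fewer than m
    mutually non-overlapping starts exist.
    """
    starts = sorted(freqs)
    n = len(starts)
    if m < 1:
        raise SelectionError("m must be >= 1")
    fs = [freqs[s] for s in starts]
    nxt = [int(np.searchsorted(starts, s + k, side="left")) for s in starts]

    INF = float("inf")
    # dp[t][i]: minimal cost picking t seeds from starts[i:].
    dp = [[0.0] * (n + 1) for _ in range(m + 1)]
    take = [[False] * (n + 1) for _ in range(m + 1)]
    for t in range(1, m + 1):
        dp[t][n] = INF
        for i in range(n - 1, -1, -1):
            skip = dp[t][i + 1]
            tk = fs[i] + dp[t - 1][nxt[i]]
            # prefer taking on ties: leftmost selection
            if tk <= skip:
                dp[t][i], take[t][i] = tk, True
            else:
                dp[t][i], take[t][i] = skip, False
    if dp[m][0] == INF:
        raise SelectionError(f"cannot place {m} non-overlapping seeds of length {k}")
    sel, i, t = [], 0, m
    while t > 0:
        if take[t][i]:
            sel.append(starts[i])
            i, t = nxt[i], t - 1
        else:
            i += 1
    return sel


def select_with_fallback(freqs, m: int, k: int) -> list[int]:
    """ops_select with graceful degradation: largest feasible count <= m."""
    for mm in range(m, 0, -1):
        try:
            return ops_select(freqs, mm, k)
        except SelectionError:
            continue
    return []


def resolve_occurrences(index: SuccinctHashIndex, positions: np.ndarray):
    """Split global occurrence positions into (seq index, local position)."""
    offsets = np.array([off for _, off, _ in index.seq_boundaries] + [1 << 62], dtype=np.int64)
    si = np.searchsorted(offsets, positions, side="right") - 1
    return si, positions - offsets[si]


def candidates_group(
    read: str | np.ndarray,
    index: SuccinctHashIndex,
    e: int,
    min_support: int = 2,
) -> list[CandidateLocation]:
    """Candidate diagonals for a read via group seeding.

    For every seed group j, OPS selects e + 2 non-overlapping length-k seeds
    among starts with offset mod l_step == j; each recorded occurrence p of a
    seed at read offset o votes for diagonal p - o, and diagonals with at
    least ``min_support`` distinct supporting seeds are kept.  Groups that
    cannot supply e + 2 clean seeds degrade to fewer seeds with support
    threshold 1, preserving sensitivity at the cost of more candidates.
    """
    enc = encode_bases(read) if isinstance(read, str) else read
    k, l_step = index.k, index.l_step
    codes, valid = kmer_codes(enc, k)
    n_win = len(codes)
    if n_win == 0:
        return []
    counts = occurrence_counts(index, codes)

    kept: dict[tuple[int, int], int] = {}
    for j in range(l_step):
        group_starts = range(j, n_win, l_step)
        freqs = {
            o: (int(counts[o]) if valid[o] else AMBIG_PENALTY) for o in group_starts
        }
        if not freqs:
            continue
        sel = select_with_fallback(freqs, m=e + 2, k=k)
        clean = [o for o in sel if valid[o]]
        threshold = min_support if len(clean) >= e + 2 else 1
        group_votes: dict[tuple[int, int], set[int]] = {}
        for o in clean:
            ps = lookup(index, int(codes[o]))
            if len(ps) == 0:
                continue
            si, lp = resolve_occurrences(index, ps)
            for s, p in zip(si, lp):
                group_votes.setdefault((int(s), int(p) - o), set()).add(o)
        for key, seeds in group_votes.items():
            if len(seeds) >= threshold:
                kept[key] = kept.get(key, 0) + len(seeds)

    out = [
        CandidateLocation(index.seq_boundaries[s][0], d, supp)
        for (s, d), supp in sorted(kept.items())
    ]
    return out
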