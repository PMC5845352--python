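"""Candidate verification: Myers bit-vector semi-global distance + traceback.

The bit-vector algorithm encodes a whole DP column in two bit-vectors (VP,
VN) and advances one text character with a constant number of word-wide
operations.  Words here are Python arbitrary-precision integers, so any
pattern length runs in the same code path (the multi-word blocking of the
fixed-width formulation is subsumed by bignum arithmetic).

``dp_oracle`` is the plain quadratic semi-global DP kept as the independent
ground truth for the bit-vector path; the property suite asserts the two
agree on random and adversarial inputs.

Verification of a candidate diagonal is banded by construction: the
reference window handed to the bit-vector scan spans the candidate's
diagonal range plus e + l_step of slack on each side, so no alignment
outside the band is ever examined, and for any true location within the
cluster's diagonals the banded minimum equals the unbanded one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _kernels
from .errors import InputError
from .index import SuccinctHashIndex, encode_bases
from .seeding_group import CandidateLocation


@dataclass
class Match:
    """A verified alignment of one read against the reference."""

    read_id: str
    seq_name: str
    ref_start: int
    strand: str  # "+" or "-"
    edit_distance: int
    cigar: str


def _as_enc(s) -> np.ndarray:
    return encode_bases(s) if isinstance(s, str) else np.asarray(s, dtype=np.uint8)


def dp_oracle(pattern, text):
    """Textbook semi-global DP: returns (min_ed, end_positions, matrix).

    The first matrix row is zero (free alignment start anywhere in the
    text); entry [i, j] is the best distance of pattern[:i] against any
    text window ending at j.  End positions are 0-based indices of the
    last aligned text character.
    """
    p, t = _as_enc(pattern), _as_enc(text)
    m, n = len(p), len(t)
    if m == 0 or n == 0:
        raise InputError("pattern and text must be non-empty")
    D = np.zeros((m + 1, n + 1), dtype=np.int32)
    D[:, 0] = np.arange(m + 1)
    jdx = np.arange(1, n + 1, dtype=np.int32)
    for i in range(1, m + 1):
        sub = D[i - 1, :-1] + (p[i - 1] != t)
        up = D[i - 1, 1:] + 1
        row = np.minimum(sub, up)
        # resolve the horizontal (left) dependency with a running minimum:
        # D[i, j] = min over j' <= j of row[j'] + (j - j')
        row = np.minimum.accumulate(row - jdx) + jdx
        D[i, 0] = i
        row = np.minimum(row, D[i, 0] + jdx - 0)  # leading column influence
        D[i, 1:] = row
    last = D[m, 1:]
    min_ed = int(last.min())
    ends = [int(j) for j in np.flatnonzero(last == min_ed)]
    return min_ed, ends, D


def myers_semiglobal(pattern, text):
    """Bit-vector semi-global distance: (min_ed, achieving end positions).

    Equivalent to ``dp_oracle``'s first two outputs; the DP column lives in
    two arbitrary-width integers and each text character costs a handful of
    word operations.
    """
    p, t = _as_enc(pattern), _as_enc(text)
    m, n = len(p), len(t)
    if m == 0 or n == 0:
        raise InputError("pattern and text must be non-empty")
    mask = (1 << m) - 1
    hb = 1 << (m - 1)
    peq = [0, 0, 0, 0, 0]  # A, C, G, T, N (N matches nothing)
    for i, b in enumerate(p):
        if b <= 3:
            peq[b] |= 1 << i
    VP, VN = mask, 0
    score = m
    min_ed, ends = m + n, []
    for j in range(n):
        eq = peq[t[j]] if t[j] <= 3 else 0
        xv = eq | VN
        xh = (((eq & VP) + VP) ^ VP) | eq
        ph = VN | (~(xh | VP) & mask)
        mh = VP & xh
        if ph & hb:
            score += 1
        elif mh & hb:
            score -= 1
        ph = (ph << 1) & mask  # shift in 0: free alignment start (row 0 = 0)
        mh = (mh << 1) & mask
        VP = (mh | (~(xv | ph) & mask)) & mask
        VN = ph & xv
        if score < min_ed:
            min_ed, ends = score, [j]
        elif score == min_ed:
            ends.append(j)
    return min_ed, ends


def leftmost_start(pattern_enc: np.ndarray, text_enc: np.ndarray, ends, min_ed: int):
    """Leftmost alignment start achieving ``min_ed`` over the given ends.

    For an alignment ending at text position j, edit distances to every
    candidate start s are the global distances of the reversed pattern
    against prefixes of the reversed text chunk text[..j]; the leftmost s
    achieving min_ed is read off that row.  Returns (start, end) with the
    smallest start (ties: smallest end).
    """
    m = len(pattern_enc)
    revp = pattern_enc[::-1].copy()
    best = None
    for j in sorted(ends):
        lo = max(0, j + 1 - (m + min_ed))
        revt = text_enc[lo : j + 1][::-1].copy()
        row = _kernels.global_last_row(revp, revt)
        us = np.flatnonzero(row == min_ed)
        if len(us) == 0:
            continue
        s = j + 1 - int(us[-1])
        if best is None or s < best[0]:
            best = (s, j)
    return best


def traceback_cigar(pattern_enc: np.ndarray, text_enc: np.ndarray) -> str:
    """CIGAR of a global alignment of pattern against the full text span.

    Deterministic move preference diagonal > D > I; M covers both match and
    mismatch.
    """
    D = _kernels.global_matrix(pattern_enc, text_enc)
    i, j = len(pattern_enc), len(text_enc)
    ops: list[str] = []
    while i > 0 or j > 0:
        if i > 0 and j > 0 and D[i, j] == D[i - 1, j - 1] + (
            0 if pattern_enc[i - 1] == text_enc[j - 1] else 1
        ):
            ops.append("M")
            i, j = i - 1, j - 1
        elif j > 0 and D[i, j] == D[i, j - 1] + 1:
            ops.append("D")
            j -= 1
        else:
            ops.append("I")
            i -= 1
    ops.reverse()
    out, run, last = [], 0, ""
    for op in ops:
        if op == last:
            run += 1
        else:
            if run:
                out.append(f"{run}{last}")
            run, last = 1, op
    if run:
        out.append(f"{run}{last}")
    return "".join(out)


def verify_candidate(
    read,
    genome,
    cand: CandidateLocation,
    e: int,
    l_step: int,
    read_id: str = "",
    strand: str = "+",
) -> Match | None:
    """Banded verification of one candidate; returns a Match or None.

    The window spans [diag - (e + l_step), diag_max + |read| + e + l_step)
    clamped to the sequence.  If the bit-vector minimum is <= e the leftmost
    start among all minimum-achieving alignments is reported with its CIGAR.
    """
    p = _as_enc(read)
    names = genome.names if hasattr(genome, "names") else [n for n, _, _ in genome]
    si = names.index(cand.seq_name)
    seq = genome.encoded[si]
    slack = e + l_step
    w0 = max(0, cand.diag - slack)
    w1 = min(len(seq), (cand.diag_max if cand.diag_max is not None else cand.diag) + len(p) + slack)
    if w1 <= w0:
        return None
    text = seq[w0:w1]
    min_ed, ends = myers_semiglobal(p, text)
    if min_ed > e:
        return None
    found = leftmost_start(p, text, ends, min_ed)
    if found is None:
        return None
    s, j = found
    cigar = traceback_cigar(p, text[s : j + 1])
    return Match(
        read_id=read_id,
        seq_name=cand.seq_name,
        ref_start=w0 + s,
        strand=strand,
        edit_distance=min_ed,
        cigar=cigar,
    )


def dedup_matches(matches: list[Match]) -> list[Match]:
    """Collapse matches sharing (seq, strand, start), keeping minimal edit
    distance (first seen wins ties); sorted by (seq, start, strand)."""
    best: dict[tuple[str, str, int], Match] = {}
    for m in matches:
        key = (m.seq_name, m.strand, m.ref_start)
        cur = best.get(key)
        if cur is None or m.edit_distance < cur.edit_distance:
            best[key] = m
    return sorted(best.values(), key=lambda m: (m.seq_name, m.ref_start, m.strand))


def cigar_consumes(cigar: str) -> tuple[int, int]:
    """(read bases, reference bases) consumed by a CIGAR over M/I/D/=/X."""
    num, read_n, ref_n = "", 0, 0
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            n = int(num)
            num = ""
            if ch in "M=X":
                read_n += n
                ref_n += n
            elif ch == "I":
                read_n += n
            elif ch == "D":
                ref_n += n
    return read_n, ref_n
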