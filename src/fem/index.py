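"""Succinct hash index: a sampled q-gram index of a reference genome.

The classical q-gram index keeps, for every k-mer, the sorted list of all
its start positions in the genome (lookup table ``Lu`` of 4**k + 1 offsets
into a flat occurrence table ``Occ``).  The succinct variant stores only
positions that are a multiple of ``l_step`` (measured within their own
sequence), shrinking ``Occ`` by a factor of ``l_step``.  Positions dropped
by the sampling are recovered at mapping time by the seeding algorithms in
:mod:`fem.seeding_group` and :mod:`fem.seeding_vl`.

Coordinates are 0-based with half-open intervals throughout.  Sampling is
anchored per sequence, never on a concatenation, so no recorded position
can describe a window spanning a sequence boundary.
"""

from __future__ import annotations

import gzip
import io
import struct
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO

from .errors import (
    IndexCorruptionError,
    IndexFormatError,
    InputError,
    ParameterError,
)

#: Sentinel code for a k-mer containing any non-ACGT character.
AMBIGUOUS = -1

#: Fixed nucleotide -> base-4 digit map (A=0, C=1, G=2, T=3; everything
#: else, including N, encodes to 4 and poisons its windows).
_BASE_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _BASE_CODE[_b] = _i
    _BASE_CODE[_b + 32] = _i  # lowercase

_COMPLEMENT = np.array([3, 2, 1, 0, 4], dtype=np.uint8)

_MAGIC = b"FEMIDX1\n"
_VERSION = 1


def encode_bases(seq: str) -> np.ndarray:
    """Encode a DNA string to a uint8 array (A=0, C=1, G=2, T=3, other=4)."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return _BASE_CODE[raw]


def decode_bases(arr: np.ndarray) -> str:
    return "".join("ACGTN"[b] for b in arr)


def reverse_complement(arr: np.ndarray) -> np.ndarray:
    """Reverse-complement an encoded base array (N maps to N)."""
    return _COMPLEMENT[arr[::-1]]


@dataclass
class ReferenceGenome:
    """An ordered collection of named DNA sequences over {A,C,G,T,N}.

    ``sequences`` is a list of (name, sequence) pairs; names must be unique
    and sequences non-empty.  Encoded arrays and global offsets are derived
    lazily and cached.
    """

    sequences: list[tuple[str, str]]
    _enc: list[np.ndarray] = field(default=None, repr=False, compare=False)
    _offsets: np.ndarray = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        if not self.sequences:
            raise InputError("genome has no sequences")
        names = [n for n, _ in self.sequences]
        if len(set(names)) != len(names):
            raise InputError("duplicate sequence names in genome")
        if any(len(s) == 0 for _, s in self.sequences):
            raise InputError("empty sequence in genome")

    @property
    def names(self) -> list[str]:
        return [n for n, _ in self.sequences]

    @property
    def total_length(self) -> int:
        return sum(len(s) for _, s in self.sequences)

    @property
    def encoded(self) -> list[np.ndarray]:
        if self._enc is None:
            self._enc = [encode_bases(s) for _, s in self.sequences]
        return self._enc

    @property
    def offsets(self) -> np.ndarray:
        """Global offset of each sequence, plus a trailing total length."""
        if self._offsets is None:
            lens = [len(s) for _, s in self.sequences]
            self._offsets = np.concatenate([[0], np.cumsum(lens)]).astype(np.int64)
        return self._offsets

    def locate(self, global_pos: int) -> tuple[int, int]:
        """Map a global position to (sequence index, local position)."""
        i = int(np.searchsorted(self.offsets, global_pos, side="right")) - 1
        return i, int(global_pos - self.offsets[i])

    @classmethod
    def from_fasta(cls, path) -> "ReferenceGenome":
        opener = gzip.open if str(path).endswith(".gz") else open
        with opener(path, "rt") as fh:
            seqs = [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(fh, "fasta")]
        return cls(seqs)


def encode_kmer(s: str, k: int | None = None) -> int:
    """Base-4 integer code of a k-mer; ``AMBIGUOUS`` if it leaves {A,C,G,T}.

    The code is bijective on ACGT-only inputs of a fixed length.
    """
    if k is not None and len(s) != k:
        raise ParameterError(f"k-mer length {len(s)} != k={k}")
    arr = encode_bases(s)
    if (arr > 3).any():
        return AMBIGUOUS
    code = 0
    for b in arr:
        code = code * 4 + int(b)
    return code


def decode_kmer(code: int, k: int) -> str:
    s = []
    for _ in range(k):
        s.append("ACGT"[code & 3])
        code >>= 2
    return "".join(reversed(s))


def kmer_codes(enc: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Codes of all k-mer windows of an encoded sequence.

    Returns ``(codes, valid)`` of length ``len(enc) - k + 1``; ``codes`` is
    int64 and only meaningful where ``valid`` (no non-ACGT base in the
    window) is True.
    """
    n = len(enc) - k + 1
    if n <= 0:
        return np.empty(0, np.int64), np.empty(0, bool)
    codes = np.zeros(n, np.int64)
    valid = np.ones(n, bool)
    for t in range(k):
        b = enc[t : t + n]
        codes = codes * 4 + b
        valid &= b <= 3
    codes[~valid] = AMBIGUOUS
    return codes, valid


@dataclass
class SuccinctHashIndex:
    """Sampled q-gram index: ``Occ`` keeps only every ``l_step``-th position.

    ``Lu[h] .. Lu[h+1]`` delimits the (ascending) occurrence slice of the
    k-mer with code ``h``.  ``Occ`` holds global 0-based positions; the
    sampling criterion ``p mod l_step == 0`` applies to the position within
    its own sequence.  ``seq_boundaries`` records (name, global_offset,
    length) per sequence.
    """

    k: int
    l_step: int
    Lu: np.ndarray  # uint32, length 4**k + 1
    Occ: np.ndarray  # uint32, global positions
    seq_boundaries: list[tuple[str, int, int]]

    @property
    def names(self) -> list[str]:
        return [n for n, _, _ in self.seq_boundaries]

    def __eq__(self, other):
        return (
            isinstance(other, SuccinctHashIndex)
            and self.k == other.k
            and self.l_step == other.l_step
            and self.seq_boundaries == other.seq_boundaries
            and np.array_equal(self.Lu, other.Lu)
            and np.array_equal(self.Occ, other.Occ)
        )


def _chunk_codes(enc: np.ndarray, positions: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Codes and validity for k-mer windows at explicit start positions."""
    codes = np.zeros(len(positions), np.int64)
    valid = np.ones(len(positions), bool)
    for t in range(k):
        b = enc[positions + t]
        codes = codes * 4 + b
        valid &= b <= 3
    return codes, valid


def build_index(
    genome: ReferenceGenome, k: int = 12, l_step: int = 2, n_workers: int = 1
) -> SuccinctHashIndex:
    """Build the succinct hash index by sort-based parallel construction.

    Every sequence is scanned at start positions 0, l_step, 2*l_step, ...
    (windows containing a non-ACGT base are skipped); (code, position)
    pairs are gathered into an auxiliary table, partitioned across
    ``n_workers``, sorted by code then position, and flattened into
    ``Lu``/``Occ``.  The result is independent of ``n_workers``.
    """
    if not 1 <= k <= 16:
        raise ParameterError(f"k={k} out of range [1, 16]")
    if l_step < 1:
        raise ParameterError(f"l_step={l_step} must be >= 1")
    if n_workers < 1:
        raise ParameterError(f"n_workers={n_workers} must be >= 1")
    if genome.total_length >= 2**32:
        raise InputError("genome longer than 2^32 bases is not supported (SOI=4)")

    # Auxiliary-table chunks: (sequence, worker-slice of sampled positions).
    jobs = []
    for si, enc in enumerate(genome.encoded):
        n_win = len(enc) - k + 1
        if n_win <= 0:
            continue
        sampled = np.arange(0, n_win, l_step, dtype=np.int64)
        for part in np.array_split(sampled, n_workers):
            if len(part):
                jobs.append((si, enc, part))

    def run(job):
        si, enc, part = job
        codes, valid = _chunk_codes(enc, part, k)
        gpos = part[valid] + genome.offsets[si]
        return codes[valid], gpos

    if n_workers > 1 and len(jobs) > 1:
        with ThreadPoolExecutor(max_workers=n_workers) as pool:
            results = list(pool.map(run, jobs))
    else:
        results = [run(j) for j in jobs]

    if results:
        all_codes = np.concatenate([c for c, _ in results])
        all_pos = np.concatenate([p for _, p in results])
    else:
        all_codes = np.empty(0, np.int64)
        all_pos = np.empty(0, np.int64)

    # Sort by (code, position); global positions are unique so the order is
    # total and the result worker-count independent.
    order = np.lexsort((all_pos, all_codes))
    occ = all_pos[order].astype(np.uint32)

    counts = np.bincount(all_codes, minlength=4**k)
    lu = np.zeros(4**k + 1, np.uint32)
    lu[1:] = np.cumsum(counts)

    boundaries = [
        (name, int(genome.offsets[i]), len(seq))
        for i, (name, seq) in enumerate(genome.sequences)
    ]
    return SuccinctHashIndex(k=k, l_step=l_step, Lu=lu, Occ=occ, seq_boundaries=boundaries)


def lookup(index: SuccinctHashIndex, code: int) -> np.ndarray:
    """Sorted recorded (sampled) occurrence positions of a k-mer code.

    AMBIGUOUS queries return an empty list: no window containing a non-ACGT
    base is ever recorded.
    """
    if code == AMBIGUOUS or code < 0:
        return np.empty(0, np.int64)
    lo, hi = int(index.Lu[code]), int(index.Lu[code + 1])
    return index.Occ[lo:hi].astype(np.int64)


def occurrence_counts(index: SuccinctHashIndex, codes: np.ndarray) -> np.ndarray:
    """Vectorized |L(code)| for an int64 code array (AMBIGUOUS -> 0)."""
    counts = np.zeros(len(codes), np.int64)
    ok = codes >= 0
    c = codes[ok]
    counts[ok] = index.Lu[c + 1].astype(np.int64) - index.Lu[c].astype(np.int64)
    return counts


def theoretical_size_bytes(G_len: int, k: int, l_step: int, SOI: int = 4) -> int:
    """Model size in bytes of the index: SOI * (4^k + ceil((|G|-k+1)/l_step)).

    With ``l_step == 1`` this is the classical dense q-gram index size.
    """
    if min(G_len, k, l_step, SOI) <= 0:
        raise ParameterError("all arguments must be positive")
    n_occ = -((G_len - k + 1) // -l_step)  # ceil division
    return SOI * (4**k + n_occ)


def save_index(index: SuccinctHashIndex, path) -> None:
    """Serialize an index: magic, version, k, l_step, boundaries, Lu, Occ.

    All integers are fixed-width little-endian unsigned.
    """
    with open(path, "wb") as fh:
        fh.write(_MAGIC)
        fh.write(struct.pack("<IIII", _VERSION, index.k, index.l_step, len(index.seq_boundaries)))
        for name, off, length in index.seq_boundaries:
            nb = name.encode("utf-8")
            fh.write(struct.pack("<I", len(nb)))
            fh.write(nb)
            fh.write(struct.pack("<QQ", off, length))
        fh.write(struct.pack("<QQ", len(index.Lu), len(index.Occ)))
        fh.write(np.ascontiguousarray(index.Lu, dtype="<u4").tobytes())
        fh.write(np.ascontiguousarray(index.Occ, dtype="<u4").tobytes())


def _read_exact(fh: io.BufferedReader, n: int) -> bytes:
    buf = fh.read(n)
    if len(buf) != n:
        raise IndexCorruptionError("index file is truncated")
    return buf


def load_index(path) -> SuccinctHashIndex:
    """Load an index written by :func:`save_index` (round-trip identity)."""
    with open(path, "rb") as fh:
        magic = fh.read(len(_MAGIC))
        if magic != _MAGIC:
            raise IndexFormatError("not a fem index file (bad magic string)")
        version, k, l_step, n_seq = struct.unpack("<IIII", _read_exact(fh, 16))
        if version != _VERSION:
            raise IndexFormatError(f"unsupported index format version {version}")
        boundaries = []
        for _ in range(n_seq):
            (name_len,) = struct.unpack("<I", _read_exact(fh, 4))
            name = _read_exact(fh, name_len).decode("utf-8")
            off, length = struct.unpack("<QQ", _read_exact(fh, 16))
            boundaries.append((name, off, length))
        n_lu, n_occ = struct.unpack("<QQ", _read_exact(fh, 16))
        if n_lu != 4**k + 1:
            raise IndexCorruptionError("lookup table length inconsistent with k")
        lu = np.frombuffer(_read_exact(fh, 4 * n_lu), dtype="<u4").astype(np.uint32)
        occ = np.frombuffer(_read_exact(fh, 4 * n_occ), dtype="<u4").astype(np.uint32)
        if fh.read(1):
            raise IndexCorruptionError("trailing bytes after index payload")
    if int(lu[0]) != 0 or int(lu[-1]) != n_occ:
        raise IndexCorruptionError("lookup table does not delimit the occurrence table")
    return SuccinctHashIndex(k=k, l_step=l_step, Lu=lu, Occ=occ, seq_boundaries=boundaries)
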