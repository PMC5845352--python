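"""The mapping workflow: read queue -> seeding -> verification -> SAM.

``map_read`` maps a single read on both strands (candidates are generated
independently for the forward read and its reverse complement; reverse
matches are reported on forward-reference coordinates with strand "-").
``run_mapping`` streams a FASTA/FASTQ file through a worker pool and writes
a SAM v1.6 file whose body is deterministic regardless of worker count.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from concurrent.futures import ThreadPoolExecutor
from pathlib import Path

import yaml
from Bio import SeqIO

from ._version import __version__ as _pkg_version
from .errors import ConfigurationError, InputError
from .index import (
    ReferenceGenome,
    SuccinctHashIndex,
    encode_bases,
    load_index,
    reverse_complement,
)
from .seeding_group import candidates_group
from .seeding_vl import candidates_vl, validate_step
from .verify import Match, dedup_matches, verify_candidate


@dataclass
class ReadRecord:
    """One sequencing read; the sequence is uppercase-normalized."""

    id: str
    sequence: str
    qualities: str | None = None

    def __post_init__(self):
        if not self.sequence:
            raise InputError(f"read {self.id!r} has an empty sequence")
        self.sequence = self.sequence.upper()


def parse_error_threshold(value) -> tuple[str, float]:
    """Parse an error threshold: 4 -> absolute, "4%" or 0.04 -> rate."""
    if isinstance(value, str) and value.endswith("%"):
        return ("rate", float(value[:-1]) / 100.0)
    if isinstance(value, float) and 0 < value < 1:
        return ("rate", value)
    return ("abs", int(value))


@dataclass
class MappingConfig:
    """Mapping parameters.

    Either ``e`` (absolute edit distance) or ``error_rate`` (fraction of
    read length; the per-read budget is floor(rate * |read|)) must be set;
    the default is the 4% rate used for Illumina-like reads.
    """

    k: int = 12
    l_step: int = 2
    e: int | None = None
    error_rate: float | None = 0.04
    seeding_mode: str = "vl"  # "vl" or "group"
    min_support: int = 2
    threads: int = 1
    output: str | None = None

    def __post_init__(self):
        if self.seeding_mode not in ("vl", "group"):
            raise ConfigurationError(f"unknown seeding mode {self.seeding_mode!r}")
        if self.min_support not in (1, 2):
            raise ConfigurationError("min_support must be 1 or 2")
        if self.e is not None:
            self.error_rate = None

    def edit_budget(self, read_len: int) -> int:
        if self.e is not None:
            return self.e
        return int(self.error_rate * read_len)

    @classmethod
    def from_yaml(cls, path) -> "MappingConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "error_threshold" in raw:
            kind, val = parse_error_threshold(raw.pop("error_threshold"))
            raw["e" if kind == "abs" else "error_rate"] = val
            if kind == "abs":
                raw.setdefault("error_rate", None)
        return cls(**raw)


def map_read(
    read: ReadRecord,
    index: SuccinctHashIndex,
    genome: ReferenceGenome,
    cfg: MappingConfig,
    stats: dict | None = None,
) -> list[Match]:
    """All matches of one read within the edit budget, both strands.

    Short reads degrade gracefully inside the seeding modules (fewer seeds,
    support threshold 1); a read with no usable seeds maps nowhere and is
    reported unmapped by :func:`run_mapping`.
    """
    e = cfg.edit_budget(len(read.sequence))
    validate_step(len(read.sequence), e, cfg.k, cfg.l_step)
    gen = candidates_vl if cfg.seeding_mode == "vl" else candidates_group

    fwd = encode_bases(read.sequence)
    matches: list[Match] = []
    for strand, enc in (("+", fwd), ("-", reverse_complement(fwd))):
        cands = gen(enc, index, e, min_support=cfg.min_support)
        if stats is not None:
            stats["candidates"] = stats.get("candidates", 0) + len(cands)
        for cand in cands:
            if stats is not None:
                stats["verified"] = stats.get("verified", 0) + 1
            m = verify_candidate(
                enc, genome, cand, e, cfg.l_step, read_id=read.id, strand=strand
            )
            if m is not None:
                matches.append(m)
    out = dedup_matches(matches)
    if stats is not None:
        stats["matches"] = stats.get("matches", 0) + len(out)
    return out


def read_records(path):
    """Iterate ReadRecords from a FASTA/FASTQ file (plain or gzip)."""
    p = str(path)
    opener = gzip.open if p.endswith(".gz") else open
    stem = p[:-3] if p.endswith(".gz") else p
    fmt = "fastq" if stem.endswith((".fq", ".fastq")) else "fasta"
    with opener(p, "rt") as fh:
        it = SeqIO.parse(fh, fmt)
        n = 0
        while True:
            try:
                rec = next(it)
            except StopIteration:
                return
            except ValueError as exc:
                raise InputError(f"malformed {fmt} near record {n + 1}: {exc}") from exc
            n += 1
            quals = None
            if "phred_quality" in rec.letter_annotations:
                quals = "".join(
                    chr(q + 33) for q in rec.letter_annotations["phred_quality"]
                )
            yield ReadRecord(id=rec.id, sequence=str(rec.seq), qualities=quals)


_COMP = str.maketrans("ACGTN", "TGCAN")


def _sam_lines(read: ReadRecord, matches: list[Match]) -> list[str]:
    if not matches:
        return [
            "\t".join(
                [read.id, "4", "*", "0", "0", "*", "*", "0", "0", read.sequence,
                 read.qualities or "*"]
            )
        ]
    # primary: lowest edit distance, then leftmost, then + before -
    order = sorted(
        range(len(matches)),
        key=lambda i: (
            matches[i].edit_distance,
            matches[i].seq_name,
            matches[i].ref_start,
            matches[i].strand,
        ),
    )
    lines = []
    for rank, i in enumerate(order):
        m = matches[i]
        flag = (16 if m.strand == "-" else 0) | (256 if rank > 0 else 0)
        if m.strand == "-":
            seq = read.sequence.translate(_COMP)[::-1]
            qual = (read.qualities or "*")[::-1] if read.qualities else "*"
        else:
            seq, qual = read.sequence, read.qualities or "*"
        lines.append(
            "\t".join(
                [read.id, str(flag), m.seq_name, str(m.ref_start + 1), "255",
                 m.cigar, "*", "0", "0", seq, qual, f"NM:i:{m.edit_distance}"]
            )
        )
    return lines


def sam_header(index: SuccinctHashIndex) -> list[str]:
    lines = ["@HD\tVN:1.6\tSO:unknown"]
    for name, _, length in index.seq_boundaries:
        lines.append(f"@SQ\tSN:{name}\tLN:{length}")
    lines.append(f"@PG\tID:fem\tPN:fem\tVN:{_pkg_version}")
    return lines


def run_mapping(ref, index, reads, cfg: MappingConfig, out_path=None) -> dict:
    """Map a read set and write SAM; returns per-stage counters.

    ``ref``/``index``/``reads`` may be paths or already-loaded objects.
    Reads are dispatched to a worker pool but emitted in input order, so
    the SAM body is byte-identical for any worker count.
    """
    genome = ReferenceGenome.from_fasta(ref) if isinstance(ref, (str, Path)) else ref
    idx = load_index(index) if isinstance(index, (str, Path)) else index
    if idx.k != cfg.k or idx.l_step != cfg.l_step:
        raise ConfigurationError(
            f"index built with k={idx.k}, l_step={idx.l_step} but config asks "
            f"k={cfg.k}, l_step={cfg.l_step}"
        )
    expected = [(n, 0, len(s)) for n, s in genome.sequences]
    actual = [(n, 0, ln) for n, _, ln in idx.seq_boundaries]
    if [(n, ln) for n, _, ln in expected] != [(n, ln) for n, _, ln in actual]:
        raise ConfigurationError("index sequences do not match the reference FASTA")

    read_iter = read_records(reads) if isinstance(reads, (str, Path)) else iter(reads)
    out_path = out_path or cfg.output
    stats = {"reads": 0, "mapped": 0, "candidates": 0, "verified": 0, "matches": 0}

    def work(read: ReadRecord):
        local: dict = {}
        matches = map_read(read, idx, genome, cfg, stats=local)
        return read, matches, local

    if cfg.threads > 1:
        pool = ThreadPoolExecutor(max_workers=cfg.threads)
        results = pool.map(work, read_iter, chunksize=16)
    else:
        pool = None
        results = map(work, read_iter)

    lines = sam_header(idx)
    try:
        for read, matches, local in results:
            stats["reads"] += 1
            stats["mapped"] += 1 if matches else 0
            for key in ("candidates", "verified", "matches"):
                stats[key] += local.get(key, 0)
            lines.extend(_sam_lines(read, matches))
    finally:
        if pool is not None:
            pool.shutdown()

    if out_path is not None:
        with open(out_path, "w") as fh:
            fh.write("\n".join(lines) + "\n")
    stats["sam"] = "\n".join(lines) + "\n"
    return stats
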