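"""Synthetic data and accuracy evaluation.

The generator emulates Illumina-like resequencing at desk scale: uniform
i.i.d. ACGT genomes (optionally with one injected repeat block to exercise
multi-mapping), and reads cut from random loci on either strand with a
known script of substitutions, insertions and deletions.  The gold standard
of *all* mapping locations within an edit budget is built independently of
the mapper — either by a literal full-genome semi-global DP scan, or, at
larger scales, by locating the e + 1 disjoint exact read pieces guaranteed
by the pigeonhole lemma on a full-resolution (unsampled) k-mer table and
running the unbanded DP around every hit.  Both routes are full-sensitive;
the suite asserts they agree.

Accuracy is scored in the three benchmark categories: *all* (every location
within the budget), *all-best* (every location at the read's minimal edit
distance) and *any-best* (at least one minimal-distance location), per edit
distance and in total, as percentages.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, NamedTuple

import numpy as np
import pysam

from ._kernels import semiglobal_end_row
from .errors import EvaluationError, ParameterError
from .index import ReferenceGenome, encode_bases, kmer_codes, reverse_complement
from .verify import Match, leftmost_start


class GoldLocation(NamedTuple):
    seq_name: str
    ref_start: int
    strand: str
    min_ed: int


@dataclass
class SimulatedRead:
    """A read with ground truth: origin locus, edit script, edit budget.

    Applying ``edit_script`` to the origin substring reproduces the read
    (before reverse-complementing for minus-strand reads).  ``true_ed`` is
    the number of injected edits; the optimal distance may be lower.
    """

    id: str
    sequence: str
    origin: tuple[str, int, str]  # (seq_name, true_start, strand)
    edit_script: list[tuple]  # (op, origin_pos, base) with op sub/ins/del
    true_ed: int


def apply_edit_script(origin_sub: str, script: list[tuple]) -> str:
    """Apply an edit script (origin coordinates, any order) to a substring."""
    s = list(origin_sub)
    for op, pos, base in sorted(script, key=lambda t: -t[1]):
        if op == "sub":
            s[pos] = base
        elif op == "del":
            del s[pos]
        elif op == "ins":
            s.insert(pos, base)
        else:
            raise ParameterError(f"unknown edit op {op!r}")
    return "".join(s)


def generate_genome(
    length: int, seed: int, repeat_length: int = 0, name: str = "ref"
) -> ReferenceGenome:
    """Uniform i.i.d. ACGT genome; optionally copy one block to a second
    locus so reads from it have >= 2 true locations. Deterministic per seed."""
    if length < 1:
        raise ParameterError("genome length must be >= 1")
    rng = np.random.default_rng(seed)
    arr = rng.integers(0, 4, size=length)
    seq = np.array(list("ACGT"))[arr]
    if repeat_length:
        if 2 * repeat_length > length:
            raise ParameterError("repeat block does not fit twice")
        src = int(rng.integers(0, length // 2 - repeat_length + 1))
        dst = int(rng.integers(length // 2, length - repeat_length + 1))
        seq[dst : dst + repeat_length] = seq[src : src + repeat_length]
    return ReferenceGenome([(name, "".join(seq))])


_RC = str.maketrans("ACGTN", "TGCAN")


def simulate_reads(
    genome: ReferenceGenome,
    n: int,
    read_len: int = 100,
    max_edits: int = 4,
    indel_fraction: float = 0.15,
    seed: int = 0,
) -> list[SimulatedRead]:
    """Reads from uniform loci/strands with 0..max_edits injected edits.

    Each edit is an indel with probability ``indel_fraction`` (split evenly
    between insertion and deletion), otherwise a substitution; edit
    positions are uniform without collision.  Deterministic per seed.
    """
    rng = np.random.default_rng(seed)
    lens = np.array([len(s) for _, s in genome.sequences], dtype=float)
    reads = []
    for ri in range(n):
        c = int(rng.integers(0, max_edits + 1))
        ops = []
        for _ in range(c):
            if rng.random() < indel_fraction:
                ops.append("ins" if rng.random() < 0.5 else "del")
            else:
                ops.append("sub")
        n_ins = ops.count("ins")
        n_del = ops.count("del")
        origin_len = read_len + n_del - n_ins
        si = int(rng.choice(len(lens), p=lens / lens.sum()))
        seq_name, seq = genome.sequences[si]
        if origin_len > len(seq):
            raise ParameterError("read plus edit budget exceeds genome length")
        start = int(rng.integers(0, len(seq) - origin_len + 1))
        sub = seq[start : start + origin_len]
        positions = rng.choice(origin_len, size=c, replace=False) if c else []
        script = []
        for op, pos in zip(ops, positions):
            pos = int(pos)
            if op == "sub":
                base = "ACGT"[int(rng.integers(0, 3))]
                if base == sub[pos]:  # force a real substitution
                    base = "ACGT"[("ACGT".index(base) + 1) % 4]
                script.append(("sub", pos, base))
            elif op == "ins":
                script.append(("ins", pos, "ACGT"[int(rng.integers(0, 4))]))
            else:
                script.append(("del", pos, ""))
        edited = apply_edit_script(sub, script)
        assert len(edited) == read_len
        strand = "+" if rng.random() < 0.5 else "-"
        sequence = edited if strand == "+" else edited.translate(_RC)[::-1]
        reads.append(
            SimulatedRead(
                id=f"r{ri:06d}",
                sequence=sequence,
                origin=(seq_name, start, strand),
                edit_script=script,
                true_ed=c,
            )
        )
    return reads


def write_genome_fasta(genome: ReferenceGenome, path) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.sequences:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")


def write_reads_fastq(reads: Iterable[SimulatedRead], path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.id}\n{r.sequence}\n+\n{'I' * len(r.sequence)}\n")


def write_truth_tsv(reads: Iterable[SimulatedRead], path) -> None:
    with open(path, "w") as fh:
        fh.write("read_id\tseq_name\ttrue_start\tstrand\ttrue_ed\tedit_script\n")
        for r in reads:
            script = ";".join(f"{op}@{pos}:{base}" for op, pos, base in r.edit_script)
            name, start, strand = r.origin
            fh.write(f"{r.id}\t{name}\t{start}\t{strand}\t{r.true_ed}\t{script}\n")


def _normalize_reads(reads) -> list[tuple[str, str]]:
    out = []
    for r in reads:
        if isinstance(r, tuple):
            out.append(r)
        else:
            out.append((r.id, r.sequence))
    return out


def _extract_locations(pat: np.ndarray, text: np.ndarray, ed_row: np.ndarray, e: int, offset: int = 0):
    """Locations from an end-position edit-distance row.

    Contiguous stretches of end positions within the budget are one locus;
    each reports the leftmost start achieving the stretch-minimal distance
    (the same normalization the mapper applies).
    """
    ok = np.flatnonzero(ed_row <= e)
    if len(ok) == 0:
        return []
    splits = np.flatnonzero(np.diff(ok) > 1) + 1
    locs = []
    for run in np.split(ok, splits):
        vals = ed_row[run]
        m_star = int(vals.min())
        ends = [int(j) for j in run[vals == m_star]]
        s, _ = leftmost_start(pat, text, ends, m_star)
        locs.append((offset + s, m_star))
    return locs


def _piece_table(enc: np.ndarray, q: int):
    codes, valid = kmer_codes(enc, q)
    idx = np.flatnonzero(valid)
    c = codes[idx]
    order = np.argsort(c, kind="stable")
    return c[order], idx[order]


def _pigeonhole_locations(pat: np.ndarray, enc: np.ndarray, table, e: int, q: int):
    """Full-sensitive location extraction via exact pigeonhole pieces."""
    m = len(pat)
    codes, valid = kmer_codes(pat, q)
    sorted_codes, sorted_pos = table
    cands = set()
    for piece in range(e + 1):
        off = piece * q
        if off >= len(codes) or not valid[off]:
            continue
        code = codes[off]
        lo = np.searchsorted(sorted_codes, code, side="left")
        hi = np.searchsorted(sorted_codes, code, side="right")
        for p in sorted_pos[lo:hi]:
            cands.add(int(p) - off)
    if not cands:
        return []
    pad = 2 * e + 2
    intervals = []
    for c in sorted(cands):
        a, b = max(0, c - pad), min(len(enc), c + m + pad)
        if intervals and a <= intervals[-1][1]:
            intervals[-1][1] = max(intervals[-1][1], b)
        else:
            intervals.append([a, b])
    locs = []
    for a, b in intervals:
        if b <= a:
            continue
        chunk = enc[a:b]
        ed_row = semiglobal_end_row(pat, chunk)
        locs.extend(_extract_locations(pat, chunk, ed_row, e, offset=a))
    return locs


def gold_standard(
    genome: ReferenceGenome, reads, e: int, method: str = "auto"
) -> dict[str, list[GoldLocation]]:
    """All mapping locations within edit distance e for every read.

    ``method``: "exhaustive" scans every sequence position with the DP;
    "pigeonhole" anchors the scan on exact occurrences of the e + 1
    disjoint read pieces (provably equivalent, far faster on large
    genomes); "auto" picks by problem size.
    """
    pairs = _normalize_reads(reads)
    if method == "auto":
        method = (
            "exhaustive"
            if genome.total_length * max(1, len(pairs)) <= 2 * 10**7
            else "pigeonhole"
        )
    gold: dict[str, list[GoldLocation]] = {rid: [] for rid, _ in pairs}

    tables = {}
    for si, (seq_name, _) in enumerate(genome.sequences):
        enc = genome.encoded[si]
        for rid, seq in pairs:
            fwd = encode_bases(seq)
            for strand, pat in (("+", fwd), ("-", reverse_complement(fwd))):
                if len(pat) > len(enc):
                    continue
                if method == "exhaustive":
                    ed_row = semiglobal_end_row(pat, enc)
                    locs = _extract_locations(pat, enc, ed_row, e)
                else:
                    q = min(len(pat) // (e + 1), 31)
                    if q < 1:
                        ed_row = semiglobal_end_row(pat, enc)
                        locs = _extract_locations(pat, enc, ed_row, e)
                    else:
                        if (si, q) not in tables:
                            tables[(si, q)] = _piece_table(enc, q)
                        locs = _pigeonhole_locations(pat, enc, tables[(si, q)], e, q)
                for start, ed in locs:
                    gold[rid].append(GoldLocation(seq_name, start, strand, ed))
    for rid in gold:
        gold[rid].sort()
    return gold


def locations_from_matches(matches_by_read: dict[str, list[Match]]):
    """Per-read location keys {(seq, strand, start)} from Match lists."""
    return {
        rid: {(m.seq_name, m.strand, m.ref_start) for m in ms}
        for rid, ms in matches_by_read.items()
    }


def locations_from_sam(path):
    """Per-read location keys from a SAM file (primary + secondary lines)."""
    found: dict[str, set] = {}
    with pysam.AlignmentFile(str(path), "r") as sam:
        for rec in sam.fetch(until_eof=True):
            found.setdefault(rec.query_name, set())
            if not rec.is_unmapped:
                strand = "-" if rec.is_reverse else "+"
                found[rec.query_name].add(
                    (rec.reference_name, strand, rec.reference_start)
                )
    return found


def _percent(num: int, den: int):
    return 100.0 * num / den if den else None


def rabema_accuracy(found, gold, category: str, e: int) -> dict:
    """Sensitivity of a mapper output against the gold standard.

    ``found`` maps read id -> set of (seq_name, strand, ref_start);
    ``category`` is "all", "all-best" or "any-best".  Returns
    {"total": pct, "per_ed": {d: pct}, "n": denominator}; per-ed keys are
    only present where the denominator is non-empty.
    """
    cat = category.replace("_", "-")
    if set(found) != set(gold):
        raise EvaluationError("read ids of mapper output and gold standard differ")

    num = {d: 0 for d in range(e + 1)}
    den = {d: 0 for d in range(e + 1)}
    for rid, locs in gold.items():
        locs = [l for l in locs if l.min_ed <= e]
        if not locs:
            continue
        hits = found[rid]
        if cat == "all":
            for l in locs:
                den[l.min_ed] += 1
                num[l.min_ed] += (l.seq_name, l.strand, l.ref_start) in hits
        else:
            best_d = min(l.min_ed for l in locs)
            best = [l for l in locs if l.min_ed == best_d]
            got = [(l.seq_name, l.strand, l.ref_start) in hits for l in best]
            if cat == "all-best":
                den[best_d] += len(best)
                num[best_d] += sum(got)
            elif cat == "any-best":
                den[best_d] += 1
                num[best_d] += any(got)
            else:
                raise EvaluationError(f"unknown category {category!r}")
    total_den = sum(den.values())
    total_num = sum(num.values())
    return {
        "total": _percent(total_num, total_den),
        "per_ed": {d: _percent(num[d], den[d]) for d in range(e + 1) if den[d]},
        "n": total_den,
    }


def rabema_report(found, gold, e: int) -> dict:
    return {
        cat: rabema_accuracy(found, gold, cat, e)
        for cat in ("all", "all-best", "any-best")
    }


def format_rabema_table(report: dict, e: int) -> str:
    """Accuracy table as TSV, percentages to two decimals."""
    cols = ["category", "total"] + [f"ED{d}" for d in range(e + 1)]
    lines = ["\t".join(cols)]
    for cat, res in report.items():
        cells = [cat]
        cells.append("-" if res["total"] is None else f"{res['total']:.2f}")
        for d in range(e + 1):
            v = res["per_ed"].get(d)
            cells.append("-" if v is None else f"{v:.2f}")
        lines.append("\t".join(cells))
    return "\n".join(lines) + "\n"
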