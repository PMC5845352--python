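"""Variable-length seeding: sub-seed arithmetic, retrieval lemma,
extension, edit-distance sensitivity."""

import numpy as np
import pytest

import fem
from fem.index import encode_bases, kmer_codes, occurrence_counts, reverse_complement
from fem.seeding_group import AMBIG_PENALTY, select_with_fallback
from fem.seeding_vl import candidates_vl, select_and_extend, sub_seeds_of


def test_min_guaranteed_seed_len():
    assert fem.min_guaranteed_seed_len(6, 4) == 9
    assert fem.min_guaranteed_seed_len(12, 1) == 12
    assert fem.min_guaranteed_seed_len(12, 2) == 13


def test_sub_seeds_of():
    assert sub_seeds_of(9, 6, 4) == [0, 1, 2, 3]
    assert sub_seeds_of(12, 12, 1) == [0]
    with pytest.raises(fem.ParameterError):
        sub_seeds_of(8, 6, 4)


def test_sub_seed_group():
    assert fem.sub_seed_group(0, 4) == 0
    assert fem.sub_seed_group(5, 4) == 1
    assert {fem.sub_seed_group(x, 4) for x in (0, 4, 8)} == {0}
    # a length-10 seed with k=6 has 5 windows in 4 groups
    groups = [fem.sub_seed_group(x, 4) for x in range(10 - 6 + 1)]
    assert sorted(set(groups)) == [0, 1, 2, 3]


def test_config_bounds():
    assert fem.max_seed_len(100, 4) == 16
    assert fem.max_step(16, 12) == 5
    assert fem.max_seed_len(250, 7) == 27
    assert fem.max_step(27, 12) == 16
    with pytest.raises(fem.ConfigurationError):
        fem.max_seed_len(10, 10)
    fem.validate_step(100, 4, 12, 5)
    with pytest.raises(fem.ConfigurationError):
        fem.validate_step(100, 4, 12, 6)


def test_estimate_frequencies_oracle(genome_10k):
    """Est[i] equals an independent re-summation of sub-seed lookup lengths."""
    idx = fem.build_index(genome_10k, k=6, l_step=3)
    name, seq = genome_10k.sequences[0]
    rng = np.random.default_rng(4)
    for _ in range(10):
        p = int(rng.integers(0, len(seq) - 60))
        read = seq[p : p + 60]
        est = fem.estimate_frequencies(read, idx)
        kp = fem.min_guaranteed_seed_len(6, 3)
        assert len(est) == 60 - kp + 1
        for i in range(len(est)):
            expect = sum(
                len(fem.lookup(idx, fem.encode_kmer(read[i + d : i + d + 6])))
                for d in range(3)
            )
            assert est[i] == expect


def test_estimate_frequencies_absent_kmers(genome_10k):
    idx = fem.build_index(genome_10k, k=12, l_step=2)
    est = fem.estimate_frequencies("ACGT" * 25, idx)  # periodic, almost surely absent
    assert (est[est < AMBIG_PENALTY] >= 0).all()


def test_lemma2_retrieval(genome_20k):
    """Every occurrence of every length-k' substring is retrieved by at
    least one of its l_step sub-seeds from the sampled index."""
    name, seq = genome_20k.sequences[0]
    enc = genome_20k.encoded[0]
    k = 6
    for l_step in (2, 3, 4):
        idx = fem.build_index(genome_20k, k=k, l_step=l_step)
        kp = k + l_step - 1
        codes, valid = kmer_codes(enc, k)
        for p in range(len(seq) - kp + 1):
            # the recorded position within [p, p + l_step) and its sub-seed
            x = (-p) % l_step
            ps = fem.lookup(idx, int(codes[p + x]))
            j = np.searchsorted(ps, p + x)
            assert j < len(ps) and ps[j] == p + x, (l_step, p)


def test_select_and_extend_partition(genome_50k, index_50k):
    name, seq = genome_50k.sequences[0]
    rng = np.random.default_rng(9)
    for _ in range(20):
        p = int(rng.integers(0, len(seq) - 100))
        read = seq[p : p + 100]
        est = fem.estimate_frequencies(read, index_50k)
        seeds, bsets = select_and_extend(read, est, e=4, index=index_50k)
        assert len(seeds) == 6  # e + 2
        # spans partition [0, len(read))
        assert seeds[0].start == 0
        for a, b in zip(seeds, seeds[1:]):
            assert b.start == a.end + 1
        # chosen sub-seeds: <= l_step per seed, inside their span
        for seed, chosen in zip(seeds, bsets):
            assert 1 <= len(chosen) <= index_50k.l_step
            for ss in chosen:
                assert seed.start <= ss.loc <= seed.end - index_50k.k + 1


def test_extension_beats_naive_choice(genome_50k, index_50k):
    """Total frequency of the chosen sub-seeds never exceeds that of the
    naive fixed-length choice (all l_step sub-seeds of unextended seeds)."""
    name, seq = genome_50k.sequences[0]
    k, l_step = index_50k.k, index_50k.l_step
    kp = k + l_step - 1
    rng = np.random.default_rng(10)
    for _ in range(30):
        p = int(rng.integers(0, len(seq) - 100))
        read = seq[p : p + 100]
        enc = encode_bases(read)
        est = fem.estimate_frequencies(enc, index_50k)
        codes, valid = kmer_codes(enc, k)
        counts = occurrence_counts(index_50k, codes)
        counts[~valid] = AMBIG_PENALTY
        _, bsets = select_and_extend(enc, est, e=4, index=index_50k)
        chosen_total = sum(ss.f for chosen in bsets for ss in chosen)
        naive_starts = select_with_fallback(
            {i: int(est[i]) for i in range(len(est))}, m=6, k=kp
        )
        naive_total = sum(
            int(counts[s + d]) for s in naive_starts for d in range(l_step)
        )
        assert chosen_total <= naive_total


def test_candidates_vl_exact_and_absent(genome_50k, index_50k):
    name, seq = genome_50k.sequences[0]
    p = 30_000
    read = seq[p : p + 100]
    cands = candidates_vl(read, index_50k, e=0)
    assert any(c.diag <= p <= c.diag_max for c in cands)
    # a random read absent from the genome yields no supported cluster
    rng = np.random.default_rng(14)
    while True:
        probe = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 100)])
        if probe not in seq:
            break
    assert candidates_vl(probe, index_50k, e=0) == []


def test_edit_distance_sensitivity(genome_50k, index_50k):
    """Reads with <= e edits (incl. indels): a candidate cluster lies
    within +-e of every true start, on the correct strand."""
    reads = fem.simulate_reads(
        genome_50k, 200, read_len=100, max_edits=4, indel_fraction=0.3, seed=22
    )
    e = 4
    for r in reads:
        name, start, strand = r.origin
        enc = encode_bases(r.sequence)
        pat = enc if strand == "+" else reverse_complement(enc)
        cands = candidates_vl(pat, index_50k, e)
        assert any(
            c.diag - e <= start <= c.diag_max + e for c in cands
        ), (r.id, strand)
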