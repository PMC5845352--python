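"""Map simulated reads and write SAM.

Every mapping location within the edit budget is reported: the lowest-
distance location is the primary line, all others are secondary (flag
0x100), and NM carries the edit distance.
"""

import fem
from fem.mapper import MappingConfig, ReadRecord

genome = fem.generate_genome(100_000, seed=3)
index = fem.build_index(genome, k=12, l_step=2)
reads = fem.simulate_reads(genome, 50, read_len=100, max_edits=4,
                           indel_fraction=0.15, seed=4)

cfg = MappingConfig(k=12, l_step=2, error_rate=0.04, seeding_mode="vl", threads=2)
records = [ReadRecord(r.id, r.sequence) for r in reads]
stats = fem.run_mapping(genome, index, records, cfg, out_path="scratch_example.sam")

print("per-stage counters:", {k: v for k, v in stats.items() if k != "sam"})
print("first mapped SAM line:")
print("  " + next(l for l in stats["sam"].splitlines() if not l.startswith("@")))
# Fields: read id, FLAG, sequence, 1-based POS, MAPQ 255 (unavailable),
# CIGAR, mate fields, sequence, qualities, NM:i:<edit distance>.
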