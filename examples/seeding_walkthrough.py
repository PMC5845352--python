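"""The two seeding strategies on one read, step by step.

Group seeding (substitution-only guarantee): reads and reference positions
are partitioned modulo l_step; position group P_i is served exactly by
seed group S_j with (i + j) mod l_step == 0.

Variable-length seeding (full edit-distance guarantee): seeds of length
k' = k + l_step - 1 are selected on estimated frequencies, extended into a
partition of the read, and the cheapest length-k sub-seed per congruence
class is queried.
"""

import fem
from fem.seeding_group import candidates_group
from fem.seeding_vl import candidates_vl, select_and_extend

l_step = 4
print(f"l_step={l_step}: position group -> seed group pairing:")
for i in range(l_step):
    print(f"  P_{i} <- S_{fem.matching_seed_group(i, l_step)}")

print(f"k'=k+l_step-1 for k=6, l_step=4: {fem.min_guaranteed_seed_len(6, 4)}")
print(f"sub-seed offsets of a length-9 seed: {fem.sub_seeds_of(9, 6, 4)}")

genome = fem.generate_genome(50_000, seed=5)
index = fem.build_index(genome, k=12, l_step=2)
name, seq = genome.sequences[0]
read = seq[20_000:20_100]

est = fem.estimate_frequencies(read, index)
seeds, bsets = select_and_extend(read, est, e=2, index=index)
print("\nselected + extended seed spans (e=2 -> e+2=4 seeds):")
for seed, chosen in zip(seeds, bsets):
    subs = [(ss.loc, ss.f) for ss in chosen]
    print(f"  span [{seed.start:3d},{seed.end:3d}]  est={seed.f:3d}  sub-seeds={subs}")

for label, cands in (
    ("group", candidates_group(read, index, e=2)),
    ("vl", candidates_vl(read, index, e=2)),
):
    print(f"{label:>5} seeding candidates: "
          f"{[(c.diag, c.support) for c in cands]}")
# Both strategies place the true locus (diagonal 20000) among the
# candidates; support counts the distinct seeds voting for it.
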