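"""Build a succinct hash index and query occurrence lists.

The index records, for every k-mer, only the genome start positions that
are a multiple of l_step — the occurrence table shrinks ~l_step-fold while
the seeding algorithms recover the sampled-away locations at map time.
"""

import fem

genome = fem.generate_genome(50_000, seed=1)
index = fem.build_index(genome, k=12, l_step=2)

name, seq = genome.sequences[0]
kmer = seq[1000:1012]
code = fem.encode_kmer(kmer)
print(f"occurrences of {kmer} (sampled, every {index.l_step}nd position):")
print(" ", fem.lookup(index, code).tolist())

dense = fem.build_index(genome, k=12, l_step=1)
print(f"dense index records {len(dense.Occ)} positions, "
      f"sampled index only {len(index.Occ)}")

hg = 3_100_000_000
print("modelled index size for a 3.1 Gb genome, k=12:")
for l_step in (1, 2, 4):
    size = fem.theoretical_size_bytes(hg, 12, l_step, SOI=4)
    print(f"  l_step={l_step}: {size / 1e9:.1f} GB")
# The sampled table turns a >12 GB dense q-gram index into ~3 GB at l_step=4.
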