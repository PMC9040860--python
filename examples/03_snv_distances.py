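"""Pairwise SNV distances and a windowed SNV-density track.

Under the substitution-only model every parent-distinguishing site in the
transconjugant matches exactly one parent, so the distances decompose:
d(tc, recipient) + d(tc, donor) = d(recipient, donor).
"""

from dctmosaic import (
    ParentPairConfig,
    TransferConfig,
    generate_parent_pair,
    simulate_transconjugant,
    snv_density_track,
    snv_matrix,
    snv_table,
)

recipient, donor, variants = generate_parent_pair(
    ParentPairConfig(length_bp=200_000, snv_density=0.001, seed=5)
)
tc, _ = simulate_transconjugant(
    recipient, donor,
    TransferConfig(n_segments=4, segment_length_dist=("log-uniform", 2_000, 20_000),
                   seed=6),
)

matrix = snv_matrix([recipient, donor, tc])
print("pairwise SNV counts:")
print(matrix.to_dataframe())

d_tr = matrix[(tc.name, recipient.name)]
d_td = matrix[(tc.name, donor.name)]
d_rd = matrix[(recipient.name, donor.name)]
print(f"\nconservation: {d_tr} + {d_td} = {d_tr + d_td} (parents differ by {d_rd})")

track = snv_density_track(snv_table(recipient, donor), 10_000, len(recipient))
print("\nSNVs per 10-kb window (recipient vs donor):")
print(" ".join(str(c) for _, c in track))
# At density 0.001/bp each 10-kb window carries ~10 SNVs; donor tracts in a
# transconjugant appear as windows where its SNVs match the donor instead.
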