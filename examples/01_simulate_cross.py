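"""Simulate a conjugal cross: divergent parents, then a mosaic transconjugant.

Builds a 500-kb collinear parent pair differing by ~1 SNV per 100 bp (the
density seen between the most divergent natural M. smegmatis isolates),
then transfers 8 donor segments into the recipient backbone.
"""

from dctmosaic import (
    ParentPairConfig,
    TransferConfig,
    generate_parent_pair,
    simulate_transconjugant,
)

recipient, donor, variants = generate_parent_pair(
    ParentPairConfig(length_bp=500_000, snv_density=0.01, seed=1)
)
print(f"parents: {len(recipient):,} bp, {len(variants):,} distinguishing SNVs")

tc, truth = simulate_transconjugant(
    recipient,
    donor,
    TransferConfig(
        n_segments=8,
        segment_length_dist=("log-uniform", 2_000, 30_000),
        seed=2,
    ),
)
print(f"transconjugant: {len(tc):,} bp")
print(f"true donor fraction: {truth.donor_fraction:.2%} "
      f"in {len(truth.donor_segments)} segments")
for iv in truth.donor_segments:
    print(f"  donor tract [{iv.start:>7,}, {iv.end:>7,})  {iv.length:>6,} bp")

# The donor fraction is the ground truth the painting pipeline must recover;
# each tract is a block of recipient chromosome replaced by donor sequence.
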