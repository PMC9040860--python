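# dctmosaic

Chromosome painting for mosaic bacterial genomes produced by
**distributive conjugal transfer (DCT)** — the mycobacterial conjugation
mechanism that moves multiple, noncontiguous chromosome segments from a
donor into a recipient, yielding transconjugant genomes that are mosaic
blends of their parents.

The package is aimed at microbial genomicists analyzing transconjugants
from defined crosses (e.g. between natural *Mycobacterium smegmatis*
isolates) and at anyone who needs a testbed for window-based
parental-origin assignment: it ships a seeded simulator of divergent
parental genome pairs and ground-truth mosaic progeny alongside the
painting pipeline itself.

## The method

Given a transconjugant genome *T* and its two collinear parents *R*
(recipient) and *D* (donor):

1. **Tile** *T* into nonoverlapping windows of *W* = 500 bp (a trailing
   window shorter than *W*/2 is merged into its neighbor).
2. **Score** each window's nucleotide identity to each parent. In aligned
   mode (collinear, equal-length genomes) identity to parent *P* is exact:
   `id_P = matches / W = 1 − Hamming(window, P) / W`. In mapping mode the
   window is seeded into *P* by shared k-mers and scored as
   `1 − editDistance / W` against its best-matching locus.
3. **Assign** each window to the parent with the strictly higher identity.
   A window identical to both parents is uninformative and inherits the
   origin of the nearest preceding assigned window; windows below a
   minimum identity τ (default 0.9) — marker cassettes, foreign tracts —
   are left unassigned.
4. **Concatenate** consecutive same-origin windows into segments. Donor
   segments of at least one window are the *transferred regions*.
5. **Report** per genome: percent of DNA from each parent, number of
   transferred regions, and the largest transferred region (bp); per
   cohort: mean event count and the donor-percent range.

Pairwise SNV tables/matrices, windowed SNV-density tracks, global
protein percent identity (BLOSUM62, affine gaps, gap-inclusive
denominator) and locus-level SNV catalogs with coding effects round out
the toolkit, along with circular/linear mosaic plots backed by plain-text
drawing tables.

## Worked example

```python
from dctmosaic import (
    ParentPairConfig, TransferConfig, generate_parent_pair,
    simulate_transconjugant, paint_genome, merge_runs, transconjugant_report,
)

recipient, donor, _ = generate_parent_pair(
    ParentPairConfig(length_bp=500_000, snv_density=0.01, seed=1))
tc, truth = simulate_transconjugant(
    recipient, donor,
    TransferConfig(n_segments=8,
                   segment_length_dist=("log-uniform", 2_000, 30_000), seed=2))

calls = paint_genome(tc, recipient, donor)
report = transconjugant_report(merge_runs(calls), len(tc),
                               recipient.name, donor.name)
print(f"{report.pct_recipient:.2f}% recipient / {report.pct_donor:.2f}% donor")
print(f"transferred regions: {report.n_transferred_regions}")
print(f"largest region: {report.largest_region_bp:,} bp")
```

prints

```
88.10% recipient / 11.90% donor
transferred regions: 8
largest region: 18,000 bp
```

The painter recovers all 8 planted donor tracts; the donor percentage
(11.90%) matches the simulated truth (11.89%) to within one 500-bp window
per segment edge, and the largest region is a whole number of windows.
The `examples/` directory holds one short script per capability
(simulation, painting, SNV distances, locus comparison, plotting,
published-cohort aggregates), each printing the numbers it computes.

A thin CLI wraps the same functions:

```bash
dctmosaic simulate-cross --length 2000000 --density 0.01 --segments 10 --seed 11 --out-dir cross
dctmosaic classify --transconjugant cross/transconjugant.fasta \
    --recipient cross/recipient.fasta --donor cross/donor.fasta --out-dir painted
dctmosaic report --windows painted/windows.tsv --out-dir report
```

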