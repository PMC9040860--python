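# Methods

## Problem and model

Distributive conjugal transfer (DCT) produces progeny whose chromosome is
a recipient backbone punctuated by multiple, noncontiguous donor-derived
tracts. Because the parents of a defined cross are collinear and differ
mainly by point substitutions, every parent-distinguishing SNV inside a
transferred tract switches allegiance from recipient to donor, and tract
boundaries can be located to roughly the spacing of informative sites.
The painting procedure operationalizes this at fixed resolution: windows
of *W* bp are assigned to whichever parent they match better, and runs of
same-origin windows become segments.

The package treats three nested tasks: (i) simulating crosses with known
ground truth, (ii) painting a genome and reporting per-genome and cohort
statistics, (iii) locus-level comparisons (protein percent identity, SNV
catalogs) that support compatibility analysis between strains.

## Coordinates and formats

All intervals are 0-based half-open, BED-compatible; 1-based positions
appear only in human-readable report columns and are labeled. FASTA I/O
is Biopython; sequences are restricted to {A, C, G, T, N} with U→T.
Circular topology is recorded as metadata but windows never wrap the
origin — painting is a linear scan, which is also why largest-region
values come out as whole multiples of the window size on tail-free
genomes.

## Synthetic data: what it emulates, and what it does not

`generate_parent_pair` draws a recipient of GC content 0.67 (typical of
*M. smegmatis*) and a donor differing at exactly `round(d·L)` uniformly
placed sites, alternate alleles uniform over the three non-reference
bases. The two default densities are the observed extremes between
natural isolates: d = 0.01 (≈1 SNV per 100 bp, a divergent pair) and
d = 0.001 (≈1 per kb, the closest pair). Uniform placement is a
simplification: real isolate pairs carry SNVs in mosaic patches
(SNV-dense blocks between near-identical stretches), plus indels,
insertion sequences and rearrangements, none of which are modeled by
default. Passing tests therefore demonstrate correctness of the painting
machinery under the collinear substitution-only model, not robustness to
structural variation; mapping mode exists for the latter but is validated
here only on marker insertions.

`simulate_transconjugant` replaces each planted tract of the recipient
with the donor's bases over the same interval. Tract count defaults to
16 (cohort draws use Poisson(16), truncated at 1) and tract lengths are
log-uniform on [1 kb, 250 kb] — bracketing the observed range of
transferred-region sizes (1,000–260,500 bp); the true tract-length
distribution of DCT is unknown, so this is a declared stand-in, not an
inference. Cohort simulation constrains realized donor fractions to the
observed 1–12% range by redrawing lengths. Placement is uniform with
rejection of overlaps and of inter-tract gaps below `min_gap_bp`
(default one window), so ground-truth event counts are unambiguous. The
optional marker cassette (default 1.5 kb of GC-0.5 random sequence at
~8/12 of the chromosome, emulating an antibiotic-resistance insert at a
phage attachment site) matches neither parent and lengthens the genome,
which breaks the shared coordinate frame: marker-bearing genomes must be
painted in mapping mode.

## Window painting

* **Tiling.** Nonoverlapping windows of *W* = 500 bp. The trailing
  partial window stands alone if at least *W*/2, else it is merged into
  the last full window — so every base is painted exactly once.
* **Aligned identity.** Exact: matches / *W*, with N counting as a
  mismatch to every parent (conservative, deterministic). Computed
  vectorized over cumulative match counts; equality with the brute-force
  per-position oracle is asserted in tests and in the acceptance suite.
* **Mapping identity.** Seeds every k-th k-mer (k = 16) of the window
  into a sorted k-mer index of the parent, votes by diagonal, and scores
  `1 − editDistance/W` (edlib, infix mode) against the best candidate
  region padded by max(8, W/20). Seeds with more than 200 index hits are
  skipped as repeat-derived. No seed → identity 0, which is a result
  (unassignable window), not an error.
* **Assignment.** Strictly greater identity wins. Both identities 1.0 —
  an uninformative window — inherits the nearest preceding assigned
  origin, falling back to the declared background parent at the start of
  the genome; equal-but-imperfect ties reuse the same lookback. Both
  cases carry an `ambiguous_inherited` flag. Windows with both
  identities below τ = 0.9 are `unassigned`; τ exists because per-genome
  percentages must be allowed to sum below 100 (marker cassettes,
  diverged tracts). The lookback is deliberately one-step — no HMM
  smoothing — preserving the character of the original rule.

With d·W ≈ 5 expected informative sites per window, a fully interior
window is misassigned in aligned mode only if it contains no informative
site (probability ≈ e⁻⁵ per window); a planted tract with ≥3 interior
windows escapes detection with probability ≲ e⁻¹⁵, which is why exact
count recovery is the deterministic expectation at the validation
suite's problem sizes.

## Segmentation and statistics

Same-origin runs are concatenated; a report row gives percent per parent
(segment bp / genome length × 100, 2 decimals, transconjugant length as
the denominator), the transferred-region count (donor segments ≥ *W*;
sub-window donor runs — possible only in finer-than-window analyses —
are excluded by rule), the largest donor segment, and the background
parent (majority parent; equals the cross's recipient whenever donor
content is below 50%). Cohort summaries report the arithmetic mean event
count (rounded half away from zero) and the donor-percent range. The
published 23-genome table ships in `dctmosaic.published` so cohort
aggregates (mean 15.65 → 16 events; largest region 260,500 bp; all
largest-region values multiples of 500) are recomputable offline.

## Divergence and locus comparisons

SNV tables/matrices are defined on collinear equal-length sequence or an
explicit gapped alignment (indel columns skipped, N positions ignored);
matrices are validated symmetric with zero diagonal. Protein percent
identity is a global affine-gap alignment (BLOSUM62, open 10, extend
0.5, Biopython `PairwiseAligner`) with **all alignment columns including
gaps in the denominator** — the convention is stated because published
per-gene percentages computed with other denominators can differ by a
few points, so low-identity anchors are treated as approximate. Locus
SNV catalogs align with edlib (indel-tolerant), refuse pairs under 80%
identity, and annotate substitutions with overlapping features and
coding effects (silent/missense) from the feature's reading frame,
including minus-strand features. `mid_identical` exposes the
kin-recognition prediction as a boolean — an empty SNV catalog over the
designated *mid* interval — and nothing more.

Real-data mode (`dctmosaic.accessions`) runs these analyses on locally
stored copies of the deposited parental genome accessions; retrieval is
the user's step, and the expected file layout is documented in the
module docstring.

## Numerical and design choices

* Seeded `numpy.random.Generator` everywhere; fixed seed ⇒ byte-identical
  outputs (asserted).
* Tie-breaks: background parent resolves the first-window tie; candidate
  mapping loci are scanned in deterministic diagonal-vote order.
* Degenerate inputs raise typed errors with specific messages (duplicate
  FASTA ids, alphabet violations, non-tiling segments, frame mismatches,
  placement failures after 1,000 rejection attempts).
* Validation problem sizes: the recovery suite uses 50 crosses on a 2-Mb
  pair (k ∈ [4, 20], tracts 2–50 kb, gaps ≥ 2 kb) and the
  identity-oracle check 20 instances at 50 kb — sizes chosen so the full
  suite runs in seconds while keeping ≥3 interior windows per tract and
  thousands of windows under test.
* Plot testing is on emitted drawing tables (coordinates, colors,
  angular extents), never pixels.

## Known limitations

Two-parent crosses only; no indel-aware aligned mode (mapping mode is
the fallback); no mutation-spectrum, selection or IS-element modeling in
the simulator; ortholog detection and annotation pipelines are out of
scope, so locus comparisons take sequences and features as given.
Real-genome SNV counts depend on the ortholog/alignment pipeline used
upstream and are not reproduced bit-for-bit by the collinear
simplification here.
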