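"""Published transconjugant statistics from the five-strain M. smegmatis study.

Twenty-three transconjugant genomes from pairwise crosses among natural
M. smegmatis isolates (recipients MKD8 and Jucho; donors mc2-155, Nishi and
Rabinowitchi) were sequenced and painted with the 500-bp window procedure.
The per-genome summary columns — percent of DNA from each parent, number of
transferred regions, largest transferred region — are reproduced here so
cohort-level aggregates can be recomputed without access to the underlying
reads (which were never deposited).

Each row: (recipient, donor, pct_recipient_like, pct_donor, n_transferred
regions, largest_region_bp). "pct_recipient_like" is the percentage of the
majority (background) parent. In the bidirectional MKD8 x Jucho cross the
background parent varies by transconjugant; the first column of each row
names the majority parent for that genome.
"""

from __future__ import annotations

from .segments import CohortSummary, cohort_summary, TransconjugantReport

PUBLISHED_ROWS: tuple[tuple[str, str, float, float, int, int], ...] = (
    # MKD8 x Jucho (bidirectional): majority parent first
    ("MKD8", "Jucho", 98.41, 1.30, 6, 54_500),
    ("Jucho", "MKD8", 91.46, 4.33, 23, 80_500),
    ("Jucho", "MKD8", 89.88, 6.21, 22, 132_500),
    ("MKD8", "Jucho", 87.09, 10.79, 15, 185_000),
    ("MKD8", "Jucho", 99.52, 0.04, 4, 1_000),
    ("Jucho", "MKD8", 81.31, 13.63, 32, 163_500),
    ("MKD8", "Jucho", 95.19, 4.26, 10, 93_500),
    ("MKD8", "Jucho", 96.75, 2.83, 10, 80_000),
    # MKD8 (recipient) x Nishi (donor)
    ("MKD8", "Nishi", 97.30, 3.22, 27, 92_500),
    ("MKD8", "Nishi", 98.01, 2.58, 10, 43_000),
    ("MKD8", "Nishi", 90.97, 8.36, 13, 166_500),
    ("MKD8", "Nishi", 87.73, 12.49, 14, 221_000),
    # Jucho (recipient) x Nishi (donor)
    ("Jucho", "Nishi", 97.17, 3.47, 36, 65_000),
    ("Jucho", "Nishi", 90.93, 9.62, 28, 233_500),
    ("Jucho", "Nishi", 90.69, 9.06, 19, 146_000),
    # MKD8 (recipient) x Rabinowitchi (donor)
    ("MKD8", "Rabinowitchi", 91.49, 8.03, 16, 128_000),
    ("MKD8", "Rabinowitchi", 99.27, 0.31, 3, 18_500),
    ("MKD8", "Rabinowitchi", 96.66, 2.31, 4, 85_000),
    ("MKD8", "Rabinowitchi", 94.97, 4.24, 11, 118_000),
    # Jucho (recipient) x Rabinowitchi (donor)
    ("Jucho", "Rabinowitchi", 97.84, 1.16, 11, 21_000),
    ("Jucho", "Rabinowitchi", 97.07, 2.05, 12, 76_500),
    ("Jucho", "Rabinowitchi", 95.15, 3.95, 16, 120_500),
    ("Jucho", "Rabinowitchi", 91.32, 7.85, 18, 260_500),
)

# Deposited parental genome accessions and assembly lengths (bp).
PARENT_GENOMES: dict[str, tuple[str, int]] = {
    "MKD8": ("CP027541.1", 7_119_169),
    "Jucho": ("CP080274", 6_895_172),
    "Rabinowitchi": ("CP080272", 7_061_747),
    "Nishi": ("CP080273", 7_010_278),
    "mc2-155": ("NC_008596", 6_988_209),
}

WINDOW_BP = 500


def published_reports() -> list[TransconjugantReport]:
    """The published rows as :class:`TransconjugantReport` objects."""
    out = []
    for i, (bg, minor, pct_bg, pct_minor, n, largest) in enumerate(PUBLISHED_ROWS):
        out.append(
            TransconjugantReport(
                name=f"published_{i + 1}",
                recipient=bg,
                donor=minor,
                pct_recipient=pct_bg,
                pct_donor=pct_minor,
                pct_unassigned=round(100.0 - pct_bg - pct_minor, 2),
                n_transferred_regions=n,
                largest_region_bp=largest,
                background_parent=bg,
            )
        )
    return out


def published_cohort_summary() -> CohortSummary:
    """Cohort aggregates recomputed from the published per-genome columns."""
    return cohort_summary(published_reports())
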