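"""Cohort aggregates recomputed from the published transconjugant table.

Twenty-three sequenced transconjugants from five-strain M. smegmatis
crosses; the per-genome columns (percent parental DNA, number of
transferred regions, largest region) are shipped with the package.
"""

from dctmosaic.published import (
    PUBLISHED_ROWS,
    published_cohort_summary,
    published_reports,
)
from dctmosaic.segments import reports_to_dataframe

summary = published_cohort_summary()
print(f"transconjugants: {summary.n_transconjugants}")
print(f"mean transferred regions: {summary.mean_events:.2f} "
      f"(rounded: {summary.mean_events_rounded})")
print(f"donor percent range: {summary.donor_fraction_min}% - "
      f"{summary.donor_fraction_max}%")
print(f"largest transferred region: {max(r[5] for r in PUBLISHED_ROWS):,} bp")
print(f"all largest-region values multiples of 500 bp: "
      f"{all(r[5] % 500 == 0 for r in PUBLISHED_ROWS)}")

print()
print(reports_to_dataframe(published_reports()).to_string(index=False))
# The 500-bp granularity of every largest-region value is the fingerprint
# of nonoverlapping window tiling: segment lengths are whole windows.
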