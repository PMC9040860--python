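"""Segment concatenation and transconjugant/cohort statistics.

Consecutive windows assigned to the same parent are concatenated into
segments; donor-origin segments are the transferred regions. Per genome,
the headline numbers are the percent of DNA from each parent, the number
of transferred regions (donor segments of at least one window), and the
largest transferred region in bp. Cohort summaries aggregate those across
transconjugants: the mean event count and the observed donor-percent range.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .io import Interval
from .windows import WindowCall


class SegmentationError(ValueError):
    pass


@dataclass(frozen=True)
class Segment:
    """A maximal run of same-origin windows."""

    interval: Interval
    origin: str
    n_windows: int
    mean_identity: float = 0.0

    @property
    def length_bp(self) -> int:
        return self.interval.length


@dataclass(frozen=True)
class TransconjugantReport:
    """Per-genome painting summary (one table row).

    Percentages are of transconjugant genome length, reported to 2
    decimals; they sum to 100 with the unassigned share included.
    ``n_transferred_regions`` counts donor segments of length >= the
    window size — sub-window rearrangements are not counted as events.
    """

    name: str
    recipient: str
    donor: str
    pct_recipient: float
    pct_donor: float
    pct_unassigned: float
    n_transferred_regions: int
    largest_region_bp: int
    background_parent: str

    @property
    def percent_per_parent(self) -> dict[str, float]:
        return {self.recipient: self.pct_recipient, self.donor: self.pct_donor}


@dataclass(frozen=True)
class CohortSummary:
    mean_events: float
    mean_events_rounded: int
    donor_fraction_min: float
    donor_fraction_max: float
    n_transconjugants: int


def merge_runs(calls: Sequence[WindowCall]) -> list[Segment]:
    """Run-length encode window origins into maximal same-origin segments."""
    if not calls:
        return []
    for a, b in zip(calls, calls[1:]):
        if a.interval.end != b.interval.start:
            raise SegmentationError("not tiled: gap between consecutive windows")
    segments: list[Segment] = []
    run_start = 0
    for i in range(1, len(calls) + 1):
        if i == len(calls) or calls[i].origin != calls[run_start].origin:
            run = calls[run_start:i]
            iv = Interval(
                run[0].interval.start, run[-1].interval.end, run[0].interval.genome
            )
            best = [max(c.identity_recipient, c.identity_donor) for c in run]
            segments.append(
                Segment(iv, run[0].origin, len(run), sum(best) / len(best))
            )
            run_start = i
    return segments


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def transconjugant_report(
    segments: Sequence[Segment],
    genome_length: int,
    recipient: str,
    donor: str,
    window_bp: int = 500,
    name: str = "transconjugant",
) -> TransconjugantReport:
    """Summarize a segment tiling into one report row."""
    total = sum(s.length_bp for s in segments)
    if total != genome_length:
        raise SegmentationError(
            f"incomplete tiling: segments cover {total} of {genome_length} bp"
        )
    bp = {"recipient": 0, "donor": 0, "unassigned": 0}
    for s in segments:
        bp[s.origin] += s.length_bp
    pct = {k: round(v / genome_length * 100, 2) for k, v in bp.items()}
    donor_segments = [
        s for s in segments if s.origin == "donor" and s.length_bp >= window_bp
    ]
    largest = max((s.length_bp for s in segments if s.origin == "donor"), default=0)
    background = recipient if bp["recipient"] >= bp["donor"] else donor
    return TransconjugantReport(
        name=name,
        recipient=recipient,
        donor=donor,
        pct_recipient=pct["recipient"],
        pct_donor=pct["donor"],
        pct_unassigned=pct["unassigned"],
        n_transferred_regions=len(donor_segments),
        largest_region_bp=largest,
        background_parent=background,
    )


def cohort_summary(reports: Sequence[TransconjugantReport]) -> CohortSummary:
    """Aggregate event counts and donor percentages over a cohort."""
    if not reports:
        raise SegmentationError("no reports")
    events = [r.n_transferred_regions for r in reports]
    donor_pct = [r.pct_donor for r in reports]
    mean = sum(events) / len(events)
    return CohortSummary(
        mean_events=mean,
        mean_events_rounded=_round_half_away(mean),
        donor_fraction_min=min(donor_pct),
        donor_fraction_max=max(donor_pct),
        n_transconjugants=len(reports),
    )


def reports_to_dataframe(reports: Iterable[TransconjugantReport]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "transconjugant": r.name,
                "recipient": r.recipient,
                "pct_recipient": r.pct_recipient,
                "donor": r.donor,
                "pct_donor": r.pct_donor,
                "pct_unassigned": r.pct_unassigned,
                "n_transferred_regions": r.n_transferred_regions,
                "largest_region_bp": r.largest_region_bp,
            }
            for r in reports
        ]
    )
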