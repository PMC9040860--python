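"""Mosaic-genome visualization.

Paints a segment tiling as a circular ideogram (the classic view of a
mosaic bacterial chromosome) or a linear track. Every figure is backed by
a plain drawing table — one row per drawn segment with its coordinates,
color and angular/linear extent — so plots are testable and scriptable
without touching pixels.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Mapping, Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

DEFAULT_COLORS = {
    "recipient": "#4fc3f7",  # cyan, recipient backbone
    "donor": "#fbc02d",  # yellow, transferred tracts
    "marker": "#616161",
    "unassigned": "#616161",
}


class VizError(ValueError):
    pass


def _check_tiling(segments: Sequence) -> int:
    segs = sorted(segments, key=lambda s: s.interval.start)
    if not segs:
        raise VizError("overlap/gap: empty segment list")
    cursor = segs[0].interval.start
    if cursor != 0:
        raise VizError("overlap/gap: tiling does not start at 0")
    for seg in segs:
        if seg.interval.start != cursor:
            raise VizError(
                f"overlap/gap at {cursor}: next segment starts {seg.interval.start}"
            )
        cursor = seg.interval.end
    return cursor


def drawing_table(
    segments: Sequence,
    style: str = "circular",
    colors: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """The exact geometry a mosaic plot draws, one row per segment.

    For circular style, ``theta_start``/``theta_end`` are degrees clockwise
    from 12 o'clock; angular extent is proportional to segment length.
    """
    palette = dict(DEFAULT_COLORS)
    if colors:
        palette.update(colors)
    total = _check_tiling(segments)
    rows = []
    for seg in sorted(segments, key=lambda s: s.interval.start):
        row = {
            "genome": seg.interval.genome,
            "start": seg.interval.start,
            "end": seg.interval.end,
            "length_bp": seg.interval.length,
            "origin": seg.origin,
            "color": palette.get(seg.origin, "#000000"),
        }
        if style == "circular":
            row["theta_start"] = 360.0 * seg.interval.start / total
            row["theta_end"] = 360.0 * seg.interval.end / total
        else:
            row["x_start"] = float(seg.interval.start)
            row["x_end"] = float(seg.interval.end)
        rows.append(row)
    return pd.DataFrame(rows)


def plot_mosaic(
    segments: Sequence,
    path: str | Path,
    style: str = "circular",
    colors: Mapping[str, str] | None = None,
    title: str = "",
    legend: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Render a mosaic ideogram and return the drawing table.

    ``legend`` maps origin labels to display names (e.g. parent strain
    names with their percentages).
    """
    if style not in ("circular", "linear"):
        raise VizError(f"unknown style {style!r}")
    table = drawing_table(segments, style, colors)
    if style == "circular":
        fig, ax = plt.subplots(
            figsize=(6, 6), subplot_kw={"projection": "polar"}
        )
        ax.set_theta_zero_location("N")
        ax.set_theta_direction(-1)
        for _, row in table.iterrows():
            t0 = math.radians(row["theta_start"])
            t1 = math.radians(row["theta_end"])
            ax.bar(
                x=(t0 + t1) / 2,
                height=0.25,
                width=t1 - t0,
                bottom=0.75,
                color=row["color"],
                edgecolor="none",
            )
        ax.set_ylim(0, 1.05)
        ax.set_xticks([])
        ax.set_yticks([])
        ax.spines["polar"].set_visible(False)
    else:
        fig, ax = plt.subplots(figsize=(10, 1.8))
        for _, row in table.iterrows():
            ax.barh(
                y=0,
                width=row["x_end"] - row["x_start"],
                left=row["x_start"],
                height=0.6,
                color=row["color"],
                edgecolor="none",
            )
        ax.set_yticks([])
        ax.set_xlabel("position (bp)")
    if title:
        ax.set_title(title)
    if legend:
        handles = [
            plt.Rectangle((0, 0), 1, 1, color=DEFAULT_COLORS.get(k, "#000000"))
            for k in legend
        ]
        ax.legend(handles, list(legend.values()), loc="center", fontsize=8)
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
    return table
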