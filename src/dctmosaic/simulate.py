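"""Synthetic parental genomes and ground-truth mosaic transconjugants.

Distributive conjugal transfer (DCT) replaces multiple, noncontiguous
tracts of a recipient chromosome with the homologous donor sequence. This
module emulates the study conditions of such crosses between collinear
M. smegmatis-like genomes:

* parent pairs differing only by point substitutions at a controlled
  density (defaults: 0.01/bp for a distant pair, 0.001/bp for a close
  pair — the two densities observed between natural isolates);
* transconjugants that are a recipient backbone carrying 1–12% donor DNA
  delivered in many segments (cohort default: mean 16 events per genome);
* an optional selection-marker cassette whose sequence matches neither
  parent, inserted at a fixed relative chromosome position.

Everything is deterministic under a seed; ground truth is returned as a
gap-free tiling so each downstream stage can be validated base by base.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .divergence import VariantTable
from .io import Genome, Interval

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

# M. smegmatis chromosomes are GC-rich (~67%).
DEFAULT_GC = 0.67


class SimulationError(ValueError):
    pass


@dataclass(frozen=True)
class ParentPairConfig:
    """Configuration for a collinear parental genome pair.

    ``snv_density`` is substitutions per bp between the two parents;
    0.01 mirrors the most divergent natural pairs (~1 SNV per 100 nt) and
    0.001 the closest (~1 per kb).
    """

    length_bp: int = 1_000_000
    snv_density: float = 0.01
    seed: int = 0
    names: tuple[str, str] = ("recipient", "donor")
    gc: float = DEFAULT_GC

    def __post_init__(self) -> None:
        if not (0.0 <= self.snv_density <= 0.25):
            raise SimulationError("snv_density must be in [0, 0.25]")
        if self.length_bp < 10 * 500:
            raise SimulationError("length_bp must be at least 10 windows (5,000 bp)")


@dataclass(frozen=True)
class TransferConfig:
    """Configuration for one simulated cross.

    ``segment_length_dist`` is ``("log-uniform", low_bp, high_bp)``; the
    default range [1 kb, 250 kb] brackets the segment lengths observed in
    sequenced transconjugants (1,000–260,500 bp). ``min_gap_bp`` keeps
    planted segments at least that far apart so ground-truth event counts
    are unambiguous. ``segments`` may pin exact (start, end) intervals,
    bypassing the random draw. ``marker`` is ``(cassette_bp, insert_at)``
    with ``insert_at=None`` meaning the default ~8/12 of the chromosome.
    """

    n_segments: int = 16
    segment_length_dist: tuple[str, float, float] = ("log-uniform", 1_000, 250_000)
    min_gap_bp: int = 500
    seed: int = 0
    segments: Optional[Sequence[tuple[int, int]]] = None
    marker: Optional[tuple[int, Optional[int]]] = None

    def __post_init__(self) -> None:
        if self.n_segments < 0:
            raise SimulationError("n_segments must be >= 0")


@dataclass(frozen=True)
class GroundTruth:
    """The true origin of every base of a simulated transconjugant.

    ``segments`` tile ``[0, length)`` exactly, alternating origins drawn
    from {recipient, donor, marker}.
    """

    segments: tuple[tuple[Interval, str], ...]
    donor_fraction: float
    recipient_name: str
    donor_name: str

    @property
    def donor_segments(self) -> list[Interval]:
        return [iv for iv, origin in self.segments if origin == "donor"]

    @property
    def length(self) -> int:
        return self.segments[-1][0].end

    def origin_at(self, pos: int) -> str:
        for iv, origin in self.segments:
            if iv.start <= pos < iv.end:
                return origin
        raise IndexError(pos)


def _random_sequence(rng: np.random.Generator, length: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return _BASES[rng.choice(4, size=length, p=p)]


def _to_str(arr: np.ndarray) -> str:
    return arr.tobytes().decode("ascii")


def generate_parent_pair(cfg: ParentPairConfig) -> tuple[Genome, Genome, VariantTable]:
    """Draw a recipient genome and a donor differing by point substitutions.

    Substitution sites are a uniform draw without replacement of
    ``round(density * L)`` positions; at each site the donor base is uniform
    over the three non-recipient bases. Returns the pair plus the exact
    variant table in their shared coordinate frame.
    """
    rng = np.random.default_rng(cfg.seed)
    L = cfg.length_bp
    n_var = int(round(cfg.snv_density * L))
    if n_var < 1:
        raise SimulationError("no variants requested (density * length < 0.5)")
    rec_arr = _random_sequence(rng, L, cfg.gc)
    positions = np.sort(rng.choice(L, size=n_var, replace=False))
    ref_idx = np.searchsorted(_BASES, rec_arr[positions])  # _BASES is sorted (ACGT)
    alt_idx = (ref_idx + rng.integers(1, 4, size=n_var)) % 4
    don_arr = rec_arr.copy()
    don_arr[positions] = _BASES[alt_idx]

    rec_name, don_name = cfg.names
    recipient = Genome(rec_name, _to_str(rec_arr), "circular")
    donor = Genome(don_name, _to_str(don_arr), "circular")
    table = VariantTable(
        positions=tuple(int(p) for p in positions),
        base_a=_to_str(rec_arr[positions]),
        base_b=_to_str(don_arr[positions]),
        frame=(rec_name, don_name),
    )
    return recipient, donor, table


def _draw_segment_length(rng: np.random.Generator, dist: tuple[str, float, float]) -> int:
    family, lo, hi = dist
    if family != "log-uniform":
        raise SimulationError(f"unknown segment length distribution {family!r}")
    return int(round(math.exp(rng.uniform(math.log(lo), math.log(hi)))))


def _place_segments(
    rng: np.random.Generator, L: int, lengths: Sequence[int], min_gap: int
) -> list[tuple[int, int]]:
    placed: list[tuple[int, int]] = []
    for seg_len in lengths:
        if seg_len > L:
            raise SimulationError("placement failure: segment longer than genome")
        for _ in range(1000):
            start = int(rng.integers(0, L - seg_len + 1))
            end = start + seg_len
            ok = all(
                end + min_gap <= s or e + min_gap <= start for s, e in placed
            )
            if ok:
                placed.append((start, end))
                break
        else:
            raise SimulationError(
                "placement failure: could not place segments disjointly"
            )
    return sorted(placed)


def _tile(L: int, donor_intervals: Sequence[tuple[int, int]], genome: str) -> list[tuple[Interval, str]]:
    tiles: list[tuple[Interval, str]] = []
    cursor = 0
    for s, e in donor_intervals:
        if s > cursor:
            tiles.append((Interval(cursor, s, genome), "recipient"))
        tiles.append((Interval(s, e, genome), "donor"))
        cursor = e
    if cursor < L:
        tiles.append((Interval(cursor, L, genome), "recipient"))
    return tiles


def simulate_transconjugant(
    recipient: Genome,
    donor: Genome,
    cfg: TransferConfig,
    name: str = "transconjugant",
) -> tuple[Genome, GroundTruth]:
    """Build a mosaic transconjugant and its ground truth.

    The transconjugant is the recipient sequence with each planted donor
    segment's bases replaced by the donor's bases over the same interval
    (the parents are collinear, so coordinates are shared). The optional
    marker cassette — random sequence matching neither parent — is inserted
    afterwards, shifting all downstream truth intervals.
    """
    if len(recipient) != len(donor):
        raise SimulationError("parents are not collinear (unequal lengths)")
    rng = np.random.default_rng(cfg.seed)
    L = len(recipient)

    if cfg.segments is not None:
        donor_ivs = sorted((int(s), int(e)) for s, e in cfg.segments)
        for (s1, e1), (s2, e2) in zip(donor_ivs, donor_ivs[1:]):
            if s2 < e1:
                raise SimulationError("placement failure: pinned segments overlap")
    elif cfg.n_segments == 0:
        donor_ivs = []
    else:
        lengths = [
            _draw_segment_length(rng, cfg.segment_length_dist)
            for _ in range(cfg.n_segments)
        ]
        donor_ivs = _place_segments(rng, L, lengths, cfg.min_gap_bp)

    rec_arr = np.frombuffer(recipient.sequence.encode(), dtype=np.uint8).copy()
    don_arr = np.frombuffer(donor.sequence.encode(), dtype=np.uint8)
    for s, e in donor_ivs:
        rec_arr[s:e] = don_arr[s:e]

    tiles = _tile(L, donor_ivs, name)

    if cfg.marker is not None:
        cassette_bp, insert_at = cfg.marker
        pos = int(round(L * 8 / 12)) if insert_at is None else int(insert_at)
        cassette = _random_sequence(rng, cassette_bp, 0.5)
        rec_arr = np.concatenate([rec_arr[:pos], cassette, rec_arr[pos:]])
        shifted: list[tuple[Interval, str]] = []
        inserted = False
        for iv, origin in tiles:
            pieces: list[tuple[int, int]] = []
            if iv.end <= pos:
                pieces = [(iv.start, iv.end)]
            elif iv.start >= pos:
                pieces = [(iv.start + cassette_bp, iv.end + cassette_bp)]
            else:  # cassette splits this tile
                pieces = [(iv.start, pos), (pos + cassette_bp, iv.end + cassette_bp)]
            for s, e in pieces:
                if not inserted and s >= pos + cassette_bp:
                    shifted.append((Interval(pos, pos + cassette_bp, name), "marker"))
                    inserted = True
                shifted.append((Interval(s, e, name), origin))
        if not inserted:  # cassette at the very end
            shifted.append((Interval(pos, pos + cassette_bp, name), "marker"))
        tiles = shifted

    total = len(rec_arr)
    donor_bp = sum(iv.length for iv, origin in tiles if origin == "donor")
    truth = GroundTruth(
        segments=tuple(tiles),
        donor_fraction=donor_bp / total,
        recipient_name=recipient.name,
        donor_name=donor.name,
    )
    return Genome(name, _to_str(rec_arr), "circular"), truth


def simulate_cohort(
    recipient: Genome,
    donor: Genome,
    n_transconjugants: int,
    seed: int = 0,
    mean_events: float = 16.0,
    donor_fraction_range: tuple[float, float] = (0.01, 0.12),
    segment_length_dist: tuple[str, float, float] = ("log-uniform", 1_000, 250_000),
    min_gap_bp: int = 500,
) -> list[tuple[Genome, GroundTruth]]:
    """Simulate a cohort of independent transconjugants from one cross.

    Event counts are Poisson with the stated mean (truncated at 1) and each
    genome's realized donor fraction is constrained to the stated range by
    redrawing segment lengths, mirroring the 1–12% donor content observed
    across sequenced transconjugants.
    """
    rng = np.random.default_rng(seed)
    L = len(recipient)
    lo, hi = donor_fraction_range
    out: list[tuple[Genome, GroundTruth]] = []
    for i in range(n_transconjugants):
        k = max(1, int(rng.poisson(mean_events)))
        for _ in range(500):
            sub_seed = int(rng.integers(0, 2**31 - 1))
            cfg = TransferConfig(
                n_segments=k,
                segment_length_dist=segment_length_dist,
                min_gap_bp=min_gap_bp,
                seed=sub_seed,
            )
            probe = np.random.default_rng(sub_seed)
            lengths = [
                _draw_segment_length(probe, segment_length_dist) for _ in range(k)
            ]
            if lo <= sum(lengths) / L <= hi:
                break
        else:
            raise SimulationError(
                "could not realize donor fraction in range; adjust configuration"
            )
        tc, truth = simulate_transconjugant(
            recipient, donor, cfg, name=f"tc{i + 1}"
        )
        out.append((tc, truth))
    return out
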