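"""Parental-origin assignment of transconjugant windows.

The painting procedure: tile the transconjugant genome into nonoverlapping
500-bp windows, score each window's nucleotide identity against both
parental genomes, and assign the window to the parent with the higher
identity. A window that is 100% identical to both parents is uninformative
and inherits the origin of the nearest preceding assigned window — a
one-step lookback, deliberately not an HMM. Windows matching neither
parent well (below ``min_identity``) are left unassigned; in practice
these are marker cassettes or tracts from outside the cross.

Two identity backends are provided:

* **aligned** — exact per-position identity in a shared coordinate frame
  (parents collinear and equal length with the transconjugant). This is
  the fragment-identity statistic reduced to its exact form, valid
  whenever the genomes are collinear.
* **mapping** — seeds the window into a parent by shared k-mers, then
  computes an edit-distance identity against the best candidate locus.
  Needed when coordinates are not shared (marker insertions, indels,
  real assemblies).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import edlib
import numpy as np
import pandas as pd

from .io import Genome, Interval


class ClassifierError(ValueError):
    pass


@dataclass(frozen=True)
class ClassifierConfig:
    """Tuning knobs for window painting.

    ``window_bp`` defaults to 500, the resolution at which transferred
    regions are counted. ``min_identity`` (default 0.9) is the floor below
    which a window is attributed to neither parent. ``mode`` selects the
    identity backend.
    """

    window_bp: int = 500
    min_identity: float = 0.9
    mode: str = "aligned"
    seed_k: int = 16

    def __post_init__(self) -> None:
        if self.window_bp < 50:
            raise ClassifierError("window_bp must be >= 50")
        if not (0.0 <= self.min_identity < 1.0):
            raise ClassifierError("min_identity must be in [0, 1)")
        if self.mode not in ("aligned", "mapping"):
            raise ClassifierError(f"unknown mode {self.mode!r}")


@dataclass(frozen=True)
class WindowCall:
    """One tiled window with its identities and assigned origin."""

    interval: Interval
    identity_recipient: float
    identity_donor: float
    origin: str  # recipient | donor | unassigned
    ambiguous_inherited: bool = False


def tile_windows(length_bp: int, window_bp: int = 500, genome: str = "") -> list[Interval]:
    """Nonoverlapping tiling ``[0, W), [W, 2W), ...`` of a genome.

    A trailing partial window shorter than ``W/2`` is merged into the last
    full window; a tail of at least ``W/2`` stands as its own window.
    """
    if length_bp < window_bp:
        raise ClassifierError(
            f"genome shorter than window ({length_bp} < {window_bp})"
        )
    n_full = length_bp // window_bp
    tail = length_bp - n_full * window_bp
    edges = [i * window_bp for i in range(n_full)]
    if tail >= window_bp / 2:
        edges.append(n_full * window_bp)
    starts = edges
    ends = edges[1:] + [length_bp]
    return [Interval(s, e, genome) for s, e in zip(starts, ends)]


# ---------------------------------------------------------------------------
# aligned mode

_N = ord("N")


def score_window_aligned(
    window_seq: str, recipient_seq: str, donor_seq: str
) -> tuple[float, float]:
    """Exact per-position identity of one window to each parent.

    All three strings must cover the same coordinates (equal length).
    N in either sequence counts as a mismatch — conservative and
    deterministic.
    """
    if not (len(window_seq) == len(recipient_seq) == len(donor_seq)):
        raise ClassifierError("frame mismatch: sequences differ in length")
    w = np.frombuffer(window_seq.encode(), dtype=np.uint8)
    r = np.frombuffer(recipient_seq.encode(), dtype=np.uint8)
    d = np.frombuffer(donor_seq.encode(), dtype=np.uint8)
    match_r = (w == r) & (w != _N)
    match_d = (w == d) & (w != _N)
    return float(match_r.mean()), float(match_d.mean())


def _aligned_identities(
    tc: Genome, recipient: Genome, donor: Genome, intervals: Sequence[Interval]
) -> list[tuple[Interval, float, float]]:
    """Vectorized aligned-mode scoring over a full tiling."""
    if not (len(tc) == len(recipient) == len(donor)):
        raise ClassifierError(
            "frame mismatch: aligned mode needs equal-length collinear genomes"
        )
    t = np.frombuffer(tc.sequence.encode(), dtype=np.uint8)
    r = np.frombuffer(recipient.sequence.encode(), dtype=np.uint8)
    d = np.frombuffer(donor.sequence.encode(), dtype=np.uint8)
    informative = t != _N
    mr = ((t == r) & informative).astype(np.int64)
    md = ((t == d) & informative).astype(np.int64)
    starts = np.array([iv.start for iv in intervals])
    cum_r = np.concatenate([[0], np.cumsum(mr)])
    cum_d = np.concatenate([[0], np.cumsum(md)])
    out = []
    for iv in intervals:
        n = iv.length
        out.append(
            (
                iv,
                (cum_r[iv.end] - cum_r[iv.start]) / n,
                (cum_d[iv.end] - cum_d[iv.start]) / n,
            )
        )
    return out


# ---------------------------------------------------------------------------
# mapping mode

_CODE = np.full(256, -1, dtype=np.int64)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i


class KmerIndex:
    """Exact k-mer → positions index over one parent genome."""

    def __init__(self, genome: Genome, k: int = 16):
        self.genome = genome
        self.k = k
        seq = np.frombuffer(genome.sequence.encode(), dtype=np.uint8)
        codes = _CODE[seq]
        self._kmers = _rolling_kmers(codes, k)
        order = np.argsort(self._kmers, kind="stable")
        self._sorted = self._kmers[order]
        self._positions = order

    def lookup(self, kmer: int) -> np.ndarray:
        lo = np.searchsorted(self._sorted, kmer, side="left")
        hi = np.searchsorted(self._sorted, kmer, side="right")
        return self._positions[lo:hi]


def _rolling_kmers(codes: np.ndarray, k: int) -> np.ndarray:
    """2-bit packed k-mers at every offset; -1 where a window contains N."""
    n = len(codes) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    valid = codes >= 0
    kmers = np.zeros(n, dtype=np.int64)
    ok = np.ones(n, dtype=bool)
    for j in range(k):
        kmers = kmers | (np.maximum(codes[j : j + n], 0) << (2 * (k - 1 - j)))
        ok &= valid[j : j + n]
    kmers[~ok] = -1
    return kmers


def score_window_mapping(
    window_seq: str, parent: Genome, k: int = 16, index: KmerIndex | None = None
) -> float:
    """Identity of a window to its best-matching locus in a parent.

    Candidate loci are found by shared k-mer seeding (diagonal voting);
    identity is ``1 - edit_distance / window_length`` against the best
    candidate region. No seed → identity 0.
    """
    w = len(window_seq)
    if w < k:
        raise ClassifierError("window shorter than seed k")
    if index is None:
        index = KmerIndex(parent, k)
    codes = _CODE[np.frombuffer(window_seq.encode(), dtype=np.uint8)]
    kmers = _rolling_kmers(codes, k)
    # sparse seeding: every k-th offset plus the final one
    offsets = list(range(0, len(kmers), k))
    if offsets[-1] != len(kmers) - 1:
        offsets.append(len(kmers) - 1)
    diagonals: dict[int, int] = {}
    for off in offsets:
        km = kmers[off]
        if km < 0:
            continue
        hits = index.lookup(int(km))
        if len(hits) > 200:  # repeat-like seed, uninformative
            continue
        for h in hits:
            diag = int(h) - off
            diagonals[diag] = diagonals.get(diag, 0) + 1
    if not diagonals:
        return 0.0
    best = max(diagonals.values())
    candidates = [d for d, v in diagonals.items() if v == best]
    pad = max(8, w // 20)
    best_identity = 0.0
    for diag in candidates[:8]:
        lo = max(0, diag - pad)
        hi = min(len(parent), diag + w + pad)
        target = parent.sequence[lo:hi]
        res = edlib.align(window_seq, target, mode="HW", task="distance")
        dist = res["editDistance"]
        if dist >= 0:
            best_identity = max(best_identity, 1.0 - dist / w)
    return best_identity


def _mapping_identities(
    tc: Genome,
    recipient: Genome,
    donor: Genome,
    intervals: Sequence[Interval],
    k: int,
) -> list[tuple[Interval, float, float]]:
    idx_r = KmerIndex(recipient, k)
    idx_d = KmerIndex(donor, k)
    out = []
    for iv in intervals:
        wseq = tc.sequence[iv.start : iv.end]
        out.append(
            (
                iv,
                score_window_mapping(wseq, recipient, k, idx_r),
                score_window_mapping(wseq, donor, k, idx_d),
            )
        )
    return out


# ---------------------------------------------------------------------------
# classification

def classify_windows(
    scored: Sequence[tuple[Interval, float, float]],
    cfg: ClassifierConfig = ClassifierConfig(),
    background: str = "recipient",
) -> list[WindowCall]:
    """Assign an origin to every scored window.

    Rules, per window in genomic order:

    a. both identities below ``min_identity`` → unassigned;
    b. identities both exactly 1.0 → origin of the nearest preceding
       assigned window, or ``background`` if none exists yet, flagged
       ``ambiguous_inherited``;
    c. identities equal but below 1.0 → same lookback rule, flagged;
    d. otherwise → the parent with the strictly greater identity.
    """
    if background not in ("recipient", "donor"):
        raise ClassifierError("background must be 'recipient' or 'donor'")
    prev_end = None
    prev_assigned: str | None = None
    calls: list[WindowCall] = []
    for iv, id_r, id_d in scored:
        if prev_end is not None and iv.start < prev_end:
            raise ClassifierError("not tiled: windows overlap or are unordered")
        prev_end = iv.end
        if max(id_r, id_d) < cfg.min_identity:
            origin, flag = "unassigned", False
        elif id_r == id_d:
            origin = prev_assigned if prev_assigned is not None else background
            flag = True
        elif id_r > id_d:
            origin, flag = "recipient", False
        else:
            origin, flag = "donor", False
        if origin in ("recipient", "donor"):
            prev_assigned = origin
        calls.append(WindowCall(iv, id_r, id_d, origin, flag))
    return calls


def paint_genome(
    transconjugant: Genome,
    recipient: Genome,
    donor: Genome,
    cfg: ClassifierConfig = ClassifierConfig(),
    background: str = "recipient",
) -> list[WindowCall]:
    """Tile, score and classify a transconjugant in one call."""
    intervals = tile_windows(len(transconjugant), cfg.window_bp, transconjugant.name)
    if cfg.mode == "aligned":
        scored = _aligned_identities(transconjugant, recipient, donor, intervals)
    else:
        scored = _mapping_identities(
            transconjugant, recipient, donor, intervals, cfg.seed_k
        )
    return classify_windows(scored, cfg, background)


def calls_to_dataframe(calls: Iterable[WindowCall]) -> pd.DataFrame:
    calls = list(calls)
    return pd.DataFrame(
        {
            "genome": [c.interval.genome for c in calls],
            "start": [c.interval.start for c in calls],
            "end": [c.interval.end for c in calls],
            "identity_recipient": [c.identity_recipient for c in calls],
            "identity_donor": [c.identity_donor for c in calls],
            "origin": [c.origin for c in calls],
            "ambiguous_inherited": [c.ambiguous_inherited for c in calls],
        }
    )
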