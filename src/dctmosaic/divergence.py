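"""Pairwise SNV counting and windowed SNV-density tracks.

Lineage-specific single-nucleotide variants are the tracer that makes
mosaic genomes legible: the density of SNVs between two collinear genomes
sets how informative each window is, and pairwise SNV counts arranged as a
symmetric matrix summarize relatedness across a strain panel.

Counting here is defined on aligned collinear sequence: equal-length
genomes compared position by position, or an explicit gapped alignment in
which indel columns are skipped (never counted as SNVs). Positions where
either base is N are ignored.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .io import Genome, Interval


class DivergenceError(ValueError):
    pass


@dataclass(frozen=True)
class VariantTable:
    """Substitution positions distinguishing two collinear genomes.

    Positions are 0-based offsets in the shared coordinate frame; ``base_a``
    and ``base_b`` hold the two alleles, index-aligned with ``positions``.
    """

    positions: tuple[int, ...]
    base_a: str
    base_b: str
    frame: tuple[str, str]

    def __post_init__(self) -> None:
        if not (len(self.positions) == len(self.base_a) == len(self.base_b)):
            raise DivergenceError("positions and alleles must be index-aligned")
        if any(p2 <= p1 for p1, p2 in zip(self.positions, self.positions[1:])):
            raise DivergenceError("positions must be strictly increasing")
        if any(a == b for a, b in zip(self.base_a, self.base_b)):
            raise DivergenceError("alleles must differ at every entry")

    def __len__(self) -> int:
        return len(self.positions)

    def to_dataframe(self) -> pd.DataFrame:
        a, b = self.frame
        return pd.DataFrame(
            {
                "position": self.positions,
                f"base_{a}": list(self.base_a),
                f"base_{b}": list(self.base_b),
            }
        )

    def to_tsv(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric pairwise SNV-count matrix with zero diagonal."""

    names: tuple[str, ...]
    counts: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        if c.shape != (len(self.names), len(self.names)):
            raise DivergenceError("matrix shape does not match names")
        if not np.array_equal(c, c.T) or np.any(np.diag(c) != 0):
            raise DivergenceError("matrix must be symmetric with zero diagonal")

    def __getitem__(self, pair: tuple[str, str]) -> int:
        i = self.names.index(pair[0])
        j = self.names.index(pair[1])
        return int(self.counts[i, j])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.names, columns=self.names)

    def to_tsv(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t")


def _as_bytes(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


_N = ord("N")


def snv_table(a: Genome, b: Genome) -> VariantTable:
    """List every position where two equal-length collinear genomes differ.

    Positions where either base is N are not counted.
    """
    if len(a) != len(b):
        raise DivergenceError(
            f"not collinear: {a.name} ({len(a)} bp) vs {b.name} ({len(b)} bp)"
        )
    arr_a, arr_b = _as_bytes(a.sequence), _as_bytes(b.sequence)
    diff = (arr_a != arr_b) & (arr_a != _N) & (arr_b != _N)
    pos = np.flatnonzero(diff)
    return VariantTable(
        positions=tuple(int(p) for p in pos),
        base_a=arr_a[pos].tobytes().decode(),
        base_b=arr_b[pos].tobytes().decode(),
        frame=(a.name, b.name),
    )


def snv_table_from_alignment(
    aligned_a: str, aligned_b: str, frame: tuple[str, str] = ("a", "b")
) -> VariantTable:
    """SNVs from an explicit gapped alignment of two sequences.

    Columns containing a gap (``-``) in either row are indel columns and are
    skipped. Positions are reported in the ungapped frame of the first
    sequence.
    """
    if len(aligned_a) != len(aligned_b):
        raise DivergenceError("alignment rows differ in length")
    positions, alleles_a, alleles_b = [], [], []
    pos_a = 0
    for ca, cb in zip(aligned_a.upper(), aligned_b.upper()):
        if ca != "-" and cb != "-":
            if ca != cb and ca != "N" and cb != "N":
                positions.append(pos_a)
                alleles_a.append(ca)
                alleles_b.append(cb)
        if ca != "-":
            pos_a += 1
    return VariantTable(
        tuple(positions), "".join(alleles_a), "".join(alleles_b), frame
    )


def snv_matrix(genomes: Sequence[Genome]) -> DistanceMatrix:
    """Pairwise SNV counts for a panel of collinear genomes."""
    n = len(genomes)
    counts = np.zeros((n, n), dtype=int)
    for i in range(n):
        for j in range(i + 1, n):
            counts[i, j] = counts[j, i] = len(snv_table(genomes[i], genomes[j]))
    return DistanceMatrix(tuple(g.name for g in genomes), counts)


def snv_density_track(
    variants: VariantTable, window_bp: int, genome_length: int
) -> list[tuple[Interval, int]]:
    """Per-window variant counts — the data behind an SNV-density bar track.

    Windows are a simple tiling ``[0, w), [w, 2w), ...`` with a final
    partial window covering the tail; counts over all windows sum to the
    table total.
    """
    if window_bp < 1:
        raise DivergenceError("window_bp must be >= 1")
    pos = np.asarray(variants.positions)
    edges = np.arange(0, genome_length + window_bp, window_bp)
    edges[-1] = max(edges[-1], genome_length)
    if edges[-1] > genome_length:
        edges[-1] = genome_length
    counts, _ = np.histogram(pos, bins=edges) if len(edges) > 1 else (np.array([]), None)
    out = []
    for k in range(len(edges) - 1):
        if edges[k + 1] > edges[k]:
            out.append((Interval(int(edges[k]), int(edges[k + 1])), int(counts[k])))
    return out
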