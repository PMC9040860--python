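"""Genome I/O and coordinate conventions.

All intervals in this package are 0-based, half-open ``[start, end)`` —
the BED convention. 1-based coordinates appear only when echoing published
genome positions in human-readable reports, and are labeled as such there.

FASTA reading and writing goes through Biopython; this module adds the
alphabet and identifier contracts the rest of the pipeline relies on.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

VALID_BASES = frozenset("ACGTN")


class GenomeIOError(ValueError):
    """Raised on contract violations while reading or writing genome data."""


@dataclass(frozen=True)
class Genome:
    """A named single-contig nucleotide sequence.

    Parameters
    ----------
    name:
        Nonempty identifier, unique within any loaded set.
    sequence:
        Upper-case nucleotide string over ``{A, C, G, T, N}``.
    topology:
        ``"linear"`` or ``"circular"``. Topology is recorded for provenance
        but windows never wrap the origin: the painting procedure is a
        linear scan over the genome.
    """

    name: str
    sequence: str
    topology: str = "linear"

    def __post_init__(self) -> None:
        if not self.name:
            raise GenomeIOError("genome name must be nonempty")
        if self.topology not in ("linear", "circular"):
            raise GenomeIOError(f"unknown topology {self.topology!r}")
        if len(self.sequence) < 1:
            raise GenomeIOError(f"genome {self.name!r} has empty sequence")

    @property
    def length_bp(self) -> int:
        return len(self.sequence)

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True, order=True)
class Interval:
    """0-based half-open interval on a named genome."""

    start: int
    end: int
    genome: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise GenomeIOError(
                f"invalid interval [{self.start}, {self.end}) on {self.genome!r}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


def _clean_sequence(name: str, raw: str) -> str:
    seq = raw.upper().replace("U", "T")
    bad = set(seq) - VALID_BASES
    if bad:
        offset = next(i for i, c in enumerate(seq) if c in bad)
        raise GenomeIOError(
            f"invalid alphabet: record {name!r} has character "
            f"{seq[offset]!r} at offset {offset}"
        )
    return seq


def read_fasta(path: str | Path, topology: str = "linear") -> list[Genome]:
    """Read a FASTA file into a list of :class:`Genome`.

    Sequences are upper-cased and U is mapped to T; any character outside
    ``{A, C, G, T, N}`` is rejected. Duplicate record identifiers and empty
    files are errors.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise GenomeIOError(f"no records in {path}")
    genomes: list[Genome] = []
    seen: set[str] = set()
    for rec in records:
        if rec.id in seen:
            raise GenomeIOError(f"duplicate identifier {rec.id!r} in {path}")
        seen.add(rec.id)
        genomes.append(Genome(rec.id, _clean_sequence(rec.id, str(rec.seq)), topology))
    return genomes


def read_genome(path: str | Path, topology: str = "linear") -> Genome:
    """Read a FASTA file expected to hold exactly one record."""
    genomes = read_fasta(path, topology)
    if len(genomes) != 1:
        raise GenomeIOError(f"expected one record in {path}, found {len(genomes)}")
    return genomes[0]


def write_fasta(genomes: Iterable[Genome], path: str | Path, width: int = 70) -> None:
    records = [
        SeqRecord(Seq(g.sequence), id=g.name, description="") for g in genomes
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


def write_bed(segments: Sequence, path: str | Path) -> None:
    """Write tiling segments as BED6.

    ``chrom`` is the genome name, ``name`` the origin label, ``score`` the
    mean window identity scaled to [0, 1000], strand ``"."``. Segments must
    all refer to one genome and tile it disjointly (sorted, non-overlapping).
    """
    segs = list(segments)
    with open(path, "w") as fh:
        fh.write("# chrom\tstart\tend\torigin\tscore\tstrand\n")
        prev_end = None
        prev_chrom = None
        for seg in sorted(segs, key=lambda s: s.interval.start):
            iv = seg.interval
            if prev_chrom is not None and iv.genome != prev_chrom:
                raise GenomeIOError("overlap: segments span multiple genomes")
            if prev_end is not None and iv.start < prev_end:
                raise GenomeIOError(
                    f"overlap: segment [{iv.start}, {iv.end}) overlaps previous"
                )
            prev_end, prev_chrom = iv.end, iv.genome
            ident = getattr(seg, "mean_identity", None)
            score = 0 if ident is None else int(round(max(0.0, min(1.0, ident)) * 1000))
            fh.write(
                f"{iv.genome}\t{iv.start}\t{iv.end}\t{seg.origin}\t{score}\t.\n"
            )


@dataclass(frozen=True)
class BedRecord:
    interval: Interval
    origin: str
    score: int


def read_bed(path: str | Path) -> list[BedRecord]:
    """Parse a BED6 file written by :func:`write_bed` back into records."""
    out: list[BedRecord] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            chrom, start, end, name, score, _strand = line.split("\t")[:6]
            out.append(
                BedRecord(Interval(int(start), int(end), chrom), name, int(score))
            )
    return out
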