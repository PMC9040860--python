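"""Locus-level comparisons: protein percent identity and SNV catalogs.

Mating compatibility in M. smegmatis tracks with the polymorphic *mid*
genes inside the *esx1* secretion locus: strains whose *mid* regions are
identical recognize each other as kin and do not conjugate. Two kinds of
evidence quantify this. First, global amino-acid percent identity between
ortholog pairs — core *esx1* proteins are highly conserved (>96.6%)
while Mid orthologs fall below ~35%. Second, nucleotide-level SNV catalogs
over a locus: near-identical loci (e.g., a shared >33-kb *esx1* region
carrying only 2 substitutions) imply recent common ancestry or exchange.

Protein identity uses a global affine-gap alignment (BLOSUM62, gap open
10, extend 0.5) with **all alignment columns, gaps included, in the
denominator** — a conservative convention that makes low identities
comparable across tools. Locus SNV cataloging uses an indel-tolerant
global nucleotide alignment and skips indel columns.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import edlib
from Bio.Align import PairwiseAligner, substitution_matrices
from Bio.Seq import Seq

from .io import Interval

PROTEIN_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX")


class LocusError(ValueError):
    pass


@dataclass(frozen=True)
class ProteinPair:
    name_a: str
    name_b: str
    seq_a: str
    seq_b: str

    def __post_init__(self) -> None:
        for label, seq in (("a", self.seq_a), ("b", self.seq_b)):
            if not seq:
                raise LocusError(f"empty protein (sequence {label})")
            bad = set(seq.upper()) - PROTEIN_ALPHABET
            if bad:
                raise LocusError(
                    f"non-standard residues {sorted(bad)} in sequence {label}"
                )


@dataclass(frozen=True)
class IdentityResult:
    percent_identity: float  # 0-100, 1 decimal
    matches: int
    alignment_columns: int


def _aligner(gap_open: float, gap_extend: float) -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -abs(gap_open)
    aligner.extend_gap_score = -abs(gap_extend)
    return aligner


def global_identity(
    pair: ProteinPair, gap_open: float = 10.0, gap_extend: float = 0.5
) -> IdentityResult:
    """Global percent identity of a protein pair under affine-gap alignment.

    Identity = identical aligned residue pairs / total alignment columns
    (gap columns included in the denominator).
    """
    aligner = _aligner(gap_open, gap_extend)
    alignment = aligner.align(pair.seq_a.upper(), pair.seq_b.upper())[0]
    counts = alignment.counts()
    columns = counts.gaps + counts.identities + counts.mismatches
    pct = round(100.0 * counts.identities / columns, 1)
    return IdentityResult(pct, counts.identities, columns)


@dataclass(frozen=True)
class Feature:
    """A GFF-like annotation on the first locus's coordinate frame.

    ``interval`` is 0-based half-open; ``strand`` is ``+`` or ``-``;
    ``cds=True`` means the interval is a reading frame starting at
    ``interval.start`` (+) or ending at ``interval.end`` (-).
    """

    name: str
    interval: Interval
    strand: str = "+"
    cds: bool = True


@dataclass(frozen=True)
class LocusSNV:
    """One substitution between two aligned loci.

    ``position_a``/``position_b`` are 0-based offsets in each ungapped
    locus; human-readable reports print them 1-based (labeled).
    """

    position_a: int
    position_b: int
    base_a: str
    base_b: str
    feature: str
    coding_effect: str  # silent | missense | noncoding | unknown


def _codon_effect(
    locus_a: str, locus_b_base: str, pos_a: int, feature: Feature
) -> str:
    iv = feature.interval
    if feature.strand == "+":
        offset = pos_a - iv.start
        codon_start = iv.start + 3 * (offset // 3)
        codon_a = locus_a[codon_start : codon_start + 3]
        in_codon = pos_a - codon_start
    else:
        offset = iv.end - 1 - pos_a
        codon_end = iv.end - 3 * (offset // 3)
        codon_a = locus_a[codon_end - 3 : codon_end]
        in_codon = pos_a - (codon_end - 3)
    if len(codon_a) != 3:
        return "unknown"
    codon_b = codon_a[:in_codon] + locus_b_base + codon_a[in_codon + 1 :]
    if feature.strand == "-":
        codon_a = str(Seq(codon_a).reverse_complement())
        codon_b = str(Seq(codon_b).reverse_complement())
    aa_a = str(Seq(codon_a).translate())
    aa_b = str(Seq(codon_b).translate())
    return "silent" if aa_a == aa_b else "missense"


def locus_snv_report(
    locus_a: str,
    locus_b: str,
    features: Optional[Sequence[Feature]] = None,
    min_identity: float = 0.8,
) -> list[LocusSNV]:
    """Catalog substitutions between two near-identical loci.

    The loci are globally aligned (indel-tolerant); indel columns are
    skipped. Each substitution is annotated with the overlapping feature
    and, when the feature provides a reading frame, its coding effect.
    Raises if alignment identity falls below ``min_identity``.
    """
    a, b = locus_a.upper(), locus_b.upper()
    if a == b:
        return []
    res = edlib.align(a, b, mode="NW", task="path")
    dist = res["editDistance"]
    longest = max(len(a), len(b))
    if 1.0 - dist / longest < min_identity:
        raise LocusError(
            "loci too diverged for SNV cataloging "
            f"(identity {1.0 - dist / longest:.3f} < {min_identity})"
        )
    snvs: list[LocusSNV] = []
    pos_a = pos_b = 0
    for n, op in _iter_cigar(res["cigar"]):
        if op == "=":
            pos_a += n
            pos_b += n
        elif op == "X":
            for i in range(n):
                base_a, base_b = a[pos_a], b[pos_b]
                if base_a != "N" and base_b != "N":
                    feature, effect = _annotate(a, base_b, pos_a, features)
                    snvs.append(
                        LocusSNV(pos_a, pos_b, base_a, base_b, feature, effect)
                    )
                pos_a += 1
                pos_b += 1
        elif op == "I":  # present in query (a) only
            pos_a += n
        elif op == "D":  # present in target (b) only
            pos_b += n
    return snvs


def _annotate(
    locus_a: str, base_b: str, pos_a: int, features: Optional[Sequence[Feature]]
) -> tuple[str, str]:
    if features is None:
        return "", "unknown"
    for feat in features:
        if feat.interval.start <= pos_a < feat.interval.end:
            if feat.cds:
                return feat.name, _codon_effect(locus_a, base_b, pos_a, feat)
            return feat.name, "noncoding"
    return "", "noncoding"


def _iter_cigar(cigar: str):
    n = ""
    for ch in cigar:
        if ch.isdigit():
            n += ch
        else:
            yield int(n), ch
            n = ""


def mid_identical(
    locus_a: str, locus_b: str, mid_interval: Interval
) -> bool:
    """True when the designated *mid* interval carries no substitutions.

    Identical *mid* regions mark two strains as kin — the genetic
    prediction is that such a pair is conjugally incompatible.
    """
    sub_a = locus_a[mid_interval.start : mid_interval.end]
    report = locus_snv_report(locus_a, locus_b)
    return not any(
        mid_interval.start <= s.position_a < mid_interval.end for s in report
    ) and len(sub_a) > 0


def min_core_identity(
    pairs: Sequence[ProteinPair], exclude: Sequence[str] = ()
) -> tuple[float, str]:
    """Minimum global percent identity over ortholog pairs, with exclusions.

    Returns ``(identity, pair_name)`` for the least-conserved included
    pair — the statistic behind "all core proteins > X% identical".
    """
    if not pairs:
        raise LocusError("no protein pairs supplied")
    best: tuple[float, str] | None = None
    excluded = {e.lower() for e in exclude}
    for pair in pairs:
        if pair.name_a.lower() in excluded or pair.name_b.lower() in excluded:
            continue
        result = global_identity(pair)
        if best is None or result.percent_identity < best[0]:
            best = (result.percent_identity, pair.name_a)
    if best is None:
        raise LocusError("all pairs excluded")
    return best
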