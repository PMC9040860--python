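import numpy as np
import pytest
from Bio.Align import substitution_matrices

from dctmosaic import (
    Feature,
    Interval,
    ProteinPair,
    global_identity,
    locus_snv_report,
    mid_identical,
    min_core_identity,
)
from dctmosaic.locus import LocusError

AA = "ACDEFGHIKLMNPQRSTVWY"


def gotoh_score(a: str, b: str, open_pen: float = 10.0, ext_pen: float = 0.5) -> float:
    """Independent affine-gap global alignment score (Gotoh DP, BLOSUM62).

    A gap of length k costs open + (k-1)*extend, matching the aligner's
    convention.
    """
    blosum = substitution_matrices.load("BLOSUM62")
    n, m = len(a), len(b)
    NEG = -1e9
    M = np.full((n + 1, m + 1), NEG)
    X = np.full((n + 1, m + 1), NEG)  # gap in b (a consumed)
    Y = np.full((n + 1, m + 1), NEG)  # gap in a
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        X[i, 0] = -open_pen - ext_pen * (i - 1)
    for j in range(1, m + 1):
        Y[0, j] = -open_pen - ext_pen * (j - 1)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = blosum[a[i - 1], b[j - 1]]
            best_prev = max(M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1])
            M[i, j] = best_prev + s
            X[i, j] = max(M[i - 1, j] - open_pen, X[i - 1, j] - ext_pen,
                          Y[i - 1, j] - open_pen)
            Y[i, j] = max(M[i, j - 1] - open_pen, Y[i, j - 1] - ext_pen,
                          X[i, j - 1] - open_pen)
    return max(M[n, m], X[n, m], Y[n, m])


class TestGlobalIdentity:
    def test_identical_sequences(self):
        r = global_identity(ProteinPair("a", "b", "MKVLAW", "MKVLAW"))
        assert r.percent_identity == 100.0
        assert r.matches == r.alignment_columns == 6

    def test_single_substitution_arithmetic(self):
        r = global_identity(ProteinPair("a", "b", "AAAA", "AAAT"))
        assert r.percent_identity == 75.0
        assert (r.matches, r.alignment_columns) == (3, 4)

    def test_empty_protein_rejected(self):
        with pytest.raises(LocusError, match="empty protein"):
            ProteinPair("a", "b", "", "MKV")

    def test_planted_substitutions_against_dp_oracle(self):
        """A 200-residue pair with 10 substitutions scores 95.0% and the
        alignment score matches an independent Gotoh DP."""
        rng = np.random.default_rng(17)
        seq_a = "".join(AA[i] for i in rng.integers(0, 20, 200))
        seq_b = list(seq_a)
        for pos in rng.choice(200, 10, replace=False):
            seq_b[pos] = AA[(AA.index(seq_b[pos]) + 7) % 20]
        pair = ProteinPair("a", "b", seq_a, "".join(seq_b))
        r = global_identity(pair)
        assert r.percent_identity == 95.0
        assert (r.matches, r.alignment_columns) == (190, 200)

        from dctmosaic.locus import _aligner

        aligner = _aligner(10, 0.5)
        assert aligner.score(seq_a, "".join(seq_b)) == pytest.approx(
            gotoh_score(seq_a, "".join(seq_b))
        )

    def test_indel_pair_score_matches_dp_oracle(self):
        rng = np.random.default_rng(23)
        seq_a = "".join(AA[i] for i in rng.integers(0, 20, 80))
        seq_b = seq_a[:30] + seq_a[36:]  # 6-residue deletion
        from dctmosaic.locus import _aligner

        aligner = _aligner(10, 0.5)
        assert aligner.score(seq_a, seq_b) == pytest.approx(
            gotoh_score(seq_a, seq_b)
        )
        r = global_identity(ProteinPair("a", "b", seq_a, seq_b))
        assert r.alignment_columns == 80  # gaps count in the denominator
        assert r.matches == 74

    def test_symmetric_in_arguments(self):
        rng = np.random.default_rng(5)
        a = "".join(AA[i] for i in rng.integers(0, 20, 60))
        b = "".join(AA[i] for i in rng.integers(0, 20, 60))
        fwd = global_identity(ProteinPair("a", "b", a, b))
        rev = global_identity(ProteinPair("b", "a", b, a))
        assert fwd.percent_identity == rev.percent_identity

    def test_invariant_under_joint_reversal(self):
        rng = np.random.default_rng(6)
        a = "".join(AA[i] for i in rng.integers(0, 20, 60))
        b = list(a)
        for pos in rng.choice(60, 6, replace=False):
            b[pos] = AA[(AA.index(b[pos]) + 3) % 20]
        b = "".join(b)
        fwd = global_identity(ProteinPair("a", "b", a, b))
        rev = global_identity(ProteinPair("a", "b", a[::-1], b[::-1]))
        assert fwd.percent_identity == rev.percent_identity


def _synthetic_locus(rng, length=33_000):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, length))


class TestLocusSnvReport:
    def test_identical_loci_empty(self):
        rng = np.random.default_rng(2)
        locus = _synthetic_locus(rng, 5_000)
        assert locus_snv_report(locus, locus) == []

    def test_two_planted_snvs_with_coding_effects(self):
        """A 33-kb locus pair differing by one silent and one missense
        substitution inside annotated reading frames."""
        rng = np.random.default_rng(8)
        locus_a = list(_synthetic_locus(rng, 33_000))
        # gene1 on [1200, 2400): codon GCT (Ala) at 1500 -> GCC (Ala), silent
        locus_a[1500:1503] = "GCT"
        locus_b = locus_a.copy()
        locus_b[1502] = "C"
        # gene2 on [9000, 10500): codon CGG (Arg) at 9300 -> CCG (Pro), missense
        locus_a[9300:9303] = "CGG"
        locus_b[9300:9303] = "CGG"
        locus_b[9301] = "C"
        features = [
            Feature("gene1", Interval(1_200, 2_400), "+"),
            Feature("gene2", Interval(9_000, 10_500), "+"),
        ]
        report = locus_snv_report("".join(locus_a), "".join(locus_b), features)
        assert len(report) == 2
        by_feature = {s.feature: s for s in report}
        assert by_feature["gene1"].coding_effect == "silent"
        assert by_feature["gene2"].coding_effect == "missense"
        assert by_feature["gene2"].position_a == 9_301
        assert (by_feature["gene2"].base_a, by_feature["gene2"].base_b) == ("G", "C")

    def test_minus_strand_effect(self):
        # reverse strand gene: genomic GCT at [0,3) read as AGC (Ser);
        # substituting genomic offset 0 G->T gives AGA (Arg): missense
        report = locus_snv_report(
            "GCTAAA", "TCTAAA", [Feature("rev", Interval(0, 3), "-")]
        )
        assert len(report) == 1
        assert report[0].coding_effect == "missense"

    def test_snv_without_features_is_unknown(self):
        report = locus_snv_report("ACGTACGT", "ACGTACTT")
        assert [s.coding_effect for s in report] == ["unknown"]

    def test_indels_tolerated_and_not_counted(self):
        rng = np.random.default_rng(9)
        locus_a = _synthetic_locus(rng, 4_000)
        locus_b = locus_a[:2_000] + locus_a[2_010:]  # 10-bp deletion
        assert locus_snv_report(locus_a, locus_b) == []

    def test_diverged_loci_rejected(self):
        rng = np.random.default_rng(10)
        a = _synthetic_locus(rng, 2_000)
        b = _synthetic_locus(rng, 2_000)
        with pytest.raises(LocusError, match="too diverged"):
            locus_snv_report(a, b)


class TestMidIdentity:
    def test_identical_mid_flags_kin(self):
        rng = np.random.default_rng(11)
        locus = _synthetic_locus(rng, 10_000)
        other = locus[:200] + ("A" if locus[200] != "A" else "C") + locus[201:]
        # substitution at 200 lies outside the designated mid interval
        assert mid_identical(locus, other, Interval(5_000, 8_000))
        assert not mid_identical(locus, other, Interval(100, 300))


class TestMinCoreIdentity:
    def test_excludes_polymorphic_pairs(self):
        rng = np.random.default_rng(12)
        core = "".join(AA[i] for i in rng.integers(0, 20, 100))
        near = core[:2] + ("A" if core[2] != "A" else "C") + core[3:]
        diverged = "".join(AA[i] for i in rng.integers(0, 20, 100))
        pairs = [
            ProteinPair("eccA", "eccA", core, near),
            ProteinPair("mid0070", "mid0070", core, diverged),
        ]
        ident, name = min_core_identity(pairs, exclude=["mid0070"])
        assert name == "eccA"
        assert ident == 99.0
        ident_all, name_all = min_core_identity(pairs)
        assert name_all == "mid0070"
        assert ident_all < 50.0
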